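"""End-to-end pipeline: event lists -> peaks -> titration table -> global fit."""

from __future__ import annotations

import warnings

import pandas as pd

from .assembly import AssemblyParams
from .deconvolution import CalibrationModel, counts_to_concentrations, deconvolve
from .fitting import RingAssemblyModel, RingAssemblyResults

__all__ = ["titration_from_events", "analyze_titration"]


def titration_from_events(
    events_list,
    monomer_mass: float,
    calib: CalibrationModel,
    max_components: int = 12,
    n_max: int = 25,
) -> pd.DataFrame:
    """Deconvolve each reading and convert counts to species concentrations.

    Each reading must carry its nominal concentration in the metadata.
    Readings whose deconvolution fails are skipped with a warning.
    """
    rows = []
    peaksets = []
    for ev in events_list:
        if ev.concentration_nM is None:
            raise ValueError("event list lacks a nominal concentration")
        try:
            peaks = deconvolve(
                ev, monomer_mass, calib, max_components=max_components, n_max=n_max
            )
            rows.append(
                counts_to_concentrations(
                    peaks, ev.concentration_nM, replicate=ev.replicate
                )
            )
            peaksets.append(peaks)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(
                f"skipping reading at {ev.concentration_nM} nM "
                f"(replicate {ev.replicate}): {exc}"
            )
    if not rows:
        raise RuntimeError("no reading could be deconvolved")
    table = pd.concat(rows, ignore_index=True)
    table.attrs["peaksets"] = peaksets
    return table


def analyze_titration(
    events_list,
    monomer_mass: float,
    calib: CalibrationModel,
    start_params: AssemblyParams | None = None,
    max_components: int = 12,
    n_max: int = 25,
    seed: int = 0,
    n_starts: int = 10,
    n_boot: int = 0,
) -> tuple[pd.DataFrame, RingAssemblyResults]:
    """Run the full analysis and return (titration table, fit results)."""
    table = titration_from_events(
        events_list, monomer_mass, calib, max_components=max_components, n_max=n_max
    )
    model = RingAssemblyModel(table, n_max=n_max)
    results = model.fit(
        start_params=start_params, seed=seed, n_starts=n_starts, n_boot=n_boot
    )
    return table, results
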