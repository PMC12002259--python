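"""Seeded synthetic-data generators for every input the pipeline reads.

Mass-photometry event lists are drawn from the equilibrium species
distribution of the assembly model: each landing event picks a species
with probability proportional to its particle concentration, takes its
ideal mass (protomer count times monomer mass), and adds Gaussian
measurement noise whose SD follows the instrument calibration line.
Events falling below the lower detection limit are discarded and not
replaced, mimicking real count loss.  Hill binding curves and
exponential annealing time courses get additive Gaussian noise.

Defaults mirror the study conditions: 60-s readings of ~2000 events,
four replicates, a titration over 10-200 nM, a 40 kDa detection floor,
and the fitted full-length-protein parameters as ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import AssemblyParams, RAD52_FITTED, equilibrium_distribution
from .deconvolution import CalibrationModel
from .io import EventList
from .kinetics import hill_curve

__all__ = [
    "DEFAULT_CALIBRATION",
    "RAD52_MONOMER_KDA",
    "RAD52_209_MONOMER_KDA",
    "SimulationSpec",
    "simulate_events",
    "simulate_titration",
    "simulate_binding_curve",
    "simulate_annealing",
]

#: sequence masses of the full-length protein and the C-terminal truncation
RAD52_MONOMER_KDA = 48.4
RAD52_209_MONOMER_KDA = 25.3

#: synthetic instrument calibration: peak SD grows linearly with mass
#: (e.g. 10 kDa at 100 kDa, 20 kDa at 300 kDa), 40 kDa detection floor
DEFAULT_CALIBRATION = CalibrationModel(
    sd_slope=0.05, sd_intercept=5.0, mass_min=40.0, mass_max=5000.0
)

#: concentrations (nM) of the titration series
DEFAULT_CONCENTRATIONS = (10.0, 25.0, 50.0, 100.0, 200.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth and acquisition settings for a synthetic titration."""

    params: AssemblyParams = RAD52_FITTED
    monomer_mass: float = RAD52_MONOMER_KDA
    concentrations: tuple = DEFAULT_CONCENTRATIONS
    events_per_reading: int = 2000
    replicates: int = 4
    calib: CalibrationModel = DEFAULT_CALIBRATION
    cluster_fraction: float = 0.0  # ring-cluster contaminant events
    seed: int = 0

    def __post_init__(self) -> None:
        if self.events_per_reading <= 0:
            raise ValueError("events_per_reading must be > 0")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be > 0")
        if not 0 <= self.cluster_fraction < 1:
            raise ValueError("cluster_fraction must be in [0, 1)")

    def truth(self) -> dict:
        p = self.params
        return {
            "kd_nM": p.kd,
            "kc0": p.kc0,
            "n_opt": p.n_opt,
            "sigma_ring": p.sigma_ring,
            "monomer_mass_kDa": self.monomer_mass,
            "concentrations_nM": list(self.concentrations),
            "events_per_reading": self.events_per_reading,
            "replicates": self.replicates,
            "calibration": {
                "sd_slope": self.calib.sd_slope,
                "sd_intercept": self.calib.sd_intercept,
                "mass_min_kDa": self.calib.mass_min,
                "mass_max_kDa": self.calib.mass_max,
            },
            "cluster_fraction": self.cluster_fraction,
            "seed": self.seed,
        }


def simulate_events(
    spec: SimulationSpec,
    c_total: float,
    replicate: int = 0,
    rng: np.random.Generator | None = None,
) -> EventList:
    """Draw one mass-photometry reading at one total concentration.

    Species are sampled in proportion to their particle concentrations;
    optional contaminant events at 2x and 3x the optimal ring mass
    emulate ring clusters.  Sub-detection-limit events are discarded and
    recorded in the metadata, not replaced.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, int(round(c_total * 1000)), replicate])
        )
    dist = equilibrium_distribution(c_total, spec.params)
    sizes = dist.sizes
    weights = np.array([dist.species(int(n)) for n in sizes])
    ideal = sizes * spec.monomer_mass
    if spec.cluster_fraction > 0:
        ring_mass = round(spec.params.n_opt) * spec.monomer_mass
        ideal = np.concatenate([ideal, [2 * ring_mass, 3 * ring_mass]])
        w_clusters = weights.sum() * spec.cluster_fraction / (1 - spec.cluster_fraction)
        weights = np.concatenate([weights, [0.6 * w_clusters, 0.4 * w_clusters]])
    if weights.sum() <= 0:
        warnings.warn("all species at zero concentration; empty event list")
        drawn = np.empty(0)
    else:
        p = weights / weights.sum()
        true_mass = rng.choice(ideal, size=spec.events_per_reading, p=p)
        drawn = true_mass + rng.normal(0.0, spec.calib.sd(true_mass))
    keep = drawn >= spec.calib.mass_min
    retained = drawn[keep]
    if retained.size == 0 and drawn.size:
        warnings.warn("all simulated events fell below the detection limit")
    return EventList(
        masses=retained,
        concentration_nM=float(c_total),
        duration_s=60.0,
        replicate=replicate,
        n_discarded=int(drawn.size - retained.size),
        meta={"seed": spec.seed},
    )


def simulate_titration(spec: SimulationSpec) -> list:
    """All readings of a titration: one EventList per (conc, replicate)."""
    return [
        simulate_events(spec, c, replicate=r)
        for c in spec.concentrations
        for r in range(spec.replicates)
    ]


def simulate_binding_curve(
    kd_app: float,
    hill: float,
    concs,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Hill binding curve with additive Gaussian noise, clipped to [0, 1]."""
    if kd_app <= 0 or hill <= 0:
        raise ValueError("kd_app and hill must be > 0")
    concs = np.asarray(concs, dtype=float)
    rng = np.random.default_rng(seed)
    theta = hill_curve(concs, kd_app, hill)
    noisy = theta + rng.normal(0.0, noise_sd, size=concs.size) if noise_sd else theta
    se = np.full(concs.size, max(noise_sd, 1e-6))
    return pd.DataFrame(
        {"conc_nM": concs, "fraction_bound": np.clip(noisy, 0.0, 1.0), "se": se}
    )


def simulate_annealing(
    k: float,
    amplitude: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-exponential annealing time course P(t) = A*(1 - exp(-k t))."""
    if k < 0:
        raise ValueError("rate k must be >= 0")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    p = amplitude * (1.0 - np.exp(-k * times))
    if noise_sd:
        p = p + rng.normal(0.0, noise_sd, size=times.size)
    return pd.DataFrame({"t_min": times, "product_fraction": p})
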