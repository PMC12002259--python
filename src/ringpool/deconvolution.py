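"""Mass-photometry histogram deconvolution.

A mass-photometry experiment yields one calibrated mass per landing
event.  Oligomer abundances are recovered by fitting a sum of Gaussian
components to the binned mass histogram, with component centers
initialized at integer multiples of the monomer mass and SDs bounded
above by an instrument calibration line (peak SD grows linearly with
molecular weight; narrower peaks are allowed, wider ones are not).  The
number of components is chosen by the Akaike information criterion,
minor components (<2% of the fitted area) are pruned, and each retained
peak is assigned the protomer count nearest its center.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares
from scipy.special import ndtr

from .io import EventList

__all__ = [
    "CalibrationModel",
    "fit_sd_calibration",
    "Peak",
    "PeakSet",
    "deconvolve",
    "select_components",
    "counts_to_concentrations",
    "aic_least_squares",
]

#: fraction of total fitted area below which a peak is discarded
PRUNE_FRACTION = 0.02


@dataclass(frozen=True)
class CalibrationModel:
    """Linear mass -> expected-peak-SD calibration with detection limits.

    ``sd(m) = sd_slope*m + sd_intercept`` (kDa); valid over
    [mass_min, mass_max], where mass_min is the instrument's lower
    detection limit and mass_max its upper calibration limit.
    """

    sd_slope: float
    sd_intercept: float
    mass_min: float = 40.0
    mass_max: float = 5000.0
    residuals: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.mass_min < self.mass_max:
            raise ValueError("require mass_min < mass_max")
        if self.sd(self.mass_min) <= 0 or self.sd(self.mass_max) <= 0:
            raise ValueError("calibration SD must be positive over its range")

    def sd(self, mass):
        """Expected (maximum) peak SD at a given mass, kDa."""
        return self.sd_slope * np.asarray(mass, dtype=float) + self.sd_intercept


def fit_sd_calibration(
    points, mass_min: float = 40.0, mass_max: float = 5000.0
) -> CalibrationModel:
    """OLS line through (mass, peak SD) calibration-standard points.

    The line is an upper bound for sample peaks: a well-defined oligomer
    can be narrower than the calibration standards, never wider.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (mass, sd) pairs")
    masses, sds = pts[:, 0], pts[:, 1]
    if np.unique(masses).size < 2:
        raise ValueError("need >= 2 distinct masses to fit the SD line")
    res = sm.OLS(sds, sm.add_constant(masses)).fit()
    intercept, slope = res.params
    return CalibrationModel(
        sd_slope=float(slope),
        sd_intercept=float(intercept),
        mass_min=mass_min,
        mass_max=mass_max,
        residuals=tuple(float(r) for r in res.resid),
    )


@dataclass(frozen=True)
class Peak:
    center: float  # kDa
    sd: float  # kDa
    area: float  # events
    area_fraction: float
    assigned_n: int | None  # protomer count; None for ring clusters
    label: str


@dataclass
class PeakSet:
    """Retained Gaussian components of a deconvolved mass histogram."""

    peaks: list
    n_components: int
    aic_table: pd.DataFrame
    monomer_mass: float
    residual_norm: float
    n_events: int

    @property
    def aic(self) -> float:
        sel = self.aic_table[self.aic_table["k"] == self.n_components]
        return float(sel["aic"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "center_kDa": p.center,
                    "sd_kDa": p.sd,
                    "area": p.area,
                    "area_fraction": p.area_fraction,
                    "assigned_n": p.assigned_n,
                    "label": p.label,
                }
                for p in self.peaks
            ]
        )

    def summary(self) -> str:
        lines = [
            f"Mass-histogram deconvolution: {len(self.peaks)} retained peaks "
            f"(k={self.n_components} by AIC, {self.n_events} events)",
            f"{'label':<12}{'center kDa':>12}{'SD kDa':>10}{'area %':>9}",
        ]
        for p in self.peaks:
            lines.append(
                f"{p.label:<12}{p.center:>12.1f}{p.sd:>10.1f}"
                f"{100 * p.area_fraction:>9.1f}"
            )
        return "\n".join(lines)


def aic_least_squares(n_obs: int, rss: float, n_params: int) -> float:
    """AIC for an unweighted least-squares fit: N*ln(RSS/N) + 2p."""
    return n_obs * math.log(max(rss, 1e-300) / n_obs) + 2 * n_params


def aic_weighted(chi2: float, n_params: int, n_obs: int | None = None) -> float:
    """AIC (up to a constant) for variance-weighted least squares.

    With per-bin Poisson variances the weighted RSS is the chi-square
    statistic and -2*loglik = chi2 + const, so AIC = chi2 + 2p.  Unlike
    the unweighted N*ln(RSS/N) form this is insensitive to how many
    empty bins the histogram range happens to contain.  When ``n_obs``
    (the number of informative bins) is given, the small-sample AICc
    correction 2p(p+1)/(n-p-1) is added.
    """
    aic = chi2 + 2 * n_params
    if n_obs is not None:
        if n_obs <= n_params + 1:
            return np.inf
        aic += 2.0 * n_params * (n_params + 1) / (n_obs - n_params - 1)
    return aic


def select_components(fits, tie_tol: float = 1e-9) -> int:
    """Pick the component count with minimal AIC, ties toward smaller k.

    ``fits`` is an iterable of (k, aic) pairs; an AIC improvement smaller
    than ``tie_tol`` does not justify extra components.
    """
    fits = sorted(fits)
    if not fits:
        raise ValueError("no successful fits to select from")
    best_k, best_aic = fits[0]
    for k, aic in fits[1:]:
        if aic < best_aic - tie_tol:
            best_k, best_aic = k, aic
    return best_k


def _mixture_counts(theta, edges, k):
    # expected counts per bin: area times the Gaussian mass in the bin
    centers = theta[0::3][:k, None]
    sds = theta[1::3][:k, None]
    areas = theta[2::3][:k, None]
    cdf = ndtr((edges[None, :] - centers) / sds)
    return np.sum(areas * np.diff(cdf, axis=1), axis=0)


def deconvolve(
    events: EventList,
    monomer_mass: float,
    calib: CalibrationModel,
    max_components: int = 12,
    bin_width: float = 4.0,
    n_max: int = 25,
    prune_fraction: float = PRUNE_FRACTION,
) -> PeakSet:
    """Decompose an event-mass histogram into oligomer peaks.

    For each candidate component count k the histogram is fitted by
    bounded least squares with centers initialized at the k most
    populated integer multiples of ``monomer_mass`` (each confined to
    +/-0.45 monomer masses of its multiple so peak identity cannot
    swap), SDs bounded above by the calibration line, and nonnegative
    areas.  Residuals are Pearson-weighted (1/sqrt(max(count, 1))) so
    the Poisson bin noise is homoscedastic and the least-squares AIC is
    calibrated.  k is selected by AIC; components below
    ``prune_fraction`` of the fitted area are then removed and fractions
    renormalized.
    """
    if monomer_mass <= 0:
        raise ValueError("monomer_mass must be > 0")
    masses = np.asarray(events.masses, dtype=float)
    masses = masses[(masses >= calib.mass_min) & (masses <= calib.mass_max)]
    if masses.size < 50:
        raise ValueError(
            f"need >= 50 events within the detection range, got {masses.size}"
        )
    edges = np.arange(calib.mass_min, masses.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(masses, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sqrtw = 1.0 / np.sqrt(np.maximum(counts, 1.0))

    # candidate components live at integer multiples of the monomer mass;
    # components are added greedily where the residual histogram mass is
    # largest (matching pursuit), warm-starting each k from the k-1 fit
    j_max = int(np.ceil(masses.max() / monomer_mass))
    multiples = {
        j: j * monomer_mass
        for j in range(1, j_max + 1)
        if calib.mass_min - 0.45 * monomer_mass <= j * monomer_mass
    }

    def residual_mass(theta, k, j):
        mu = multiples[j]
        resid = counts - (
            _mixture_counts(theta, edges, k) if k else 0.0
        )
        win = np.abs(centers - mu) <= 0.5 * monomer_mass
        return float(np.clip(resid[win], 0.0, None).sum())

    def comp_bounds(j):
        mu = multiples[j]
        c_lo = max(mu - 0.45 * monomer_mass, calib.mass_min)
        c_hi = mu + 0.45 * monomer_mass
        sd_hi = float(calib.sd(mu))  # provisional; tightened self-consistently
        return c_lo, c_hi, sd_hi

    def fit_k(theta0, lo, hi, k):
        def run(th0, hi_arr):
            return least_squares(
                lambda th: (
                    _mixture_counts(th, edges, k) - counts
                ) * sqrtw,
                np.clip(th0, lo, hi_arr),
                bounds=(lo, hi_arr),
                xtol=1e-10,
                ftol=1e-10,
                max_nfev=500,
            )

        hi_arr = np.array(hi, dtype=float)
        sol = run(theta0, hi_arr)
        # the SD bound must hold at the *fitted* center: if a center moved
        # down-mass past its bound, tighten and refit
        for _ in range(2):
            viol = False
            for i in range(k):
                limit = float(calib.sd(sol.x[3 * i]))
                if sol.x[3 * i + 1] > limit + 1e-9:
                    hi_arr[3 * i + 1] = limit
                    viol = True
            if not viol:
                break
            sol = run(sol.x, hi_arr)
        return sol

    # stepwise forward selection: a component is only kept if it improves
    # the AIC itself, which keeps near-degenerate neighbor components of a
    # single broad peak out of the model
    fits = {}
    chosen: list = []
    theta_prev = np.empty(0)
    lo_prev: list = []
    hi_prev: list = []
    best_aic = np.inf
    for k in range(1, min(max_components, len(multiples)) + 1):
        free = [j for j in multiples if j not in chosen]
        if not free:
            break
        gains = {j: residual_mass(theta_prev, k - 1, j) for j in free}
        candidates = sorted(free, key=lambda j: (-gains[j], j))[:3]
        accepted = False
        for j_new in candidates:
            if gains[j_new] <= 0 and k > 1:
                continue
            c_lo, c_hi, sd_hi = comp_bounds(j_new)
            sd0 = min(float(calib.sd(multiples[j_new])), sd_hi)
            a0 = max(gains[j_new], 1.0)
            # no physical lower SD bound: a well-defined oligomer may be
            # narrower than the calibration standards
            theta0 = np.concatenate([theta_prev, [multiples[j_new], sd0, a0]])
            lo = lo_prev + [c_lo, 0.5, 0.0]
            hi = hi_prev + [c_hi, sd_hi, 10.0 * masses.size]
            try:
                sol = fit_k(theta0, lo, hi, k)
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"mixture fit failed for k={k}: {exc}")
                continue
            aic = aic_weighted(
                float(2.0 * sol.cost), 3 * k, n_obs=int((counts > 0).sum())
            )
            if k == 1 or aic < best_aic - 1e-9:
                chosen.append(j_new)
                theta_prev, lo_prev, hi_prev = sol.x, lo, hi
                best_aic = aic
                fits[k] = (sol, aic)
                accepted = True
                break
        if not accepted:
            break

    if not fits:
        raise RuntimeError("no mixture fit converged for any component count")
    k_best = select_components([(k, aic) for k, (_, aic) in fits.items()])
    sol, _ = fits[k_best]

    raw = [
        (sol.x[3 * i], sol.x[3 * i + 1], sol.x[3 * i + 2]) for i in range(k_best)
    ]
    total_area = sum(a for _, _, a in raw)
    kept = [(c, s, a) for c, s, a in raw if a / total_area >= prune_fraction]
    kept_area = sum(a for _, _, a in kept)
    peaks = []
    for c, s, a in sorted(kept):
        j = int(round(c / monomer_mass))
        if j <= n_max:
            peaks.append(
                Peak(
                    center=float(c),
                    sd=float(s),
                    area=float(a),
                    area_fraction=float(a / kept_area),
                    assigned_n=j,
                    label=f"{j}-mer",
                )
            )
        else:
            peaks.append(
                Peak(
                    center=float(c),
                    sd=float(s),
                    area=float(a),
                    area_fraction=float(a / kept_area),
                    assigned_n=None,
                    label="cluster",
                )
            )
    aic_table = pd.DataFrame(
        [
            {"k": k, "aic": aic, "rss": float(2.0 * s.cost)}
            for k, (s, aic) in sorted(fits.items())
        ]
    )
    return PeakSet(
        peaks=peaks,
        n_components=k_best,
        aic_table=aic_table,
        monomer_mass=monomer_mass,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        n_events=int(masses.size),
    )


def counts_to_concentrations(
    peaks: PeakSet, nominal_total: float, replicate=0
) -> pd.DataFrame:
    """Convert peak areas (event counts) to species concentrations.

    Landing events sample particles in proportion to their species
    concentration (equal per-particle landing probability), so species
    concentrations are ``c_i = f_i * S`` with f_i the area fractions over
    protomer-assigned peaks and the scale S fixed by protomer mass
    balance sum(n_i * c_i) = nominal_total.  Ring-cluster peaks are
    excluded.  Returns titration-table rows.
    """
    if nominal_total <= 0:
        raise ValueError("nominal_total must be > 0")
    assigned = [p for p in peaks.peaks if p.assigned_n is not None]
    if not assigned:
        raise ValueError("no protomer-assigned peaks; cannot set the scale")
    frac = np.array([p.area_fraction for p in assigned])
    frac = frac / frac.sum()  # renormalize after dropping clusters
    n = np.array([p.assigned_n for p in assigned], dtype=float)
    scale = nominal_total / float(np.sum(n * frac))
    return pd.DataFrame(
        {
            "c_total_nM": nominal_total,
            "n": n.astype(int),
            "conc_nM": frac * scale,
            "count": [int(round(p.area)) for p in assigned],
            "replicate": replicate,
        }
    )
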