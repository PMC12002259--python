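"""Model fitting: the global assembly fit and the empirical linear ring model.

Both follow the Model/Results pattern: construct a model from a tidy
titration table, call ``fit()``, and get a results object carrying point
estimates, uncertainties and a ``summary()``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .assembly import (
    AssemblyParams,
    SHORT_SIZES,
    RING_SIZES,
    equilibrium_distribution,
)

__all__ = [
    "TITRATION_COLUMNS",
    "validate_titration",
    "EmpiricalRingFit",
    "EmpiricalRingModel",
    "RingAssemblyModel",
    "RingAssemblyResults",
]

#: canonical column names of a titration table (CSV header)
TITRATION_COLUMNS = ["c_total_nM", "n", "conc_nM", "count", "replicate"]


def validate_titration(table: pd.DataFrame) -> pd.DataFrame:
    """Check a titration table against the schema; returns a clean copy."""
    missing = [c for c in ("c_total_nM", "n", "conc_nM") if c not in table]
    if missing:
        raise ValueError(f"titration table missing columns: {missing}")
    out = table.copy()
    if "count" not in out:
        out["count"] = np.nan
    if "replicate" not in out:
        out["replicate"] = 0
    if (out["c_total_nM"] <= 0).any():
        raise ValueError("c_total_nM must be > 0")
    if (out["n"] < 1).any():
        raise ValueError("oligomer size n must be >= 1")
    if (out["conc_nM"] < 0).any():
        raise ValueError("species concentrations must be >= 0")
    out["n"] = out["n"].astype(int)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# empirical linear ring model: c_ring = (c_protomer - c_crit) / n_avg
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmpiricalRingFit:
    """Weighted-least-squares line through ring pool vs total concentration.

    The slope is 1/n_avg (each n_avg protomers added above the critical
    concentration make one ring) and the x-intercept is the critical
    concentration c_crit.  Above c_crit the short pool should plateau at
    about c_crit; ``plateau_short`` records its mean level when short-pool
    data are supplied.
    """

    c_crit: float
    n_avg: float
    c_crit_se: float
    n_avg_se: float
    plateau_short: float | None = None
    plateau_short_se: float | None = None
    negative_c_crit: bool = False

    def predict(self, c_total) -> np.ndarray:
        c = np.asarray(c_total, dtype=float)
        return np.clip((c - self.c_crit) / self.n_avg, 0.0, None)

    def summary(self) -> str:
        lines = [
            "Empirical ring model  c_ring = (c_protomer - c_crit)/n_avg",
            f"  c_crit  = {self.c_crit:8.3f} +/- {self.c_crit_se:.3f} nM",
            f"  n_avg   = {self.n_avg:8.3f} +/- {self.n_avg_se:.3f} protomers",
        ]
        if self.plateau_short is not None:
            lines.append(
                f"  short-pool plateau = {self.plateau_short:.3f} nM "
                "(expected ~ c_crit)"
            )
        if self.negative_c_crit:
            lines.append("  WARNING: fitted c_crit is negative")
        return "\n".join(lines)


class EmpiricalRingModel:
    """WLS line fit of ring-pool concentration against total concentration."""

    def __init__(self, c_total, ring_pool, short_pool=None, weights=None):
        self.c_total = np.asarray(c_total, dtype=float)
        self.ring_pool = np.asarray(ring_pool, dtype=float)
        self.short_pool = (
            None if short_pool is None else np.asarray(short_pool, dtype=float)
        )
        self.weights = (
            np.ones_like(self.c_total)
            if weights is None
            else np.asarray(weights, dtype=float)
        )
        if self.c_total.size < 3:
            raise ValueError("need >= 3 concentrations for the line fit")
        if np.all(self.ring_pool == 0):
            raise ValueError("all ring pools are zero; no line to fit")
        if np.unique(self.c_total).size < 2:
            raise ValueError("rank deficient: need >= 2 distinct c_total values")

    def fit(self) -> EmpiricalRingFit:
        X = sm.add_constant(self.c_total)
        res = sm.WLS(self.ring_pool, X, weights=self.weights).fit()
        a, b = res.params  # intercept, slope
        if b <= 0:
            raise ValueError("non-positive slope: ring pool does not grow")
        cov = res.cov_params()
        n_avg = 1.0 / b
        c_crit = -a / b
        # delta method: grad of c_crit wrt (a, b) is (-1/b, a/b**2)
        g = np.array([-1.0 / b, a / b**2])
        c_crit_se = float(np.sqrt(g @ cov @ g))
        n_avg_se = float(np.sqrt(cov[1, 1]) / b**2)
        plateau = plateau_se = None
        if self.short_pool is not None:
            plateau = float(np.mean(self.short_pool))
            plateau_se = float(
                np.std(self.short_pool, ddof=1) / np.sqrt(self.short_pool.size)
            )
        if c_crit < 0:
            warnings.warn("fitted critical concentration is negative")
        return EmpiricalRingFit(
            c_crit=float(c_crit),
            n_avg=float(n_avg),
            c_crit_se=c_crit_se,
            n_avg_se=n_avg_se,
            plateau_short=plateau,
            plateau_short_se=plateau_se,
            negative_c_crit=bool(c_crit < 0),
        )


# ---------------------------------------------------------------------------
# global fit of the cyclization model to a titration
# ---------------------------------------------------------------------------

_FIT_NAMES = ("kd", "kc0", "n_opt", "sigma_ring")


def _pack(params: AssemblyParams) -> np.ndarray:
    return np.array(
        [
            math.log10(params.kd),
            math.log10(max(params.kc0, 1.0)),
            params.n_opt,
            params.sigma_ring,
        ]
    )


def _unpack(theta: np.ndarray, template: AssemblyParams) -> AssemblyParams:
    return template.replace(
        kd=10.0 ** theta[0],
        kc0=10.0 ** theta[1],
        n_opt=float(theta[2]),
        sigma_ring=float(theta[3]),
    )


class RingAssemblyModel:
    """Global fit of the isodesmic + cyclization model to a titration table.

    Observations are per-size species concentrations (open + ring at the
    same size are indistinguishable by mass) at several total protomer
    concentrations, optionally replicated.  Residuals are weighted by
    1/sqrt(max(count, 1)), the Poisson-motivated scheme for species
    concentrations derived from event counts.

    Parameters
    ----------
    table : DataFrame
        Columns ``c_total_nM, n, conc_nM`` and optionally ``count,
        replicate``.
    n_max, n_ring_min : int
        Size cutoffs of the thermodynamic model.
    """

    #: optimizer bounds in packed coordinates (log10 kd, log10 kc0, n_opt, sigma)
    BOUNDS = (
        np.array([-1.0, 0.0, 5.0, 0.1]),
        np.array([3.0, 12.0, 20.0, 5.0]),
    )

    def __init__(self, table: pd.DataFrame, n_max: int = 25, n_ring_min: int = 3):
        self.table = validate_titration(table)
        self.n_max = n_max
        self.n_ring_min = n_ring_min
        if self.table["c_total_nM"].nunique() < 3:
            raise ValueError(
                "global fit needs >= 3 distinct total concentrations "
                "(parameters are not identifiable from fewer)"
            )
        w = 1.0 / np.maximum(self.table["count"].fillna(1.0).to_numpy(), 1.0)
        self._sqrtw = np.sqrt(w)
        self._groups = [
            (
                float(c_tot),
                self.table.index.get_indexer(idx),
                self.table.loc[idx, "n"].to_numpy(),
            )
            for c_tot, idx in self.table.groupby("c_total_nM").groups.items()
        ]

    def _predict_table(self, params: AssemblyParams) -> np.ndarray:
        pred = np.empty(len(self.table))
        for c_tot, pos, sizes in self._groups:
            dist = equilibrium_distribution(c_tot, params)
            pred[pos] = [dist.species(int(n)) for n in sizes]
        return pred

    def _residuals(self, theta: np.ndarray, template: AssemblyParams) -> np.ndarray:
        params = _unpack(theta, template)
        return (
            self._predict_table(params) - self.table["conc_nM"].to_numpy()
        ) * self._sqrtw

    def _objective(self, theta, template) -> float:
        r = self._residuals(theta, template)
        return float(r @ r)

    def fit(
        self,
        start_params: AssemblyParams | None = None,
        n_starts: int = 10,
        n_boot: int = 200,
        seed: int = 0,
    ) -> "RingAssemblyResults":
        """Run the multistart global fit with bootstrap uncertainties.

        ``n_starts`` seeded random perturbations of the start guard
        against local minima; ``n_boot`` nonparametric bootstrap
        resamples over replicates give standard errors (set 0 to skip).
        """
        rng = np.random.default_rng(seed)
        template = start_params or AssemblyParams(
            kd=20.0, kc0=1.0e6, n_opt=10.0, sigma_ring=1.0,
            n_max=self.n_max, n_ring_min=self.n_ring_min,
        )
        template = template.replace(n_max=self.n_max, n_ring_min=self.n_ring_min)
        theta0 = _pack(template)
        lo, hi = self.BOUNDS
        starts = [theta0]
        for _ in range(max(n_starts - 1, 0)):
            jitter = rng.normal(0.0, [0.3, 0.5, 0.8, 0.15])
            starts.append(np.clip(theta0 + jitter, lo, hi))

        best = None
        for s in starts:
            sol = least_squares(
                self._residuals, s, args=(template,), bounds=self.BOUNDS,
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        assert best is not None
        params_hat = _unpack(best.x, template)
        objective = 2.0 * best.cost  # least_squares cost is 0.5*sum(r^2)
        at_bounds = [
            name
            for name, x, l, h in zip(_FIT_NAMES, best.x, lo, hi)
            if x - l < 1e-6 or h - x < 1e-6
        ]
        if at_bounds:
            warnings.warn(f"fitted parameters at bounds: {at_bounds}")

        boot = self._bootstrap(best.x, template, n_boot, rng) if n_boot else None
        return RingAssemblyResults(
            model=self,
            params=params_hat,
            objective=objective,
            start=template,
            bse={} if boot is None else {
                name: float(np.std(col, ddof=1))
                for name, col in zip(_FIT_NAMES, boot.T)
            },
            bootstrap_samples=boot,
            at_bounds=at_bounds,
            seed=seed,
            n_starts=n_starts,
            n_boot=n_boot,
        )

    def _bootstrap(self, theta_hat, template, n_boot, rng) -> np.ndarray:
        groups = self.table.groupby(["c_total_nM", "replicate"]).groups
        keys = list(groups)
        by_conc: dict[float, list] = {}
        for c_tot, rep in keys:
            by_conc.setdefault(c_tot, []).append((c_tot, rep))
        out = np.empty((n_boot, 4))
        for b in range(n_boot):
            # resample replicate readings with replacement within each conc
            idx = []
            for c_tot, reps in by_conc.items():
                choice = rng.integers(0, len(reps), size=len(reps))
                for j in choice:
                    idx.extend(groups[reps[j]])
            sub = RingAssemblyModel(
                self.table.loc[idx], n_max=self.n_max, n_ring_min=self.n_ring_min
            )
            sol = least_squares(
                sub._residuals, theta_hat, args=(template,),
                bounds=self.BOUNDS, xtol=1e-10, ftol=1e-10,
            )
            out[b] = [10.0 ** sol.x[0], 10.0 ** sol.x[1], sol.x[2], sol.x[3]]
        return out


@dataclass
class RingAssemblyResults:
    """Fitted assembly parameters with bootstrap uncertainties."""

    model: RingAssemblyModel
    params: AssemblyParams
    objective: float
    start: AssemblyParams
    bse: dict
    bootstrap_samples: np.ndarray | None
    at_bounds: list
    seed: int
    n_starts: int
    n_boot: int

    def predict(self, c_total: float):
        return equilibrium_distribution(c_total, self.params)

    def summary(self) -> str:
        p = self.params
        rows = [
            ("kd (nM)", p.kd),
            ("kc0", p.kc0),
            ("n_opt", p.n_opt),
            ("sigma_ring", p.sigma_ring),
        ]
        lines = [
            "Ring assembly model — global fit",
            "=" * 44,
            f"{'parameter':<12}{'estimate':>14}{'boot SE':>14}",
        ]
        for (label, val), name in zip(rows, _FIT_NAMES):
            se = self.bse.get(name)
            se_s = f"{se:>14.4g}" if se is not None else f"{'--':>14}"
            lines.append(f"{label:<12}{val:>14.5g}{se_s}")
        lines.append(f"objective (weighted SSR): {self.objective:.6g}")
        if self.at_bounds:
            lines.append(f"parameters at bounds: {', '.join(self.at_bounds)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {
                "kd_nM": p.kd,
                "kc0": p.kc0,
                "n_opt": p.n_opt,
                "sigma_ring": p.sigma_ring,
                "n_max": p.n_max,
                "n_ring_min": p.n_ring_min,
            },
            "bootstrap_se": self.bse,
            "objective": self.objective,
            "at_bounds": self.at_bounds,
            "settings": {
                "n_starts": self.n_starts,
                "n_boot": self.n_boot,
                "seed": self.seed,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
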