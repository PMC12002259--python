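"""Cooperative ssDNA binding and single-strand-annealing kinetics.

Hill fits of binding curves, single-exponential annealing fits with
enhancement over a protein-free hybridization control, and the small
rate calculators used to reason about oligomer-size-dependent DNA
affinity: k_off = Kd*k_on, per-protomer Kd scaling, and the ring-closure
free energy ln(Kc0) in k_B*T.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CONC_UNITS",
    "to_molar",
    "from_molar",
    "off_rate",
    "scaled_kd",
    "ring_closure_energy",
    "hill_curve",
    "HillBindingModel",
    "HillFit",
    "AnnealingKineticsModel",
    "KineticsResult",
    "DIFFUSION_LIMITED_KON",
]

CONC_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}

#: order-of-magnitude diffusion-limited association rate, M^-1 s^-1
DIFFUSION_LIMITED_KON = 1e8


def to_molar(value: float, unit: str = "M") -> float:
    """Convert a concentration to molar."""
    try:
        return value * CONC_UNITS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


def from_molar(value: float, unit: str = "M") -> float:
    """Convert a molar concentration to the requested unit."""
    try:
        return value / CONC_UNITS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


def off_rate(kd: float, k_on: float = DIFFUSION_LIMITED_KON, kd_unit: str = "M") -> float:
    """Dissociation rate k_off = Kd * k_on, in s^-1."""
    if kd < 0 or k_on <= 0:
        raise ValueError("kd must be >= 0 and k_on > 0")
    return to_molar(kd, kd_unit) * k_on


def scaled_kd(kd_ref: float, delta_n: int, f: float = 0.34) -> float:
    """Dissociation constant after delta_n additional bound protomers.

    Each extra protomer in the nucleoprotein complex multiplies the
    dissociation constant by f (f = 0.34 is the cross-protein estimate
    from the Red-beta homologue; always overridable).
    """
    if delta_n < 0:
        raise ValueError("delta_n must be >= 0")
    if not 0 < f <= 1:
        raise ValueError("scaling factor f must be in (0, 1]")
    return kd_ref * f**delta_n


def ring_closure_energy(kc0: float) -> float:
    """Free-energy gain of ring closure, ln(Kc0), in units of k_B*T."""
    if kc0 <= 0:
        raise ValueError("kc0 must be > 0")
    return math.log(kc0)


def hill_curve(c, kd_app, hill):
    """Hill binding isotherm theta = c^H / (K^H + c^H)."""
    c = np.asarray(c, dtype=float)
    ch = np.power(c, hill)
    return ch / (kd_app**hill + ch)


@dataclass(frozen=True)
class HillFit:
    """Cooperative-binding fit results."""

    kd_app: float  # nM (units of the input concentrations)
    hill: float
    kd_app_se: float
    hill_se: float
    weighted_resid_norm: float

    def predict(self, c):
        return hill_curve(c, self.kd_app, self.hill)

    def summary(self) -> str:
        return (
            "Hill binding fit\n"
            f"  Kd_app = {self.kd_app:.3g} +/- {self.kd_app_se:.2g} "
            "(input concentration units)\n"
            f"  H      = {self.hill:.3g} +/- {self.hill_se:.2g}\n"
            f"  weighted residual norm = {self.weighted_resid_norm:.3g}"
        )


class HillBindingModel:
    """Weighted nonlinear least-squares fit of the Hill equation.

    Per-point standard errors are used as weights (sigma) when given,
    matching error-bar-weighted fitting of gel-quantified binding data.
    """

    def __init__(self, conc, fraction_bound, se=None):
        self.conc = np.asarray(conc, dtype=float)
        self.frac = np.asarray(fraction_bound, dtype=float)
        self.se = None if se is None else np.asarray(se, dtype=float)
        if self.conc.size < 4:
            raise ValueError("need >= 4 concentrations spanning the transition")
        if self.se is not None and np.any(self.se <= 0):
            raise ValueError("standard errors must be > 0")
        if np.ptp(self.frac) < 0.05:
            raise ValueError(
                "binding data are flat; Kd and H are not identifiable"
            )

    def fit(self, fix_hill: float | None = None) -> HillFit:
        # half-saturation guess: concentration nearest theta = 0.5
        k0 = float(self.conc[np.argmin(np.abs(self.frac - 0.5))])
        k0 = max(k0, 1e-12)
        if fix_hill is None:
            popt, pcov = curve_fit(
                hill_curve, self.conc, self.frac, p0=[k0, 1.5],
                sigma=self.se, absolute_sigma=self.se is not None,
                bounds=([1e-12, 0.05], [np.inf, 20.0]), maxfev=20000,
            )
            kd_app, hill = popt
            kd_se, hill_se = np.sqrt(np.diag(pcov))
        else:
            f = lambda c, k: hill_curve(c, k, fix_hill)
            popt, pcov = curve_fit(
                f, self.conc, self.frac, p0=[k0], sigma=self.se,
                absolute_sigma=self.se is not None,
                bounds=(1e-12, np.inf), maxfev=20000,
            )
            kd_app, hill = float(popt[0]), float(fix_hill)
            kd_se, hill_se = float(np.sqrt(pcov[0, 0])), 0.0
        resid = self.frac - hill_curve(self.conc, kd_app, hill)
        if self.se is not None:
            resid = resid / self.se
        return HillFit(
            kd_app=float(kd_app),
            hill=float(hill),
            kd_app_se=float(kd_se),
            hill_se=float(hill_se),
            weighted_resid_norm=float(np.linalg.norm(resid)),
        )


@dataclass(frozen=True)
class KineticsResult:
    """Single-exponential annealing fit: P(t) = A*(1 - exp(-k*t))."""

    rate: float  # min^-1
    amplitude: float
    rate_se: float
    amplitude_se: float
    enhancement: float | None = None  # protein rate / control rate

    @property
    def rate_per_s(self) -> float:
        return self.rate / 60.0

    @property
    def time_constant(self) -> float:
        """1/rate, min."""
        if self.rate <= 0:
            raise ZeroDivisionError("time constant undefined at zero rate")
        return 1.0 / self.rate

    def predict(self, t):
        return self.amplitude * (1.0 - np.exp(-self.rate * np.asarray(t, float)))

    def summary(self) -> str:
        lines = [
            "Annealing kinetics fit  P(t) = A*(1 - exp(-k t))",
            f"  k = {self.rate:.3g} +/- {self.rate_se:.2g} min^-1 "
            f"({self.rate_per_s:.3g} s^-1)",
            f"  A = {self.amplitude:.3g} +/- {self.amplitude_se:.2g}",
        ]
        if self.rate > 0:
            lines.append(f"  time constant = {self.time_constant:.3g} min")
        if self.enhancement is not None:
            lines.append(f"  enhancement over control = {self.enhancement:.3g}x")
        return "\n".join(lines)


class AnnealingKineticsModel:
    """Fit a single exponential to an annealing time course (t in min)."""

    def __init__(self, t, product_fraction):
        self.t = np.asarray(t, dtype=float)
        self.frac = np.asarray(product_fraction, dtype=float)
        if self.t.size < 3:
            raise ValueError("need >= 3 time points")
        order = np.argsort(self.t)
        diffs = np.diff(self.frac[order])
        if np.any(diffs < -0.25 * max(np.ptp(self.frac), 1e-12)):
            warnings.warn("time course is grossly non-monotone; fit is suspect")

    def fit(self, control_rate: float | None = None) -> KineticsResult:
        f = lambda t, a, k: a * (1.0 - np.exp(-k * t))
        a0 = max(float(np.max(self.frac)), 1e-6)
        t_pos = self.t[self.t > 0]
        k0 = 1.0 / float(np.median(t_pos)) if t_pos.size else 1.0
        popt, pcov = curve_fit(
            f, self.t, self.frac, p0=[a0, k0],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
        a, k = popt
        a_se, k_se = np.sqrt(np.diag(pcov))
        enh = None
        if control_rate is not None:
            if control_rate <= 0:
                raise ValueError("control_rate must be > 0")
            enh = float(k / control_rate)
        return KineticsResult(
            rate=float(k),
            amplitude=float(a),
            rate_se=float(k_se),
            amplitude_se=float(a_se),
            enhancement=enh,
        )
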