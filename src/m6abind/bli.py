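"""Biolayer-interferometry (BLI) kinetics: simulation and 1:1 fitting.

The sensor reports binding of an analyte (protein at concentration C) to
an immobilised ligand as response units over time.  Under ideal 1:1
Langmuir kinetics the association phase is a single exponential,

    R(t) = Req * (1 - exp(-kobs * t)),   kobs = kon*C + koff,
    Req  = Rmax * C / (C + KD),

and the dissociation phase is R(t) = R0 * exp(-koff * t).  The analysis
mirrors standard biosensor practice: kobs is fitted per trace, kon is
the slope of kobs versus concentration, koff comes from a single
dissociation curve, and KD = koff/kon.

Rates are in nM^-1 s^-1 (kon) and s^-1 (koff); concentrations in nM.
Multiply kon by 1e9 for M^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FittingError, ValidationError

__all__ = [
    "SensorTrace",
    "KineticParameters",
    "KobsSeries",
    "KobsFit",
    "FoldChanges",
    "DEFAULT_CONCENTRATIONS_NM",
    "simulate_association",
    "simulate_dissociation",
    "fit_kobs",
    "fit_kon",
    "fit_koff",
    "derive_kd",
    "fold_changes",
    "analyze_traces",
]

#: Doubling dilution series spanning the 5-320 nM analyte range used for
#: KH34 titrations on immobilised Zipcode RNA.
DEFAULT_CONCENTRATIONS_NM: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0)

NM_TO_M_KON = 1e9  # nM^-1 s^-1 -> M^-1 s^-1


@dataclass(frozen=True)
class SensorTrace:
    """One biosensor phase: time (s) versus response (RU)."""

    time: np.ndarray
    response: np.ndarray
    phase: Literal["association", "dissociation"]
    analyte_concentration: float | None = None  # nM, association only

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if t.ndim != 1 or t.shape != r.shape:
            raise ValidationError("time and response must be 1-D and equal length")
        if t.size < 2:
            raise ValidationError("a trace needs at least two samples")
        if t[0] != 0.0:
            raise ValidationError("time must start at 0")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("time must be strictly increasing")
        if self.phase not in ("association", "dissociation"):
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.phase == "association" and self.analyte_concentration is not None:
            if not (math.isfinite(self.analyte_concentration) and self.analyte_concentration > 0):
                raise ValidationError("analyte_concentration must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class KineticParameters:
    """kon (nM^-1 s^-1), koff (s^-1), KD (nM) and Rmax (RU) for one condition."""

    kon: float
    koff: float
    kd: float
    rmax: float = 1.0

    def __post_init__(self):
        for name in ("kon", "koff", "kd", "rmax"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and non-negative")
        if self.kon <= 0 or self.rmax <= 0:
            raise ValidationError("kon and rmax must be strictly positive")
        if self.koff > 0 and self.kd > 0:
            if abs(self.kd - self.koff / self.kon) > 1e-9 * max(self.kd, 1e-30):
                raise ValidationError("kd must equal koff/kon")

    @classmethod
    def from_rates(cls, kon: float, koff: float, rmax: float = 1.0) -> "KineticParameters":
        return cls(kon=kon, koff=koff, kd=derive_kd(kon, koff), rmax=rmax)

    @property
    def kon_per_molar(self) -> float:
        return self.kon * NM_TO_M_KON


@dataclass(frozen=True)
class KobsSeries:
    """Observed rates versus analyte concentration with the fitted line.

    The slope of kobs = kon*C + koff estimates kon; the intercept is an
    independent (usually noisier) estimate of koff.
    """

    concentrations: np.ndarray
    kobs: np.ndarray
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class KobsFit:
    """Single-trace exponential fit result with diagnostics."""

    kobs: float
    plateau: float
    rmse: float
    n_points: int


@dataclass(frozen=True)
class FoldChanges:
    """Ratios comparing two kinetic conditions (a over/under b as defined).

    lifetime_fold = koff_a/koff_b (fold increase in complex lifetime
    1/koff going from a to b), affinity_fold = kd_a/kd_b, and
    kon_fold = kon_a/kon_b; since kd = koff/kon, lifetime_fold ==
    affinity_fold * kon_fold identically.
    """

    lifetime_fold: float
    affinity_fold: float
    kon_fold: float


def _rng(seed: int | None) -> np.random.Generator:
    if seed is None:
        raise ValidationError("seed is mandatory for simulation")
    return np.random.default_rng(seed)


def simulate_association(
    truth: KineticParameters,
    concentration: float,
    time_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> SensorTrace:
    """Noisy 1:1 association trace at a single analyte concentration."""
    if not (math.isfinite(concentration) and concentration > 0):
        raise ValidationError("concentration must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    t = np.asarray(list(time_grid), dtype=float)
    kobs = truth.kon * concentration + truth.koff
    req = truth.rmax * concentration / (concentration + truth.kd)
    response = req * (1.0 - np.exp(-kobs * t))
    if noise_sd > 0:
        response = response + _rng(seed).normal(0.0, noise_sd, size=t.size)
    return SensorTrace(time=t, response=response, phase="association", analyte_concentration=concentration)


def simulate_dissociation(
    koff: float,
    r0: float,
    time_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> SensorTrace:
    """Noisy single-exponential dissociation trace starting from R0."""
    if not (math.isfinite(koff) and koff > 0):
        raise ValidationError("koff must be positive")
    if not (math.isfinite(r0) and r0 > 0):
        raise ValidationError("r0 must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    t = np.asarray(list(time_grid), dtype=float)
    response = r0 * np.exp(-koff * t)
    if noise_sd > 0:
        response = response + _rng(seed).normal(0.0, noise_sd, size=t.size)
    return SensorTrace(time=t, response=response, phase="dissociation")


def fit_kobs(trace: SensorTrace) -> KobsFit:
    """Fit R(t) = Req*(1 - exp(-kobs*t)) to an association trace.

    Starting values: the plateau from the last response, kobs from the
    reciprocal of the time at half-plateau. Bounded below at zero.
    """
    if trace.phase != "association":
        raise ValidationError("fit_kobs expects an association trace")
    if len(trace) < 5:
        raise FittingError("association fit needs at least 5 points", {"n_points": len(trace)})
    t, r = trace.time, trace.response

    plateau0 = float(r[-1])
    span = float(np.ptp(r))
    if plateau0 <= 0 or span <= 1e-12 * max(1.0, abs(plateau0)):
        raise FittingError("flat or non-positive trace", {"plateau0": plateau0, "span": span})
    half_idx = np.argmax(r >= 0.5 * plateau0)
    t_half = t[half_idx] if t[half_idx] > 0 else t[len(t) // 2]
    kobs0 = 1.0 / t_half if t_half > 0 else 1.0

    def model(tt, req, kobs):
        return req * (1.0 - np.exp(-kobs * tt))

    try:
        popt, _ = optimize.curve_fit(
            model, t, r, p0=[plateau0, kobs0],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FittingError(f"association fit did not converge: {exc}",
                           {"p0": [plateau0, kobs0]}) from exc
    req, kobs = float(popt[0]), float(popt[1])
    if kobs <= 0 or req <= 0:
        raise FittingError("non-physical association fit", {"req": req, "kobs": kobs})
    rmse = float(np.sqrt(np.mean((model(t, *popt) - r) ** 2)))
    return KobsFit(kobs=kobs, plateau=req, rmse=rmse, n_points=len(trace))


def fit_kon(concentrations: Sequence[float], kobs: Sequence[float]) -> KobsSeries:
    """Ordinary least-squares line through (concentration, kobs) points.

    The slope estimates kon and the intercept koff.
    """
    c = np.asarray(list(concentrations), dtype=float)
    k = np.asarray(list(kobs), dtype=float)
    if c.size != k.size:
        raise ValidationError("concentrations and kobs must have equal length")
    if c.size < 3:
        raise ValidationError("kon regression needs at least 3 points")
    res = stats.linregress(c, k)
    return KobsSeries(
        concentrations=c,
        kobs=k,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def fit_koff(trace: SensorTrace) -> float:
    """Single-curve dissociation analysis: fit R0*exp(-koff*t)."""
    if trace.phase != "dissociation":
        raise ValidationError("fit_koff expects a dissociation trace")
    if len(trace) < 5:
        raise FittingError("dissociation fit needs at least 5 points", {"n_points": len(trace)})
    t, r = trace.time, trace.response
    r0_0 = float(r[0])
    if r0_0 <= 0:
        raise FittingError("dissociation trace must start positive", {"r0": r0_0})
    # A trace that trends upward is not a dissociation phase.
    if float(np.polyfit(t, r, 1)[0]) >= 0:
        raise FittingError("response does not decay; not a dissociation phase")
    tail = float(r[-1])
    koff0 = math.log(r0_0 / tail) / t[-1] if tail > 0 else 1.0 / t[-1]

    def model(tt, r0, koff):
        return r0 * np.exp(-koff * tt)

    try:
        popt, _ = optimize.curve_fit(
            model, t, r, p0=[r0_0, max(koff0, 1e-12)],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FittingError(f"dissociation fit did not converge: {exc}") from exc
    koff = float(popt[1])
    if koff <= 0:
        raise FittingError("fitted koff is non-positive", {"koff": koff})
    return koff


def derive_kd(kon: float, koff: float) -> float:
    """KD = koff/kon, in nM. koff = 0 gives the irreversible limit KD = 0."""
    if not (math.isfinite(kon) and kon > 0):
        raise ValidationError("kon must be positive")
    if not (math.isfinite(koff) and koff >= 0):
        raise ValidationError("koff must be non-negative")
    return koff / kon


def fold_changes(a: KineticParameters, b: KineticParameters) -> FoldChanges:
    """Kinetic and affinity fold changes between two conditions."""
    return FoldChanges(
        lifetime_fold=a.koff / b.koff,
        affinity_fold=a.kd / b.kd,
        kon_fold=a.kon / b.kon,
    )


def analyze_traces(
    association: Sequence[SensorTrace],
    dissociation: SensorTrace,
) -> tuple[KineticParameters, KobsSeries]:
    """Full single-condition analysis from raw traces.

    Replicate association traces at the same concentration are fitted
    individually and their kobs averaged; the kobs-versus-concentration
    slope gives kon, the dissociation trace gives koff, and
    KD = koff/kon.  Rmax is back-calculated from the fitted plateaus.
    """
    if not association:
        raise ValidationError("at least one association trace required")
    by_conc: dict[float, list[KobsFit]] = {}
    for trace in association:
        if trace.analyte_concentration is None:
            raise ValidationError("association traces must carry analyte_concentration")
        by_conc.setdefault(trace.analyte_concentration, []).append(fit_kobs(trace))

    concs = sorted(by_conc)
    kobs_mean = [float(np.mean([f.kobs for f in by_conc[c]])) for c in concs]
    series = fit_kon(concs, kobs_mean)
    kon = series.slope
    koff = fit_koff(dissociation)
    kd = derive_kd(kon, koff)
    rmax_estimates = [
        f.plateau * (c + kd) / c for c in concs for f in by_conc[c]
    ]
    params = KineticParameters(kon=kon, koff=koff, kd=kd, rmax=float(np.mean(rmax_estimates)))
    return params, series
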