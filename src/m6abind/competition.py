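"""Two-ligand competition equilibrium for an m6A reader protein.

A single protein P binds two RNA species — an unmethylated RNA and its
m6A-methylated counterpart — each as an independent 1:1 site:

    P + RNA   <=> P.RNA      KD_unmod
    P + meRNA <=> P.meRNA    KD_meth

At equilibrium the free-protein concentration [P] satisfies the mass
balance

    g([P]) = [P] + [RNA]t*[P]/(KD_unmod + [P])
                 + [meRNA]t*[P]/(KD_meth + [P]) - [P]t = 0,

which rearranges to a cubic in [P].  g is strictly increasing on
[0, [P]t] with g(0) = -[P]t <= 0 and g([P]t) >= 0, so exactly one
physical root exists.  Bound concentrations follow from the isotherm

    [P.RNA_i] = [L]t,i * [P] / (KD_i + [P]).

All concentrations are nanomolar.  The model describes how a modest
KD differential between methylated and unmethylated RNA (for IMP1
KH34 binding the beta-actin Zipcode: 3.7 vs 20.9 nM) translates into a
protein-concentration-dependent discrimination window: the bound-
fraction enhancement is largest at low free protein and vanishes at
saturation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CompetitionSystem",
    "BindingState",
    "BindingCurve",
    "free_protein_cubic",
    "free_protein_oracle",
    "bound_species",
    "enhancement_ratio",
    "binding_curve",
]

AxisMode = Literal["free_protein", "total_protein"]


def _require_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be non-negative, got {value!r}")
    return value


@dataclass(frozen=True)
class CompetitionSystem:
    """Total concentrations and dissociation constants, all in nM.

    Attributes
    ----------
    total_protein
        Total protein concentration [P]t.
    total_rna_unmod, total_rna_meth
        Total concentrations of the unmethylated and methylated RNA.
    kd_unmod, kd_meth
        Equilibrium dissociation constants of the two 1:1 reactions.
    """

    total_protein: float
    total_rna_unmod: float
    total_rna_meth: float
    kd_unmod: float
    kd_meth: float

    def __post_init__(self):
        for name in ("total_protein", "total_rna_unmod", "total_rna_meth"):
            object.__setattr__(self, name, _require_finite_nonneg(name, getattr(self, name)))
        for name in ("kd_unmod", "kd_meth"):
            v = _require_finite_nonneg(name, getattr(self, name))
            if v == 0:
                raise ValidationError(f"{name} must be strictly positive")
            object.__setattr__(self, name, v)

    def with_total_protein(self, total_protein: float) -> "CompetitionSystem":
        return CompetitionSystem(
            total_protein=total_protein,
            total_rna_unmod=self.total_rna_unmod,
            total_rna_meth=self.total_rna_meth,
            kd_unmod=self.kd_unmod,
            kd_meth=self.kd_meth,
        )

    def mass_balance(self, free_protein: float) -> float:
        """g(P): free plus bound protein minus the total. Strictly increasing in P."""
        p = free_protein
        return (
            p
            + self.total_rna_unmod * p / (self.kd_unmod + p)
            + self.total_rna_meth * p / (self.kd_meth + p)
            - self.total_protein
        )


@dataclass(frozen=True)
class BindingState:
    """Equilibrium concentrations at one protein concentration (nM)."""

    free_protein: float
    bound_unmod: float
    bound_meth: float
    fraction_bound_unmod: float
    fraction_bound_meth: float


@dataclass(frozen=True)
class BindingCurve:
    """Bound-fraction curves along a protein-concentration grid.

    ``axis_mode`` records whether ``protein_grid`` is free or total
    protein; in total-protein mode the free concentration at each grid
    point is solved from the cubic mass balance.
    """

    axis_mode: AxisMode
    protein_grid: np.ndarray
    states: list[BindingState] = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": self.protein_grid,
                "free_protein": [s.free_protein for s in self.states],
                "bound_unmod": [s.bound_unmod for s in self.states],
                "bound_meth": [s.bound_meth for s in self.states],
                "fraction_unmod": [s.fraction_bound_unmod for s in self.states],
                "fraction_meth": [s.fraction_bound_meth for s in self.states],
            }
        )


def _cubic_coefficients(system: CompetitionSystem) -> tuple[float, float, float, float]:
    pt = system.total_protein
    lu, lm = system.total_rna_unmod, system.total_rna_meth
    ku, km = system.kd_unmod, system.kd_meth
    a2 = -pt + ku + km + lu + lm
    a1 = -pt * (ku + km) + ku * km + lu * km + lm * ku
    a0 = -pt * ku * km
    return 1.0, a2, a1, a0


def free_protein_cubic(system: CompetitionSystem) -> float:
    """Free-protein concentration from the closed-form cubic mass balance.

    Selects the unique real root in [0, total_protein] and polishes it
    with Newton steps on the monotone mass-balance function so the
    residual is below 1e-9 * max(1, total_protein) even when the cubic
    is ill-conditioned (widely separated KDs).
    """
    pt = system.total_protein
    if pt == 0.0:
        return 0.0
    if system.total_rna_unmod == 0.0 and system.total_rna_meth == 0.0:
        return pt

    roots = np.roots(_cubic_coefficients(system))
    real = roots[np.abs(roots.imag) < 1e-8 * max(1.0, np.abs(roots).max())].real
    # keep roots inside the physical bracket, with slack for round-off
    slack = 1e-9 * max(1.0, pt)
    candidates = [r for r in real if -slack <= r <= pt + slack]
    if not candidates:  # fall back to the monotone bracket midpoint
        candidates = [pt / 2.0]
    p = float(np.clip(min(candidates, key=lambda r: abs(system.mass_balance(r))), 0.0, pt))

    # Newton polish; g' >= 1 everywhere so the iteration is stable.
    tol = 1e-12 * max(1.0, pt)
    for _ in range(60):
        g = system.mass_balance(p)
        if abs(g) < tol:
            break
        dg = (
            1.0
            + system.total_rna_unmod * system.kd_unmod / (system.kd_unmod + p) ** 2
            + system.total_rna_meth * system.kd_meth / (system.kd_meth + p) ** 2
        )
        p = float(np.clip(p - g / dg, 0.0, pt))
    return p


def free_protein_oracle(system: CompetitionSystem, tolerance: float = 1e-12) -> float:
    """Bisection on the monotone mass balance over [0, total_protein].

    Deliberately simple and independent of the cubic route; serves as
    the verification oracle. ``tolerance`` is relative to
    max(1, total_protein).
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")
    pt = system.total_protein
    if pt == 0.0:
        return 0.0
    lo, hi = 0.0, pt
    # g(lo) = -pt < 0 and g(hi) >= 0: the root is bracketed.
    target = tolerance * max(1.0, pt)
    while hi - lo > target:
        mid = 0.5 * (lo + hi)
        if system.mass_balance(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bound_species(system: CompetitionSystem, free_protein: float) -> BindingState:
    """Bound concentrations and fractions at a given free-protein level.

    bound_i = [L]t,i * [P] / (KD_i + [P]); the bound fraction of a
    species with zero total concentration is defined as 0.
    """
    p = _require_finite_nonneg("free_protein", free_protein)
    bound_u = system.total_rna_unmod * p / (system.kd_unmod + p)
    bound_m = system.total_rna_meth * p / (system.kd_meth + p)
    frac_u = bound_u / system.total_rna_unmod if system.total_rna_unmod > 0 else 0.0
    frac_m = bound_m / system.total_rna_meth if system.total_rna_meth > 0 else 0.0
    return BindingState(
        free_protein=p,
        bound_unmod=bound_u,
        bound_meth=bound_m,
        fraction_bound_unmod=frac_u,
        fraction_bound_meth=frac_m,
    )


def enhancement_ratio(free_protein: float, kd_meth: float, kd_unmod: float) -> float:
    """Fold enhancement of the methylated over the unmethylated bound fraction.

    At a fixed free-protein concentration [P] the bound fraction of each
    RNA species is [P]/(KD + [P]), so the ratio reduces to

        (kd_unmod + [P]) / (kd_meth + [P]).

    It exceeds 1 exactly when kd_meth < kd_unmod, decreases monotonically
    with [P], tends to kd_unmod/kd_meth as [P] -> 0 and to 1 as
    [P] -> infinity: discrimination by methylation is strongest when
    free protein is scarce.
    """
    for name, v in (("free_protein", free_protein), ("kd_meth", kd_meth), ("kd_unmod", kd_unmod)):
        if not (math.isfinite(v) and v > 0):
            raise ValidationError(f"{name} must be finite and positive, got {v!r}")
    return (kd_unmod + free_protein) / (kd_meth + free_protein)


def binding_curve(
    system: CompetitionSystem,
    protein_grid: Sequence[float],
    axis_mode: AxisMode = "free_protein",
) -> BindingCurve:
    """Sweep the competition model over a protein-concentration grid.

    Parameters
    ----------
    system
        Template; its ``total_protein`` is ignored and replaced by each
        grid value (total-protein mode) or bypassed entirely
        (free-protein mode).
    protein_grid
        Strictly increasing, non-negative concentrations (nM).
    axis_mode
        ``free_protein``: fractions evaluated directly at each grid
        value. ``total_protein``: the free concentration is solved from
        the cubic mass balance at each grid value, so RNA totals deplete
        the protein pool.
    """
    grid = np.asarray(list(protein_grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("protein_grid must not be empty")
    if not np.all(np.isfinite(grid)) or np.any(grid < 0):
        raise ValidationError("protein_grid must be finite and non-negative")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValidationError("protein_grid must be strictly increasing")
    if axis_mode not in ("free_protein", "total_protein"):
        raise ValidationError(f"unknown axis_mode {axis_mode!r}")

    states = []
    for value in grid:
        if axis_mode == "free_protein":
            states.append(bound_species(system, value))
        else:
            sys_i = system.with_total_protein(value)
            states.append(bound_species(sys_i, free_protein_cubic(sys_i)))
    return BindingCurve(axis_mode=axis_mode, protein_grid=grid, states=states)
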