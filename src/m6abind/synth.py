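"""Synthetic datasets with known ground truth for every analysis stage.

Each generator emulates one experimental data type at study-like
conditions — biosensor titrations of a reader protein over a 5-320 nM
doubling series in triplicate, amide peak tables for a ~180-residue KH
di-domain with a planted binding interface, and a small genome with a
planted number of peak/m6A overlaps — and returns the generating truth
alongside the data so recovery can be scored automatically.

A single top-level seed is split into fixed per-generator streams
(via ``numpy`` SeedSequence spawn keys), so adding a generator never
perturbs the fixtures of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import bli
from .bli import KineticParameters, SensorTrace
from .clip_overlap import GenomicInterval
from .csp import PeakTable
from .errors import GenerationError, ValidationError

__all__ = [
    "BLICondition",
    "BLIDataset",
    "PeakTablePair",
    "GenomeFixture",
    "DEFAULT_BLI_TRUTH",
    "gen_bli_dataset",
    "gen_peak_tables",
    "gen_genome_fixture",
]

# Fixed spawn keys: one independent stream per generator.
_STREAMS = {"bli": 0, "csp": 1, "genome": 2}


def _rng(seed: int, generator: str, index: int = 0) -> np.random.Generator:
    if seed is None:
        raise ValidationError("seed is mandatory")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[generator], index))
    return np.random.default_rng(ss)


# --------------------------------------------------------------------------
# BLI

#: Scenario truth for the methylated/unmethylated contrast: equal kon,
#: an 8-fold slower dissociation from methylated RNA (the complex-
#: lifetime contrast), kon = 1e-4 nM^-1 s^-1 = 1e5 M^-1 s^-1.
DEFAULT_BLI_TRUTH: dict[str, KineticParameters] = {
    "meth": KineticParameters.from_rates(kon=1e-4, koff=2.5e-4, rmax=1.0),
    "unmod": KineticParameters.from_rates(kon=1e-4, koff=2.0e-3, rmax=1.0),
}


@dataclass(frozen=True)
class BLICondition:
    """Simulated traces plus generating truth for one RNA condition."""

    truth: KineticParameters
    association: tuple[SensorTrace, ...]
    dissociation: SensorTrace


@dataclass(frozen=True)
class BLIDataset:
    conditions: dict[str, BLICondition]
    manifest: dict = field(repr=False)


def gen_bli_dataset(
    truth: Mapping[str, KineticParameters] | None = None,
    concentrations: Sequence[float] = bli.DEFAULT_CONCENTRATIONS_NM,
    noise_sd: float = 0.01,
    replicates: int = 3,
    seed: int = 0,
    association_time: float = 600.0,
    dissociation_time: float = 3600.0,
    dt: float = 1.0,
) -> BLIDataset:
    """Association traces per concentration per replicate + one dissociation.

    Defaults emulate the study conditions: a 5-320 nM analyte doubling
    series, triplicate measurements, and Gaussian noise at 1% of Rmax.
    """
    truth = dict(truth or DEFAULT_BLI_TRUTH)
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    t_assoc = np.arange(0.0, association_time + dt / 2, dt)
    t_diss = np.arange(0.0, dissociation_time + dt / 2, dt)

    conditions = {}
    for cond_idx, (label, params) in enumerate(sorted(truth.items())):
        rng_stream = _rng(seed, "bli", cond_idx)
        assoc = []
        for conc in concentrations:
            for _ in range(replicates):
                sub_seed = int(rng_stream.integers(0, 2**31 - 1))
                assoc.append(bli.simulate_association(
                    params, conc, t_assoc, noise_sd=noise_sd, seed=sub_seed))
        c_max = max(concentrations)
        r0 = params.rmax * c_max / (c_max + params.kd)
        diss = bli.simulate_dissociation(
            params.koff, r0, t_diss, noise_sd=noise_sd,
            seed=int(rng_stream.integers(0, 2**31 - 1)))
        conditions[label] = BLICondition(truth=params, association=tuple(assoc),
                                         dissociation=diss)
    manifest = {
        "scenario": "bli",
        "seed": int(seed),
        "noise_sd": noise_sd,
        "replicates": replicates,
        "concentrations_nM": [float(c) for c in concentrations],
        "truth": {
            label: {"kon": p.kon, "koff": p.koff, "kd": p.kd, "rmax": p.rmax}
            for label, p in truth.items()
        },
    }
    return BLIDataset(conditions=conditions, manifest=manifest)


# --------------------------------------------------------------------------
# CSP peak tables


@dataclass(frozen=True)
class PeakTablePair:
    free: PeakTable
    bound: PeakTable
    perturbed_residues: tuple[int, ...]
    bound_deltas: dict[int, tuple[float, float]] = field(repr=False)
    manifest: dict = field(repr=False)


def gen_peak_tables(
    n_residues: int = 180,
    perturbed_fraction: float = 0.1,
    effect_h_ppm: tuple[float, float] = (0.08, 0.25),
    effect_n_ppm: tuple[float, float] = (0.4, 1.5),
    noise_sd: float = 0.005,
    seed: int = 0,
    first_residue: int = 387,
) -> PeakTablePair:
    """Free/bound amide peak tables with a planted perturbed subset.

    Residue count and numbering default to a KH34-sized di-domain.
    Unperturbed residues differ between the tables only by measurement
    noise; perturbed ones additionally carry a drawn (dH, dN) change
    with uniform magnitude in ``effect_*_ppm`` and random sign.
    """
    if not 0.0 <= perturbed_fraction <= 1.0:
        raise ValidationError("perturbed_fraction must be in [0, 1]")
    if n_residues < 1:
        raise ValidationError("n_residues must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = _rng(seed, "csp")
    residues = np.arange(first_residue, first_residue + n_residues)
    # baseline amide positions in realistic HSQC ranges
    base_h = rng.uniform(6.5, 10.5, size=n_residues)
    base_n = rng.uniform(105.0, 135.0, size=n_residues)

    n_perturbed = int(round(perturbed_fraction * n_residues))
    perturbed = np.sort(rng.choice(residues, size=n_perturbed, replace=False))
    deltas: dict[int, tuple[float, float]] = {}
    d_h = np.zeros(n_residues)
    d_n = np.zeros(n_residues)
    for res in perturbed:
        i = res - first_residue
        dh = rng.uniform(*effect_h_ppm) * rng.choice([-1.0, 1.0])
        dn = rng.uniform(*effect_n_ppm) * rng.choice([-1.0, 1.0])
        d_h[i], d_n[i] = dh, dn
        deltas[int(res)] = (float(dh), float(dn))

    def noisy(values):
        return values + rng.normal(0.0, noise_sd, size=values.size) if noise_sd > 0 else values

    free = PeakTable("free", residues, noisy(base_h), noisy(base_n))
    bound = PeakTable("bound", residues, noisy(base_h + d_h), noisy(base_n + d_n))
    manifest = {
        "scenario": "csp",
        "seed": int(seed),
        "n_residues": n_residues,
        "perturbed_fraction": perturbed_fraction,
        "noise_sd": noise_sd,
        "perturbed_residues": [int(r) for r in perturbed],
        "bound_deltas": {str(r): list(d) for r, d in deltas.items()},
    }
    return PeakTablePair(free=free, bound=bound,
                         perturbed_residues=tuple(int(r) for r in perturbed),
                         bound_deltas=deltas, manifest=manifest)


# --------------------------------------------------------------------------
# Genome fixture


@dataclass(frozen=True)
class GenomeFixture:
    peaks: tuple[GenomicInterval, ...]
    sites: tuple[GenomicInterval, ...]
    region_counts: dict[str, float]
    region_lengths: dict[str, float]
    manifest: dict = field(repr=False)


#: Rough relative genomic lengths of the transcriptomic region classes
#: summarised in CLIP analyses (nt, toy scale).
DEFAULT_REGION_LENGTHS: dict[str, float] = {
    "3UTR": 20_000.0,
    "5UTR": 4_000.0,
    "CDS": 30_000.0,
    "intron": 200_000.0,
    "ncRNA": 15_000.0,
}


def gen_genome_fixture(
    n_peaks: int = 20,
    n_sites: int = 12,
    planted_overlap_count: int = 7,
    peak_width: int = 30,
    site_width: int = 1,
    region_lengths: Mapping[str, float] | None = None,
    region_density_weights: Mapping[str, float] | None = None,
    chrom: str = "chrS",
    seed: int = 0,
) -> GenomeFixture:
    """Peaks and m6A sites on a toy chromosome with planted overlaps.

    Exactly ``planted_overlap_count`` peaks share bases (and strand)
    with a site; every other peak keeps a guard gap of >= 1 nt from all
    sites, so the overlap truth holds under both strand modes.  Region
    count tables (mean counts drawn per class around planted densities)
    accompany the intervals for the length-normalisation summary.
    """
    if planted_overlap_count > min(n_peaks, n_sites):
        raise GenerationError(
            "planted_overlap_count exceeds min(n_peaks, n_sites)")
    if n_peaks < 0 or n_sites < 0:
        raise ValidationError("counts must be non-negative")
    rng = _rng(seed, "genome")
    pitch = 10 * peak_width  # slot spacing large enough to isolate features
    if pitch <= 2 * peak_width + 2:
        raise GenerationError("peak_width too large for the slot layout")

    sites = []
    for j in range(n_sites):
        pos = 1000 + j * pitch + int(rng.integers(0, peak_width))
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(GenomicInterval(chrom, pos, pos + site_width, f"site_{j}", 0, strand))

    peaks = []
    chosen = rng.choice(n_sites, size=planted_overlap_count, replace=False) if planted_overlap_count else []
    for k, j in enumerate(sorted(int(x) for x in np.atleast_1d(chosen))):
        site = sites[j]
        offset = int(rng.integers(0, peak_width - site_width + 1))
        start = max(site.start - offset, 0)
        peaks.append(GenomicInterval(chrom, start, start + peak_width,
                                     f"peak_ov_{k}", int(rng.integers(1, 50)), site.strand))

    # non-overlapping peaks live beyond the site region with a guard gap
    clear_start = 1000 + n_sites * pitch + pitch
    for k in range(n_peaks - planted_overlap_count):
        start = clear_start + k * pitch + int(rng.integers(0, peak_width))
        strand = "+" if rng.random() < 0.5 else "-"
        peaks.append(GenomicInterval(chrom, start, start + peak_width,
                                     f"peak_bg_{k}", int(rng.integers(1, 50)), strand))
    peaks.sort()

    lengths = dict(region_lengths or DEFAULT_REGION_LENGTHS)
    weights = dict(region_density_weights or
                   {"3UTR": 10.0, "CDS": 2.0, "5UTR": 1.0, "intron": 0.1, "ncRNA": 0.5})
    if set(weights) != set(lengths):
        raise ValidationError("region keys of lengths and density weights must match")
    counts = {region: float(rng.poisson(weights[region] * lengths[region] / 1000.0))
              for region in sorted(lengths)}

    manifest = {
        "scenario": "genome",
        "seed": int(seed),
        "n_peaks": n_peaks,
        "n_sites": n_sites,
        "planted_overlap_count": planted_overlap_count,
        "overlapping_peaks": [p.name for p in peaks if p.name.startswith("peak_ov_")],
        "region_lengths": lengths,
        "region_density_weights": weights,
        "region_counts": counts,
    }
    return GenomeFixture(peaks=tuple(peaks), sites=tuple(sites),
                         region_counts=counts, region_lengths=lengths, manifest=manifest)
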