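"""Synthetic Hi-C and fragment-coverage experiments with planted truth.

The generators emulate, at desk scale, the two data types the pipeline
consumes: cis contact maps with power-law distance decay, an A/B checkerboard,
replicate depth variation, low-coverage bins and planted condition-specific
loops; and fragment coverage with enriched peaks, condition-specific
gains/losses, depth differences and a bimodal fragment-length mixture.
Every planted feature is recorded in a :class:`TruthRecord` so downstream
stages can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .io_formats import BinnedContactMap, GenomicInterval

__all__ = [
    "PlantedLoop",
    "HiCSimParams",
    "PlantedPeak",
    "FragSimParams",
    "TruthRecord",
    "SampleFragments",
    "simulate_hic_experiment",
    "simulate_fragment_experiment",
    "default_hic_params",
    "default_frag_params",
]

LOOP_STATUSES = ("shared", "cond1_only", "cond2_only")


@dataclass(frozen=True)
class PlantedLoop:
    chrom: str
    i: int
    j: int
    enrichment: float
    status: str  # shared | cond1_only | cond2_only

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError("loop requires i < j")
        if self.enrichment <= 1:
            raise ValueError("loop enrichment must exceed 1")
        if self.status not in LOOP_STATUSES:
            raise ValueError(f"unknown loop status {self.status!r}")


@dataclass
class HiCSimParams:
    """Conditions for a synthetic Hi-C experiment.

    ``base_intensity`` is the expected count of a diagonal cell at unit depth
    before compartment/loop modulation; a cell at bin distance d has
    expectation ``depth * C * (1 + d) ** -gamma`` times the compartment factor
    ``1 + s`` (same compartment) or ``1 - s`` and times the loop enrichment
    ``f`` inside the 3x3 peak window of a loop active in that condition.
    Low-coverage bins have all expectations scaled by 0.05.
    """

    chrom_lengths: dict = field(default_factory=lambda: {"chrS": 2_000_000})
    bin_size: int = 5_000
    n_replicates: int = 3
    depth_factors: dict = None  # (condition, replicate) -> positive float
    base_intensity: float = 50.0
    gamma: float = 1.0
    compartment_block_bins: int = 25
    compartment_strength: float = 0.3
    loops: Sequence[PlantedLoop] = ()
    low_coverage_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.compartment_strength < 1):
            raise ValueError("compartment strength must lie in [0, 1)")
        if self.gamma <= 0 or self.base_intensity <= 0:
            raise ValueError("gamma and base_intensity must be positive")
        if self.depth_factors is not None:
            for v in self.depth_factors.values():
                if v <= 0:
                    raise ValueError("depth factors must be positive")

    def n_bins(self, chrom: str) -> int:
        return int(np.ceil(self.chrom_lengths[chrom] / self.bin_size))


@dataclass(frozen=True)
class PlantedPeak:
    interval: GenomicInterval
    intensity: dict  # condition -> fragments per bp added over background

    def __post_init__(self):
        if any(v < 0 for v in self.intensity.values()):
            raise ValueError("peak intensities must be non-negative")


@dataclass
class FragSimParams:
    """Conditions for a synthetic fragment-coverage experiment."""

    genome_length: int = 1_000_000
    chrom: str = "chrS"
    peaks: Sequence[PlantedPeak] = ()
    background_rate: float = 0.01  # fragments per bp at unit depth
    length_means: tuple = (80.0, 200.0)
    length_sds: tuple = (15.0, 30.0)
    length_weights: tuple = (0.6, 0.4)
    n_replicates: int = 3
    depth_factors: dict = None
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.length_weights) - 1) > 1e-9:
            raise ValueError("fragment-length mixture weights must sum to 1")
        for p in self.peaks:
            if p.interval.end > self.genome_length:
                raise ValueError(
                    f"peak {p.interval.start}-{p.interval.end} outside genome"
                )


@dataclass
class SampleFragments:
    """Fragments of one sample (one replicate of one condition)."""

    sample_id: str
    condition: str
    fragments: list  # of GenomicInterval

    def __post_init__(self):
        for f in self.fragments:
            if f.length <= 0:
                raise ValueError("fragments must have positive length")

    @property
    def n(self) -> int:
        return len(self.fragments)


@dataclass
class TruthRecord:
    """Planted ground truth for acceptance testing."""

    loops: list = field(default_factory=list)  # PlantedLoop
    differential_peaks: list = field(default_factory=list)  # (interval, direction)
    compartment_labels: dict = field(default_factory=dict)  # chrom -> array of 'A'/'B'
    low_coverage_bins: dict = field(default_factory=dict)  # chrom -> bool array
    tss_positions: dict = field(default_factory=dict)  # chrom -> int array

    def differential_loops(self):
        return [lp for lp in self.loops if lp.status != "shared"]

    def to_json(self, path) -> None:
        payload = {
            "loops": [asdict(lp) for lp in self.loops],
            "differential_peaks": [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "direction": d}
                for iv, d in self.differential_peaks
            ],
            "compartment_labels": {c: "".join(v) for c, v in self.compartment_labels.items()},
            "low_coverage_bins": {
                c: np.asarray(v, dtype=int).tolist()
                for c, v in self.low_coverage_bins.items()
            },
            "tss_positions": {c: np.asarray(v).tolist() for c, v in self.tss_positions.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _default_depths(rng: np.random.Generator, conditions, n_rep) -> dict:
    """Per-replicate depth factors, log-uniform in [0.7, 1.4]."""
    out = {}
    for c in conditions:
        for r in range(n_rep):
            out[(c, r)] = float(np.exp(rng.uniform(np.log(0.7), np.log(1.4))))
    return out


def simulate_hic_experiment(params: HiCSimParams):
    """Generate per-replicate-per-condition contact maps plus planted truth.

    Returns ``(maps, truth)`` where ``maps`` is a dict keyed by
    ``(condition, replicate, chrom)`` holding :class:`BinnedContactMap`.
    Conditions are named ``cond1`` (control) and ``cond2`` (treatment).
    """
    rng = np.random.default_rng(params.seed)
    conditions = ("cond1", "cond2")
    depths = params.depth_factors or _default_depths(rng, conditions, params.n_replicates)

    truth = TruthRecord(loops=list(params.loops))
    maps = {}
    for chrom, length in params.chrom_lengths.items():
        n = params.n_bins(chrom)
        for lp in params.loops:
            if lp.chrom == chrom and lp.j >= n:
                raise ValueError(f"loop bin {lp.j} outside chromosome {chrom} ({n} bins)")

        # compartment checkerboard: alternating A/B blocks
        block = params.compartment_block_bins
        labels = np.array(["A" if (b // block) % 2 == 0 else "B" for b in range(n)])
        same = labels[:, None] == labels[None, :]
        s = params.compartment_strength
        comp_factor = np.where(same, 1 + s, 1 - s)

        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        decay = (1.0 + d) ** (-params.gamma)

        loop_factor = np.ones((n, n))
        cond_loop = {c: np.ones((n, n)) for c in conditions}
        for lp in params.loops:
            if lp.chrom != chrom:
                continue
            sl_i = slice(max(lp.i - 1, 0), min(lp.i + 2, n))
            sl_j = slice(max(lp.j - 1, 0), min(lp.j + 2, n))
            active = (
                conditions
                if lp.status == "shared"
                else (("cond1",) if lp.status == "cond1_only" else ("cond2",))
            )
            for c in active:
                cond_loop[c][sl_i, sl_j] = lp.enrichment
                cond_loop[c][sl_j, sl_i] = lp.enrichment

        n_low = int(round(params.low_coverage_fraction * n))
        low_bins = rng.choice(n, size=n_low, replace=False) if n_low else np.array([], int)
        low_mask = np.zeros(n, dtype=bool)
        low_mask[low_bins] = True
        low_factor = np.ones(n)
        low_factor[low_mask] = 0.05
        low_outer = np.outer(low_factor, low_factor)

        truth.compartment_labels[chrom] = labels
        truth.low_coverage_bins[chrom] = low_mask

        # TSS positions enriched in A bins (3:1 per-bin rate), for PC1 orientation
        tss = []
        for b in range(n):
            lam = 0.75 if labels[b] == "A" else 0.25
            k = rng.poisson(lam)
            if k:
                tss.extend(
                    (b * params.bin_size + rng.integers(0, params.bin_size, size=k)).tolist()
                )
        truth.tss_positions[chrom] = np.sort(np.asarray(tss, dtype=int))

        base = params.base_intensity * decay * comp_factor * low_outer
        iu = np.triu_indices(n)
        for c in conditions:
            expect = base * cond_loop[c]
            for r in range(params.n_replicates):
                lam = depths[(c, r)] * expect
                draws = rng.poisson(lam[iu])
                vals = np.zeros((n, n))
                vals[iu] = draws
                vals = vals + np.triu(vals, 1).T
                cov = vals.sum(axis=1)
                valid = cov > 0
                vals = vals.astype(float)
                vals[~valid, :] = np.nan
                vals[:, ~valid] = np.nan
                maps[(c, r, chrom)] = BinnedContactMap(
                    chrom, params.bin_size, vals, valid
                )
    return maps, truth


def simulate_fragment_experiment(params: FragSimParams):
    """Generate per-sample fragment lists plus planted truth.

    Per region, fragment counts are Poisson with rate
    ``depth * (background + intensity)`` per bp; fragment lengths come from a
    two-component normal mixture (truncated at 10 bp) and midpoints are
    uniform within the source region.
    """
    rng = np.random.default_rng(params.seed)
    conditions = ("cond1", "cond2")
    depths = params.depth_factors or _default_depths(rng, conditions, params.n_replicates)

    truth = TruthRecord()
    for p in params.peaks:
        i1, i2 = p.intensity.get("cond1", 0.0), p.intensity.get("cond2", 0.0)
        if i2 > i1:
            direction = "gained"
        elif i2 < i1:
            direction = "lost"
        else:
            direction = "unchanged"
        truth.differential_peaks.append((p.interval, direction))

    def draw_lengths(k):
        comp = rng.choice(len(params.length_weights), size=k, p=params.length_weights)
        ln = rng.normal(
            np.asarray(params.length_means)[comp], np.asarray(params.length_sds)[comp]
        )
        return np.maximum(ln, 10.0)

    samples = {}
    for c in conditions:
        for r in range(params.n_replicates):
            depth = depths[(c, r)]
            frags = []

            def emit(region_start, region_end, rate):
                k = rng.poisson(depth * rate * (region_end - region_start))
                if k == 0:
                    return
                mids = rng.uniform(region_start, region_end, size=k)
                lens = draw_lengths(k)
                starts = np.maximum(np.round(mids - lens / 2).astype(int), 0)
                ends = np.minimum(
                    np.round(mids + lens / 2).astype(int), params.genome_length
                )
                for s0, e0 in zip(starts, ends):
                    if e0 > s0:
                        frags.append(GenomicInterval(params.chrom, int(s0), int(e0)))

            emit(0, params.genome_length, params.background_rate)
            for p in params.peaks:
                emit(p.interval.start, p.interval.end, p.intensity.get(c, 0.0))

            frags.sort(key=lambda f: (f.start, f.end))
            samples[(c, r)] = SampleFragments(f"{c}_rep{r + 1}", c, frags)
    return samples, truth


def default_hic_params(seed: int = 0) -> HiCSimParams:
    """The standard synthetic Hi-C experiment used throughout the test suite.

    One 2 Mb chromosome at 5 kb bins (400 bins), 3 replicates per condition,
    compartment blocks of 25 bins at strength 0.3, 2% low-coverage bins, and
    30 planted loops at enrichment f=5: 10 shared, 10 control-specific (lost
    upon treatment) and 10 treatment-specific (gained).
    """
    rng = np.random.default_rng(seed + 104729)  # loop placement stream
    loops = []
    taken = []
    statuses = ["shared"] * 10 + ["cond1_only"] * 10 + ["cond2_only"] * 10
    for status in statuses:
        while True:
            i = int(rng.integers(10, 330))
            d = int(rng.integers(10, 60))
            j = i + d
            if j >= 390:
                continue
            if all(max(abs(i - a), abs(j - b)) > 6 for a, b in taken):
                taken.append((i, j))
                break
        loops.append(PlantedLoop("chrS", i, j, 5.0, status))
    return HiCSimParams(loops=loops, seed=seed)


def default_frag_params(seed: int = 0, n_differential: int = 10) -> FragSimParams:
    """The standard synthetic fragment experiment: 1 Mb genome, 40 peaks of
    1 kb, background 0.01 fragments/bp, with ``n_differential`` peaks split
    between 4-fold gains and losses."""
    rng = np.random.default_rng(seed + 15485863)  # peak placement stream
    starts = np.sort(rng.choice(np.arange(20, 980) * 1000, size=40, replace=False))
    peaks = []
    kinds = ["gained"] * (n_differential // 2) + ["lost"] * (n_differential - n_differential // 2)
    kinds += ["flat"] * (40 - n_differential)
    rng.shuffle(kinds)
    for s0, kind in zip(starts, kinds):
        iv = GenomicInterval("chrS", int(s0), int(s0) + 1000)
        if kind == "gained":
            inten = {"cond1": 0.05, "cond2": 0.20}
        elif kind == "lost":
            inten = {"cond1": 0.20, "cond2": 0.05}
        else:
            inten = {"cond1": 0.20, "cond2": 0.20}
        peaks.append(PlantedPeak(iv, inten))
    return FragSimParams(peaks=peaks, seed=seed)
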