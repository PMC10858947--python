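"""Background-based normalization of fragment coverage.

The procedure equalizes sequencing depth across samples using the signal
*outside* enriched regions: fragments are size-filtered, peaks are called on
the pooled samples, peak-flanking regions are derived, per-sample flank counts
feed a median-of-ratios size-factor estimate, and each sample is then thinned
(binomially subsampled) so that background depth matches the shallowest
sample.  Normalizing on peak flanks rather than peaks keeps genuine
condition-specific occupancy changes out of the scale estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomicInterval
from .synthetic_data import SampleFragments

__all__ = [
    "RegionCountMatrix",
    "filter_fragments_by_size",
    "call_enriched_regions",
    "flank_regions",
    "count_fragments_in_regions",
    "size_factors_median_of_ratios",
    "thin_fragments",
    "normalize_experiment",
    "DEFAULT_SIZE_FILTERS",
]

logger = logging.getLogger(__name__)

# maximum fragment length retained per assay; None = no size filter
DEFAULT_SIZE_FILTERS = {"tf": 120, "atac": 150, "histone": None, "chip": None}


@dataclass
class RegionCountMatrix:
    """Fragment counts per region (rows) per sample (columns)."""

    regions: list  # of GenomicInterval
    samples: list  # ordered sample ids
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("count matrix shape mismatch")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be non-negative integers")
            self.counts = np.round(self.counts).astype(int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def filter_fragments_by_size(sample: SampleFragments, max_len: int) -> SampleFragments:
    """Retain fragments strictly shorter than ``max_len`` bp, preserving order."""
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    kept = [f for f in sample.fragments if f.length < max_len]
    logger.info(
        "size filter <%d bp: %s kept %d/%d fragments",
        max_len, sample.sample_id, len(kept), sample.n,
    )
    return SampleFragments(sample.sample_id, sample.condition, kept)


def call_enriched_regions(
    fragments,
    genome_len: int,
    window: int = 500,
    alpha: float = 0.05,
    chrom: str | None = None,
):
    """Poisson-tail peak calling on pooled fragments.

    The genome is tiled into fixed windows; each fragment is assigned to the
    window containing its midpoint.  Against a uniform background with rate
    ``lambda = N * window / genome_len`` per window, the per-window p-value is
    the Poisson upper tail P(X >= c); windows significant after BH at
    ``alpha`` are merged when separated by at most one window, and each merged
    region carries the minimum member-window raw p-value.
    """
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    if window <= 0:
        raise ValueError("window must be positive")
    fragments = list(fragments)
    if not fragments:
        raise ValueError("no fragments to call peaks on")
    if chrom is None:
        chrom = fragments[0].chrom

    n_windows = int(np.ceil(genome_len / window))
    mids = np.array([f.midpoint for f in fragments])
    widx = np.minimum((mids // window).astype(int), n_windows - 1)
    counts = np.bincount(widx, minlength=n_windows)

    lam = len(fragments) * window / genome_len
    pvals = stats.poisson.sf(counts - 1, lam)  # P(X >= c)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")

    sig = np.flatnonzero(reject)
    out = []
    if sig.size:
        run = [sig[0]]
        for w in sig[1:]:
            if w - run[-1] <= 2:  # gap of at most one non-significant window
                run.append(w)
            else:
                out.append(run)
                run = [w]
        out.append(run)
    regions = []
    for run in out:
        start = run[0] * window
        end = min((run[-1] + 1) * window, genome_len)
        p = float(pvals[run].min())
        regions.append((GenomicInterval(chrom, start, end), p))
    return regions


def flank_regions(peaks, flank: int = 5000, genome_len: int | None = None):
    """Peak-flanking background regions: ``flank`` bp each side of every peak,
    clipped to the chromosome and with any overlap with any peak subtracted."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    peaks = sorted(peaks, key=lambda p: (p.chrom, p.start))
    by_chrom: dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))

    out = []
    for p in peaks:
        candidates = [
            (max(p.start - flank, 0), p.start),
            (p.end, p.end + flank if genome_len is None else min(p.end + flank, genome_len)),
        ]
        for s, e in candidates:
            pieces = [(s, e)] if s < e else []
            for qs, qe in by_chrom[p.chrom]:
                nxt = []
                for ps, pe in pieces:
                    if qe <= ps or qs >= pe:
                        nxt.append((ps, pe))
                        continue
                    if ps < qs:
                        nxt.append((ps, qs))
                    if qe < pe:
                        nxt.append((qe, pe))
                pieces = nxt
            out.extend(GenomicInterval(p.chrom, ps, pe) for ps, pe in pieces if pe > ps)
    return out


def count_fragments_in_regions(samples: dict, regions) -> RegionCountMatrix:
    """Count each sample's fragments per region by midpoint containment.

    ``samples`` maps keys to :class:`SampleFragments`; column order follows
    the dict order of ``samples``.
    """
    regions = list(regions)
    ids = [s.sample_id for s in samples.values()]
    counts = np.zeros((len(regions), len(samples)), dtype=int)
    for j, s in enumerate(samples.values()):
        mids: dict[str, np.ndarray] = {}
        for f in s.fragments:
            mids.setdefault(f.chrom, []).append(f.midpoint)
        mids = {c: np.sort(np.asarray(v)) for c, v in mids.items()}
        for ridx, r in enumerate(regions):
            m = mids.get(r.chrom)
            if m is None:
                continue
            counts[ridx, j] = np.searchsorted(m, r.end, side="left") - np.searchsorted(
                m, r.start, side="left"
            )
    return RegionCountMatrix(regions, ids, counts)


def size_factors_median_of_ratios(counts: RegionCountMatrix) -> dict:
    """Median-of-ratios size factors (the estimator behind DESeq's
    estimateSizeFactors): sf_j = median over regions i of
    counts[i, j] / geomean_i, over regions with positive geometric mean."""
    c = counts.counts.astype(float)
    if c.shape[1] < 2:
        raise ValueError("need at least two samples")
    with np.errstate(divide="ignore"):
        logc = np.log(c)
    g = np.exp(logc.mean(axis=1))  # 0 when any sample has 0
    ok = g > 0
    if not np.any(ok):
        raise ValueError("no region with all-positive counts")
    ratios = c[ok] / g[ok, None]
    sf = np.median(ratios, axis=0)
    if np.any(sf <= 0):
        raise ValueError("non-positive size factor")
    return {sid: float(v) for sid, v in zip(counts.samples, sf)}


def thin_fragments(sample: SampleFragments, sf: dict, seed: int) -> SampleFragments:
    """Binomially subsample a sample to the depth of the shallowest sample.

    The retention rate is ``r_j = min(sf) / sf_j`` (in (0, 1]); each fragment
    is kept independently with probability ``r_j``.
    """
    if sample.sample_id not in sf:
        raise KeyError(f"sample {sample.sample_id} missing from size factors")
    r = min(sf.values()) / sf[sample.sample_id]
    if r >= 1.0:
        return SampleFragments(sample.sample_id, sample.condition, list(sample.fragments))
    rng = np.random.default_rng(seed)
    keep = rng.random(sample.n) < r
    kept = [f for f, k in zip(sample.fragments, keep) if k]
    logger.info("thin %s: rate %.4f, kept %d/%d", sample.sample_id, r, len(kept), sample.n)
    return SampleFragments(sample.sample_id, sample.condition, kept)


def normalize_experiment(
    samples: dict,
    genome_len: int,
    assay: str = "histone",
    window: int = 500,
    alpha: float = 0.05,
    flank: int = 5000,
    seed: int = 0,
):
    """Full background-based normalization chain.

    filter -> pool -> call peaks -> flanks -> count -> size factors -> thin.
    Returns ``(thinned_samples, peaks, flanks, size_factors)``.
    """
    max_len = DEFAULT_SIZE_FILTERS.get(assay)
    if assay not in DEFAULT_SIZE_FILTERS:
        raise ValueError(f"unknown assay {assay!r}")
    filtered = {
        k: (filter_fragments_by_size(s, max_len) if max_len else s)
        for k, s in samples.items()
    }
    pooled = [f for s in filtered.values() for f in s.fragments]
    peaks_p = call_enriched_regions(pooled, genome_len, window=window, alpha=alpha)
    peaks = [iv for iv, _ in peaks_p]
    flanks = flank_regions(peaks, flank=flank, genome_len=genome_len)
    counts = count_fragments_in_regions(filtered, flanks)
    sf = size_factors_median_of_ratios(counts)
    ss = np.random.SeedSequence(seed).spawn(len(filtered))
    thinned = {
        k: thin_fragments(s, sf, seed=int(child.generate_state(1)[0] % (2**31)))
        for (k, s), child in zip(filtered.items(), ss)
    }
    return thinned, peaks_p, flanks, sf
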