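"""Replicate-aware differential loop analysis.

The statistic works on a union of loop calls: every candidate is re-scored in
every sample, scores are z-normalized within each sample across all
candidates, differences of control-minus-treatment z-scores are formed over
replicate pairings (the full cross product by default), and the resulting
difference scores DS are combined with Stouffer's method,

    Z(i, j) = sum(DS) / sqrt(k),      k = |DS|,

with two-sided normal p-values; candidates with p below the threshold are
significant.  Z > 0 means the interaction is weaker in the treatment (lost),
Z < 0 means gained.

The DS elements share replicates, so they are not fully independent and the
meta-analysis is mildly anticonservative; the test suite characterizes this
by permutation rather than correcting it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats

from .hic_loops import DEFAULTS, LoopCandidate, loop_score
from .io_formats import BinnedContactMap, GenomicInterval

__all__ = [
    "SampleLoopScores",
    "DifferentialLoop",
    "score_union_loops",
    "differential_loop_meta",
    "interaction_change_summary",
    "locus_rearrangement_enrichment",
    "loop_anchor_intervals",
]


@dataclass
class SampleLoopScores:
    """Per-sample loop scores and within-sample z-scores over the union."""

    sample_id: str
    condition: str
    scores: np.ndarray
    z: np.ndarray = field(default=None)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.z is None:
            sd = self.scores.std()  # population (n-denominator) convention
            if sd == 0:
                raise ValueError(
                    f"sample {self.sample_id}: zero variance in loop scores; "
                    "z-normalization undefined"
                )
            self.z = (self.scores - self.scores.mean()) / sd
        self.z = np.asarray(self.z, dtype=float)


@dataclass
class DifferentialLoop:
    candidate: LoopCandidate
    ds: np.ndarray
    z_meta: float
    p: float
    direction: str
    significant: bool

    @property
    def k(self) -> int:
        return len(self.ds)


def score_union_loops(
    maps: dict,
    per_sample_calls: dict,
    p: int = DEFAULTS["p"],
    w: int = DEFAULTS["w"],
    m_min: int = DEFAULTS["m_min"],
):
    """Union per-sample loop calls and score every candidate in every sample.

    ``maps`` maps sample key -> smoothed O/E :class:`BinnedContactMap`;
    ``per_sample_calls`` maps the same keys to that sample's loop calls
    (:class:`~loopshift.hic_loops.ScoredLoop` or bare candidates).  Candidates
    invalid in any sample are dropped.  Returns ``(candidates, scores)`` with
    ``scores`` a dict of :class:`SampleLoopScores` keyed like ``maps``.
    """
    union = set()
    for calls in per_sample_calls.values():
        for c in calls:
            cand = c.candidate if hasattr(c, "candidate") else c
            union.add((cand.chrom, cand.i, cand.j))
    if not union:
        raise ValueError("empty loop union")
    candidates = [LoopCandidate(*t) for t in sorted(union)]

    raw = {}
    keep = np.ones(len(candidates), dtype=bool)
    for key, cmap in maps.items():
        vals = np.full(len(candidates), np.nan)
        for idx, cand in enumerate(candidates):
            if cand.chrom != cmap.chrom:
                keep[idx] = False
                continue
            comp = loop_score(cmap, cand, p=p, w=w, m_min=m_min)
            if comp.valid:
                vals[idx] = comp.score
            else:
                keep[idx] = False
        raw[key] = vals

    kept = [c for c, k in zip(candidates, keep) if k]
    if not kept:
        raise ValueError("no candidate is valid in every sample")
    scores = {}
    for key, cmap in maps.items():
        sid, cond = _sample_identity(key)
        scores[key] = SampleLoopScores(sid, cond, raw[key][keep])
    return kept, scores


def _sample_identity(key):
    """Best-effort (sample_id, condition) from a maps key like (cond, rep) or
    (cond, rep, chrom)."""
    if isinstance(key, tuple) and len(key) >= 2:
        return f"{key[0]}_rep{key[1]}", str(key[0])
    return str(key), str(key)


def differential_loop_meta(
    scores: dict,
    mode: str = "all_combinations",
    alpha: float = 0.05,
    conditions: tuple | None = None,
    candidates=None,
):
    """Stouffer meta-analysis of per-replicate z-score differences.

    ``scores`` maps keys to :class:`SampleLoopScores`; ``conditions`` names
    (control, treatment) — by default the two labels in sorted order.  DS
    elements are z_control - z_treatment over the full replicate cross
    product (``all_combinations``) or positionally matched replicates
    (``matched_pairs``).
    """
    by_cond: dict = {}
    for s in scores.values():
        by_cond.setdefault(s.condition, []).append(s)
    if conditions is None:
        if len(by_cond) != 2:
            raise ValueError("exactly two conditions required")
        conditions = tuple(sorted(by_cond))
    c1, c2 = conditions
    reps1 = sorted(by_cond[c1], key=lambda s: s.sample_id)
    reps2 = sorted(by_cond[c2], key=lambda s: s.sample_id)
    if not reps1 or not reps2:
        raise ValueError("need at least one replicate per condition")

    n_cand = len(reps1[0].z)
    for s in list(reps1) + list(reps2):
        if len(s.z) != n_cand:
            raise ValueError("replicates scored on different candidate sets")
        if s.scores.std() == 0:
            raise ValueError(f"sample {s.sample_id}: zero variance in loop scores")

    if mode == "all_combinations":
        pairs = list(product(reps1, reps2))
    elif mode == "matched_pairs":
        if len(reps1) != len(reps2):
            raise ValueError("matched_pairs requires equal replicate counts")
        pairs = list(zip(reps1, reps2))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ds = np.stack([a.z - b.z for a, b in pairs], axis=1)  # candidates x k
    k = ds.shape[1]
    z_meta = ds.sum(axis=1) / np.sqrt(k)
    p = 2 * stats.norm.sf(np.abs(z_meta))

    if candidates is None:
        candidates = [LoopCandidate("chrU", i, i + 1 + n_cand) for i in range(n_cand)]
    out = []
    for idx, cand in enumerate(candidates):
        sig = p[idx] < alpha
        if sig and z_meta[idx] > 0:
            direction = "lost"
        elif sig and z_meta[idx] < 0:
            direction = "gained"
        else:
            direction = "unchanged"
        out.append(
            DifferentialLoop(cand, ds[idx].copy(), float(z_meta[idx]), float(p[idx]),
                             direction, bool(sig))
        )
    return out


def loop_anchor_intervals(loop: DifferentialLoop, bin_size: int):
    """The two anchor bin intervals of a loop candidate."""
    c = loop.candidate
    return (
        GenomicInterval(c.chrom, c.i * bin_size, (c.i + 1) * bin_size),
        GenomicInterval(c.chrom, c.j * bin_size, (c.j + 1) * bin_size),
    )


def interaction_change_summary(
    diffs,
    genes,
    bin_size: int,
    tss_halfwidth: int = 5000,
    hotspot_window: int = 1_000_000,
):
    """Downstream summaries of significant differential loops.

    Returns ``(per_chrom, ranked_promoters, hotspots)``: a per-chromosome
    count of significant loops; genes ranked by the number of significant
    loops with an anchor intersecting [TSS - h, TSS + h] (descending count,
    ties by gene id); and sliding windows (width ``hotspot_window``, step
    half the width) ranked by contained significant-loop anchor count.
    """
    sig = [d for d in diffs if d.significant]
    per_chrom: dict = {}
    anchors = []
    for d in sig:
        per_chrom[d.candidate.chrom] = per_chrom.get(d.candidate.chrom, 0) + 1
        anchors.append((d, loop_anchor_intervals(d, bin_size)))

    gene_counts = []
    for g in genes:
        lo, hi = g.tss - tss_halfwidth, g.tss + tss_halfwidth
        cnt = sum(
            1
            for d, (a, b) in anchors
            if any(iv.chrom == g.chrom and iv.start <= hi and lo < iv.end for iv in (a, b))
        )
        gene_counts.append((g.gene_id, cnt))
    ranked = sorted(gene_counts, key=lambda t: (-t[1], t[0]))

    hotspots = []
    if anchors:
        step = max(hotspot_window // 2, 1)
        by_chrom: dict = {}
        for d, (a, b) in anchors:
            for iv in (a, b):
                by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            span = max(iv.end for iv in ivs)
            for start in range(0, span, step):
                end = start + hotspot_window
                cnt = sum(1 for iv in ivs if iv.start < end and start < iv.end)
                if cnt:
                    hotspots.append((GenomicInterval(chrom, start, end), cnt))
        hotspots.sort(key=lambda t: (-t[1], t[0].chrom, t[0].start))
    return per_chrom, ranked, hotspots


def locus_rearrangement_enrichment(
    diffs,
    loci_all,
    loci_subset,
    bin_size: int,
    halfwidth: int = 5000,
    side: str = "two-sided",
):
    """Welch's unequal-variance t comparing rearrangement counts at a locus
    subset vs all loci.

    Per locus, the count of significant differential loops with an anchor
    intersecting [center - h, center + h].  Returns
    ``(mean_all, mean_subset, t, p)``; the statistic is positive when the
    subset is more rearranged.
    """
    loci_all, loci_subset = list(loci_all), list(loci_subset)
    if len(loci_all) < 2 or len(loci_subset) < 2:
        raise ValueError("need at least two loci in each group")
    sig_anchors = [
        iv
        for d in diffs
        if d.significant
        for iv in loop_anchor_intervals(d, bin_size)
    ]

    def counts(loci):
        out = np.zeros(len(loci))
        for k, locus in enumerate(loci):
            center = locus.midpoint if hasattr(locus, "midpoint") else float(locus)
            chrom = locus.chrom if hasattr(locus, "chrom") else None
            lo, hi = center - halfwidth, center + halfwidth
            out[k] = sum(
                1
                for iv in sig_anchors
                if (chrom is None or iv.chrom == chrom) and iv.start <= hi and lo < iv.end
            )
        return out

    x = counts(loci_subset)
    y = counts(loci_all)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups; Welch's t undefined")
    alternative = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[side]
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return float(y.mean()), float(x.mean()), float(res.statistic), float(res.pvalue)
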