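"""Peak-to-gene scoring, loop-anchor enhancer/promoter annotation, and
gain/loss bias statistics.

Peak-to-gene scoring spreads each differential peak's evidence over nearby
genes: a peak with p-value P and n genes within the TSS window contributes
(1/n) * (-10 * log10 P) to each of those genes (PHRED-like, base 10, on the
raw p-value).

Loop anchors are classified as promoter (within a TSS window, which takes
precedence) or enhancer (overlapping an active-chromatin peak, e.g.
H3K27ac), and flagged with named differential-binding changes.  The gain/loss
bias of a category is the ratio of significant gained to lost loops with a
qualifying anchor; category pairs are compared by a one-sided Wilcoxon
rank-sum test on per-anchor net change, BH-corrected across comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .differential_binding import bh_adjust
from .differential_loops import DifferentialLoop, loop_anchor_intervals
from .io_formats import GenomicInterval

__all__ = [
    "GeneAnnotation",
    "GeneScoreTable",
    "AnchorAnnotation",
    "BiasResult",
    "score_genes_from_peaks",
    "annotate_anchors",
    "annotate_loop_anchors",
    "gain_loss_bias",
    "rank_sum_one_sided",
]

MAX_NEGLOGP = -10 * np.log10(1e-300)  # cap for p == 0


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self):
        if self.tss == self.tts:
            raise ValueError("tss must differ from tts")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError("+ strand requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError("- strand requires tss > tts")


@dataclass
class GeneScoreTable:
    scores: dict  # gene id -> cumulative score
    contributions: dict  # gene id -> list of (peak, n, p, contribution)

    def ranked(self):
        return sorted(self.scores.items(), key=lambda t: (-t[1], t[0]))


@dataclass
class AnchorAnnotation:
    anchor: GenomicInterval
    classes: frozenset  # subset of {"promoter", "enhancer"}
    flags: frozenset = frozenset()  # names of matched differential sets


@dataclass
class BiasResult:
    category: str
    gained: int
    lost: int
    bias: float | None  # None when lost == 0
    u: float | None = None
    p: float | None = None
    padj: float | None = None
    versus: str | None = None


def score_genes_from_peaks(peaks, genes, window: int = 25_000) -> GeneScoreTable:
    """Cumulative (1/n) * (-10 log10 p) gene scores from differential peaks.

    ``n`` is the number of genes whose TSS lies within ``window`` bp
    (inclusive) of the peak midpoint; peaks near no gene contribute nothing.
    p = 0 is capped at the -10*log10(1e-300) contribution and flagged.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    scores: dict = {}
    contributions: dict = {}
    for peak in peaks:
        center = peak.interval.midpoint
        near = [
            g for g in genes
            if g.chrom == peak.interval.chrom and abs(g.tss - center) <= window
        ]
        n = len(near)
        if n == 0:
            continue
        nlp = MAX_NEGLOGP if peak.p <= 0 else min(-10 * np.log10(peak.p), MAX_NEGLOGP)
        contrib = nlp / n
        for g in near:
            scores[g.gene_id] = scores.get(g.gene_id, 0.0) + contrib
            contributions.setdefault(g.gene_id, []).append((peak, n, peak.p, contrib))
    return GeneScoreTable(scores, contributions)


def annotate_anchors(
    anchors,
    genes,
    k27ac_peaks,
    differential_sets: dict | None = None,
    promoter_halfwidth: int = 2_000,
):
    """Classify anchors as promoter/enhancer and attach differential flags.

    Promoter: the anchor intersects any [tss - h, tss + h] window (takes
    precedence).  Enhancer: otherwise, the anchor intersects an active-mark
    peak.  ``differential_sets`` maps a flag name to
    ``(DifferentialRegion list, required_direction)`` with direction in
    {"gained", "lost", "any"}.
    """
    if promoter_halfwidth <= 0:
        raise ValueError("promoter_halfwidth must be positive")
    differential_sets = differential_sets or {}
    qualifying = {}
    for name, (regions, required) in differential_sets.items():
        if required not in {"gained", "lost", "any"}:
            raise ValueError(f"unknown direction token {required!r}")
        qualifying[name] = [
            r for r in regions
            if (r.direction != "unchanged" if required == "any" else r.direction == required)
        ]

    out = []
    for anchor in anchors:
        is_promoter = any(
            g.chrom == anchor.chrom
            and anchor.start <= g.tss + promoter_halfwidth
            and g.tss - promoter_halfwidth < anchor.end
            for g in genes
        )
        classes = set()
        if is_promoter:
            classes.add("promoter")
        elif any(anchor.overlaps(pk) for pk in k27ac_peaks):
            classes.add("enhancer")
        flags = {
            name
            for name, regions in qualifying.items()
            if any(anchor.overlaps(r.interval) for r in regions)
        }
        out.append(AnchorAnnotation(anchor, frozenset(classes), frozenset(flags)))
    return out


def annotate_loop_anchors(diffs, bin_size: int, genes, k27ac_peaks,
                          differential_sets=None, promoter_halfwidth: int = 2_000):
    """Annotate the distinct anchor bins of a differential-loop list.

    Returns a dict keyed by (chrom, bin index) -> :class:`AnchorAnnotation`.
    """
    keys = []
    seen = set()
    for d in diffs:
        for b in (d.candidate.i, d.candidate.j):
            key = (d.candidate.chrom, b)
            if key not in seen:
                seen.add(key)
                keys.append(key)
    anchors = [
        GenomicInterval(chrom, b * bin_size, (b + 1) * bin_size) for chrom, b in keys
    ]
    annos = annotate_anchors(anchors, genes, k27ac_peaks, differential_sets,
                             promoter_halfwidth)
    return dict(zip(keys, annos))


def rank_sum_one_sided(x, y):
    """Wilcoxon rank-sum (Mann-Whitney) U and one-sided p (x greater),
    normal approximation with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic",
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def gain_loss_bias(
    diffs,
    annos: dict,
    bin_size: int,
    categories: dict,
    compare=(),
):
    """Gain/loss counts and bias per anchor category, with optional pairwise
    one-sided rank-sum comparisons.

    ``annos`` is keyed by (chrom, bin) as from :func:`annotate_loop_anchors`;
    ``categories`` maps a name to a predicate over :class:`AnchorAnnotation`;
    ``compare`` lists (category_a, category_b) pairs tested one-sided for
    category_a showing greater per-anchor net change (gained minus lost loop
    count per qualifying anchor), BH-corrected across the listed comparisons.
    """
    sig = [d for d in diffs if d.significant]

    def anchor_keys(d):
        return [(d.candidate.chrom, d.candidate.i), (d.candidate.chrom, d.candidate.j)]

    results = {}
    nets = {}
    for name, pred in categories.items():
        qualifying = {key for key, anno in annos.items() if pred(anno)}
        g = sum(
            1 for d in sig
            if d.direction == "gained" and any(k in qualifying for k in anchor_keys(d))
        )
        l = sum(
            1 for d in sig
            if d.direction == "lost" and any(k in qualifying for k in anchor_keys(d))
        )
        bias = (g / l) if l > 0 else None
        results[name] = BiasResult(name, g, l, bias)
        per_anchor = {}
        for d in sig:
            delta = 1 if d.direction == "gained" else -1 if d.direction == "lost" else 0
            for k in anchor_keys(d):
                if k in qualifying:
                    per_anchor[k] = per_anchor.get(k, 0) + delta
        for k in qualifying:
            per_anchor.setdefault(k, 0)
        nets[name] = np.array(sorted(per_anchor.values()), dtype=float)

    comparisons = []
    pvals = []
    for ca, cb in compare:
        if ca not in categories or cb not in categories:
            raise KeyError(f"unknown category in comparison ({ca}, {cb})")
        x, y = nets[ca], nets[cb]
        if x.size == 0 or y.size == 0:
            raise ValueError(f"empty category in comparison ({ca}, {cb})")
        u, p = rank_sum_one_sided(x, y)
        comparisons.append((ca, cb, u, p))
        pvals.append(p)
    padj = bh_adjust(pvals) if pvals else []
    out = list(results.values())
    for (ca, cb, u, p), q in zip(comparisons, padj):
        r = results[ca]
        out.append(
            BiasResult(ca, r.gained, r.lost, r.bias, u=u, p=p, padj=float(q), versus=cb)
        )
    return out
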