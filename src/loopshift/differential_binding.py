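"""Two-group differential occupancy on a common region catalog.

The test mirrors the standard negative-binomial Wald workflow for count data:
size-factor-normalized counts per region, a gene-wise moment estimate of NB
dispersion from within-condition residuals shrunk toward a mean-dispersion
trend fitted across all regions, and a Wald statistic on the log2 fold change
with a delta-method standard error.  Multiple testing is controlled by
Benjamini-Hochberg across the catalog.

Also houses the overlap and co-occurrence statistics used downstream: the
one-sided hypergeometric test on peak-set overlaps and the extraction of
multi-assay co-differential loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage_normalization import (
    RegionCountMatrix,
    call_enriched_regions,
    count_fragments_in_regions,
)
from .io_formats import GenomicInterval

__all__ = [
    "DifferentialRegion",
    "differential_test",
    "differential_regions",
    "overlap_significance",
    "co_differential_loci",
    "bh_adjust",
]

DIRECTIONS = ("gained", "lost", "unchanged")


@dataclass
class DifferentialRegion:
    """One region's differential-binding result (condition 2 over condition 1)."""

    interval: GenomicInterval
    log2fc: float
    p: float
    padj: float
    direction: str

    def __post_init__(self):
        if not (0 <= self.p <= 1):
            raise ValueError("p must lie in [0, 1]")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _trended_dispersion(qmat: np.ndarray, groups: list) -> np.ndarray:
    """Per-region NB dispersion: within-group moment estimates shrunk to a
    fitted a0 + a1/mu trend across regions.

    ``qmat`` is regions x samples of normalized counts; ``groups`` is a list
    of column-index arrays, one per condition.  Within-group variances are
    residuals after the condition effect, so true fold changes do not inflate
    the dispersion.  The trend is fitted by least squares on trimmed moment
    estimates; per-region values are the trend evaluated at the region mean
    (strong shrinkage, appropriate for the few replicates typical here).
    """
    n_regions = qmat.shape[0]
    ests = np.full(n_regions, np.nan)
    mus = qmat.mean(axis=1)
    for r in range(n_regions):
        vals = []
        for g in groups:
            if len(g) < 2:
                continue
            qg = qmat[r, g]
            m = qg.mean()
            if m <= 0:
                continue
            vals.append((qg.var(ddof=1) - m) / m**2)
        if vals:
            ests[r] = float(np.mean(vals))

    ok = np.isfinite(ests) & (mus > 0)
    if ok.sum() >= 10:
        y = np.clip(ests[ok], -2.0, 10.0)
        x = 1.0 / mus[ok]
        X = np.column_stack([np.ones(ok.sum()), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        a0 = max(coef[0], 0.0)
        a1 = max(coef[1], 0.0)
    elif ok.any():
        a0, a1 = max(float(np.median(ests[ok])), 0.0), 0.0
    else:
        a0, a1 = 0.0, 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mus > 0, mus, np.inf)
    return np.maximum(trend, 1e-8)


def differential_test(
    counts: RegionCountMatrix,
    conditions: dict,
    sf: dict,
    alpha: float = 0.05,
    gate_on_adjusted: bool = True,
):
    """NB Wald test per region for condition 2 vs condition 1.

    ``conditions`` maps sample id -> condition label; the two labels are
    ordered lexicographically unless exactly ``cond1``/``cond2`` style order
    is given by first occurrence.  Returns a list of
    :class:`DifferentialRegion` in catalog order.
    """
    labels = [conditions[s] for s in counts.samples]
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError("exactly two conditions required")
    c1, c2 = uniq
    g1 = np.flatnonzero([lab == c1 for lab in labels])
    g2 = np.flatnonzero([lab == c2 for lab in labels])
    if len(counts.regions) == 0:
        raise ValueError("empty region catalog")

    sfv = np.array([sf[s] for s in counts.samples], dtype=float)
    q = counts.counts / sfv[None, :]

    disp = _trended_dispersion(q, [g1, g2])

    q1 = q[:, g1].mean(axis=1)
    q2 = q[:, g2].mean(axis=1)
    delta = np.log2((q2 + 0.5) / (q1 + 0.5))

    # delta-method variance of log2 of each group mean; 0.5 floor keeps the
    # SE finite for empty groups
    m1 = np.maximum(q1, 0.5)
    m2 = np.maximum(q2, 0.5)
    v1 = m1 + disp * m1**2
    v2 = m2 + disp * m2**2
    se2 = (1 / np.log(2)) ** 2 * (v1 / (len(g1) * m1**2) + v2 / (len(g2) * m2**2))
    se = np.sqrt(se2)

    with np.errstate(invalid="ignore"):
        w = np.where(se > 0, delta / se, 0.0)
    p = 2 * stats.norm.sf(np.abs(w))
    padj = bh_adjust(p)

    gate = padj if gate_on_adjusted else p
    out = []
    for k, region in enumerate(counts.regions):
        if gate[k] < alpha and delta[k] > 0:
            direction = "gained"
        elif gate[k] < alpha and delta[k] < 0:
            direction = "lost"
        else:
            direction = "unchanged"
        out.append(
            DifferentialRegion(region, float(delta[k]), float(p[k]), float(padj[k]), direction)
        )
    return out


def differential_regions(
    samples: dict,
    sf: dict,
    alpha: float = 0.05,
    genome_len: int | None = None,
    window: int = 500,
    gate_on_adjusted: bool = True,
):
    """Catalog-based differential binding from fragment samples.

    Pools all samples' fragments, calls enriched regions to define the common
    catalog, counts fragments per region per sample, and runs the NB Wald
    test.  ``samples`` maps keys to :class:`SampleFragments` whose
    ``condition`` labels define the two groups.
    """
    pooled = [f for s in samples.values() for f in s.fragments]
    if genome_len is None:
        genome_len = max(f.end for f in pooled)
    catalog = call_enriched_regions(pooled, genome_len, window=window)
    if not catalog:
        raise ValueError("empty region catalog: no enriched regions found")
    counts = count_fragments_in_regions(samples, [iv for iv, _ in catalog])
    conditions = {s.sample_id: s.condition for s in samples.values()}
    return differential_test(counts, conditions, sf, alpha=alpha,
                             gate_on_adjusted=gate_on_adjusted)


def overlap_significance(a, b, catalog_size: int):
    """One-sided hypergeometric overlap test on two catalog subsets.

    ``a`` and ``b`` are iterables of catalog indices; returns
    ``(M, p)`` where M is the overlap count and p the upper-tail
    hypergeometric probability P(X >= M) with population ``catalog_size``,
    ``|a|`` successes, and ``|b|`` draws.  BH over a batch of such tests is
    the caller's job (via :func:`bh_adjust`).
    """
    a, b = set(a), set(b)
    if len(a) > catalog_size or len(b) > catalog_size:
        raise ValueError("subset larger than catalog")
    m = len(a & b)
    p = float(stats.hypergeom.sf(m - 1, catalog_size, len(a), len(b)))
    return m, min(p, 1.0)


def co_differential_loci(sets: dict, merge_gap: int = 0):
    """Loci where every named assay shows a qualifying differential region.

    ``sets`` maps a name to ``(regions, required_direction)`` where regions
    are :class:`DifferentialRegion` and ``required_direction`` is one of
    ``gained``, ``lost``, or ``any`` (any non-unchanged direction).
    Qualifying regions from all sets are unioned, merged when separated by at
    most ``merge_gap`` bp, and merged loci are kept only if they intersect at
    least one qualifying region from *every* set.  Returns
    ``(locus_interval, {name: [regions...]})`` pairs.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    qualifying = {}
    for name, (regions, required) in sets.items():
        if required not in {"gained", "lost", "any"}:
            raise ValueError(f"unknown direction token {required!r}")
        if required == "any":
            q = [r for r in regions if r.direction != "unchanged"]
        else:
            q = [r for r in regions if r.direction == required]
        qualifying[name] = q

    allq = [(r.interval, name, r) for name, q in qualifying.items() for r in q]
    if not allq:
        return []
    allq.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))

    loci = []
    cur_chrom, cur_s, cur_e = allq[0][0].chrom, allq[0][0].start, allq[0][0].end
    members = [allq[0]]
    for iv, name, r in allq[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_e + merge_gap:
            cur_e = max(cur_e, iv.end)
            members.append((iv, name, r))
        else:
            loci.append((GenomicInterval(cur_chrom, cur_s, cur_e), members))
            cur_chrom, cur_s, cur_e = iv.chrom, iv.start, iv.end
            members = [(iv, name, r)]
    loci.append((GenomicInterval(cur_chrom, cur_s, cur_e), members))

    out = []
    for locus, members in loci:
        bysets: dict = {}
        for _, name, r in members:
            bysets.setdefault(name, []).append(r)
        if set(bysets) == set(sets):
            out.append((locus, bysets))
    return out
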