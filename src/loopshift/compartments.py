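"""A/B compartment analysis: PC1 with TSS-based sign orientation, saddle
plots with low-coverage removal, and compartment-switching statistics.

PC1 is the leading eigenvector of the Pearson correlation matrix of the O/E
contact map (HOMER-style).  Its sign is arbitrary, so the track is oriented
by TSS density: the sign class with the higher mean TSS count per bin becomes
'+' (the A, gene-dense compartment).

The saddle analysis drops the 1% lowest-coverage bins per chromosome, ranks
the rest by PC1 from high to low, coarse-grains the O/E map into a 100 x 100
percentile matrix, and averages over chromosomes; AA, BB and AB interaction
strengths are the mean O/E in the top-left, bottom-right and top-right
25 x 25 corner blocks (the top/bottom 25% of PC1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .hic_loops import oe_normalize
from .io_formats import BinnedContactMap

__all__ = [
    "CompartmentTrack",
    "SaddleResult",
    "compartment_pc1",
    "saddle_analysis",
    "saddle_diff",
    "switching_fraction",
]

logger = logging.getLogger(__name__)


@dataclass
class CompartmentTrack:
    chrom: str
    bin_size: int
    pc1: np.ndarray  # full-length, NaN on invalid bins
    valid_mask: np.ndarray
    orientation_fixed: bool = False
    ambiguous: bool = False

    def __post_init__(self):
        self.pc1 = np.asarray(self.pc1, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.pc1.shape != self.valid_mask.shape:
            raise ValueError("pc1/valid_mask length mismatch")


@dataclass
class SaddleResult:
    S: np.ndarray  # n_groups x n_groups mean O/E
    AA: float
    BB: float
    AB: float
    bins_used: dict  # chrom -> bin count after removal
    n_groups: int = 100


def compartment_pc1(cmap: BinnedContactMap, tss_positions) -> CompartmentTrack:
    """PC1 of the O/E correlation matrix, oriented so TSS-dense bins are '+'.

    ``tss_positions`` are bp coordinates on the same chromosome.  If the two
    sign classes tie in TSS density the track is left unflipped and marked
    ambiguous.
    """
    valid = cmap.valid_mask.copy()
    if valid.sum() < 10:
        raise ValueError("need at least 10 valid bins for PC1")
    oe = oe_normalize(cmap).values[np.ix_(valid, valid)]
    # rare cells on zero-expected pooled diagonals: neutral O/E
    oe = np.where(np.isnan(oe), 1.0, oe)

    sd = oe.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate correlation matrix: constant O/E column")
    corr = np.corrcoef(oe, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    v = evecs[:, -1]  # largest eigenvalue
    if v[np.argmax(np.abs(v))] < 0:
        v = -v  # deterministic gauge before orientation

    pc1 = np.full(cmap.n_bins, np.nan)
    pc1[valid] = v

    tss = np.asarray(list(tss_positions), dtype=float)
    counts = np.zeros(cmap.n_bins)
    if tss.size:
        bins = np.clip((tss // cmap.bin_size).astype(int), 0, cmap.n_bins - 1)
        counts = np.bincount(bins, minlength=cmap.n_bins).astype(float)
    pos = valid & (pc1 > 0)
    neg = valid & (pc1 < 0)
    dens_pos = counts[pos].mean() if pos.any() else 0.0
    dens_neg = counts[neg].mean() if neg.any() else 0.0
    ambiguous = math.isclose(dens_pos, dens_neg)
    if not ambiguous and dens_neg > dens_pos:
        pc1 = -pc1
    return CompartmentTrack(
        cmap.chrom, cmap.bin_size, pc1, valid,
        orientation_fixed=not ambiguous, ambiguous=ambiguous,
    )


def _partition_sizes(n: int, groups: int) -> list:
    base, rem = divmod(n, groups)
    return [base + 1 if g < rem else base for g in range(groups)]


def saddle_analysis(maps: dict, tracks: dict, n_groups: int = 100) -> SaddleResult:
    """Percentile-coarse-grained saddle matrix averaged over chromosomes.

    ``maps`` holds raw observed maps per chromosome (coverage is taken from
    them, O/E is computed here); ``tracks`` the matching oriented PC1 tracks.
    Chromosomes with fewer than ``n_groups`` usable bins after removing the
    ceil(1%) lowest-coverage bins are skipped.
    """
    mats = []
    bins_used = {}
    for chrom, cmap in maps.items():
        track = tracks[chrom]
        if track.chrom != cmap.chrom or len(track.pc1) != cmap.n_bins:
            raise ValueError(f"{chrom}: track/map bin grids mismatched")
        usable = cmap.valid_mask & ~np.isnan(track.pc1)
        idx = np.flatnonzero(usable)
        if idx.size == 0:
            continue
        cov = cmap.coverage[idx]
        n_drop = math.ceil(0.01 * idx.size)
        keep = idx[np.argsort(cov, kind="stable")[n_drop:]]
        if keep.size < n_groups:
            logger.info("saddle: skipping %s (%d bins < %d)", chrom, keep.size, n_groups)
            continue
        order = keep[np.argsort(-track.pc1[keep], kind="stable")]
        oe = oe_normalize(cmap).values

        sizes = _partition_sizes(order.size, n_groups)
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        s = np.full((n_groups, n_groups), np.nan)
        groups_idx = [order[bounds[g] : bounds[g + 1]] for g in range(n_groups)]
        for m in range(n_groups):
            for nn in range(m, n_groups):
                block = oe[np.ix_(groups_idx[m], groups_idx[nn])]
                ok = ~np.isnan(block)
                if ok.any():
                    s[m, nn] = s[nn, m] = block[ok].mean()
        mats.append(s)
        bins_used[chrom] = int(keep.size)

    if not mats:
        raise ValueError("no chromosome had enough bins for the saddle analysis")
    S = np.nanmean(np.stack(mats), axis=0)
    q = n_groups // 4
    AA = float(np.nanmean(S[:q, :q]))
    BB = float(np.nanmean(S[-q:, -q:]))
    AB = float(np.nanmean(S[:q, -q:]))
    return SaddleResult(S, AA, BB, AB, bins_used, n_groups)


def saddle_diff(a: SaddleResult, b: SaddleResult) -> np.ndarray:
    """Element-wise log2 fold change of two saddle matrices; cells undefined
    (NaN) where either side is missing or non-positive."""
    if a.S.shape != b.S.shape:
        raise ValueError("saddle grids differ")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((a.S > 0) & (b.S > 0), np.log2(a.S / b.S), np.nan)
    return out


def switching_fraction(a: CompartmentTrack, b: CompartmentTrack) -> float:
    """Fraction of common valid bins whose oriented PC1 signs disagree.

    Bins with PC1 exactly 0 in either track are excluded from the
    denominator.
    """
    if len(a.pc1) != len(b.pc1):
        raise ValueError("tracks on different grids")
    common = (
        a.valid_mask & b.valid_mask & ~np.isnan(a.pc1) & ~np.isnan(b.pc1)
        & (a.pc1 != 0) & (b.pc1 != 0)
    )
    if not common.any():
        raise ValueError("no common valid bins")
    return float(np.mean(np.sign(a.pc1[common]) != np.sign(b.pc1[common])))
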