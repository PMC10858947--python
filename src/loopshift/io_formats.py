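"""Readers and writers for the genomic text formats the pipeline touches.

All coordinates are 0-based half-open throughout the package; bin ``b`` of a
binned contact map spans ``[b * bin_size, (b + 1) * bin_size)``.  Contact maps
distinguish "observed zero" from "missing": a cell is missing (NaN) iff either
of its bins has zero total coverage, so the imputation stage knows what to
fill in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "BinnedContactMap",
    "read_intervals",
    "write_intervals",
    "read_contact_map",
    "write_contact_map",
    "read_dense_map",
    "write_dense_map",
    "write_longrange",
    "read_longrange",
    "write_bedgraph",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand and attributes."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    attrs: tuple = ()

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def attr_dict(self) -> dict:
        return dict(self.attrs)


@dataclass
class BinnedContactMap:
    """A symmetric cis contact matrix for one chromosome.

    ``values`` holds non-negative reals with NaN for missing cells; a cell is
    missing iff either bin has zero marginal coverage.  ``valid_mask`` marks
    bins with any signal; masked bins are excluded from all statistics.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    valid_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must be a square matrix")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("contact values must be non-negative")
        if self.valid_mask is None:
            cov = np.nansum(np.nan_to_num(self.values), axis=1)
            self.valid_mask = cov > 0
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (self.n_bins,):
            raise ValueError("valid_mask length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        """Per-bin marginal sum over defined cells."""
        return np.nansum(np.nan_to_num(self.values), axis=1)

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def copy_with(self, values: np.ndarray) -> "BinnedContactMap":
        return BinnedContactMap(
            chrom=self.chrom,
            bin_size=self.bin_size,
            values=values,
            valid_mask=self.valid_mask.copy(),
        )


def _parse_int(token: str, path, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed {what}: {token!r}") from None


def read_intervals(path, kind: str = "bed"):
    """Read a BED3+ or BEDPE file into intervals (or interval pairs).

    Extra columns beyond the coordinate columns are preserved in ``attrs`` as
    ``(("col4", value), ...)`` pairs; file order is preserved.  BEDPE rows are
    returned as ``(interval_a, interval_b)`` tuples whose shared extra columns
    are attached to both anchors.
    """
    if kind not in {"bed", "bedpe"}:
        raise ValueError(f"unknown kind {kind!r}")
    ncoord = 3 if kind == "bed" else 6
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncoord:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {ncoord} tab-separated columns, "
                    f"got {len(fields)}"
                )
            extra = tuple(
                (f"col{ncoord + 1 + k}", v) for k, v in enumerate(fields[ncoord:])
            )
            if kind == "bed":
                start = _parse_int(fields[1], path, lineno, "start")
                end = _parse_int(fields[2], path, lineno, "end")
                try:
                    out.append(GenomicInterval(fields[0], start, end, attrs=extra))
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: {e}") from None
            else:
                s1 = _parse_int(fields[1], path, lineno, "start1")
                e1 = _parse_int(fields[2], path, lineno, "end1")
                s2 = _parse_int(fields[4], path, lineno, "start2")
                e2 = _parse_int(fields[5], path, lineno, "end2")
                try:
                    a = GenomicInterval(fields[0], s1, e1, attrs=extra)
                    b = GenomicInterval(fields[3], s2, e2, attrs=extra)
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: {e}") from None
                out.append((a, b))
    return out


def write_intervals(records, path, kind: str = "bed") -> None:
    """Write intervals (BED) or interval pairs (BEDPE), attrs as extra columns."""
    with open(path, "w") as fh:
        for rec in records:
            if kind == "bed":
                iv = rec
                extra = [str(v) for _, v in iv.attrs]
                fh.write("\t".join([iv.chrom, str(iv.start), str(iv.end), *extra]) + "\n")
            elif kind == "bedpe":
                a, b = rec
                extra = [str(v) for _, v in a.attrs]
                fh.write(
                    "\t".join(
                        [a.chrom, str(a.start), str(a.end),
                         b.chrom, str(b.start), str(b.end), *extra]
                    )
                    + "\n"
                )
            else:
                raise ValueError(f"unknown kind {kind!r}")


def read_contact_map(matrix_path, bins_path) -> dict:
    """Read a triplet contact matrix plus bin table into per-chromosome maps.

    ``bins_path`` is BED with the absolute bin id in column 4; ``matrix_path``
    holds whitespace-separated ``id_i id_j value`` triplets (upper triangle is
    sufficient).  Cells absent from the triplets are 0 for bins with any
    signal and missing (NaN) for fully silent bins, whose ``valid_mask`` entry
    is False.
    """
    bins = {}  # absolute id -> (chrom, local index)
    per_chrom = {}  # chrom -> (bin_size, n_bins)
    with open(bins_path) as fh:
        order = {}
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{bins_path}:{lineno}: need 4 columns (chrom start end id)")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            bid = int(f[3])
            idx = order.setdefault(chrom, 0)
            order[chrom] = idx + 1
            bins[bid] = (chrom, idx)
            size = end - start
            if chrom in per_chrom:
                per_chrom[chrom] = (max(per_chrom[chrom][0], size), idx + 1)
            else:
                per_chrom[chrom] = (size, idx + 1)

    mats = {
        chrom: np.zeros((n, n)) for chrom, (_, n) in per_chrom.items()
    }
    with open(matrix_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            f = line.split()
            if len(f) != 3:
                raise ValueError(f"{matrix_path}:{lineno}: expected 3 fields")
            i, j = int(f[0]), int(f[1])
            v = float(f[2])
            if v < 0:
                raise ValueError(f"{matrix_path}:{lineno}: negative value {v}")
            if i not in bins or j not in bins:
                raise ValueError(
                    f"{matrix_path}:{lineno}: bin id {i if i not in bins else j} "
                    "absent from bins file"
                )
            (ci, ii), (cj, jj) = bins[i], bins[j]
            if ci != cj:
                continue  # only cis maps are materialized
            mats[ci][ii, jj] += v
            if ii != jj:
                mats[ci][jj, ii] += v

    out = {}
    for chrom, (size, n) in per_chrom.items():
        m = mats[chrom]
        cov = m.sum(axis=1)
        valid = cov > 0
        vals = m.astype(float)
        vals[~valid, :] = np.nan
        vals[:, ~valid] = np.nan
        out[chrom] = BinnedContactMap(chrom, size, vals, valid)
    return out


def write_contact_map(maps: dict, matrix_path, bins_path) -> None:
    """Write per-chromosome maps as a HiC-Pro-style bin table + triplet file."""
    bid = 1
    with open(bins_path, "w") as bf, open(matrix_path, "w") as mf:
        for chrom in sorted(maps):
            cmap = maps[chrom]
            ids = list(range(bid, bid + cmap.n_bins))
            for k, b in enumerate(ids):
                bf.write(
                    f"{chrom}\t{k * cmap.bin_size}\t{(k + 1) * cmap.bin_size}\t{b}\n"
                )
            vals = cmap.values
            for i in range(cmap.n_bins):
                for j in range(i, cmap.n_bins):
                    v = vals[i, j]
                    if not np.isnan(v) and v != 0:
                        out = int(v) if float(v).is_integer() else v
                        mf.write(f"{ids[i]} {ids[j]} {out}\n")
            bid += cmap.n_bins


def read_dense_map(path, chrom: str = "chr1", bin_size: int = 5000) -> BinnedContactMap:
    """Read a dense TSV matrix (NaN or 'nan' for missing cells)."""
    vals = np.loadtxt(path, delimiter="\t", ndmin=2)
    return BinnedContactMap(chrom, bin_size, vals)


def write_dense_map(cmap: BinnedContactMap, path) -> None:
    np.savetxt(path, cmap.values, delimiter="\t", fmt="%.10g")


def write_longrange(pairs, path) -> None:
    """Write scored anchor pairs in the WashU longrange text format.

    Each record is ``(anchor_a, anchor_b, score)``; output lines are
    ``chrom\tstart\tend\tchrom2:start2-end2,score`` sorted by (chrom, start)
    so the file is ready for bgzip + tabix.
    """
    rows = []
    for a, b, score in pairs:
        s = float(score)  # raises for non-numeric scores
        rows.append((a.chrom, a.start, a.end, b.chrom, b.start, b.end, s))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3], r[4]))
    with open(path, "w") as fh:
        for c1, s1, e1, c2, s2, e2, sc in rows:
            sc_out = int(sc) if float(sc).is_integer() else sc
            fh.write(f"{c1}\t{s1}\t{e1}\t{c2}:{s2}-{e2},{sc_out}\n")


def read_longrange(path):
    """Read a longrange file back into (anchor_a, anchor_b, score) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            target, _, score = f[3].rpartition(",")
            chrom2, _, span = target.partition(":")
            s2, _, e2 = span.partition("-")
            out.append(
                (
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    GenomicInterval(chrom2, int(s2), int(e2)),
                    float(score),
                )
            )
    return out


def write_bedgraph(chrom: str, starts, ends, values, path) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")
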