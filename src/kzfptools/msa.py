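"""Projection of per-base genomic signal onto multiple sequence
alignments of TE copies, and consensus-centered unaligned profiles.

A precomputed alignment of the genomic copies of a TE subfamily (e.g.
from MAFFT) places homologous bases of every copy in the same column.
Laying each copy's ChIP signal onto its row of the alignment, removing
gap-dominated columns, min-max scaling each row and averaging down the
columns yields a meta-profile of where on the element a protein binds.
For composite elements whose internal repeats defeat alignment (SVA
VNTRs), copies are instead centered on the best match of a consensus
motif and profiled in plain genomic windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Track = dict[str, np.ndarray]


@dataclass
class AlignedCopy:
    """One aligned sequence with its genomic provenance."""

    id: str
    chrom: str
    start: int  # 0-based half-open genomic span
    end: int
    strand: str
    aligned_seq: str  # alignment row; '-' = gap

    @property
    def ungapped_length(self) -> int:
        return len(self.aligned_seq) - self.aligned_seq.count("-")


@dataclass
class AlignedSignalMatrix:
    copy_ids: list[str]
    values: np.ndarray  # copies x columns, float
    gap_mask: np.ndarray  # True = gap
    flank_bp: int = 0
    dropped: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def _track_value(track: Track, chrom: str, pos: np.ndarray) -> np.ndarray:
    """Track lookup; bases outside the stored array read as 0."""
    arr = track.get(chrom)
    out = np.zeros(len(pos), dtype=float)
    if arr is None:
        return out
    ok = (pos >= 0) & (pos < len(arr))
    out[ok] = arr[pos[ok]]
    return out


def project_signal(
    copies: list[AlignedCopy],
    track: Track,
    flank_bp: int = 0,
) -> AlignedSignalMatrix:
    """Lay the signal track onto the alignment, one row per copy.

    Column j of a copy holds the track value at the genomic base of the
    j-th non-gap character, counted along the copy's own orientation
    (minus-strand copies read the genome right to left).  Gap cells are
    masked.  With ``flank_bp`` > 0, that many unaligned columns of
    flanking genomic signal are prepended and appended (element
    orientation preserved); flank cells falling outside the track are
    masked.
    """
    if not copies:
        raise ValueError("no aligned copies")
    width = len(copies[0].aligned_seq)
    for c in copies:
        if len(c.aligned_seq) != width:
            raise ValueError(f"copy {c.id}: alignment rows differ in width")
        if c.ungapped_length != c.end - c.start:
            raise ValueError(
                f"copy {c.id}: ungapped length {c.ungapped_length} != genomic span "
                f"{c.end - c.start}"
            )
    total = width + 2 * flank_bp
    values = np.zeros((len(copies), total), dtype=float)
    gap_mask = np.ones((len(copies), total), dtype=bool)
    for r, c in enumerate(copies):
        is_gap = np.frombuffer(c.aligned_seq.encode(), dtype=np.uint8) == ord("-")
        nongap_cols = np.flatnonzero(~is_gap)
        i = np.arange(len(nongap_cols))
        if c.strand == "+":
            pos = c.start + i
        else:
            pos = c.end - 1 - i
        values[r, flank_bp + nongap_cols] = _track_value(track, c.chrom, pos)
        gap_mask[r, flank_bp + nongap_cols] = False
        if flank_bp:
            k = np.arange(1, flank_bp + 1)
            if c.strand == "+":
                left, right = c.start - k[::-1], c.end - 1 + k
            else:
                left, right = c.end - 1 + k[::-1], c.start - k
            for cols, gpos in (
                (np.arange(flank_bp), left),
                (np.arange(total - flank_bp, total), right),
            ):
                arr = track.get(c.chrom)
                n = len(arr) if arr is not None else 0
                ok = (gpos >= 0) & (gpos < n)
                values[r, cols[ok]] = _track_value(track, c.chrom, gpos[ok])
                gap_mask[r, cols[ok]] = False
    return AlignedSignalMatrix([c.id for c in copies], values, gap_mask, flank_bp)


def filter_gap_columns(matrix: AlignedSignalMatrix, max_gap_frac: float = 0.85) -> AlignedSignalMatrix:
    """Drop columns whose gap fraction strictly exceeds ``max_gap_frac``.

    The default 0.85 keeps columns with exactly 85% gaps (strict
    inequality); column order is preserved.
    """
    frac = matrix.gap_mask.mean(axis=0)
    keep = frac <= max_gap_frac
    return AlignedSignalMatrix(
        matrix.copy_ids,
        matrix.values[:, keep],
        matrix.gap_mask[:, keep],
        matrix.flank_bp,
        list(matrix.dropped),
    )


def scale_rows(matrix: AlignedSignalMatrix) -> AlignedSignalMatrix:
    """Min-max scale each row to [0,1] over its non-gap cells.

    Constant rows (max == min) are set to 0 everywhere; gap cells are
    untouched.  Idempotent.
    """
    values = matrix.values.copy()
    for r in range(values.shape[0]):
        sel = ~matrix.gap_mask[r]
        if not sel.any():
            continue
        v = values[r, sel]
        lo, hi = v.min(), v.max()
        values[r, sel] = 0.0 if hi == lo else (v - lo) / (hi - lo)
    return AlignedSignalMatrix(
        matrix.copy_ids, values, matrix.gap_mask.copy(), matrix.flank_bp, list(matrix.dropped)
    )


def mean_profile(matrix: AlignedSignalMatrix) -> np.ndarray:
    """Per-column mean over non-gap cells; all-gap columns yield NaN."""
    counts = (~matrix.gap_mask).sum(axis=0)
    sums = np.where(matrix.gap_mask, 0.0, matrix.values).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _hamming_scan(seq: str, motif: str) -> tuple[int, int]:
    """(best offset, best Hamming distance) of motif in seq; ties leftmost."""
    m = len(motif)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    q = np.frombuffer(motif.encode(), dtype=np.uint8)
    n = len(s) - m + 1
    if n <= 0:
        raise ValueError("sequence shorter than motif")
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    dists = (windows != q).sum(axis=1)
    off = int(np.argmin(dists))  # argmin is leftmost on ties
    return off, int(dists[off])


def center_on_consensus(
    copies: list[AlignedCopy],
    track: Track,
    motif: str,
    flank: int,
    max_mismatch: int | None = None,
) -> AlignedSignalMatrix:
    """Unaligned profiling: center each copy on its best motif match.

    ``copies`` carry ungapped element sequences (gaps, if present, are
    ignored).  The motif is placed at the minimum-Hamming-distance
    offset (leftmost on ties); copies whose best distance exceeds
    ``max_mismatch`` (default ceil(len(motif)/4)) or that are shorter
    than the motif are dropped and listed in ``dropped``.  The window is
    [match midpoint - flank, match midpoint + flank) in element
    coordinates, mapped strand-aware to the genome; out-of-element cells
    are masked.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if max_mismatch is None:
        max_mismatch = int(np.ceil(len(motif) / 4))
    ids, rows, masks, dropped = [], [], [], []
    width = 2 * flank
    for c in copies:
        seq = c.aligned_seq.replace("-", "")
        if len(seq) < len(motif):
            dropped.append(c.id)
            continue
        off, dist = _hamming_scan(seq, motif)
        if dist > max_mismatch:
            dropped.append(c.id)
            continue
        mid = off + len(motif) // 2
        elem_idx = np.arange(mid - flank, mid + flank)
        inside = (elem_idx >= 0) & (elem_idx < len(seq))
        if c.strand == "+":
            gpos = c.start + elem_idx
        else:
            gpos = c.end - 1 - elem_idx
        vals = np.zeros(width, dtype=float)
        vals[inside] = _track_value(track, c.chrom, gpos[inside])
        ids.append(c.id)
        rows.append(vals)
        masks.append(~inside)
    if not ids:
        values = np.zeros((0, width))
        gap_mask = np.ones((0, width), dtype=bool)
    else:
        values = np.vstack(rows)
        gap_mask = np.vstack(masks)
    return AlignedSignalMatrix(ids, values, gap_mask, flank_bp=0, dropped=dropped)
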