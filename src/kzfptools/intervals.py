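"""Sorted-interval algebra on 0-based half-open coordinates.

An *interval set* here is a dict mapping chromosome name to an (n, 2)
int64 numpy array of disjoint, sorted [start, end) rows.  All genomic
bookkeeping in the package (mappable-genome construction, enrichment
overlap counting, recurrence blacklists) runs on this representation:
it is compact, and membership/overlap queries reduce to
``numpy.searchsorted`` which is what makes the 10^4-iteration shuffle
oracle affordable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

IntervalSet = dict[str, np.ndarray]

_EMPTY = np.empty((0, 2), dtype=np.int64)


def _as_array(rows) -> np.ndarray:
    arr = np.asarray(rows, dtype=np.int64)
    if arr.size == 0:
        return _EMPTY.copy()
    return arr.reshape(-1, 2)


def from_dataframe(df: pd.DataFrame, chrom="chrom", start="start", end="end") -> IntervalSet:
    """Build an interval set from a BED-like frame (intervals are merged)."""
    out: IntervalSet = {}
    for c, sub in df.groupby(chrom, sort=True):
        out[str(c)] = merge(_as_array(sub[[start, end]].to_numpy()))
    return out


def to_dataframe(ivs: IntervalSet) -> pd.DataFrame:
    rows = []
    for c in sorted(ivs):
        for s, e in ivs[c]:
            rows.append((c, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def merge(arr: np.ndarray, gap: int = 0) -> np.ndarray:
    """Merge a (n,2) array; runs closer than `gap` bp are fused.

    gap=0 fuses only touching/overlapping runs; gap=g fuses runs whose
    separation is strictly less than g.
    """
    arr = _as_array(arr)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [arr[0].copy()]
    for s, e in arr[1:]:
        if s - out[-1][1] < max(gap, 1):  # < gap separation, or touching when gap==0
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e], dtype=np.int64))
    return np.vstack(out)


def merge_set(ivs: IntervalSet, gap: int = 0) -> IntervalSet:
    return {c: merge(a, gap) for c, a in ivs.items()}


def total_length(ivs: IntervalSet) -> int:
    return int(sum((a[:, 1] - a[:, 0]).sum() for a in ivs.values()))


def intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two disjoint sorted (n,2) arrays (linear sweep)."""
    a, b = _as_array(a), _as_array(b)
    i = j = 0
    out = []
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return _as_array(out)


def intersect(x: IntervalSet, y: IntervalSet) -> IntervalSet:
    out: IntervalSet = {}
    for c in x:
        if c in y:
            r = intersect_arrays(x[c], y[c])
            if len(r):
                out[c] = r
    return out


def subtract_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a minus b, both disjoint sorted."""
    a, b = _as_array(a), _as_array(b)
    if len(a) == 0 or len(b) == 0:
        return a.copy()
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return _as_array(out)


def subtract(x: IntervalSet, y: IntervalSet) -> IntervalSet:
    out: IntervalSet = {}
    for c, a in x.items():
        r = subtract_arrays(a, y.get(c, _EMPTY))
        if len(r):
            out[c] = r
    return out


def genome_set(chrom_lengths: dict[str, int]) -> IntervalSet:
    return {c: np.array([[0, int(l)]], dtype=np.int64) for c, l in chrom_lengths.items() if l > 0}


def overlaps_any(frag: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Vectorised: does each query [starts[i], ends[i]) overlap the
    disjoint sorted fragment array `frag` by >= 1 bp?"""
    frag = _as_array(frag)
    if len(frag) == 0:
        return np.zeros(len(starts), dtype=bool)
    # first fragment whose end is > query start
    idx = np.searchsorted(frag[:, 1], starts, side="right")
    hit = idx < len(frag)
    res = np.zeros(len(starts), dtype=bool)
    res[hit] = frag[idx[hit], 0] < ends[hit]
    return res


def count_overlapping(frag_set: IntervalSet, peaks: pd.DataFrame) -> int:
    """Number of peaks (rows with chrom/start/end) overlapping the set by >=1 bp."""
    n = 0
    for c, sub in peaks.groupby("chrom", sort=False):
        frag = frag_set.get(str(c))
        if frag is None:
            continue
        n += int(overlaps_any(frag, sub["start"].to_numpy(), sub["end"].to_numpy()).sum())
    return n


class MappablePositions:
    """Flat indexing of every base of an interval set, for uniform sampling.

    Position k in [0, G) maps to (chrom, base) through cumulative interval
    lengths; used to drop peaks uniformly onto the mappable genome.
    """

    def __init__(self, ivs: IntervalSet):
        self.chroms: list[str] = []
        self.starts: list[np.ndarray] = []
        self.ends: list[np.ndarray] = []
        lens = []
        for c in sorted(ivs):
            a = ivs[c]
            if len(a) == 0:
                continue
            self.chroms.append(c)
            self.starts.append(a[:, 0])
            self.ends.append(a[:, 1])
            lens.append((a[:, 1] - a[:, 0]).sum())
        if not lens:
            raise ValueError("empty interval set")
        self._flat_starts = np.concatenate(self.starts)
        self._flat_lens = np.concatenate(
            [e - s for s, e in zip(self.starts, self.ends)]
        )
        self._cum = np.concatenate([[0], np.cumsum(self._flat_lens)])
        self.total = int(self._cum[-1])
        counts = [len(s) for s in self.starts]
        self._chrom_of_iv = np.repeat(np.arange(len(self.chroms)), counts)

    def positions(self, flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """flat indices -> (chrom index array, genomic base array)."""
        iv = np.searchsorted(self._cum, flat, side="right") - 1
        base = self._flat_starts[iv] + (flat - self._cum[iv])
        return self._chrom_of_iv[iv], base

    def chrom_name(self, ci: int) -> str:
        return self.chroms[ci]
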