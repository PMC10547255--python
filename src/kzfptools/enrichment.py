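"""TE-subfamily/-family enrichment of ChIP peak sets with a
mappable-genome-corrected binomial null.

ChIP peaks of a KZFP are tested for over-representation on each repeat
unit (RepeatMasker subfamily or family).  The null places each peak
uniformly on the *mappable* genome — the reference minus regions with
zero coverage across all experiments and minus excluded chromosomes —
so that systematically unsequenced territory does not deflate expected
overlaps.  For a unit whose mappable fragments have total length L_u in
m_u pieces, a peak of mean width w overlaps the unit with probability

    p_u = min(1, (L_u + m_u (w - 1)) / G)

(the (w-1) term counts the extra start positions from which a peak
reaches into a fragment).  Observed overlap counts are scored with an
upper-tail binomial test, Benjamini-Hochberg corrected across units;
FDR < 0.05 is significant, and units whose -log10(FDR) exceeds 0.9 of
the experiment's maximum are *primary targets*.  A permutation oracle
(uniform re-placement of the peaks) validates the closed-form null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import intervals as iv
from .intervals import IntervalSet, MappablePositions


@dataclass
class MappableGenome:
    intervals: IntervalSet
    excluded_chroms: list[str] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return iv.total_length(self.intervals)


def compute_mappable(
    zero_coverage: list[IntervalSet],
    chrom_lengths: dict[str, int],
    merge_gap: int = 100,
    min_region: int = 40_000,
    exclude_chroms: tuple[str, ...] = ("chrY",),
) -> MappableGenome:
    """Mappable genome from per-experiment zero-coverage masks.

    Zero-coverage regions common to *all* experiments are intersected,
    runs separated by < merge_gap bp merged, merged runs longer than
    min_region kept, and the mappable genome is the reference minus
    those runs and minus the excluded chromosomes (chrY by default:
    absent from the HEK293T cells the assays run in).  With no
    experiments the mappable genome is the reference minus exclusions.
    """
    genome = iv.genome_set({c: l for c, l in chrom_lengths.items() if c not in exclude_chroms})
    if not zero_coverage:
        return MappableGenome(genome, list(exclude_chroms))
    common = zero_coverage[0]
    for z in zero_coverage[1:]:
        common = iv.intersect(common, z)
    merged = iv.merge_set(common, gap=merge_gap)
    kept = {
        c: a[(a[:, 1] - a[:, 0]) > min_region]
        for c, a in merged.items()
    }
    kept = {c: a for c, a in kept.items() if len(a)}
    return MappableGenome(iv.subtract(genome, kept), list(exclude_chroms))


def build_recurrence_blacklist(
    peak_sets: list[pd.DataFrame],
    min_fraction: float = 1.0,
) -> IntervalSet:
    """Genomic bases peaked in >= min_fraction of experiments.

    With the default 1.0 this is the "present in all ChIPs irrespective
    of the bait" filter that removes promiscuous, bait-independent
    signal before enrichment.  Returns merged intervals.
    """
    n = len(peak_sets)
    if n == 0:
        return {}
    need = min_fraction * n
    per_chrom_events: dict[str, list[np.ndarray]] = {}
    for ps in peak_sets:
        merged = iv.from_dataframe(ps) if len(ps) else {}
        for c, arr in merged.items():
            per_chrom_events.setdefault(c, []).append(arr)
    out: IntervalSet = {}
    for c, arrs in per_chrom_events.items():
        starts = np.concatenate([a[:, 0] for a in arrs])
        ends = np.concatenate([a[:, 1] for a in arrs])
        points = np.concatenate([starts, ends])
        deltas = np.concatenate([np.ones_like(starts), -np.ones_like(ends)])
        order = np.argsort(points, kind="mergesort")
        points, deltas = points[order], deltas[order]
        # collapse equal coordinates, then sweep coverage
        uniq, idx = np.unique(points, return_index=True)
        agg = np.add.reduceat(deltas, idx)
        cov = np.cumsum(agg)
        hot = cov >= need
        rows = []
        for i in np.flatnonzero(hot):
            rows.append((uniq[i], uniq[i + 1]))
        if rows:
            out[c] = iv.merge(np.array(rows, dtype=np.int64))
    return out


def filter_peaks(peaks: pd.DataFrame, blacklist: IntervalSet) -> pd.DataFrame:
    """Drop peaks overlapping the blacklist by >= 1 bp."""
    peaks = peaks.reset_index(drop=True)
    if not blacklist or len(peaks) == 0:
        return peaks
    keep = np.ones(len(peaks), dtype=bool)
    for c, sub in peaks.groupby("chrom", sort=False):
        bl = blacklist.get(str(c))
        if bl is None:
            continue
        hit = iv.overlaps_any(bl, sub["start"].to_numpy(), sub["end"].to_numpy())
        keep[sub.index[hit]] = False
    return peaks[keep].reset_index(drop=True)


def _clip_peaks_to_mappable(peaks: pd.DataFrame, mappable: IntervalSet) -> pd.DataFrame:
    """Keep peaks with >= 1 mappable bp, clipped to their mappable extent."""
    rows = []
    for c, sub in peaks.groupby("chrom", sort=False):
        mp = mappable.get(str(c))
        if mp is None:
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        hit = iv.overlaps_any(mp, s, e)
        for i in np.flatnonzero(hit):
            pieces = iv.intersect_arrays(np.array([[s[i], e[i]]]), mp)
            rows.append((c, int(pieces[0, 0]), int(pieces[-1, 1])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _unit_fragments(
    annotation: pd.DataFrame, mappable: IntervalSet, level: str
) -> dict[str, IntervalSet]:
    """Per-unit fragment sets restricted to the mappable genome."""
    if level not in ("subfamily", "family"):
        raise ValueError("level must be 'subfamily' or 'family'")
    units: dict[str, IntervalSet] = {}
    for u, sub in annotation.groupby(level, sort=True):
        restricted = iv.intersect(iv.from_dataframe(sub), mappable)
        if iv.total_length(restricted) > 0:
            units[str(u)] = restricted
    return units


def enrich(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    mappable: MappableGenome | IntervalSet,
    level: str = "subfamily",
    clip: bool = True,
) -> pd.DataFrame:
    """Binomial enrichment of a peak set over repeat units.

    Peaks and fragments are clipped to the mappable genome; a peak
    overlapping several fragments of one unit counts once, and one peak
    may count toward several units.  Returns one row per unit with
    n, k (observed), p_overlap, expected, p_value, fdr, sorted by FDR.
    """
    ivs = mappable.intervals if isinstance(mappable, MappableGenome) else mappable
    G = iv.total_length(ivs)
    if G == 0:
        raise ValueError("mappable genome is empty")
    if clip:
        peaks = _clip_peaks_to_mappable(peaks, ivs)
    n = len(peaks)
    if n == 0:
        raise ValueError("no peaks on the mappable genome")
    w_bar = float((peaks["end"] - peaks["start"]).mean())
    units = _unit_fragments(annotation, ivs, level)
    fam_of = {}
    cls_of = {}
    if level == "subfamily" and "family" in annotation.columns:
        fam_of = annotation.groupby("subfamily")["family"].first().to_dict()
    if "class" in annotation.columns:
        key = level
        cls_of = annotation.groupby(key)["class"].first().to_dict()
    rows = []
    for u, frags in units.items():
        L_u = iv.total_length(frags)
        m_u = sum(len(a) for a in frags.values())
        p_u = min(1.0, (L_u + m_u * (w_bar - 1.0)) / G)
        k = iv.count_overlapping(frags, peaks)
        p_val = float(stats.binom.sf(k - 1, n, p_u)) if p_u < 1.0 else 1.0
        rows.append((u, fam_of.get(u, ""), cls_of.get(u, ""), n, k, p_u, n * p_u, p_val))
    res = pd.DataFrame(
        rows,
        columns=["unit", "family", "class", "n_peaks", "observed",
                 "p_overlap", "expected", "p_value"],
    )
    res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
    return res.sort_values(["fdr", "p_value", "unit"], kind="mergesort").reset_index(drop=True)


def shuffle_oracle(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    mappable: MappableGenome | IntervalSet,
    n_iter: int = 10_000,
    level: str = "subfamily",
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Empirical per-unit p-values by uniform re-placement of the peaks.

    Each iteration drops every peak at a uniform start within the
    mappable set (width preserved, clipped to the chromosome end) and
    recounts per-unit overlaps; the empirical p-value is
    (1 + #{iterations with k* >= k_obs}) / (n_iter + 1).  This is the
    model-free arbiter for the closed-form binomial null.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    ivs = mappable.intervals if isinstance(mappable, MappableGenome) else mappable
    peaks = _clip_peaks_to_mappable(peaks, ivs)
    widths = (peaks["end"] - peaks["start"]).to_numpy()
    n = len(peaks)
    units = _unit_fragments(annotation, ivs, level)
    k_obs = {u: iv.count_overlapping(frags, peaks) for u, frags in units.items()}
    mp = MappablePositions(ivs)
    if chrom_lengths is None:
        chrom_lengths = {c: int(a[:, 1].max()) for c, a in ivs.items()}
    chrom_len_arr = np.array([chrom_lengths[c] for c in mp.chroms], dtype=np.int64)
    rng = np.random.default_rng(seed)
    exceed = {u: 0 for u in units}
    # pre-split fragment arrays by chromosome index for fast lookup
    unit_frags_by_ci = {
        u: [frags.get(c, np.empty((0, 2), dtype=np.int64)) for c in mp.chroms]
        for u, frags in units.items()
    }
    for _ in range(n_iter):
        flat = rng.integers(0, mp.total, size=n)
        cis, starts = mp.positions(flat)
        ends = np.minimum(starts + widths, chrom_len_arr[cis])
        for u, frag_list in unit_frags_by_ci.items():
            k_star = 0
            for ci in np.unique(cis):
                frag = frag_list[ci]
                if len(frag) == 0:
                    continue
                sel = cis == ci
                k_star += int(iv.overlaps_any(frag, starts[sel], ends[sel]).sum())
            if k_star >= k_obs[u]:
                exceed[u] += 1
    rows = [
        (u, k_obs[u], (1 + exceed[u]) / (n_iter + 1))
        for u in sorted(units)
    ]
    return pd.DataFrame(rows, columns=["unit", "observed", "empirical_p"])


def classify_targets(
    results: pd.DataFrame,
    alpha: float = 0.05,
    primary_cut: float = 0.9,
) -> pd.DataFrame:
    """Flag significant units and primary targets.

    significant <=> fdr < alpha.  -log10(FDR) values are divided by the
    experiment's maximum, yielding a 0-to-1 least-to-most-enriched
    scale; primary <=> significant and scaled score > primary_cut.
    Exact-zero FDRs are floored to (smallest positive FDR in the set)/10
    before the log so the scaling stays finite and rank-preserving.
    """
    if len(results) == 0:
        raise ValueError("no enrichment results")
    res = results.copy()
    fdr = res["fdr"].to_numpy(dtype=float)
    pos = fdr[fdr > 0]
    floor = (pos.min() / 10.0) if len(pos) else np.finfo(float).tiny
    fdr = np.where(fdr <= 0, floor, fdr)
    nlf = -np.log10(fdr)
    res["neg_log10_fdr"] = nlf
    mx = nlf.max()
    res["scaled_score"] = nlf / mx if mx > 0 else 0.0
    res["significant"] = res["fdr"] < alpha
    res["primary"] = res["significant"] & (res["scaled_score"] > primary_cut)
    return res


def target_dispersion(
    primary_map: dict[str, set[str]],
    gene_clusters: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """How widely each TE unit is targeted across the KZFP cluster map.

    ``primary_map`` maps each KZFP to the set of units it targets
    (primary-only or all-significant, per the caller's choice);
    ``gene_clusters`` maps KZFPs to their cluster name — unclustered
    genes count as their own singleton location.  Returns (per-unit
    table with n_kzfps and n_clusters, column-normalized frequency
    matrix of (n_kzfps, n_clusters) pairs).
    """
    per_unit: dict[str, list[str]] = {}
    for kz, units in primary_map.items():
        for u in units:
            per_unit.setdefault(u, []).append(kz)
    rows = []
    for u in sorted(per_unit):
        kzs = per_unit[u]
        locs = {gene_clusters.get(k, f"__singleton_{k}") for k in kzs}
        rows.append((u, len(kzs), len(locs)))
    table = pd.DataFrame(rows, columns=["unit", "n_kzfps", "n_clusters"])
    if len(table):
        freq = pd.crosstab(table["n_clusters"], table["n_kzfps"])
        freq = freq / freq.sum(axis=0)
    else:
        freq = pd.DataFrame()
    return table, freq
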