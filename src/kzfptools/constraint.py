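"""Population coding-constraint scores for KZFP genes.

Protein-altering variants (missense plus loss-of-function: frameshift,
stop-gain, essential splice) from a population cohort are filtered
through a quality cascade, assigned to functional regions of each gene
(KRAB domain, zinc finger array, and within fingers the structural
Cys/His residues, the -1/+3/+6 fingerprint residues, or other finger
positions), counted, normalized, and turned into per-region Z scores
across the gene set.  A negative Z score marks a gene whose region
carries fewer variants than the family average, i.e. stronger purifying
selection.  No theoretically expected mutation count is used: the
repetitive, structurally unstable ZF-coding regions make that
expectation unreliable, so the scores are purely relative to the gene
set analysed.

Filtering cascade (in order):

1. drop variants not flagged PASS;
2. keep only missense and LoF consequences;
3. drop low-confidence LoF and any LoF in the last 5% of the canonical
   CDS (positions >= ceil(0.95 x L));
4. drop genes whose transcript-wide mean coverage is < 20x (reported);
5. drop exons with mean coverage < 20x, remove their variants, and
   shorten the effective CDS length used for normalization;
6. drop singletons (allele count = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

from .fingerprint import ZincFinger

REGION_CLASSES = ["FULL", "KRAB", "ZF_ALL", "ZF_OTHER", "FINGERPRINT", "C2H2", "LOF"]
LOF_CONSEQUENCES = frozenset({"frameshift", "stop_gain", "splice"})
VALID_CONSEQUENCES = LOF_CONSEQUENCES | {"missense"}

# per-CDS-position labels
KRAB, ZF_C2H2, ZF_FINGERPRINT, ZF_OTHER, OUTSIDE = (
    "KRAB", "ZF_C2H2", "ZF_FINGERPRINT", "ZF_OTHER", "OUTSIDE",
)


def exon_table(gene_models: pd.DataFrame) -> pd.DataFrame:
    """Equal-split exon layout in CDS coordinates (1-based inclusive).

    Synthetic gene models carry an ``n_exons`` column; real inputs may
    supply their own (gene_id, exon_index, cds_start, cds_end) table
    instead.
    """
    rows = []
    for _, g in gene_models.iterrows():
        n = int(g.get("n_exons", 1))
        L = int(g.cds_length)
        bounds = np.linspace(0, L, n + 1, dtype=int)
        for i in range(n):
            rows.append((g.gene_id, i, int(bounds[i]) + 1, int(bounds[i + 1])))
    return pd.DataFrame(rows, columns=["gene_id", "exon_index", "cds_start", "cds_end"])


def uniform_coverage(gene_models: pd.DataFrame, depth: float = 30.0) -> pd.DataFrame:
    """Convenience coverage table: every exon at the same mean depth."""
    ex = exon_table(gene_models)
    ex["mean_depth"] = depth
    return ex[["gene_id", "exon_index", "mean_depth"]]


def filter_variants(
    variants: pd.DataFrame,
    gene_models: pd.DataFrame,
    coverage: pd.DataFrame,
    min_coverage: float = 20.0,
    last_fraction: float = 0.05,
    drop_singletons: bool = True,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Apply the quality cascade; see the module docstring for the order.

    ``coverage`` holds (gene_id, exon_index, mean_depth) and must cover
    every exon of every gene.  Returns (surviving variants, per-gene
    effective CDS length, excluded gene ids).  Idempotent on its own
    output.
    """
    models = gene_models.set_index("gene_id")
    exons = exon_table(gene_models).merge(
        coverage, on=["gene_id", "exon_index"], how="left", validate="one_to_one"
    )
    if exons["mean_depth"].isna().any():
        missing = exons.loc[exons["mean_depth"].isna(), "gene_id"].unique()
        raise ValueError(f"coverage table missing exons for genes: {list(missing)}")

    v = variants.copy()
    v = v[v["filter_pass"]]
    v = v[v["consequence"].isin(VALID_CONSEQUENCES)]
    is_lof = v["consequence"].isin(LOF_CONSEQUENCES)
    cds_len = models["cds_length"]
    last_start = v["gene_id"].map(lambda g: ceil((1 - last_fraction) * cds_len[g]))
    v = v[~(is_lof & (v["lof_low_confidence"] | (v["cds_position"] >= last_start)))]

    exons["length"] = exons["cds_end"] - exons["cds_start"] + 1
    gene_cov = exons.groupby("gene_id").apply(
        lambda t: np.average(t["mean_depth"], weights=t["length"]),
        include_groups=False,
    )
    excluded = sorted(gene_cov.index[gene_cov < min_coverage])
    v = v[~v["gene_id"].isin(excluded)]

    bad_exons = exons[(exons["mean_depth"] < min_coverage) & ~exons["gene_id"].isin(excluded)]
    eff_len = cds_len.astype(np.int64).copy()
    eff_len.loc[excluded] = 0
    if len(bad_exons):
        lost = bad_exons.groupby("gene_id")["length"].sum()
        eff_len.loc[lost.index] = eff_len.loc[lost.index] - lost
        keep = np.ones(len(v), dtype=bool)
        for _, ex in bad_exons.iterrows():
            keep &= ~(
                (v["gene_id"] == ex.gene_id)
                & (v["cds_position"] >= ex.cds_start)
                & (v["cds_position"] <= ex.cds_end)
            ).to_numpy()
        v = v[keep]

    if drop_singletons:
        v = v[v["allele_count"] > 1]
    eff_len = eff_len.drop(index=excluded)
    return v.reset_index(drop=True), eff_len.rename("effective_cds_length"), excluded


@dataclass
class RegionMap:
    gene_id: str
    labels: np.ndarray  # per-CDS-position (1-based position p -> labels[p-1])
    n_zf_domains: int
    krab_len_bp: int
    zf_len_bp: int
    effective_cds_length: int | None = None


def annotate_positions(
    gene_model: pd.Series,
    fingers: list[ZincFinger],
) -> RegionMap:
    """Project per-residue classes onto CDS positions (3 per residue).

    Residue classes: the two Cys and two His of each finger are C2H2;
    the -1/+3/+6 residues are FINGERPRINT; remaining residues inside the
    ZF array are ZF_OTHER; KRAB residues are KRAB; everything else
    OUTSIDE.  Classes are disjoint by construction; the precedence
    C2H2 > FINGERPRINT > ZF_OTHER > KRAB guards malformed inputs only.
    """
    L = int(gene_model.cds_length)
    n_res = (L - 3) // 3 if L % 3 == 0 else L // 3
    labels = np.full(n_res, OUTSIDE, dtype=object)

    def set_res(i: int, lab: str, force: bool = False) -> None:
        if not 0 <= i < n_res:
            raise ValueError(f"{gene_model.gene_id}: residue {i} outside CDS")
        labels[i] = lab

    for i in range(int(gene_model.krab_aa_start), int(gene_model.krab_aa_end)):
        set_res(i, KRAB)
    if fingers:
        zf_lo = min(f.start for f in fingers)
        zf_hi = max(f.end for f in fingers)
        for i in range(zf_lo, zf_hi):
            set_res(i, ZF_OTHER)
        for f in fingers:
            for i in f.fingerprint_positions:
                set_res(i, ZF_FINGERPRINT)
            for i in f.cys_his_positions:
                set_res(i, ZF_C2H2)
        zf_len_bp = 3 * (zf_hi - zf_lo)
    else:
        zf_len_bp = 0
    cds_labels = np.repeat(labels, 3)
    if len(cds_labels) < L:  # stop codon / trailing bases are OUTSIDE
        cds_labels = np.concatenate([cds_labels, np.full(L - len(cds_labels), OUTSIDE)])
    return RegionMap(
        gene_id=str(gene_model.gene_id),
        labels=cds_labels,
        n_zf_domains=len(fingers),
        krab_len_bp=3 * (int(gene_model.krab_aa_end) - int(gene_model.krab_aa_start)),
        zf_len_bp=zf_len_bp,
    )


def count_variants_by_region(
    variants: pd.DataFrame,
    region_maps: dict[str, RegionMap],
) -> pd.DataFrame:
    """Per-gene counts for the seven region classes.

    FULL counts every surviving variant in the CDS; LOF counts LoF
    survivors anywhere in the CDS (a truncating variant ablates the
    whole protein, not one residue class); KRAB and ZF_ALL count all
    survivors at their positions; C2H2, FINGERPRINT and ZF_OTHER count
    missense only.  Variants beyond the CDS are dropped with a warning
    column in the return (``n_dropped`` attr).
    """
    counts = pd.DataFrame(
        0, index=pd.Index(sorted(region_maps), name="gene_id"), columns=REGION_CLASSES
    )
    n_dropped = 0
    for gid, sub in variants.groupby("gene_id"):
        rm = region_maps.get(gid)
        if rm is None:
            continue
        pos = sub["cds_position"].to_numpy()
        inside = (pos >= 1) & (pos <= len(rm.labels))
        n_dropped += int((~inside).sum())
        sub = sub[inside]
        pos = pos[inside]
        lab = rm.labels[pos - 1]
        is_lof = sub["consequence"].isin(LOF_CONSEQUENCES).to_numpy()
        is_mis = ~is_lof
        counts.loc[gid, "FULL"] = len(sub)
        counts.loc[gid, "LOF"] = int(is_lof.sum())
        counts.loc[gid, "KRAB"] = int((lab == KRAB).sum())
        in_zf = np.isin(lab, [ZF_C2H2, ZF_FINGERPRINT, ZF_OTHER])
        counts.loc[gid, "ZF_ALL"] = int(in_zf.sum())
        counts.loc[gid, "C2H2"] = int((is_mis & (lab == ZF_C2H2)).sum())
        counts.loc[gid, "FINGERPRINT"] = int((is_mis & (lab == ZF_FINGERPRINT)).sum())
        counts.loc[gid, "ZF_OTHER"] = int((is_mis & (lab == ZF_OTHER)).sum())
    counts.attrs["n_dropped"] = n_dropped
    return counts


def _normalizers(region_maps: dict[str, RegionMap], eff_len: pd.Series) -> pd.DataFrame:
    """Per-gene per-class normalizer: effective CDS length for FULL/LOF,
    domain length (bp) for KRAB and the ZF classes, finger count for C2H2."""
    rows = {}
    for gid, rm in region_maps.items():
        L = float(eff_len.get(gid, rm.effective_cds_length or 0))
        rows[gid] = dict(
            FULL=L, LOF=L, KRAB=float(rm.krab_len_bp),
            ZF_ALL=float(rm.zf_len_bp), ZF_OTHER=float(rm.zf_len_bp),
            FINGERPRINT=float(rm.zf_len_bp), C2H2=float(rm.n_zf_domains),
        )
    return pd.DataFrame.from_dict(rows, orient="index").loc[sorted(rows), REGION_CLASSES]


def compute_zscores(
    counts: pd.DataFrame,
    region_maps: dict[str, RegionMap] | pd.DataFrame,
    effective_cds_length: pd.Series | None = None,
) -> pd.DataFrame:
    """Normalized rates and per-class Z scores across the gene set.

    rate = count / normalizer; z = (rate - mean(rate)) / sd(rate) with
    sample (n-1) sd, computed within each region class over all genes
    with a positive normalizer.  Raises if a class has zero spread.
    Returns a long frame (gene_id, region, x, normalizer, rate, z).
    """
    if isinstance(region_maps, pd.DataFrame):
        norm = region_maps
    else:
        if effective_cds_length is None:
            raise ValueError("effective_cds_length required with region maps")
        norm = _normalizers(region_maps, effective_cds_length)
    norm = norm.reindex(index=counts.index, columns=REGION_CLASSES)
    if norm.isna().any().any():
        raise ValueError("normalizer table does not cover all genes/classes")
    rows = []
    for cls in REGION_CLASSES:
        ok = norm[cls] > 0
        if ok.sum() < 3:
            raise ValueError(f"class {cls}: fewer than 3 genes with positive normalizer")
        rate = counts.loc[ok, cls] / norm.loc[ok, cls]
        sd = rate.std(ddof=1)
        if sd == 0:
            raise ValueError(f"class {cls}: zero standard deviation of rates")
        z = (rate - rate.mean()) / sd
        for gid in rate.index:
            rows.append((gid, cls, int(counts.loc[gid, cls]), float(norm.loc[gid, cls]),
                         float(rate[gid]), float(z[gid])))
    return pd.DataFrame(rows, columns=["gene_id", "region", "x", "normalizer", "rate", "z"])


def correlate_scores(
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Spearman correlations with a Bonferroni significance mask.

    ``scores`` is the long frame from :func:`compute_zscores`;
    ``covariates`` an optional per-gene table (e.g. dN/dS, age) indexed
    by gene_id.  Correlations use complete pairs; the Bonferroni factor
    is the number of unique off-diagonal cells.  Columns with no spread
    yield NaN rho and are flagged undefined.
    """
    wide = scores.pivot(index="gene_id", columns="region", values="z")
    wide = wide[[c for c in REGION_CLASSES if c in wide.columns]]
    if covariates is not None:
        wide = wide.join(covariates, how="left")
    cols = list(wide.columns)
    m = len(cols) * (len(cols) - 1) // 2
    rows = []
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            pair = wide[[a, b]].dropna()
            if i == j:
                rows.append((a, b, 1.0, 0.0, 0.0, False, False))
                continue
            if len(pair) < 3 or pair[a].nunique() == 1 or pair[b].nunique() == 1:
                rows.append((a, b, np.nan, np.nan, np.nan, False, True))
                continue
            rho, p = stats.spearmanr(pair[a], pair[b])
            p_adj = min(1.0, p * m)
            rows.append((a, b, float(rho), float(p), float(p_adj), p_adj < alpha, False))
    return pd.DataFrame(
        rows, columns=["a", "b", "rho", "p", "p_bonferroni", "significant", "undefined"]
    )
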