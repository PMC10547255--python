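"""Variant filtering cascade, region annotation, counting and Z scores."""

import numpy as np
import pandas as pd
import pytest
from math import ceil

from kzfptools import constraint as cn
from kzfptools import synthetic as syn
from kzfptools.fingerprint import find_zf_domains
from tests.conftest import single_gene_model


def toy_variants():
    """Six variants engineered to exercise every filter stage.

    Gene G has CDS 1000 bp in 5 equal exons; exon index 1 ([201,400])
    has 15x coverage.  Expected survivors: the two clean missense.
    """
    rows = [
        # (pos, consequence, AC, pass, low_conf)
        (50, "missense", 5, False, False),   # non-PASS
        (150, "missense", 1, True, False),   # singleton
        (980, "stop_gain", 8, True, False),  # LoF in last 5%
        (250, "missense", 4, True, False),   # inside the 15x exon
        (100, "missense", 3, True, False),   # clean
        (600, "missense", 7, True, False),   # clean
    ]
    return pd.DataFrame(
        [("G", *r) for r in rows],
        columns=["gene_id", "cds_position", "consequence", "allele_count",
                 "filter_pass", "lof_low_confidence"],
    )


def toy_coverage():
    return pd.DataFrame(
        {
            "gene_id": ["G"] * 5,
            "exon_index": range(5),
            "mean_depth": [30.0, 15.0, 30.0, 30.0, 30.0],
        }
    )


def brute_force_filter(variants, cds_length=1000, bad_exon=(201, 400)):
    """Independent row-by-row re-statement of the cascade."""
    out = []
    for r in variants.itertuples():
        if not r.filter_pass:
            continue
        if r.consequence not in {"missense", "stop_gain", "frameshift", "splice"}:
            continue
        if r.consequence != "missense":
            if r.lof_low_confidence or r.cds_position >= ceil(0.95 * cds_length):
                continue
        if bad_exon[0] <= r.cds_position <= bad_exon[1]:
            continue
        if r.allele_count == 1:
            continue
        out.append(r.Index)
    return variants.loc[out]


class TestFilterVariants:
    def test_six_row_toy_leaves_two_survivors(self):
        models = single_gene_model("G", cds_length=1000, n_exons=5)
        fv, eff, excl = cn.filter_variants(toy_variants(), models, toy_coverage())
        expected = brute_force_filter(toy_variants())
        assert len(fv) == 2
        assert sorted(fv["cds_position"]) == sorted(expected["cds_position"]) == [100, 600]
        assert excl == []
        assert eff["G"] == 800  # 1000 minus the 200-bp low-coverage exon

    def test_all_singletons_filtered_to_empty(self):
        models = single_gene_model("G")
        v = toy_variants().assign(allele_count=1, filter_pass=True)
        v = v[v["consequence"] == "missense"]
        fv, _, _ = cn.filter_variants(v, models, cn.uniform_coverage(models))
        assert len(fv) == 0

    def test_low_mean_coverage_gene_excluded(self):
        models = single_gene_model("G", n_exons=2)
        cov = pd.DataFrame(
            {"gene_id": ["G", "G"], "exon_index": [0, 1], "mean_depth": [19.9, 19.9]}
        )
        fv, eff, excl = cn.filter_variants(toy_variants(), models, cov)
        assert excl == ["G"] and len(fv) == 0 and "G" not in eff.index

    def test_idempotent(self):
        models = single_gene_model("G", cds_length=1000, n_exons=5)
        fv1, eff1, _ = cn.filter_variants(toy_variants(), models, toy_coverage())
        fv2, eff2, _ = cn.filter_variants(fv1, models, toy_coverage())
        assert fv1.equals(fv2) and eff1.equals(eff2)


def finger_protein(n_fingers, x1=2):
    body = "C" + "A" * x1 + "C" + "A" * 12 + "H" + "AAA" + "H"
    return "M" * 45 + "G" * 10 + body * n_fingers + "KKKKK"


def model_for_protein(prot, gene_id="G"):
    m = single_gene_model(gene_id, cds_length=3 * len(prot) + 3)
    fingers = find_zf_domains(prot)
    if fingers:
        m["zf_aa_start"] = min(f.start for f in fingers)
        m["zf_aa_end"] = max(f.end for f in fingers)
    return m


class TestAnnotatePositions:
    def test_single_23_residue_finger_position_counts(self):
        prot = finger_protein(1, x1=4)  # 23-residue finger
        fingers = find_zf_domains(prot)
        assert len(fingers) == 1 and len(fingers[0].sequence) == 23
        rm = cn.annotate_positions(model_for_protein(prot).iloc[0], fingers)
        assert (rm.labels == cn.ZF_C2H2).sum() == 12  # 4 Cys/His x 3
        assert (rm.labels == cn.ZF_FINGERPRINT).sum() == 9  # 3 residues x 3

    def test_no_fingers_no_zf_labels(self):
        prot = "M" * 100
        rm = cn.annotate_positions(model_for_protein(prot).iloc[0], [])
        assert not np.isin(rm.labels, [cn.ZF_C2H2, cn.ZF_FINGERPRINT, cn.ZF_OTHER]).any()

    def test_krab_of_45_residues_is_135_positions(self):
        prot = finger_protein(2)
        rm = cn.annotate_positions(
            model_for_protein(prot).iloc[0], find_zf_domains(prot)
        )
        assert (rm.labels == cn.KRAB).sum() == 135

    def test_classes_partition_cds(self):
        prot = finger_protein(3)
        rm = cn.annotate_positions(model_for_protein(prot).iloc[0], find_zf_domains(prot))
        valid = {cn.KRAB, cn.ZF_C2H2, cn.ZF_FINGERPRINT, cn.ZF_OTHER, cn.OUTSIDE}
        assert set(rm.labels) <= valid
        assert len(rm.labels) == 3 * len(prot) + 3


class TestCountByRegion:
    def _setup(self):
        prot = finger_protein(1)
        model = model_for_protein(prot)
        fingers = find_zf_domains(prot)
        rm = cn.annotate_positions(model.iloc[0], fingers)
        return model, rm, fingers[0]

    def _variant(self, pos, consequence="missense"):
        return pd.DataFrame(
            [("G", pos, consequence, 5, True, False)],
            columns=["gene_id", "cds_position", "consequence", "allele_count",
                     "filter_pass", "lof_low_confidence"],
        )

    def test_missense_at_cys_codon(self):
        model, rm, finger = self._setup()
        cys_res = finger.cys_his_positions[0]
        v = self._variant(3 * cys_res + 1)
        counts = cn.count_variants_by_region(v, {"G": rm})
        row = counts.loc["G"]
        assert (row["C2H2"], row["ZF_ALL"], row["FULL"], row["FINGERPRINT"]) == (1, 1, 1, 0)

    def test_stop_gain_in_krab(self):
        model, rm, _ = self._setup()
        v = self._variant(30, "stop_gain")  # residue 9, inside KRAB
        counts = cn.count_variants_by_region(v, {"G": rm})
        row = counts.loc["G"]
        assert (row["LOF"], row["FULL"], row["KRAB"], row["C2H2"]) == (1, 1, 1, 0)

    def test_zero_variants_all_zero_row(self):
        model, rm, _ = self._setup()
        empty = self._variant(1).iloc[:0]
        counts = cn.count_variants_by_region(empty, {"G": rm})
        assert (counts.loc["G"] == 0).all()


class TestZScores:
    def _three_gene_counts(self, full=(0, 1, 2)):
        counts = pd.DataFrame(
            0, index=pd.Index(["A", "B", "C"], name="gene_id"),
            columns=cn.REGION_CLASSES,
        )
        counts["FULL"] = full
        counts["LOF"] = [0, 1, 2]
        counts["KRAB"] = [1, 2, 3]
        counts["ZF_ALL"] = [2, 1, 0]
        counts["ZF_OTHER"] = [1, 0, 2]
        counts["FINGERPRINT"] = [0, 2, 1]
        counts["C2H2"] = [2, 0, 1]
        return counts

    def _norm(self, scale=1.0):
        return pd.DataFrame(
            scale * 1000.0, index=["A", "B", "C"], columns=cn.REGION_CLASSES
        )

    def test_equal_lengths_full_counts_give_unit_spaced_z(self):
        scores = cn.compute_zscores(self._three_gene_counts(), self._norm())
        z = scores[scores["region"] == "FULL"].set_index("gene_id")["z"]
        assert z["A"] == pytest.approx(-1) and z["B"] == pytest.approx(0)
        assert z["C"] == pytest.approx(1)

    def test_identical_rates_raise_named_error(self):
        counts = self._three_gene_counts(full=(1, 1, 1))
        with pytest.raises(ValueError, match="FULL"):
            cn.compute_zscores(counts, self._norm())

    def test_scale_invariance_of_z(self):
        counts = self._three_gene_counts()
        a = cn.compute_zscores(counts, self._norm(1.0))
        b = cn.compute_zscores(counts * 2, self._norm(2.0))
        assert np.allclose(a["z"], b["z"])

    def test_mean_zero_sd_one_per_class(self, toy_genome):
        models, prots, _ = syn.generate_kzfp_genes(toy_genome, 12, [], (3, 6), seed=41)
        mult = {g: m for g, m in zip(models["gene_id"], np.linspace(0.3, 4, 12))}
        v = syn.generate_variants(models, 0.05, mult, seed=42)
        fv, eff, _ = cn.filter_variants(v, models, cn.uniform_coverage(models))
        rmaps = {
            r.gene_id: cn.annotate_positions(r, find_zf_domains(prots[r.gene_id]))
            for r in (models.iloc[i] for i in range(len(models)))
        }
        counts = cn.count_variants_by_region(fv, rmaps)
        scores = cn.compute_zscores(counts, rmaps, eff)
        for cls, sub in scores.groupby("region"):
            assert abs(sub["z"].mean()) < 1e-9
            assert abs(sub["z"].std(ddof=1) - 1) < 1e-9

    def test_adding_a_variant_never_decreases_z(self):
        counts = self._three_gene_counts()
        base = cn.compute_zscores(counts, self._norm())
        bumped_counts = counts.copy()
        bumped_counts.loc["A", "FULL"] += 1
        bumped = cn.compute_zscores(bumped_counts, self._norm())

        def z_of(s, g):
            return s[(s["region"] == "FULL") & (s["gene_id"] == g)]["z"].iloc[0]

        assert z_of(bumped, "A") >= z_of(base, "A")


class TestCorrelateScores:
    def _scores(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            x = rng.normal()
            for cls in cn.REGION_CLASSES:
                rows.append((f"g{i}", cls, 0, 1.0, 0.0, x + 0.1 * rng.normal()))
        return pd.DataFrame(rows, columns=["gene_id", "region", "x", "normalizer", "rate", "z"])

    def test_diagonal_is_identity(self):
        corr = cn.correlate_scores(self._scores())
        diag = corr[corr["a"] == corr["b"]]
        assert (diag["rho"] == 1.0).all()

    def test_antitone_covariate_gives_minus_one(self):
        scores = self._scores()
        z = scores[scores["region"] == "FULL"].set_index("gene_id")["z"]
        cov = pd.DataFrame({"neg": -z})
        corr = cn.correlate_scores(scores, cov)
        cell = corr[(corr["a"] == "FULL") & (corr["b"] == "neg")]
        assert cell["rho"].iloc[0] == pytest.approx(-1.0)

    def test_planted_multipliers_recovered_positively(self, toy_genome):
        models, prots, _ = syn.generate_kzfp_genes(toy_genome, 40, [], (3, 6), seed=51)
        rng = np.random.default_rng(52)
        mult = {g: float(m) for g, m in
                zip(models["gene_id"], np.exp(rng.uniform(np.log(0.2), np.log(5), 40)))}
        v = syn.generate_variants(models, 0.03, mult, seed=53)
        fv, eff, _ = cn.filter_variants(v, models, cn.uniform_coverage(models))
        rmaps = {
            r.gene_id: cn.annotate_positions(r, find_zf_domains(prots[r.gene_id]))
            for r in (models.iloc[i] for i in range(len(models)))
        }
        scores = cn.compute_zscores(cn.count_variants_by_region(fv, rmaps), rmaps, eff)
        cov = pd.DataFrame({"multiplier": pd.Series(mult)})
        corr = cn.correlate_scores(scores, cov)
        cell = corr[(corr["a"] == "FULL") & (corr["b"] == "multiplier")].iloc[0]
        assert cell["rho"] > 0 and cell["significant"]
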