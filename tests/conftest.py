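import numpy as np
import pandas as pd
import pytest

from kzfptools import synthetic as syn


@pytest.fixture(scope="session")
def toy_genome():
    """1-Mb single-chromosome genome with three planted subfamilies."""
    return syn.generate_genome(
        7,
        {"chr1": 1_000_000},
        [
            syn.SubfamilySpec("L1TGT", "L1", 60, 150, "LINE"),
            syn.SubfamilySpec("AluX", "Alu", 80, 120, "SINE"),
            syn.SubfamilySpec("MER9", "ERV", 40, 200, "LTR"),
        ],
    )


@pytest.fixture(scope="session")
def toy_mappable():
    return {"chr1": np.array([[0, 1_000_000]], dtype=np.int64)}


def single_gene_model(gene_id="G1", cds_length=1000, n_exons=5):
    """Minimal gene-model row for constraint tests (no genomic placement)."""
    return pd.DataFrame(
        [
            dict(
                gene_id=gene_id, chrom="chr1", start=0, end=cds_length, strand="+",
                cds_length=cds_length, n_fingers=0,
                krab_aa_start=0, krab_aa_end=45,
                zf_aa_start=55, zf_aa_end=55,
                krab_start=0, krab_end=135, zf_start=165, zf_end=165,
                n_exons=n_exons, coding=True, age_myo=np.nan,
            )
        ]
    )
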