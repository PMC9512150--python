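import numpy as np
import pandas as pd
import pytest

from rareburden import SimConfig, simulate
from rareburden.formats import SamplePanel, VariantRecord, VariantTable

NULL_CAUSAL = {"SNP": 0.0, "INDEL": 0.0, "SV": 0.0}


@pytest.fixture(scope="session")
def planted_sim():
    """Moderate synthetic dataset with planted effects (shared, read-only)."""
    return simulate(SimConfig.scaled(300, seed=11))


@pytest.fixture(scope="session")
def null_sim():
    """Moderate synthetic dataset with no planted effects."""
    return simulate(SimConfig.scaled(300, seed=12, causal_fraction=dict(NULL_CAUSAL)))


def make_panel(n: int) -> SamplePanel:
    return SamplePanel.from_ids(f"S{i + 1:03d}" for i in range(n))


def snp(vid, pos, genotypes, panel, chrom="chr1", **annotations) -> VariantRecord:
    return VariantRecord(
        variant_id=vid, chrom=chrom, pos=pos, end=pos, ref="A", alt="T",
        vclass="SNP", length=1,
        genotypes=np.asarray(genotypes, dtype=np.int8),
        annotations=annotations)


def table_of(records, panel) -> VariantTable:
    return VariantTable.from_records(records, panel)


def gene_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col in ("recomb_rate", "connectivity", "te_overlap"):
        if col not in df.columns:
            df[col] = np.nan
    if "tss" not in df.columns:
        df["tss"] = np.where(df.strand == "+", df.start, df.end)
    return df
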