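import numpy as np
import pandas as pd
import pytest

from granulecall.io import CountMatrix
from granulecall.protein import ProteinQuantTable


def make_sheet(genotypes=("wildtype", "mutant"), fractions=("tissue_lysate", "granules_1"),
               replicates=3):
    rows = [
        {
            "sample_id": f"{g}_{f}_r{r}",
            "genotype": g,
            "fraction": f,
            "replicate": r,
        }
        for g in genotypes
        for f in fractions
        for r in range(1, replicates + 1)
    ]
    return pd.DataFrame(rows)


def make_protein_table(values: dict[str, list[float]], sheet: pd.DataFrame,
                       protein_ids=None) -> ProteinQuantTable:
    """Build a ProteinQuantTable from per-sample value lists (NaN = missing)."""
    df = pd.DataFrame(values, dtype=float)
    if protein_ids is None:
        protein_ids = [f"p{i}" for i in range(len(df))]
    df.index = pd.Index(protein_ids, name="protein_id")
    return ProteinQuantTable(values=df, flags=None, samples=sheet)


def make_de_table(feature_ids, log2fc, p_value, base_mean=50.0):
    n = len(feature_ids)
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "log2fc": np.broadcast_to(np.asarray(log2fc, float), (n,)).copy(),
            "base_mean": np.broadcast_to(np.asarray(base_mean, float), (n,)).copy(),
            "p_value": np.broadcast_to(np.asarray(p_value, float), (n,)).copy(),
            "p_adjusted": np.broadcast_to(np.asarray(p_value, float), (n,)).copy(),
        }
    )


@pytest.fixture
def tiny_count_matrix():
    sheet = make_sheet(genotypes=("wildtype",), fractions=("tissue_lysate", "granules_1"),
                       replicates=2)
    counts = pd.DataFrame(
        {s: [10, 20, 30] for s in sheet["sample_id"]},
        index=pd.Index(["g1", "g2", "g3"], name="feature_id"),
    )
    return CountMatrix(counts=counts, samples=sheet)
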