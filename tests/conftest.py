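import numpy as np
import pandas as pd
import pytest

from vdgrs.qc import DosageMatrix
from vdgrs.weights import packaged_weight_table


@pytest.fixture(scope="session")
def panel():
    return packaged_weight_table()


def make_matrix(dosages: dict, meta: dict | None = None, sample_ids=None) -> DosageMatrix:
    """Build a DosageMatrix from {rsid: [dosages...]}; metadata defaults to
    the packaged panel orientation (ALT = effect allele)."""
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in dosages.items()})
    n = len(df)
    df.index = pd.Index(sample_ids or [f"S{i}" for i in range(n)], name="sample_id")
    if meta is None:
        wt = {w.rsid: w for w in packaged_weight_table()}
        meta = {
            r: {
                "ref": wt[r].other_allele if r in wt else "A",
                "alt": wt[r].effect_allele if r in wt else "G",
                "info": None,
            }
            for r in df.columns
        }
    return DosageMatrix(df, pd.DataFrame.from_dict(meta, orient="index"))


@pytest.fixture
def make_dosage_matrix():
    return make_matrix
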