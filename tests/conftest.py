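import numpy as np
import pandas as pd
import pytest

from pqtlx.sumstats import LocusSumStats


def make_locus(
    pos, beta, se, eaf=None, a1=None, a2=None, p=None, n=10_000,
    protein_id="prot", chrom="1", gene_start=1_000, gene_end=2_000,
):
    """Assemble a LocusSumStats from parallel lists (test fixture helper)."""
    m = len(pos)
    from scipy import stats as sps

    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if p is None:
        p = 2 * sps.norm.sf(np.abs(beta / se))
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
            "eaf": eaf if eaf is not None else [0.3] * m,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )
    return LocusSumStats(protein_id, chrom, gene_start, gene_end, df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_locus():
    return make_locus(
        pos=[1100, 1400, 1800],
        beta=[0.2, -0.1, 0.05],
        se=[0.02, 0.02, 0.02],
        eaf=[0.3, 0.45, 0.2],
        a1=["A", "C", "G"],
        a2=["G", "T", "T"],
    )
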