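import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def nac_folds():
    """Tidy per-case signed-fold table of the 12 consistently changed miRNAs."""
    from mirchemo.datasets import load_nac_fold_table

    return load_nac_fold_table()


def make_ct_long(ct_by_case: dict) -> pd.DataFrame:
    """Build a long-format Ct table from {case: {'pre': {mirna: ct}, 'post': ...}}."""
    rows = []
    for case, tps in ct_by_case.items():
        for tp, cts in tps.items():
            for mirna, ct in cts.items():
                rows.append(
                    {"mirna_id": mirna, "case_id": case, "timepoint": tp,
                     "ct": np.nan if ct is None else float(ct)}
                )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_ct_pair():
    """One matched pair: miR-a halves its Ct distance to the mean (up 2-fold),
    miR-b does the opposite; mean-centering is unchanged between timepoints."""
    return make_ct_long(
        {"case1": {"pre": {"miR-a": 24.0, "miR-b": 26.0},
                   "post": {"miR-a": 23.0, "miR-b": 27.0}}}
    )


@pytest.fixture
def consensus_fixture():
    """Prediction table reproducing the nomination set algebra: SEMA6D predicted
    by all five algorithms, HOXA10 by four, plus a consensus-only and a
    pulldown-only decoy."""
    algos = ["miRanda", "PicTar", "TargetScan", "RNA22", "PITA"]
    rows = []
    for algo in algos:
        rows.append({"gene_id": "SEMA6D", "mirna_id": "miR-195", "algorithm": algo})
    for algo in algos[:4]:
        rows.append({"gene_id": "HOXA10", "mirna_id": "miR-195", "algorithm": algo})
    for algo in algos:  # strong consensus but absent from the pulldown
        rows.append({"gene_id": "DECOY1", "mirna_id": "miR-195", "algorithm": algo})
    rows.append({"gene_id": "WEAK1", "mirna_id": "miR-195", "algorithm": "PITA"})
    return pd.DataFrame(rows)
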