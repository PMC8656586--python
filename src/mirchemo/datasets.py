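"""Small built-in reference tables.

``load_nac_fold_table`` returns the published per-case signed fold-change
matrix for the 12 miRNAs found consistently differentially expressed between
matched pre- and post-neoadjuvant-chemotherapy breast cancer samples in five
ER-positive cases.  Entries printed as lower bounds (">30" etc.) arise from
pairs where one sample was undetected and its Ct was imputed at the 40-cycle
detection limit; they are flagged as estimates and carried at their bound
value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["load_nac_fold_table"]

CASES = ["case1", "case2", "case3", "case4", "case5"]

# signed per-case folds; None = value is an estimated bound (see _ESTIMATES)
_FOLDS = {
    "miR-195": [3.46, 1.84, 1.70, 1.33, 4.50],
    "miR-26b": [3.39, 1.54, 1.92, 1.79, 15.7],
    "let-7c": [1.71, 2.76, 1.99, 1.15, 1.94],
    "miR-10a": [-2.33, -1.42, -14.4, -1.27, -1.36],
    "miR-26a": [1.72, 1.18, 2.83, 1.54, 2.69],
    "miR-330": [1.70, 1.32, 1.11, 1.82, 30.0],
    "miR-335": [3.15, 4.94, 1.16, 1.55, 120.0],
    "miR-362": [1.68, 1.03, 1.27, 2.85, 100.0],
    "miR-483-5p": [7020.0, 3.34, 1.13, 2.27, 19.9],
    "miR-885-5p": [870.0, 1.14, 42.0, 2.69, 20.0],
    "miR-625": [27.8, 1.24, 1.10, 4.04, 10.0],
    "miR-365": [-1.18, -1.47, -4.03, -1.19, -1.66],
}

# (miRNA, case index) pairs whose folds are undetected-imputed bounds
_ESTIMATES = {
    ("miR-330", 4),
    ("miR-335", 4),
    ("miR-362", 4),
    ("miR-885-5p", 0),
    ("miR-885-5p", 4),
    ("miR-625", 4),
}


def load_nac_fold_table(tidy: bool = True) -> pd.DataFrame:
    """The 12-miRNA matched pre/post fold-change matrix.

    With ``tidy=True`` (default) returns a long frame with columns
    ``mirna_id``, ``case_id``, ``signed_fold``, ``ratio``, ``is_estimate``,
    ``missing`` compatible with the qpcr module's fold-table operations.
    Otherwise returns the wide signed-fold matrix with a parallel boolean
    estimate mask in ``df.attrs['is_estimate']``.
    """
    wide = pd.DataFrame(_FOLDS, index=CASES).T
    wide.index.name = "mirna_id"
    est = pd.DataFrame(False, index=wide.index, columns=wide.columns)
    for mirna, i in _ESTIMATES:
        est.loc[mirna, CASES[i]] = True
    if not tidy:
        wide.attrs["is_estimate"] = est
        return wide
    long = wide.stack().rename("signed_fold").reset_index().rename(columns={"level_1": "case_id"})
    long["ratio"] = np.where(
        long["signed_fold"] >= 1, long["signed_fold"], -1.0 / long["signed_fold"]
    )
    long["is_estimate"] = [
        bool(est.loc[m, c]) for m, c in zip(long["mirna_id"], long["case_id"])
    ]
    long["missing"] = False
    return long
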