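"""Matched-pair qPCR miRNA array analysis by the global-mean delta-delta Ct method.

The discovery stage of the pipeline: each tumour is profiled on a qPCR miRNA
array before and after neoadjuvant chemotherapy, per-sample Ct values are
normalized to the mean Ct of all miRNAs detected in that sample (global-mean
normalization), and post/pre expression ratios are computed per miRNA per case
as 2^(-ddCt).  Ratios are reported on the signed-fold convention (ratios < 1
become negative reciprocals, so |fold| >= 1 always).  miRNAs changing in the
same direction in every case survive the consistency filter; a per-case
magnitude filter (default 1.3-fold in every tumour) then selects the focal
candidates.

Undetected reactions (Ct at or beyond the detection limit, default 40 cycles,
or missing) are handled as in the source assay convention: if one side of a
pair is undetected its Ct is imputed at the detection limit, the resulting
fold is a *bound* flagged as an estimate; estimates participate in the
consistency and magnitude filters at their bound value but are excluded from
mean fold differences.  Pairs undetected on both sides carry no directional
evidence and disqualify the miRNA from consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "signed_fold",
    "ratio_from_signed",
    "normalize_sample",
    "normalize_to_reference",
    "case_fold_records",
    "fold_table",
    "mean_signed_fold",
    "consistency_filter",
    "magnitude_filter",
    "summarize_signed_folds",
    "DifferentialMirnaAnalysis",
]

DETECTION_LIMIT_CT = 40.0


def signed_fold(ratio):
    """Convert a positive post/pre expression ratio to the signed-fold convention.

    Ratios >= 1 are returned as-is; ratios < 1 are returned as the negative
    reciprocal (0.5 -> -2.0), so down-regulation reads as a fold with a minus
    sign and |signed fold| >= 1 always.
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r <= 0):
        raise ValueError("expression ratios must be positive")
    out = np.where(r >= 1.0, r, -1.0 / r)
    return float(out) if np.isscalar(ratio) or out.ndim == 0 else out


def ratio_from_signed(fold):
    """Inverse of :func:`signed_fold`: signed fold back to a positive ratio."""
    f = np.asarray(fold, dtype=float)
    if np.any(np.abs(f) < 1):
        raise ValueError("signed folds must have magnitude >= 1")
    out = np.where(f >= 1.0, f, -1.0 / f)
    return float(out) if np.isscalar(fold) or out.ndim == 0 else out


def normalize_sample(
    ct: pd.Series,
    detection_limit_ct: float = DETECTION_LIMIT_CT,
    sample_name: str | None = None,
) -> pd.Series:
    """Global-mean normalization of one sample's Ct vector.

    dCt = Ct - mean(Ct over detected miRNAs of this sample).  Entries that are
    missing or at/beyond the detection limit are undetected and stay NaN; they
    do not contribute to the normalization mean.
    """
    ct = pd.Series(ct, dtype=float)
    detected = ct.notna() & (ct < detection_limit_ct)
    if not detected.any():
        name = sample_name if sample_name is not None else (ct.name or "<unnamed>")
        raise ValueError(f"sample {name!r} has no detected miRNAs")
    mean_ct = ct[detected].mean()
    dct = ct.where(detected) - mean_ct
    return dct


def normalize_to_reference(
    ct: pd.Series,
    reference_id: str,
    detection_limit_ct: float = DETECTION_LIMIT_CT,
) -> pd.Series:
    """Single-reference normalization: dCt = Ct - Ct(reference gene).

    Used for follow-up qPCR where a single endogenous control (e.g. RNU48 for
    miRNA, ACTB for mRNA) replaces the array-stage global mean.
    """
    ct = pd.Series(ct, dtype=float)
    ref = ct.get(reference_id, np.nan)
    if not np.isfinite(ref) or ref >= detection_limit_ct:
        raise ValueError(f"reference {reference_id!r} is undetected in this sample")
    detected = ct.notna() & (ct < detection_limit_ct)
    return ct.where(detected) - ref


def case_fold_records(
    ct_pre: pd.Series,
    ct_post: pd.Series,
    case_id: str,
    detection_limit_ct: float = DETECTION_LIMIT_CT,
) -> pd.DataFrame:
    """Per-miRNA fold records for one matched pre/post pair.

    Both vectors must share the same miRNA index.  Undetected entries on one
    side only are imputed at the detection limit *after* the global-mean
    normalization (imputed values are bounds, not measurements, so they do not
    pull the sample mean); the resulting record is flagged ``is_estimate``.
    Double-undetected pairs are returned with NaN ratio and ``missing=True``.
    """
    ct_pre = pd.Series(ct_pre, dtype=float)
    ct_post = pd.Series(ct_post, dtype=float)
    if not ct_pre.index.equals(ct_post.index):
        raise ValueError("pre and post Ct vectors must share the same miRNA panel")

    det_pre = ct_pre.notna() & (ct_pre < detection_limit_ct)
    det_post = ct_post.notna() & (ct_post < detection_limit_ct)

    dct_pre = normalize_sample(ct_pre, detection_limit_ct, f"{case_id}:pre")
    dct_post = normalize_sample(ct_post, detection_limit_ct, f"{case_id}:post")
    # impute undetected side at the detection limit, relative to the detected-only mean
    mean_pre = ct_pre[det_pre].mean()
    mean_post = ct_post[det_post].mean()
    dct_pre = dct_pre.where(det_pre, detection_limit_ct - mean_pre)
    dct_post = dct_post.where(det_post, detection_limit_ct - mean_post)

    ddct = dct_post - dct_pre
    ratio = np.power(2.0, -ddct)
    missing = ~det_pre & ~det_post
    is_estimate = (det_pre ^ det_post)

    rec = pd.DataFrame(
        {
            "mirna_id": ct_pre.index,
            "case_id": case_id,
            "ratio": ratio.values,
            "signed_fold": np.where(ratio.values >= 1, ratio.values, -1.0 / ratio.values),
            "is_estimate": is_estimate.values,
            "missing": missing.values,
        }
    )
    rec.loc[rec["missing"], ["ratio", "signed_fold"]] = np.nan
    rec.loc[rec["missing"], "is_estimate"] = False
    return rec


def fold_table(
    ct_long: pd.DataFrame, detection_limit_ct: float = DETECTION_LIMIT_CT
) -> pd.DataFrame:
    """Fold records for every case in a long-format Ct table.

    Expects columns ``mirna_id``, ``case_id``, ``timepoint`` (pre|post), ``ct``
    (float, NaN = undetected).  Every (miRNA, case, timepoint) cell must be
    present exactly once and all cases must share the same panel.
    """
    required = {"mirna_id", "case_id", "timepoint", "ct"}
    if missing_cols := required - set(ct_long.columns):
        raise ValueError(f"Ct table missing columns: {sorted(missing_cols)}")
    bad_tp = set(ct_long["timepoint"].unique()) - {"pre", "post"}
    if bad_tp:
        raise ValueError(f"unknown timepoint values: {sorted(bad_tp)}")
    if ct_long.duplicated(["mirna_id", "case_id", "timepoint"]).any():
        raise ValueError("duplicate (mirna, case, timepoint) cells in Ct table")

    wide = ct_long.pivot(index="mirna_id", columns=["case_id", "timepoint"], values="ct")
    records = []
    for case in sorted(ct_long["case_id"].unique()):
        for tp in ("pre", "post"):
            if (case, tp) not in wide.columns:
                raise ValueError(f"case {case!r} lacks a {tp!r} sample")
        records.append(
            case_fold_records(wide[(case, "pre")], wide[(case, "post")], case, detection_limit_ct)
        )
    return pd.concat(records, ignore_index=True)


def mean_signed_fold(signed_folds, is_estimate=None) -> float:
    """Estimate-excluded mean fold difference on the ratio scale.

    Signed folds of non-estimate records are converted to positive ratios,
    averaged arithmetically, and the mean ratio converted back to a signed
    fold.  This reproduces both up-regulated and down-regulated summary rows
    of matched-pair array reports.
    """
    f = np.asarray(signed_folds, dtype=float)
    if is_estimate is None:
        est = np.zeros(f.shape, dtype=bool)
    else:
        est = np.asarray(is_estimate, dtype=bool)
    keep = ~est & ~np.isnan(f)
    if not keep.any():
        raise ValueError("no non-estimate fold records to average")
    ratios = ratio_from_signed(f[keep])
    return signed_fold(float(np.mean(np.atleast_1d(ratios))))


def _fold_wide(folds: pd.DataFrame):
    sf = folds.pivot(index="mirna_id", columns="case_id", values="signed_fold")
    est = folds.pivot(index="mirna_id", columns="case_id", values="is_estimate").astype(bool)
    return sf, est


def consistency_filter(folds: pd.DataFrame) -> set[str]:
    """miRNAs whose signed folds agree in sign, with |fold| > 1, in every case.

    Estimates participate at their bound value; a missing (double-undetected)
    case disqualifies the miRNA.
    """
    sf, _ = _fold_wide(folds)
    complete = sf.notna().all(axis=1)
    all_up = (sf > 1).all(axis=1)
    all_down = (sf < -1).all(axis=1)
    return set(sf.index[complete & (all_up | all_down)])


def magnitude_filter(folds: pd.DataFrame, min_fold: float = 1.3) -> set[str]:
    """miRNAs with |signed fold| >= min_fold in every case (estimates at bound)."""
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    sf, _ = _fold_wide(folds)
    ok = sf.notna().all(axis=1) & (sf.abs() >= min_fold).all(axis=1)
    return set(sf.index[ok])


def summarize_signed_folds(
    folds: pd.DataFrame, min_fold: float = 1.3, require_consistent: bool = True
) -> pd.DataFrame:
    """Summary table over a tidy fold table (one row per retained miRNA).

    Columns: per-case signed folds, ``mean_fold`` (estimate-excluded, ratio
    scale), ``n_estimates``, ``passes_filter`` (per-case magnitude >=
    ``min_fold``), ``direction``.  Rows ordered by |mean fold| descending,
    ties broken by identifier.
    """
    sf, est = _fold_wide(folds)
    keep = consistency_filter(folds) if require_consistent else set(sf.index)
    passing = magnitude_filter(folds, min_fold)
    rows = []
    for mirna in sf.index:
        if mirna not in keep:
            continue
        try:
            mean = mean_signed_fold(sf.loc[mirna].values, est.loc[mirna].values)
        except ValueError:
            mean = np.nan  # every case was an undetected-imputed bound
        row = {"mirna_id": mirna}
        row.update({c: sf.loc[mirna, c] for c in sf.columns})
        row["mean_fold"] = mean
        row["n_estimates"] = int(est.loc[mirna].sum())
        row["estimate_flags"] = ";".join(c for c in sf.columns if est.loc[mirna, c]) or "-"
        row["passes_filter"] = mirna in passing
        row["direction"] = "up" if (sf.loc[mirna] > 0).all() else "down"
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["mean_fold", "mirna_id"],
            key=lambda s: s.abs() if s.name == "mean_fold" else s,
            ascending=[False, True],
        ).reset_index(drop=True)
    return out


@dataclass
class _FilterConfig:
    min_fold: float = 1.3
    require_all_cases_consistent: bool = True
    detection_limit_ct: float = DETECTION_LIMIT_CT


class DifferentialMirnaAnalysis(BaseEstimator):
    """Matched-pair differential miRNA selector over qPCR array Ct tables.

    A feature-selection-shaped estimator: ``fit`` takes the long-format Ct
    table of matched pre/post samples, computes global-mean-normalized
    delta-delta-Ct folds per case, and selects miRNAs that change consistently
    in every case with at least ``min_fold`` magnitude in every case.

    Parameters
    ----------
    min_fold : float, default 1.3
        Per-case minimum |signed fold| for the magnitude filter.
    detection_limit_ct : float, default 40
        Ct at or beyond which a reaction counts as undetected; also the
        imputation value for singly-undetected pairs.
    require_consistent : bool, default True
        Whether the summary is restricted to direction-consistent miRNAs.

    Attributes
    ----------
    fold_table_ : DataFrame of per-(miRNA, case) fold records.
    summary_ : Summary table (one row per consistency-passing miRNA).
    consistent_mirnas_ : set of direction-consistent miRNA ids.
    selected_mirnas_ : set passing both filters.
    n_up_, n_down_ : direction tallies over the consistent set.
    """

    def __init__(self, min_fold: float = 1.3, detection_limit_ct: float = DETECTION_LIMIT_CT,
                 require_consistent: bool = True):
        self.min_fold = min_fold
        self.detection_limit_ct = detection_limit_ct
        self.require_consistent = require_consistent

    def fit(self, X: pd.DataFrame, y=None):
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        self.fold_table_ = fold_table(X, self.detection_limit_ct)
        self.consistent_mirnas_ = consistency_filter(self.fold_table_)
        self.summary_ = summarize_signed_folds(
            self.fold_table_, self.min_fold, self.require_consistent
        )
        self.selected_mirnas_ = self.consistent_mirnas_ & magnitude_filter(
            self.fold_table_, self.min_fold
        )
        if len(self.summary_):
            self.n_up_ = int((self.summary_["direction"] == "up").sum())
            self.n_down_ = int((self.summary_["direction"] == "down").sum())
        else:
            self.n_up_ = self.n_down_ = 0
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict a long-format Ct table to the selected miRNAs."""
        if not hasattr(self, "selected_mirnas_"):
            raise ValueError("estimator is not fitted")
        return X[X["mirna_id"].isin(self.selected_mirnas_)].copy()
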