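"""Candidate target calling from biotinylated-mimic pulldown RNA-seq counts.

Cells are transfected with a biotin-tagged miRNA mimic (or a scrambled
control), mimic-bound mRNAs are recovered on streptavidin beads and
sequenced; genes whose reads-per-million abundance in the mimic pulldown is
at least 100-fold that of the scrambled-control pulldown are called candidate
targets.  A pseudocount of 0.5 per gene keeps the ratio defined when the
control pulldown has zero reads; such pseudocount-dominated calls are
flagged.  Input (pre-pulldown lysate) samples are carried through and
reported but do not gate candidacy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["normalize_rpm", "enrichment_table", "call_candidates", "PulldownEnrichment"]

REQUIRED_COLUMNS = ("gene_id", "sample_id", "role", "condition", "count")


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if missing := set(REQUIRED_COLUMNS) - set(counts.columns):
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if (counts["count"] < 0).any():
        raise ValueError("negative counts")
    if counts.duplicated(["gene_id", "sample_id"]).any():
        raise ValueError("duplicate (gene, sample) cells in count table")
    bad_role = set(counts["role"].unique()) - {"pulldown", "input"}
    if bad_role:
        raise ValueError(f"unknown role values: {sorted(bad_role)}")
    return counts


def normalize_rpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-sample reads-per-million after pseudocount addition.

    rpm = (count + pseudocount) / sum_over_genes(count + pseudocount) * 1e6.
    Totals are computed after the pseudocount so rpm vectors always sum to 1e6.
    """
    counts = _validate_counts(counts)
    out = counts.copy()
    out["adj"] = out["count"].astype(float) + pseudocount
    totals = out.groupby("sample_id")["adj"].transform("sum")
    if (out.groupby("sample_id")["count"].sum() == 0).any():
        zero = out.groupby("sample_id")["count"].sum()
        bad = sorted(zero.index[zero == 0])
        raise ValueError(f"samples with zero total reads: {bad}")
    out["rpm"] = out["adj"] / totals * 1e6
    return out.drop(columns="adj")


def enrichment_table(
    counts: pd.DataFrame, threshold: float = 100.0, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-gene enrichment of each mimic pulldown over the control pulldown.

    The ``condition`` column distinguishes the scrambled ``control`` from one
    or more mimic conditions (e.g. ``miR-195``).  Returns one row per
    (condition, gene) with control/mimic pulldown RPM, input RPM where
    present, the enrichment ratio, the candidate flag (ratio >= threshold)
    and a flag for pseudocount-dominated ratios (control pulldown raw count
    of zero).
    """
    if threshold <= 1:
        raise ValueError("enrichment threshold must be > 1")
    rpm = normalize_rpm(counts, pseudocount)
    pull = rpm[rpm["role"] == "pulldown"]
    if "control" not in set(pull["condition"]):
        raise ValueError("no control pulldown sample in count table")
    ctrl = pull[pull["condition"] == "control"].set_index("gene_id")
    inputs = rpm[rpm["role"] == "input"]
    ctrl_input = inputs[inputs["condition"] == "control"].set_index("gene_id")

    frames = []
    for cond in sorted(set(pull["condition"]) - {"control"}):
        mi = pull[pull["condition"] == cond].set_index("gene_id")
        genes = mi.index.intersection(ctrl.index)
        df = pd.DataFrame(index=genes)
        df["condition"] = cond
        df["rpm_control_pulldown"] = ctrl.loc[genes, "rpm"]
        df["rpm_mirna_pulldown"] = mi.loc[genes, "rpm"]
        df["enrichment_ratio"] = df["rpm_mirna_pulldown"] / df["rpm_control_pulldown"]
        df["is_candidate"] = df["enrichment_ratio"] >= threshold
        df["pseudocount_dominated"] = (ctrl.loc[genes, "count"] == 0).values
        if len(ctrl_input):
            df["rpm_control_input"] = ctrl_input["rpm"].reindex(genes)
        cond_input = inputs[inputs["condition"] == cond].set_index("gene_id")
        if len(cond_input):
            df["rpm_mirna_input"] = cond_input["rpm"].reindex(genes)
        df = df.sort_values(
            ["enrichment_ratio", "condition"], ascending=[False, True], kind="mergesort"
        )
        frames.append(df.rename_axis("gene_id").reset_index())
    return pd.concat(frames, ignore_index=True)


def call_candidates(enrichment: pd.DataFrame, threshold: float = 100.0) -> dict[str, list[str]]:
    """Candidate gene lists per mimic condition, ordered by ratio descending."""
    if threshold <= 1:
        raise ValueError("enrichment threshold must be > 1")
    out: dict[str, list[str]] = {}
    for cond, df in enrichment.groupby("condition"):
        hits = df[df["enrichment_ratio"] >= threshold].sort_values(
            ["enrichment_ratio", "gene_id"], ascending=[False, True], kind="mergesort"
        )
        out[cond] = hits["gene_id"].tolist()
    return out


class PulldownEnrichment(BaseEstimator):
    """Caller for mimic-bound candidate targets from pulldown count tables.

    Parameters
    ----------
    threshold : float, default 100
        Minimum mimic-pulldown / control-pulldown RPM ratio for candidacy.
    pseudocount : float, default 0.5
        Added to every raw count before totals and RPM.

    Attributes
    ----------
    rpm_ : long RPM table.
    enrichment_ : per-(condition, gene) enrichment records.
    candidates_ : dict mapping mimic condition to ordered candidate gene list.
    """

    def __init__(self, threshold: float = 100.0, pseudocount: float = 0.5):
        self.threshold = threshold
        self.pseudocount = pseudocount

    def fit(self, X: pd.DataFrame, y=None):
        self.rpm_ = normalize_rpm(X, self.pseudocount)
        self.enrichment_ = enrichment_table(X, self.threshold, self.pseudocount)
        self.candidates_ = call_candidates(self.enrichment_, self.threshold)
        return self
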