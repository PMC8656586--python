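"""Drug-response quantification for MTT viability and clonogenic survival assays.

Implements the double normalization used throughout the cell-line validation
experiments: survival is first expressed relative to the vehicle control
within each transfection condition, then the targeted condition's relative
survival is divided by its scrambled control's, so transfection and plating
effects cancel.  Condition differences are tested with paired one-tailed t
tests over biological replicates (technical replicates are averaged first).
Clonogenic assays are summarized as plating efficiency (colonies/seeded,
counting >30 cells as a colony upstream) and surviving fraction.  ICxx values
are read off dose-response curves by linear interpolation of relative
survival against log10(dose); no parametric model is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "relative_survival_vs_vehicle",
    "relative_to_control_transfection",
    "paired_one_tailed_t",
    "surviving_fraction",
    "estimate_ic",
    "resistance_ratio",
    "DoseResponseAnalysis",
]

PLATE_COLUMNS = ("condition", "dose_nM", "bio_rep", "tech_rep", "signal")


@dataclass
class PairedTResult:
    statistic: float
    p_value: float
    df: int
    direction: str
    degenerate: bool = False


def _bio_rep_means(plate: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Technical replicates averaged within (bio rep, dose) for one condition."""
    if missing := set(PLATE_COLUMNS) - set(plate.columns):
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    sub = plate[plate["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no wells for condition {condition!r}")
    return sub.groupby(["bio_rep", "dose_nM"], as_index=False)["signal"].mean()


def relative_survival_vs_vehicle(plate: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per-dose survival relative to the vehicle (dose 0) wells of one condition.

    Technical replicates are averaged within each biological replicate, each
    biological replicate is normalized to its own vehicle mean, and the
    per-dose mean, SD and SEM across biological replicates are returned along
    with the per-replicate values (column ``relative_survival`` in the
    ``per_rep`` attribute of the result frame).
    """
    reps = _bio_rep_means(plate, condition)
    if 0 not in set(reps["dose_nM"]):
        raise ValueError(f"condition {condition!r} has no vehicle (dose 0) wells")
    vehicle = reps[reps["dose_nM"] == 0].set_index("bio_rep")["signal"]
    if (vehicle <= 0).any():
        raise ValueError(f"non-positive vehicle signal for condition {condition!r}")
    reps = reps.merge(vehicle.rename("vehicle"), left_on="bio_rep", right_index=True)
    reps["relative_survival"] = reps["signal"] / reps["vehicle"]
    curve = (
        reps.groupby("dose_nM")["relative_survival"]
        .agg(mean_relative_survival="mean", sd="std", n="size")
        .reset_index()
        .sort_values("dose_nM")
        .reset_index(drop=True)
    )
    curve["sem"] = curve["sd"] / np.sqrt(curve["n"])
    curve.attrs["condition"] = condition
    curve.attrs["per_rep"] = reps[["bio_rep", "dose_nM", "relative_survival"]]
    return curve


def relative_to_control_transfection(
    curve_target: pd.DataFrame, curve_control: pd.DataFrame
) -> pd.DataFrame:
    """Per-dose, per-biological-replicate ratio of target to control relative survival."""
    t = curve_target.attrs["per_rep"]
    c = curve_control.attrs["per_rep"]
    if set(t["dose_nM"]) != set(c["dose_nM"]):
        raise ValueError("dose grids of target and control conditions do not match")
    merged = t.merge(c, on=["bio_rep", "dose_nM"], suffixes=("_target", "_control"))
    merged["ratio"] = (
        merged["relative_survival_target"] / merged["relative_survival_control"]
    )
    out = (
        merged.groupby("dose_nM")["ratio"]
        .agg(mean_ratio="mean", sd="std", n="size")
        .reset_index()
        .sort_values("dose_nM")
        .reset_index(drop=True)
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.attrs["per_rep"] = merged[["bio_rep", "dose_nM", "ratio"]]
    return out


def paired_one_tailed_t(target_values, control_values, direction: str = "greater") -> PairedTResult:
    """Paired one-tailed t test over biological replicates.

    ``direction='greater'`` tests H1: target > control (the mimic/siRNA
    resistance hypothesis); ``'less'`` tests target < control (inhibitors).
    Zero variance of the paired differences is degenerate: p is 0 or 1 by the
    sign of the common difference (0.5 if all differences are zero).
    """
    if direction not in {"greater", "less"}:
        raise ValueError("direction must be 'greater' or 'less'")
    x = np.asarray(target_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            p = 0.5
        else:
            favours = d.mean() > 0 if direction == "greater" else d.mean() < 0
            p = 0.0 if favours else 1.0
        return PairedTResult(np.inf if p == 0.0 else (0.0 if p == 0.5 else -np.inf),
                             p, len(x) - 1, direction, degenerate=True)
    res = stats.ttest_rel(x, y, alternative=direction)
    return PairedTResult(float(res.statistic), float(res.pvalue), len(x) - 1, direction)


def surviving_fraction(colonies_treated: int, seeded_treated: int,
                       colonies_vehicle: int, seeded_vehicle: int) -> float:
    """Clonogenic surviving fraction: PE(treated) / PE(vehicle)."""
    if seeded_treated <= 0 or seeded_vehicle <= 0:
        raise ValueError("seeded cell counts must be positive")
    pe_vehicle = colonies_vehicle / seeded_vehicle
    if pe_vehicle == 0:
        raise ValueError("vehicle plating efficiency is zero")
    return (colonies_treated / seeded_treated) / pe_vehicle


def estimate_ic(doses, survival, target_fraction: float = 0.5) -> float:
    """ICxx by linear interpolation of survival against log10(dose).

    ``target_fraction`` is the surviving fraction at the sought dose (0.5 for
    IC50, 0.75 for IC25, 0.25 for IC75).  The vehicle point (dose 0) cannot
    appear on a log-dose axis and is ignored.  The first down-crossing of the
    target level along ascending dose is interpolated; an exact grid hit
    returns that dose.  Levels outside the observed survival range raise —
    no extrapolation.
    """
    doses = np.asarray(doses, dtype=float)
    survival = np.asarray(survival, dtype=float)
    keep = doses > 0
    doses, survival = doses[keep], survival[keep]
    if len(doses) < 2:
        raise ValueError("need at least two positive doses")
    order = np.argsort(doses)
    doses, survival = doses[order], survival[order]
    hits = np.isclose(survival, target_fraction)
    if hits.any():
        return float(doses[hits][0])
    for i in range(len(doses) - 1):
        s0, s1 = survival[i], survival[i + 1]
        if (s0 - target_fraction) * (s1 - target_fraction) < 0:
            l0, l1 = np.log10(doses[i]), np.log10(doses[i + 1])
            frac = (target_fraction - s0) / (s1 - s0)
            return float(10 ** (l0 + frac * (l1 - l0)))
    raise ValueError(
        f"survival level {target_fraction} is not bracketed by the observed curve"
    )


def resistance_ratio(ic_resistant: float, ic_parental: float) -> float:
    """Fold resistance: ICxx(resistant line) / ICxx(parental line)."""
    if ic_resistant <= 0 or ic_parental <= 0:
        raise ValueError("IC values must be positive")
    return ic_resistant / ic_parental


class DoseResponseAnalysis(BaseEstimator):
    """Dose-response summarization of a viability plate across conditions.

    ``fit`` takes a long plate table (``condition``, ``dose_nM``, ``bio_rep``,
    ``tech_rep``, ``signal``) and builds vehicle-normalized curves for every
    condition.  Pairwise comparisons against a control condition use the
    double normalization and a paired one-tailed t test per dose.

    Attributes
    ----------
    curves_ : dict condition -> per-dose relative-survival frame.
    conditions_ : sorted condition labels.
    """

    def __init__(self, ic_fractions: tuple[float, ...] = (0.75, 0.5, 0.25)):
        self.ic_fractions = ic_fractions

    def fit(self, X: pd.DataFrame, y=None):
        self.conditions_ = sorted(X["condition"].unique())
        self.curves_ = {
            c: relative_survival_vs_vehicle(X, c) for c in self.conditions_
        }
        return self

    def ic(self, condition: str, xx: float = 50.0) -> float:
        """ICxx for one condition (xx on the percent-inhibition scale)."""
        curve = self.curves_[condition]
        return estimate_ic(
            curve["dose_nM"].values, curve["mean_relative_survival"].values, 1 - xx / 100
        )

    def compare(self, target: str, control: str, direction: str = "greater") -> pd.DataFrame:
        """Per-dose paired one-tailed t tests of target vs control condition."""
        ratios = relative_to_control_transfection(
            self.curves_[target], self.curves_[control]
        )
        per_rep_t = self.curves_[target].attrs["per_rep"]
        per_rep_c = self.curves_[control].attrs["per_rep"]
        rows = []
        for dose in sorted(set(per_rep_t["dose_nM"])):
            if dose == 0:
                continue
            tv = per_rep_t[per_rep_t["dose_nM"] == dose].sort_values("bio_rep")
            cv = per_rep_c[per_rep_c["dose_nM"] == dose].sort_values("bio_rep")
            res = paired_one_tailed_t(
                tv["relative_survival"].values, cv["relative_survival"].values, direction
            )
            rows.append(
                {
                    "dose_nM": dose,
                    "mean_ratio": float(
                        ratios.loc[ratios["dose_nM"] == dose, "mean_ratio"].iloc[0]
                    ),
                    "t_statistic": res.statistic,
                    "p_value": res.p_value,
                    "df": res.df,
                    "direction": direction,
                    "degenerate": res.degenerate,
                }
            )
        return pd.DataFrame(rows)
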