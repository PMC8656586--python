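"""Synthetic-data generators for every pipeline input.

Each generator emulates the statistical structure its consuming stage
assumes, with planted ground truth so recovery can be verified end to end:

* matched pre/post qPCR Ct arrays (377 miRNAs x 5 pairs by default) with
  planted consistent fold changes, Gaussian Ct noise and detection dropout
  beyond the 40-cycle limit;
* pulldown/input RNA-seq count tables with planted strongly-enriched genes
  in the mimic pulldown only;
* five-algorithm prediction tables with configurable per-gene support and
  genes forced to 5-of-5 or 4-of-5;
* survival cohorts in which low expression raises the event hazard only in
  the chemotherapy arm;
* logistic dose-response viability plates and binomial clonogenic counts
  with a shiftable IC50 per condition.

A single integer seed drives one ``numpy.random.SeedSequence`` whose spawned
children give every generator an independent stream, so outputs are
reproducible jointly and individually.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .targets import ALGORITHMS

__all__ = [
    "SimulationConfig",
    "gen_ct_arrays",
    "gen_pulldown_counts",
    "gen_prediction_table",
    "gen_survival_cohort",
    "gen_viability",
    "gen_clonogenic",
    "simulate_all",
]

# default planted post/pre ratios; magnitudes mirror the 2.6- and 4.9-fold
# mean changes of the two focal miRNAs, both directions represented
DEFAULT_PLANTED_MIRNAS = {
    "miR-sim-up1": 2.0,
    "miR-sim-up2": 2.6,
    "miR-sim-up3": 3.2,
    "miR-sim-up4": 4.0,
    "miR-sim-up5": 4.9,
    "miR-sim-dn1": 1 / 2.0,
    "miR-sim-dn2": 1 / 3.0,
}


@dataclass
class SimulationConfig:
    """Parameters for all generators; defaults mirror the study's scale."""

    seed: int = 0
    # qPCR arrays
    n_mirnas: int = 377
    n_pairs: int = 5
    planted_mirnas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_MIRNAS)
    )
    ct_noise_sd: float = 0.15
    dropout_ct: float = 40.0
    baseline_ct_mean: float = 29.0
    baseline_ct_sd: float = 4.0
    # pulldown counts
    n_genes: int = 6000
    planted_targets: dict[str, float] = field(
        default_factory=lambda: {
            "SEMA6D": 200.0,
            "HOXA10": 200.0,
            **{f"GENE{i:04d}": 200.0 for i in range(18)},
        }
    )
    library_size: int = 1_000_000
    planted_abundance_factor: float = 0.35
    mirna_label: str = "miR-195"
    # predictions
    forced_5of5: tuple[str, ...] = ("SEMA6D",)
    forced_4of5: tuple[str, ...] = ("HOXA10",)
    mean_support: float = 1.2
    # survival cohort
    cohort_n: int = 2000
    chemo_fraction: float = 0.21
    hazard_ratio_low: float = 2.0
    low_cutoff_sd: float = -0.82
    baseline_hazard: float = 0.006  # events per month
    censoring_rate: float = 0.3
    # viability / clonogenic
    ic50_by_condition: dict[str, float] = field(
        default_factory=lambda: {"mimic-control": 100.0, "mimic": 200.0}
    )
    hill_slope: float = 1.0
    doses_nM: tuple[float, ...] = (0.0, 30.0, 60.0, 125.0, 250.0, 500.0, 1000.0)
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    signal_noise_cv: float = 0.05
    seeded_cells: int = 100
    plating_efficiency: float = 0.6

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(5)
        names = ("ct", "pulldown", "predictions", "survival", "viability")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _rng_for(config: SimulationConfig, stream: str) -> np.random.Generator:
    return config.streams()[stream]


def gen_ct_arrays(config: SimulationConfig) -> pd.DataFrame:
    """Long-format Ct table for matched pre/post qPCR arrays.

    Planted miRNAs shift their post-treatment Ct by -log2(true ratio); all
    Cts get Gaussian noise; values at/beyond ``dropout_ct`` are undetected
    (NaN).  Planted miRNAs are assigned mid-range baselines so they stay
    detectable and recovery reflects the filters, not dropout.
    """
    if any(r <= 0 for r in config.planted_mirnas.values()):
        raise ValueError("planted ratios must be positive")
    rng = _rng_for(config, "ct")
    planted = list(config.planted_mirnas)
    if len(planted) > config.n_mirnas:
        raise ValueError("more planted miRNAs than panel size")
    n_null = config.n_mirnas - len(planted)
    mirnas = planted + [f"miR-null-{i:03d}" for i in range(n_null)]

    base = rng.normal(config.baseline_ct_mean, config.baseline_ct_sd, size=config.n_mirnas)
    # keep planted miRNAs well inside the detectable range
    base[: len(planted)] = rng.uniform(24.0, 32.0, size=len(planted))
    shift = np.zeros(config.n_mirnas)
    shift[: len(planted)] = -np.log2(list(config.planted_mirnas.values()))

    rows = []
    for p in range(config.n_pairs):
        case = f"case{p + 1}"
        ct_pre = base + rng.normal(0, config.ct_noise_sd, config.n_mirnas)
        ct_post = base + shift + rng.normal(0, config.ct_noise_sd, config.n_mirnas)
        for tp, ct in (("pre", ct_pre), ("post", ct_post)):
            detected = ct < config.dropout_ct
            rows.append(
                pd.DataFrame(
                    {
                        "mirna_id": mirnas,
                        "case_id": case,
                        "timepoint": tp,
                        "ct": np.where(detected, ct, np.nan),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def gen_pulldown_counts(config: SimulationConfig) -> pd.DataFrame:
    """Pulldown/input count tables with planted enrichment in the mimic pulldown.

    Null genes share expected reads-per-million across the control and mimic
    pulldowns; planted targets have their mimic-pulldown rate multiplied by
    the configured enrichment.  Planted targets are modelled as moderately
    expressed (``planted_abundance_factor`` times the mean null abundance),
    as is typical of regulatory-target mRNAs.  Counts are Poisson at the
    configured library size.
    """
    rng = _rng_for(config, "pulldown")
    planted = list(config.planted_targets)
    n_null = config.n_genes - len(planted)
    if n_null < 0:
        raise ValueError("more planted targets than genes")
    genes = planted + [f"NULL{i:05d}" for i in range(n_null)]
    weights = np.empty(config.n_genes)
    weights[len(planted):] = rng.uniform(0.5, 1.5, size=n_null)
    weights[: len(planted)] = config.planted_abundance_factor
    enrich = np.ones(config.n_genes)
    enrich[: len(planted)] = list(config.planted_targets.values())

    base_rate = weights / weights.sum() * config.library_size
    rows = []
    samples = {
        ("pulldown", "control"): base_rate,
        ("pulldown", config.mirna_label): base_rate * enrich,
        ("input", "control"): base_rate,
        ("input", config.mirna_label): base_rate,
    }
    for (role, condition), lam in samples.items():
        counts = rng.poisson(lam)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "sample_id": f"{role}_{condition}",
                    "role": role,
                    "condition": condition,
                    "count": counts,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def gen_prediction_table(config: SimulationConfig) -> pd.DataFrame:
    """Five-algorithm prediction memberships with forced 5-of-5/4-of-5 genes."""
    rng = _rng_for(config, "predictions")
    algos = sorted(ALGORITHMS)
    planted = list(config.planted_targets)
    extra = [g for g in (*config.forced_5of5, *config.forced_4of5) if g not in planted]
    genes = planted + extra
    rows = []
    for gene in genes:
        if gene in config.forced_5of5:
            support = 5
        elif gene in config.forced_4of5:
            support = 4
        else:
            support = int(np.clip(rng.poisson(config.mean_support), 0, 5))
        for algo in rng.choice(algos, size=support, replace=False):
            rows.append({"gene_id": gene, "mirna_id": config.mirna_label, "algorithm": algo})
    return pd.DataFrame(rows, columns=["gene_id", "mirna_id", "algorithm"])


def gen_survival_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Cohort with an expression-linked hazard confined to the chemotherapy arm.

    Event times are exponential with the baseline hazard, multiplied by
    ``hazard_ratio_low`` for low-expression patients (z below
    ``low_cutoff_sd``) in the chemo arm only.  Censoring times are
    independent exponentials tuned to the configured censoring rate.  ER and
    HER2 status are drawn at realistic breast-cancer marginals (75% ER+,
    15% HER2+) independent of outcome.
    """
    if config.hazard_ratio_low < 1:
        raise ValueError("hazard_ratio_low must be >= 1")
    rng = _rng_for(config, "survival")
    n = config.cohort_n
    z = rng.normal(0.0, 1.0, n)
    chemo = rng.random(n) < config.chemo_fraction
    low = z < config.low_cutoff_sd
    hazard = np.full(n, config.baseline_hazard)
    hazard[chemo & low] *= config.hazard_ratio_low
    event_time = rng.exponential(1.0 / hazard)
    c = config.censoring_rate
    cens_rate = config.baseline_hazard * c / max(1.0 - c, 1e-9)
    censor_time = rng.exponential(1.0 / cens_rate, n) if cens_rate > 0 else np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "time_months": time,
            "event": event.astype(int),
            "expression_z": z,
            "chemo_treated": chemo,
            "er_status": rng.choice(["positive", "negative"], n, p=[0.75, 0.25]),
            "her2_status": rng.choice(["positive", "negative"], n, p=[0.15, 0.85]),
        }
    )


def _logistic_survival(dose: np.ndarray, ic50: float, hill: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(dose <= 0, 1.0, 1.0 / (1.0 + (dose / ic50) ** hill))


def gen_viability(config: SimulationConfig) -> pd.DataFrame:
    """MTT-style plate signals from a logistic dose-response per condition."""
    if any(v <= 0 for v in config.ic50_by_condition.values()):
        raise ValueError("IC50 values must be positive")
    rng = _rng_for(config, "viability")
    doses = np.asarray(config.doses_nM, dtype=float)
    rows = []
    for condition, ic50 in config.ic50_by_condition.items():
        surv = _logistic_survival(doses, ic50, config.hill_slope)
        for bio in range(1, config.n_bio_reps + 1):
            vehicle_level = rng.uniform(0.8, 1.2)
            for dose, s in zip(doses, surv):
                for tech in range(1, config.n_tech_reps + 1):
                    noise = rng.lognormal(0.0, config.signal_noise_cv)
                    rows.append(
                        {
                            "condition": condition,
                            "dose_nM": dose,
                            "bio_rep": f"bio{bio}",
                            "tech_rep": f"tech{tech}",
                            "signal": vehicle_level * s * noise,
                        }
                    )
    return pd.DataFrame(rows)


def gen_clonogenic(config: SimulationConfig) -> pd.DataFrame:
    """Clonogenic colony counts: binomial with PE scaled by logistic survival."""
    rng = _rng_for(config, "viability")
    rng = np.random.default_rng(rng.integers(2**31))  # sub-stream; keeps plates independent
    doses = np.asarray(config.doses_nM, dtype=float)
    rows = []
    for condition, ic50 in config.ic50_by_condition.items():
        surv = _logistic_survival(doses, ic50, config.hill_slope)
        for dose, s in zip(doses, surv):
            pe = config.plating_efficiency * s
            colonies = rng.binomial(config.seeded_cells, min(pe, 1.0))
            rows.append(
                {
                    "condition": condition,
                    "dose_nM": dose,
                    "seeded": config.seeded_cells,
                    "colonies": int(colonies),
                }
            )
    return pd.DataFrame(rows)


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every generator's table as TSV plus a manifest of config and seed."""
    from .io import write_table  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "ct_arrays": gen_ct_arrays(config),
        "pulldown_counts": gen_pulldown_counts(config),
        "predictions": gen_prediction_table(config),
        "survival_cohort": gen_survival_cohort(config),
        "viability": gen_viability(config),
        "clonogenic": gen_clonogenic(config),
    }
    paths = {}
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        write_table(df, path)
        paths[name] = path
    manifest = {
        "seed": config.seed,
        "config": {
            k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = manifest_path
    return paths
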