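"""Pipeline orchestration: run every analysis stage in order and write outputs.

Stage order follows the study design: miRNA discovery from matched qPCR
arrays, chemoresponse quantification, target nomination (pulldown enrichment
plus prediction consensus), then survival evaluation of the nominated target.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .chemo import DoseResponseAnalysis
from .io import file_sha256, read_table, write_manifest, write_table
from .pulldown import PulldownEnrichment
from .qpcr import DifferentialMirnaAnalysis
from .survival import DEFAULT_CUTOFFS, ExpressionSurvivalAnalysis
from .targets import TargetNominator

log = logging.getLogger("mirchemo")

DEFAULT_THRESHOLDS = {
    "min_fold": 1.3,
    "detection_limit_ct": 40.0,
    "enrichment_threshold": 100.0,
    "consensus_k": 5,
    "cutoff_sd_dfs": DEFAULT_CUTOFFS["DFS"],
    "cutoff_sd_dss": DEFAULT_CUTOFFS["DSS"],
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict) -> dict:
    """Run all stages named in ``config`` and write a result bundle.

    ``config`` keys: ``outdir`` (required); input paths ``ct``, ``counts``,
    ``predictions``, ``plate``, ``clonogenic``, ``cohort`` (each optional —
    stages with missing inputs are skipped); threshold overrides from
    ``DEFAULT_THRESHOLDS``.  Returns a dict of stage -> output paths.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **{k: config[k] for k in DEFAULT_THRESHOLDS if k in config}}
    log.info("thresholds: %s", thresholds)
    outputs: dict[str, str] = {}
    input_hashes = {
        k: file_sha256(config[k])
        for k in ("ct", "counts", "predictions", "plate", "clonogenic", "cohort")
        if k in config
    }

    pulldown_candidates = None
    if "ct" in config:
        try:
            ct = read_table(config["ct"], "ct")
            est = DifferentialMirnaAnalysis(
                min_fold=thresholds["min_fold"],
                detection_limit_ct=thresholds["detection_limit_ct"],
            ).fit(ct)
            outputs["ddct_summary"] = str(write_table(est.summary_, outdir / "ddct_summary.tsv"))
            outputs["ddct_folds"] = str(write_table(est.fold_table_, outdir / "ddct_folds.tsv"))
            log.info(
                "ddct: %d consistent (%d up / %d down), %d pass %.2f-fold filter",
                len(est.consistent_mirnas_), est.n_up_, est.n_down_,
                len(est.selected_mirnas_), thresholds["min_fold"],
            )
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError("ddct", exc) from exc

    if "counts" in config:
        try:
            counts = read_table(config["counts"], "counts")
            pe = PulldownEnrichment(threshold=thresholds["enrichment_threshold"]).fit(counts)
            outputs["enrichment"] = str(write_table(pe.enrichment_, outdir / "enrichment.tsv"))
            pulldown_candidates = pe.candidates_
            log.info("pulldown: %s", {k: len(v) for k, v in pe.candidates_.items()})
        except Exception as exc:
            raise StageError("pulldown", exc) from exc

    if "predictions" in config and pulldown_candidates:
        try:
            preds = read_table(config["predictions"], "predictions")
            nom = TargetNominator(k=thresholds["consensus_k"]).fit(
                preds, pulldown_candidates=pulldown_candidates
            )
            rows = []
            for mirna, cs in nom.nominated_.items():
                for gene in cs.genes:
                    rows.append(
                        {"mirna_id": mirna, "gene_id": gene, "source": cs.source,
                         "k_required": cs.k_required, "n_algorithms": cs.support.get(gene, 0)}
                    )
            outputs["targets"] = str(
                write_table(
                    pd.DataFrame(
                        rows,
                        columns=["mirna_id", "gene_id", "source", "k_required", "n_algorithms"],
                    ),
                    outdir / "targets.tsv",
                )
            )
            log.info("targets: %s", {m: list(c.genes) for m, c in nom.nominated_.items()})
        except Exception as exc:
            raise StageError("targets", exc) from exc

    if "plate" in config:
        try:
            plate = read_table(config["plate"], "plate")
            dra = DoseResponseAnalysis().fit(plate)
            curves = pd.concat(
                [c.assign(condition=name) for name, c in dra.curves_.items()],
                ignore_index=True,
            )
            outputs["dose_response"] = str(write_table(curves, outdir / "dose_response.tsv"))
            log.info("chemo: %d conditions", len(dra.conditions_))
        except Exception as exc:
            raise StageError("chemo", exc) from exc

    if "cohort" in config:
        try:
            cohort = read_table(config["cohort"], "cohort")
            cohort["chemo_treated"] = cohort["chemo_treated"].astype(str).str.lower().isin(
                ["true", "1", "yes"]
            )
            esa = ExpressionSurvivalAnalysis(cutoff_sd=thresholds["cutoff_sd_dfs"]).fit(cohort)
            rows = [
                {
                    "comparison": "full_cohort",
                    "statistic": esa.logrank_.statistic,
                    "p_value": esa.logrank_.p_value,
                    "n_low": esa.logrank_.n_groups[0],
                    "n_high": esa.logrank_.n_groups[1],
                }
            ]
            for name, res in esa.subgroups("chemo").items():
                if name.startswith("_") or res is None:
                    continue
                rows.append(
                    {
                        "comparison": name,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "n_low": res.n_groups[0],
                        "n_high": res.n_groups[1],
                    }
                )
            outputs["survival"] = str(
                write_table(pd.DataFrame(rows), outdir / "survival.tsv")
            )
            if esa.km_low_ is not None:
                outputs["km_low"] = str(write_table(esa.km_low_, outdir / "km_low.tsv"))
            if esa.km_high_ is not None:
                outputs["km_high"] = str(write_table(esa.km_high_, outdir / "km_high.tsv"))
            log.info("survival: full-cohort p=%.4g", esa.logrank_.p_value)
        except Exception as exc:
            raise StageError("survival", exc) from exc

    write_manifest(
        outdir / "run_manifest.json",
        version=__version__,
        seed=config.get("seed"),
        thresholds=thresholds,
        input_hashes=input_hashes,
        outputs=outputs,
    )
    outputs["manifest"] = str(outdir / "run_manifest.json")
    return outputs
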