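"""Tabular IO: one TSV dialect, schema validation, manifests.

All pipeline tables are tab-separated UTF-8 with a header row and ``NA`` for
missing values, matching common array / cbioportal export conventions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "read_table", "write_table", "file_sha256", "write_manifest"]

# schema name -> (required columns, numeric columns, unique-key columns or None)
SCHEMAS = {
    "ct": (("mirna_id", "case_id", "timepoint", "ct"), ("ct",),
           ("mirna_id", "case_id", "timepoint")),
    "counts": (("gene_id", "sample_id", "role", "condition", "count"), ("count",),
               ("gene_id", "sample_id")),
    "predictions": (("gene_id", "mirna_id", "algorithm"), (),
                    ("gene_id", "mirna_id", "algorithm")),
    "plate": (("condition", "dose_nM", "bio_rep", "tech_rep", "signal"),
              ("dose_nM", "signal"), None),
    "clonogenic": (("condition", "dose_nM", "seeded", "colonies"),
                   ("dose_nM", "seeded", "colonies"), None),
    "cohort": (("patient_id", "time_months", "event", "expression_z",
                "chemo_treated", "er_status", "her2_status"),
               ("time_months", "event", "expression_z"), ("patient_id",)),
}


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    """Read a pipeline TSV, optionally validating against a named schema."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if schema is not None:
        if schema not in SCHEMAS:
            raise ValueError(f"unknown schema {schema!r}")
        required, numeric, key = SCHEMAS[schema]
        if missing := set(required) - set(df.columns):
            raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
        for col in numeric:
            try:
                df[col] = pd.to_numeric(df[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path.name}: column {col!r} is not numeric") from exc
        if key is not None and df.duplicated(list(key)).any():
            first = df[df.duplicated(list(key))].index[0]
            raise ValueError(f"{path.name}: duplicate key {key} at row {first}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a pipeline TSV (tab-separated, NA for missing, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA", index=False)
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, **entries) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(entries, indent=2, default=str))
    return path
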