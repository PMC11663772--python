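"""CSV / YAML / JSON input-output.

Feature tables are CSV with a mandatory ``subject_id`` first column and
one column per element; the clinical table is CSV with columns
``subject_id, group, hdrs_baseline, hdrs_followup``.  Reports are JSON
with the config and seeds echoed so every number is reproducible from
(config, seed) alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CLINICAL_COLUMNS, Cohort, FeatureSet
from .errors import SchemaError

__all__ = [
    "read_feature_csv",
    "write_feature_csv",
    "read_clinical_csv",
    "write_clinical_csv",
    "read_feature_dir",
    "write_json_report",
    "load_yaml",
]


def read_feature_csv(path, name: str | None = None) -> FeatureSet:
    path = Path(path)
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path.name}: missing column 'subject_id'")
    df = df.set_index("subject_id")
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise SchemaError(f"{path.name}: non-numeric element column {bad[0]!r}")
    return FeatureSet(name or path.stem, df)


def write_feature_csv(fs: FeatureSet, path) -> None:
    fs.data.rename_axis("subject_id").to_csv(path)


def read_clinical_csv(path) -> Cohort:
    path = Path(path)
    df = pd.read_csv(path)
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    return Cohort(df)


def write_clinical_csv(cohort: Cohort, path) -> None:
    cohort.clinical.to_csv(path, index=False)


def read_feature_dir(directory) -> dict:
    """Every ``*.csv`` in a directory as a FeatureSet keyed by stem."""
    directory = Path(directory)
    sets = {}
    for path in sorted(directory.glob("*.csv")):
        if path.stem == "clinical":
            continue
        sets[path.stem] = read_feature_csv(path)
    if not sets:
        raise SchemaError(f"no feature CSVs found in {directory}")
    return sets


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
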