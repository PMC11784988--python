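"""Delimited-text readers and writers for the pipeline's standard tables.

All artefacts are plain text: beta matrices as CSV with sample ids in
the first column and CpG ids in the header (empty cell = missing),
weight tables and reference panels as TSV/CSV, phenotypes as tidy CSV,
and configuration as a YAML key:value hierarchy.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from mpscrp.scoring import MethylationMatrix


def write_beta_matrix(matrix: MethylationMatrix, path) -> None:
    df = matrix.betas.copy()
    df.insert(0, "plate", matrix.plate if matrix.plate is not None else "")
    df.to_csv(path, float_format="%.6g")


def read_beta_matrix(path, array_label: str) -> MethylationMatrix:
    df = pd.read_csv(path, index_col=0)
    plate = None
    if "plate" in df.columns:
        plate = df.pop("plate")
    return MethylationMatrix(df.astype(float), array_label, plate)


def read_reference(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def load_config_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def dump_config_yaml(obj, path) -> None:
    data = asdict(obj) if hasattr(obj, "__dataclass_fields__") else dict(obj)
    clean = {}
    for k, v in data.items():
        if isinstance(v, tuple):
            v = list(v)
        clean[k] = v
    Path(path).write_text(yaml.safe_dump(clean, sort_keys=True))
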