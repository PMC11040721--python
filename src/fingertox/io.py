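"""TSV readers/writers for the pipeline's tables.

All tables share one schema: tab-separated, header row, first column
``chem_id``, remaining columns feature or assay identifiers.  Missing labels
are written as empty cells; both empty strings and the literal ``NaN`` are
accepted on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import PlantedModel

__all__ = [
    "write_table",
    "read_table",
    "read_label_table",
    "write_records",
    "read_records",
    "write_planted_model",
    "read_planted_model",
]


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = "chem_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="chem_id")


def read_label_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", index_col="chem_id", na_values=["", "NaN"], keep_default_na=True
    )
    return table.astype(float)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Raw (possibly duplicated) label records; chem_id is a plain column."""
    records.to_csv(path, sep="\t", index=False, na_rep="")


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["", "NaN"], keep_default_na=True)


def write_planted_model(model: PlantedModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def read_planted_model(path: str | Path) -> PlantedModel:
    return PlantedModel.from_dict(json.loads(Path(path).read_text()))
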