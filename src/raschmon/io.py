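"""CSV readers and writers for the pipeline's tabular artifacts.

All files are UTF-8 CSV with a header row and '.' decimal separator. Response
files are wide format: first column ``respondent_id``, remaining columns one
per item (V-prefixed codes by convention), cells strictly 0 or 1 with no
blanks — duplicated ids, missing cells and non-binary values are distinct
hard errors that name the offending row/column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import ItemParameters, PersonParameters, ResponseMatrix
from .errors import (
    DuplicateRespondentError,
    MissingValueError,
    NonBinaryValueError,
    ResponseFormatError,
)
from .prioritization import BurdenTable

__all__ = [
    "read_response_csv",
    "write_response_csv",
    "read_burden_csv",
    "write_burden_csv",
    "read_worker_centre_map",
    "write_item_parameters_csv",
    "write_person_parameters_csv",
]


def read_response_csv(path) -> ResponseMatrix:
    """Read and validate a wide-format binary response file."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if df.shape[1] < 3:
        raise ResponseFormatError(
            f"{path.name}: need a respondent-id column plus at least 2 item columns"
        )
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    dup = ids[ids.duplicated()].unique()
    if dup.size:
        raise DuplicateRespondentError(
            f"{path.name}: duplicate respondent id(s): {', '.join(dup)}"
        )
    items = list(df.columns[1:])
    cells = df[items]
    na = cells.isna()
    if na.to_numpy().any():
        row, col = next(zip(*np.nonzero(na.to_numpy())))
        raise MissingValueError(
            f"{path.name}: missing value at respondent {ids.iloc[row]!r}, "
            f"item {items[col]!r}"
        )
    valid = cells.isin(["0", "1"])
    if not valid.to_numpy().all():
        row, col = next(zip(*np.nonzero(~valid.to_numpy())))
        raise NonBinaryValueError(
            f"{path.name}: non-binary value {cells.iat[row, col]!r} at respondent "
            f"{ids.iloc[row]!r}, item {items[col]!r}"
        )
    return ResponseMatrix(ids.tolist(), items, cells.astype(int).to_numpy())


def write_response_csv(matrix: ResponseMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, index=False)


def read_burden_csv(path, mam_weight: float = 0.5) -> BurdenTable:
    """Read a centre burden file (columns centre_id, sam, mam)."""
    df = pd.read_csv(path, dtype={"centre_id": str})
    missing = {"centre_id", "sam", "mam"} - set(df.columns)
    if missing:
        raise ResponseFormatError(
            f"{Path(path).name}: missing column(s): {', '.join(sorted(missing))}"
        )
    return BurdenTable.from_dataframe(df, mam_weight=mam_weight)


def write_burden_csv(burden: BurdenTable, path) -> None:
    burden.to_dataframe().to_csv(path, index=False)


def read_worker_centre_map(path) -> pd.Series:
    """Read a worker-to-centre mapping (columns respondent_id, centre_id)."""
    df = pd.read_csv(path, dtype=str)
    missing = {"respondent_id", "centre_id"} - set(df.columns)
    if missing:
        raise ResponseFormatError(
            f"{Path(path).name}: missing column(s): {', '.join(sorted(missing))}"
        )
    dup = df["respondent_id"][df["respondent_id"].duplicated()].unique()
    if dup.size:
        raise DuplicateRespondentError(
            f"{Path(path).name}: duplicate respondent id(s): {', '.join(dup)}"
        )
    return df.set_index("respondent_id")["centre_id"]


def write_item_parameters_csv(items: ItemParameters, path) -> None:
    df = items.to_dataframe()
    df["normalization"] = items.normalization
    df["conditional_loglik"] = items.conditional_loglik
    df.to_csv(path, index=False)


def write_person_parameters_csv(persons: PersonParameters, path) -> None:
    persons.assignments.to_csv(path, index=False)
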