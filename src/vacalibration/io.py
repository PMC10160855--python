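"""CSV readers and writers for records, matrices and CSMF summaries.

All files are RFC-4180 CSV with a header row, UTF-8.  Record files use one
column per (algorithm, cause) pair named ``<algorithm>__<cause>`` plus a
``<algorithm>__inconclusive`` flag column; paired files additionally carry
``underlying``, ``immediate`` and ``site``.  Numeric round-trips are exact
to 1e-12 (values are printed with 17 significant digits).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CauseList,
    CompositionError,
    PairedRecord,
    SurveyRecord,
    as_composition,
    as_misclass_matrix,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"
_SEP = "__"


def _algo_columns(columns, cause_list: CauseList):
    """Infer algorithm names from ``<algo>__<cause>`` header columns."""
    algos: dict[str, set[str]] = {}
    for col in columns:
        if _SEP not in col:
            continue
        algo, _, tail = col.partition(_SEP)
        if tail == "inconclusive":
            algos.setdefault(algo, set())
        elif tail in cause_list.causes:
            algos.setdefault(algo, set()).add(tail)
        else:
            raise ValueError(f"unknown cause label in column {col!r}")
    for algo, seen in algos.items():
        missing = set(cause_list.causes) - seen
        if missing:
            raise ValueError(
                f"algorithm {algo!r} missing required column(s) for "
                f"cause(s) {sorted(missing)}"
            )
    return sorted(algos)


def _row_va(row, algo: str, cause_list: CauseList):
    flag_col = f"{algo}{_SEP}inconclusive"
    inconclusive = bool(row[flag_col]) if flag_col in row.index else False
    if inconclusive:
        return None, True
    scores = np.array(
        [float(row[f"{algo}{_SEP}{c}"]) for c in cause_list.causes]
    )
    if np.any(scores < 0):
        raise CompositionError(f"negative score for algorithm {algo!r}")
    return as_composition(scores), False


def read_records(path, cause_list: CauseList, schema: str,
                 ) -> list[PairedRecord] | list[SurveyRecord]:
    """Read a paired- or survey-record CSV, validating every invariant."""
    from .preprocess import encode_mits

    if schema not in ("paired", "survey"):
        raise ValueError(f"schema must be 'paired' or 'survey', got {schema!r}")
    df = pd.read_csv(path, dtype={"id": str})
    algos = _algo_columns(df.columns, cause_list)
    if schema == "paired":
        for col in ("id", "underlying"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
    elif "id" not in df.columns:
        raise ValueError("missing required column 'id'")

    records = []
    for _, row in df.iterrows():
        va, flags = {}, {}
        for algo in algos:
            y, inc = _row_va(row, algo, cause_list)
            va[algo] = y
            flags[algo] = inc
        if schema == "survey":
            rec = SurveyRecord(id=row["id"], va=va, inconclusive=flags)
        else:
            underlying = row["underlying"]
            immediate = row.get("immediate")
            if pd.isna(immediate):
                immediate = None
            x = encode_mits(underlying, immediate, cause_list)
            rec = PairedRecord(
                id=row["id"],
                underlying=underlying,
                immediate=immediate,
                x=x,
                va=va,
                inconclusive=flags,
                site=str(row.get("site", "main")),
            )
        rec.validate(cause_list)
        records.append(rec)
    return records


def write_records(records, cause_list: CauseList, path) -> None:
    rows = []
    for rec in records:
        row: dict = {"id": rec.id}
        if isinstance(rec, PairedRecord):
            row["underlying"] = rec.underlying
            row["immediate"] = rec.immediate if rec.immediate is not None else ""
            row["site"] = rec.site
        for algo in sorted(rec.va):
            inc = rec.inconclusive.get(algo, False)
            row[f"{algo}{_SEP}inconclusive"] = int(inc)
            y = rec.va[algo]
            for j, c in enumerate(cause_list.causes):
                row[f"{algo}{_SEP}{c}"] = "" if y is None else repr(float(y[j]))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_matrix(m, cause_list: CauseList, path) -> None:
    """Write a row-stochastic matrix; raises on invariant violations."""
    m = as_misclass_matrix(m)
    df = pd.DataFrame(m, index=list(cause_list.causes),
                      columns=list(cause_list.causes))
    df.index.name = "cause"
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_matrix(path, cause_list: CauseList) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(cause_list.causes) or \
            list(df.columns) != list(cause_list.causes):
        raise ValueError("matrix row/column labels do not match the cause list")
    return as_misclass_matrix(df.to_numpy())


def write_csmf(summary: pd.DataFrame, path) -> None:
    """Write a CSMF summary table (cause + numeric columns)."""
    if "cause" not in summary.columns:
        raise ValueError("CSMF summary must have a 'cause' column")
    summary.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_csmf(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
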