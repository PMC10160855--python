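"""Packaged reference tables from the Mozambique child/neonate VA study.

``table1``/``table2`` hold the raw multi-cause aggregate VA scores (and the
percentages as printed) for the 1,841 child and 818 neonatal survey deaths;
``table3``/``table4`` hold the reference-standard underlying-by-immediate
cause contingency tables for the 426 child and 340 neonatal MITS deaths
(the neonate table already excludes the 274 South Africa deaths).  Values
are stored exactly as printed, never re-derived.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .types import (
    AggregateScoreTable,
    CauseList,
    ContingencyTable,
    children_causes,
    neonates_causes,
)

_STRATUM = {
    "table1": "children",
    "table2": "neonates",
    "table3": "children",
    "table4": "neonates",
}


def fixture_cause_list(name: str) -> CauseList:
    if _STRATUM[name] == "children":
        return children_causes()
    return neonates_causes()


def load_fixture(name: str) -> AggregateScoreTable | ContingencyTable:
    """Load one of the packaged tables ("table1" .. "table4")."""
    if name not in _STRATUM:
        raise KeyError(f"unknown fixture name: {name!r}")
    cause_list = fixture_cause_list(name)
    with resources.files("vacalibration.data").joinpath(f"{name}.csv").open() as fh:
        df = pd.read_csv(fh)
    causes = list(cause_list.causes)
    if name in ("table1", "table2"):
        n = int(df["n"].iloc[0])
        scores, pct = {}, {}
        for algo, sub in df.groupby("algorithm"):
            sub = sub.set_index("quantity")
            scores[algo] = sub.loc["score", causes].to_numpy(dtype=float)
            pct[algo] = sub.loc["pct", causes].to_numpy(dtype=float)
        return AggregateScoreTable(cause_list, n, scores, pct)
    counts = df.set_index("underlying").loc[causes, causes].to_numpy(dtype=int)
    return ContingencyTable(cause_list, np.asarray(counts))
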