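"""Data adjustments applied before misclassification estimation and
calibration.

Covers: the {1, 0.5, 0} encoding of up-to-two reference causes (underlying
and immediate), the plurality rule collapsing a score vector to one cause,
construction of the two-pass rank-based multi-cause output, imputation of
inconclusive records (survey side: mean of conclusive scores; paired side:
the single-cause misclassification row of the death's underlying cause),
site exclusion, cause grouping, and raw-CSMF aggregation.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .types import CauseList, PairedRecord, SurveyRecord

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    eava_weight: float = 0.75
    exclude_sites: list[str] = field(default_factory=list)
    tie_break: str = "lowest-index"
    grouping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.5 < self.eava_weight <= 1.0:
            raise ValueError("eava_weight must lie in (0.5, 1]")
        if self.tie_break != "lowest-index":
            raise ValueError(f"unsupported tie_break: {self.tie_break!r}")


def encode_mits(underlying: str, immediate: str | None,
                cause_list: CauseList) -> np.ndarray:
    """{1, 0.5, 0} encoding of the reference causes.

    A missing immediate cause, or one equal to the underlying cause, leaves
    a single-cause (one-hot) encoding; two distinct causes get 0.5 each.
    """
    C = len(cause_list)
    x = np.zeros(C)
    i = cause_list.index(underlying)
    if immediate is None or immediate == underlying:
        x[i] = 1.0
    else:
        x[i] = 0.5
        x[cause_list.index(immediate)] = 0.5
    return x


def plurality_rule(y: np.ndarray, tie_break: str = "lowest-index") -> int:
    """Index of the maximal score; ties break to the lowest cause index."""
    if tie_break != "lowest-index":
        raise ValueError(f"unsupported tie_break: {tie_break!r}")
    return int(np.argmax(y))


def eava_multicause(first: str, second: str, w: float,
                    cause_list: CauseList) -> np.ndarray:
    """Two-pass rank-based multi-cause output: weight ``w`` on the top
    cause, ``1 - w`` on the runner-up, zero elsewhere."""
    if first == second:
        raise ValueError("first and second cause must differ")
    if not 0.5 < w <= 1.0:
        raise ValueError("weight must lie in (0.5, 1]")
    y = np.zeros(len(cause_list))
    y[cause_list.index(first)] = w
    y[cause_list.index(second)] = 1.0 - w
    return y


def impute_survey_inconclusive(records: list[SurveyRecord],
                               algorithm: str) -> list[SurveyRecord]:
    """Replace inconclusive survey scores with the element-wise mean of the
    conclusive scores for that algorithm.  Imputation flags are retained."""
    conclusive = [r.va[algorithm] for r in records
                  if not r.inconclusive.get(algorithm, False)]
    has_inconclusive = any(r.inconclusive.get(algorithm, False) for r in records)
    if has_inconclusive and not conclusive:
        raise ValueError(
            f"no conclusive records for algorithm {algorithm!r}; cannot impute"
        )
    if not has_inconclusive:
        return records
    mean_y = np.mean(np.stack(conclusive), axis=0)
    mean_y = mean_y / mean_y.sum()
    out = []
    for r in records:
        if r.inconclusive.get(algorithm, False):
            r = copy.deepcopy(r)
            r.va[algorithm] = mean_y.copy()
            r.imputed[algorithm] = True
        out.append(r)
    return out


def singlecause_rows(records: list[PairedRecord], algorithm: str,
                     cause_list: CauseList) -> dict[str, np.ndarray]:
    """Average conclusive VA scores per *underlying* cause (the single-cause
    misclassification rows, with the reference treated as one-hot)."""
    rows: dict[str, list[np.ndarray]] = {}
    for r in records:
        if not r.inconclusive.get(algorithm, False):
            rows.setdefault(r.underlying, []).append(r.va[algorithm])
    return {
        cause: np.mean(np.stack(ys), axis=0) for cause, ys in rows.items()
    }


def impute_paired_inconclusive(records: list[PairedRecord], algorithm: str,
                               cause_list: CauseList,
                               m_single: dict[str, np.ndarray] | None = None,
                               ) -> list[PairedRecord]:
    """Impute inconclusive paired records with the single-cause
    misclassification row of their underlying reference cause.

    ``m_single`` maps underlying cause -> mean conclusive VA composition;
    when omitted it is computed from the conclusive records in ``records``.
    Single pass: the imputed records then enter the multi-cause estimator
    once, with no iteration.
    """
    if m_single is None:
        m_single = singlecause_rows(records, algorithm, cause_list)
    out = []
    for r in records:
        if r.inconclusive.get(algorithm, False):
            if r.underlying not in m_single:
                raise ValueError(
                    f"no conclusive data for underlying cause "
                    f"{r.underlying!r}; cannot impute record {r.id}"
                )
            r = copy.deepcopy(r)
            row = m_single[r.underlying]
            r.va[algorithm] = np.asarray(row, dtype=float) / np.sum(row)
            r.imputed[algorithm] = True
        out.append(r)
    return out


def exclude_sites(records: list[PairedRecord],
                  labels: list[str]) -> list[PairedRecord]:
    """Drop records whose site is in ``labels``; logs the removal count."""
    kept = [r for r in records if r.site not in set(labels)]
    removed = len(records) - len(kept)
    if removed:
        logger.info("excluded %d record(s) from site(s) %s", removed, labels)
    return kept


def raw_csmf(records, algorithm: str) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate scores (element-wise sum of y) and the raw CSMF q.

    All records must be conclusive or already imputed for ``algorithm``.
    """
    if not records:
        raise ValueError("no records to aggregate")
    ys = []
    for r in records:
        y = r.va[algorithm]
        if y is None:
            raise ValueError(
                f"record {r.id} has no usable score for {algorithm!r} "
                "(impute inconclusive records first)"
            )
        ys.append(y)
    aggregate = np.sum(np.stack(ys), axis=0)
    return aggregate, aggregate / len(ys)


def group_composition(y: np.ndarray, fine_causes: list[str],
                      cause_list: CauseList) -> np.ndarray:
    """Collapse a fine-cause composition onto the canonical cause list by
    summing scores within groups (mass-preserving)."""
    out = np.zeros(len(cause_list))
    for score, fine in zip(np.asarray(y, dtype=float), fine_causes):
        out[cause_list.index(cause_list.group_of(fine))] += score
    return out


def group_records(records, fine_causes: list[str], cause_list: CauseList):
    """Apply cause grouping to every record (before all other steps)."""
    out = []
    for r in records:
        r = copy.deepcopy(r)
        for algo, y in r.va.items():
            if y is not None:
                r.va[algo] = group_composition(y, fine_causes, cause_list)
        if isinstance(r, PairedRecord):
            r.underlying = cause_list.group_of(r.underlying)
            if r.immediate is not None:
                r.immediate = cause_list.group_of(r.immediate)
            r.x = encode_mits(r.underlying, r.immediate, cause_list)
        out.append(r)
    return out


def contingency_to_paired(table) -> list[PairedRecord]:
    """Expand an underlying-by-immediate contingency table into one
    x-only paired record per counted death."""
    cause_list = table.cause_list
    records = []
    k = 0
    for i, underlying in enumerate(cause_list.causes):
        for j, immediate in enumerate(cause_list.causes):
            for _ in range(int(table.counts[i, j])):
                records.append(PairedRecord(
                    id=f"ct-{k}",
                    underlying=underlying,
                    immediate=immediate,
                    x=encode_mits(underlying, immediate, cause_list),
                    va={},
                    inconclusive={},
                ))
                k += 1
    return records
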