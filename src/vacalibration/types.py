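"""Core domain types for verbal-autopsy calibration.

The analysis manipulates three kinds of simplex-valued objects: per-death
cause compositions (VA algorithm output ``y``, reference-standard MITS
encoding ``x``), population cause-specific mortality fractions (``p`` true,
``q`` raw/apparent), and row-stochastic misclassification matrices ``M``
whose (i, j) entry is the average score a VA algorithm assigns to cause j
for deaths whose reference cause is i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPOSITION_TOL = 1e-8
#: compositions whose sum deviates from 1 by at most this much are
#: renormalized on ingest; larger deviations are data errors
RENORM_TOL = 1e-6

CHILD_CAUSES = (
    "malaria",
    "pneumonia",
    "diarrhea",
    "severe malnutrition",
    "HIV",
    "other",
    "other infections",
)

NEONATE_CAUSES = (
    "congenital malformation",
    "infection",
    "IPRE",
    "other",
    "prematurity",
)


class CompositionError(ValueError):
    """A vector violates the nonnegative / sums-to-one contract."""


@dataclass(frozen=True)
class CauseList:
    """Ordered cause vocabulary for one age stratum.

    ``grouping`` maps fine cause labels onto the canonical (grouped) labels;
    every group label must itself be a member of ``causes``.  The canonical
    orders are fixed to the raw-CSMF table orders so that every matrix and
    vector in the pipeline shares one index.
    """

    stratum: str
    causes: tuple[str, ...]
    grouping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.causes)) != len(self.causes):
            raise ValueError("duplicate cause labels")
        if self.stratum == "children" and self.causes != CHILD_CAUSES:
            raise ValueError(
                "children stratum must use the canonical 7-cause order"
            )
        if self.stratum == "neonates" and self.causes != NEONATE_CAUSES:
            raise ValueError(
                "neonates stratum must use the canonical 5-cause order"
            )
        for fine, group in self.grouping.items():
            if group not in self.causes:
                raise ValueError(
                    f"group label {group!r} (for {fine!r}) not in cause list"
                )

    def __len__(self) -> int:
        return len(self.causes)

    def index(self, cause: str) -> int:
        try:
            return self.causes.index(cause)
        except ValueError:
            raise KeyError(f"unknown cause label: {cause!r}") from None

    def group_of(self, fine: str) -> str:
        """Canonical label for a fine cause (identity if already canonical)."""
        if fine in self.grouping:
            return self.grouping[fine]
        if fine in self.causes:
            return fine
        raise KeyError(f"cause label {fine!r} neither canonical nor grouped")


def children_causes(grouping: dict[str, str] | None = None) -> CauseList:
    return CauseList("children", CHILD_CAUSES, grouping or {})


def neonates_causes(grouping: dict[str, str] | None = None) -> CauseList:
    return CauseList("neonates", NEONATE_CAUSES, grouping or {})


def as_composition(values, *, renorm_tol: float = RENORM_TOL) -> np.ndarray:
    """Validate a score vector and return it as a simplex ndarray.

    Entries must be nonnegative and sum to 1; sums off by at most
    ``renorm_tol`` (CSV rounding) are silently renormalized, larger
    deviations raise :class:`CompositionError`.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise CompositionError(f"composition must be 1-D, got shape {arr.shape}")
    if np.any(arr < 0):
        raise CompositionError(f"negative score in composition: {arr}")
    total = arr.sum()
    if not np.isfinite(total) or abs(total - 1.0) > renorm_tol:
        raise CompositionError(
            f"composition sums to {total!r}, outside 1 ± {renorm_tol}"
        )
    if total != 1.0:
        arr = arr / total
    return arr


def is_composition(arr: np.ndarray, tol: float = COMPOSITION_TOL) -> bool:
    arr = np.asarray(arr, dtype=float)
    return bool(
        arr.ndim == 1 and np.all(arr >= 0) and abs(arr.sum() - 1.0) <= tol
    )


def as_misclass_matrix(values, *, tol: float = COMPOSITION_TOL) -> np.ndarray:
    """Validate a row-stochastic C x C matrix (rows: reference cause,
    columns: VA cause)."""
    m = np.asarray(values, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"misclassification matrix must be square, got {m.shape}")
    if np.any(m < 0):
        raise ValueError("misclassification matrix has negative entries")
    rowsums = m.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > tol):
        raise ValueError(f"rows must sum to 1 (got sums {rowsums})")
    return m


@dataclass
class PairedRecord:
    """One death in the calibration (MITS-paired) set.

    ``x`` is the {1, 0.5, 0} encoding of the underlying/immediate reference
    causes; ``va`` maps algorithm name to its score composition (None while
    the algorithm is inconclusive and not yet imputed).
    """

    id: str
    underlying: str
    immediate: str | None
    x: np.ndarray
    va: dict[str, np.ndarray | None]
    inconclusive: dict[str, bool]
    site: str = "main"
    imputed: dict[str, bool] = field(default_factory=dict)

    def validate(self, cause_list: CauseList) -> None:
        C = len(cause_list)
        cause_list.index(self.underlying)
        if self.immediate is not None:
            cause_list.index(self.immediate)
        if self.x.shape != (C,):
            raise ValueError(f"x has shape {self.x.shape}, expected ({C},)")
        nz = self.x[self.x > 0]
        if not (
            (len(nz) == 1 and np.isclose(nz[0], 1.0))
            or (len(nz) == 2 and np.allclose(nz, 0.5))
        ):
            raise ValueError(f"x entries must be one 1 or two 0.5s, got {self.x}")
        for algo, flag in self.inconclusive.items():
            y = self.va.get(algo)
            if not flag:
                if y is None or not is_composition(y):
                    raise ValueError(
                        f"conclusive record {self.id}: invalid composition "
                        f"for algorithm {algo!r}"
                    )


@dataclass
class SurveyRecord:
    """One death in the survey (VA-only) set."""

    id: str
    va: dict[str, np.ndarray | None]
    inconclusive: dict[str, bool]
    imputed: dict[str, bool] = field(default_factory=dict)

    def validate(self, cause_list: CauseList) -> None:
        C = len(cause_list)
        for algo, flag in self.inconclusive.items():
            y = self.va.get(algo)
            if not flag:
                if y is None or y.shape != (C,) or not is_composition(y):
                    raise ValueError(
                        f"conclusive record {self.id}: invalid composition "
                        f"for algorithm {algo!r}"
                    )


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of reference-standard underlying (rows) by immediate (columns)
    causes of death."""

    cause_list: CauseList
    counts: np.ndarray

    def __post_init__(self) -> None:
        C = len(self.cause_list)
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (C, C):
            raise ValueError(f"counts must be {C}x{C}, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AggregateScoreTable:
    """Per-algorithm aggregate VA scores (column sums of per-death
    compositions) over a cohort of ``n`` deaths, as printed in raw-CSMF
    tables, optionally with the percentages as printed."""

    cause_list: CauseList
    n: int
    scores: dict[str, np.ndarray]
    printed_pct: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for algo, s in self.scores.items():
            s = np.asarray(s, dtype=float)
            if abs(s.sum() - self.n) > 0.5:
                raise ValueError(
                    f"{algo}: aggregate scores sum to {s.sum()}, "
                    f"expected {self.n} ± 0.5"
                )

    def csmf(self, algorithm: str) -> np.ndarray:
        """Raw cause-specific mortality fractions q = scores / n."""
        return np.asarray(self.scores[algorithm], dtype=float) / self.n
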