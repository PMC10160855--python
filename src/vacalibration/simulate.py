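"""Synthetic calibration- and survey-population generators.

The generator emulates the statistical structure the calibration assumes:
distinct CSMFs in the calibration (MITS-paired) and survey populations, an
underlying-to-immediate cause transition kernel, a probabilistic VA
algorithm whose score vector is Dirichlet noise centered on the relevant
misclassification row, a rank-based algorithm emitting weight/(1-weight)
two-cause output, a stated fraction of inconclusive rank-algorithm records,
and a site flag for exclusion.  Defaults for the two age-stratum presets
mirror the study cohort sizes (426/1,841 children, 614/818 neonates with a
274/614 site-exclusion rate) and the published contingency-table profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .preprocess import encode_mits
from .types import (
    CauseList,
    PairedRecord,
    SurveyRecord,
    as_composition,
    as_misclass_matrix,
    children_causes,
    neonates_causes,
)

PROBABILISTIC = "probabilistic"
RANK = "rank"


@dataclass
class SimConfig:
    """Truth and sampling plan for one synthetic study."""

    C: int
    n_paired: int
    n_survey: int
    p_survey: np.ndarray
    p_calib_underlying: np.ndarray
    immediate_kernel: np.ndarray
    M_true: dict[str, np.ndarray]
    algo_kind: dict[str, str] = field(default_factory=dict)
    concentration: float = 20.0
    eava_weight: float = 0.75
    p_inconclusive: float = 0.0
    p_site_excluded: float = 0.0
    seed: int = 0
    cause_list: CauseList | None = None

    def __post_init__(self) -> None:
        if self.C < 2:
            raise ValueError("need at least 2 causes")
        self.p_survey = as_composition(self.p_survey)
        self.p_calib_underlying = as_composition(self.p_calib_underlying)
        self.immediate_kernel = as_misclass_matrix(self.immediate_kernel)
        self.M_true = {a: as_misclass_matrix(m) for a, m in self.M_true.items()}
        for a, m in self.M_true.items():
            if np.any(m.sum(axis=1) == 0):
                raise ValueError(f"degenerate all-zero row in M_true[{a!r}]")
        for a in self.M_true:
            self.algo_kind.setdefault(
                a, RANK if a.startswith("eava") else PROBABILISTIC)
        if not 0.5 < self.eava_weight <= 1.0:
            raise ValueError("eava_weight must lie in (0.5, 1]")
        if not 0.0 <= self.p_inconclusive < 1.0:
            raise ValueError("p_inconclusive must lie in [0, 1)")
        if not 0.0 <= self.p_site_excluded < 1.0:
            raise ValueError("p_site_excluded must lie in [0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    @property
    def causes(self) -> list[str]:
        if self.cause_list is not None:
            return list(self.cause_list.causes)
        return [f"cause_{j + 1}" for j in range(self.C)]

    def to_json(self) -> str:
        return json.dumps({
            "C": self.C, "n_paired": self.n_paired, "n_survey": self.n_survey,
            "p_survey": self.p_survey.tolist(),
            "p_calib_underlying": self.p_calib_underlying.tolist(),
            "immediate_kernel": self.immediate_kernel.tolist(),
            "M_true": {a: m.tolist() for a, m in self.M_true.items()},
            "algo_kind": self.algo_kind,
            "concentration": self.concentration,
            "eava_weight": self.eava_weight,
            "p_inconclusive": self.p_inconclusive,
            "p_site_excluded": self.p_site_excluded,
            "seed": self.seed,
        }, indent=1)


def _dirichlet_centered(rng, mean: np.ndarray, concentration: float,
                        ) -> np.ndarray:
    """Mean-preserving Dirichlet draw; zero-mean components stay exactly 0
    (a gamma with shape 0 is a point mass at 0)."""
    alpha = concentration * mean
    g = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
    total = g.sum()
    if total == 0:  # pathological tiny concentration; fall back to the mean
        return mean.copy()
    return g / total


def _rank_output(rng, row: np.ndarray, w: float, C: int) -> np.ndarray:
    """Rank-style two-cause output with top weight ``w``.

    Top cause and runner-up are drawn independently from the row; a
    collision yields a single-cause output.  This keeps the construction
    mean-preserving — E[y | z] = w*row + (1-w)*row = row — so the empirical
    misclassification of the rank algorithm converges to its true matrix.
    """
    first = rng.choice(C, p=row)
    second = rng.choice(C, p=row)
    y = np.zeros(C)
    if first == second or w == 1.0:
        y[first] = 1.0
    else:
        y[first] = w
        y[second] = 1.0 - w
    return y


def _draw_va(rng, cfg: SimConfig, z: int):
    """Per-algorithm VA output and inconclusive flags for latent cause z."""
    va: dict[str, np.ndarray | None] = {}
    inconclusive: dict[str, bool] = {}
    for a, m in cfg.M_true.items():
        kind = cfg.algo_kind[a]
        if kind == RANK and rng.uniform() < cfg.p_inconclusive:
            va[a] = None
            inconclusive[a] = True
            continue
        inconclusive[a] = False
        row = m[z]
        if kind == PROBABILISTIC:
            va[a] = _dirichlet_centered(rng, row, cfg.concentration)
        else:
            va[a] = _rank_output(rng, row, cfg.eava_weight, cfg.C)
    return va, inconclusive


def gen_paired(cfg: SimConfig) -> list[PairedRecord]:
    """Calibration-population records: reference causes plus VA output.

    underlying ~ p_calib_underlying, immediate ~ kernel row, x per the
    {1, 0.5, 0} encoding; the latent class z behind the VA output is drawn
    from x (a 0.5/0.5 encoding is a 50:50 mixture of the two causes).
    """
    rng = np.random.default_rng(cfg.seed)
    causes = cfg.causes
    cl = cfg.cause_list or CauseList("synthetic", tuple(causes))
    records = []
    for k in range(cfg.n_paired):
        u = int(rng.choice(cfg.C, p=cfg.p_calib_underlying))
        imm = int(rng.choice(cfg.C, p=cfg.immediate_kernel[u]))
        x = encode_mits(causes[u], causes[imm], cl)
        z = int(rng.choice(cfg.C, p=x))
        va, inconclusive = _draw_va(rng, cfg, z)
        site = "excluded" if rng.uniform() < cfg.p_site_excluded else "main"
        records.append(PairedRecord(
            id=f"paired-{k}", underlying=causes[u],
            immediate=None if imm == u else causes[imm],
            x=x, va=va, inconclusive=inconclusive, site=site,
        ))
    return records


def gen_survey(cfg: SimConfig) -> list[SurveyRecord]:
    """Survey-population records: VA output only, cause ~ p_survey."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    records = []
    for k in range(cfg.n_survey):
        z = int(rng.choice(cfg.C, p=cfg.p_survey))
        va, inconclusive = _draw_va(rng, cfg, z)
        records.append(SurveyRecord(
            id=f"survey-{k}", va=va, inconclusive=inconclusive,
        ))
    return records


@dataclass
class RecoveryReport:
    """End-to-end recovery of the truth on one synthetic dataset."""

    p_true: np.ndarray
    p_est: np.ndarray
    p_lower: np.ndarray
    p_upper: np.ndarray
    p_abs_error: np.ndarray
    csmf_accuracy: float
    covered: np.ndarray  # per-cause: true p inside the credible interval
    m_true: dict[str, np.ndarray]
    m_est: dict[str, np.ndarray]
    m_max_abs_error: dict[str, float]
    draws: object = None


def recovery_harness(cfg: SimConfig, gb_cfg=None, algorithms=None,
                     level: float = 0.95, pointwise: bool = False,
                     ) -> RecoveryReport:
    """Generate data, run preprocess -> M fit -> calibration, and report
    recovery of the true CSMF and misclassification matrices."""
    from .calibration import GBConfig, sample_posterior, summarize_posterior
    from .misclassification import fit_multicause_M
    from .model_eval import csmfa
    from .preprocess import (
        exclude_sites,
        impute_paired_inconclusive,
        impute_survey_inconclusive,
    )

    if gb_cfg is None:
        gb_cfg = GBConfig(n_chains=2, n_iter=2000, n_burn=1000, seed=cfg.seed)
    algorithms = list(algorithms or cfg.M_true)
    cl = cfg.cause_list or CauseList("synthetic", tuple(cfg.causes))

    paired = exclude_sites(gen_paired(cfg), ["excluded"])
    survey = gen_survey(cfg)
    for a in algorithms:
        if cfg.algo_kind[a] == RANK:
            paired = impute_paired_inconclusive(paired, a, cl)
            survey = impute_survey_inconclusive(survey, a)

    m_init = {}
    for a in algorithms:
        xs = np.stack([r.x for r in paired])
        ys = np.stack([r.va[a] for r in paired])
        m_init[a] = fit_multicause_M(xs, ys, cause_labels=cfg.causes).m

    draws = sample_posterior(paired, survey, gb_cfg, algorithms,
                             cause_labels=cfg.causes, m_init=m_init,
                             pointwise=pointwise)
    summ = summarize_posterior(draws, level=level)["p"]
    p_est = summ["mean"].to_numpy()
    lower = summ["lower"].to_numpy()
    upper = summ["upper"].to_numpy()
    m_est = {a: draws.m_draws(a).mean(axis=0) for a in algorithms}
    return RecoveryReport(
        p_true=cfg.p_survey,
        p_est=p_est,
        p_lower=lower,
        p_upper=upper,
        p_abs_error=np.abs(p_est - cfg.p_survey),
        csmf_accuracy=csmfa(p_est, cfg.p_survey),
        covered=(lower <= cfg.p_survey) & (cfg.p_survey <= upper),
        m_true={a: cfg.M_true[a] for a in algorithms},
        m_est=m_est,
        m_max_abs_error={
            a: float(np.max(np.abs(m_est[a] - cfg.M_true[a])))
            for a in algorithms
        },
        draws=draws,
    )


# ---------------------------------------------------------------------------
# stratum presets (study conditions)

def _diag_dominant(C: int, diag: float) -> np.ndarray:
    m = np.full((C, C), (1.0 - diag) / (C - 1))
    np.fill_diagonal(m, diag)
    return m


def children_config(seed: int = 0, **overrides) -> SimConfig:
    """Child-stratum preset: 7 causes, 426 paired / 1,841 survey deaths,
    calibration-population profile from the published contingency table."""
    from .fixtures import load_fixture

    table = load_fixture("table3")
    counts = table.counts.astype(float)
    kw = dict(
        C=7, n_paired=426, n_survey=1841,
        p_survey=np.array([0.20, 0.10, 0.21, 0.05, 0.04, 0.12, 0.28]),
        p_calib_underlying=counts.sum(axis=1) / counts.sum(),
        immediate_kernel=counts / counts.sum(axis=1, keepdims=True),
        M_true={"insilicova": _diag_dominant(7, 0.55),
                "eava": _diag_dominant(7, 0.45)},
        p_inconclusive=0.175,
        seed=seed,
        cause_list=children_causes(),
    )
    kw.update(overrides)
    return SimConfig(**kw)


def neonates_config(seed: int = 0, **overrides) -> SimConfig:
    """Neonate-stratum preset: 5 causes, 614 paired (of which ~274 at an
    excluded site) / 818 survey deaths."""
    from .fixtures import load_fixture

    table = load_fixture("table4")
    counts = table.counts.astype(float)
    kw = dict(
        C=5, n_paired=614, n_survey=818,
        p_survey=np.array([0.04, 0.62, 0.20, 0.04, 0.10]),
        p_calib_underlying=counts.sum(axis=1) / counts.sum(),
        immediate_kernel=counts / counts.sum(axis=1, keepdims=True),
        M_true={"insilicova": _diag_dominant(5, 0.60),
                "eava": _diag_dominant(5, 0.50)},
        p_inconclusive=0.175,
        p_site_excluded=274.0 / 614.0,
        seed=seed,
        cause_list=neonates_causes(),
    )
    kw.update(overrides)
    return SimConfig(**kw)
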