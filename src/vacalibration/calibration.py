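"""Generalized-Bayes calibration of cause-specific mortality fractions.

The population CSMF ``p`` relates to the raw (apparent) CSMF ``q`` of a VA
algorithm through the misclassification matrix: q = M'p.  With multi-cause
(compositional) data a multinomial likelihood is unavailable, so inference
uses a generalized posterior built from the Kullback-Leibler loss,

    posterior(p, {M_a}) ∝ exp[ -sum_a w_a ( L_paired(M_a) + L_survey(M_a, p) ) ]
                           × Dirichlet priors on p and on each M row,

where for algorithm ``a``

    L_paired = - sum_paired  sum_j y_ij log( (M_a' x_i)_j )
    L_survey = - sum_survey  sum_j y_kj log( (M_a' p)_j ).

For one-hot data the loss is the multinomial negative log-likelihood up to
a constant, so the calibration generalizes the single-cause one.  Summing
the losses of several algorithms (equal weights by default) gives the
ensemble calibration.

Sampling is random-walk Metropolis within Gibbs on additive-log-ratio
coordinates of ``p`` and each M row, with per-block proposal scales adapted
during burn-in toward ~25% acceptance and frozen afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .misclassification import EPSILON, fit_multicause_M
from .types import as_composition, as_misclass_matrix

logger = logging.getLogger(__name__)

RHAT_WARN = 1.05


@dataclass
class GBConfig:
    """Configuration of the generalized-Bayes sampler.

    ``prior_p`` / ``prior_m`` are Dirichlet concentration parameters
    (scalars broadcast; default 1 = uniform on the simplex).  The
    ``learning_rate`` tempers the loss inside the exponent and is fixed at
    1 for the published posterior; it is exposed for research use only.
    """

    prior_p: float | np.ndarray = 1.0
    prior_m: float | np.ndarray = 1.0
    n_chains: int = 4
    n_iter: int = 5000
    n_burn: int = 2500
    proposal_scale: float = 0.3
    seed: int = 0
    loss_weights: dict[str, float] = field(default_factory=dict)
    learning_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be < n_iter")
        if np.any(np.asarray(self.prior_p) <= 0) or \
                np.any(np.asarray(self.prior_m) <= 0):
            raise ValueError("Dirichlet concentrations must be positive")
        if self.proposal_scale <= 0:
            raise ValueError("proposal_scale must be positive")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, per-observation losses and diagnostics."""

    p: np.ndarray                    # (chains, kept, C)
    m: dict[str, np.ndarray]         # algo -> (chains, kept, C, C)
    pointwise_loss: np.ndarray | None  # (chains*kept, n_obs)
    diagnostics: dict
    cause_labels: list[str]
    algorithms: list[str]
    n_paired: int = 0
    n_survey: int = 0

    @property
    def p_draws(self) -> np.ndarray:
        return self.p.reshape(-1, self.p.shape[-1])

    def m_draws(self, algorithm: str) -> np.ndarray:
        m = self.m[algorithm]
        return m.reshape(-1, *m.shape[-2:])


# ---------------------------------------------------------------------------
# simplex <-> unconstrained coordinates

def alr(v: np.ndarray) -> np.ndarray:
    return np.log(v[:-1]) - np.log(v[-1])


def alr_inv(z: np.ndarray) -> np.ndarray:
    w = np.concatenate([z, [0.0]])
    w = np.exp(w - w.max())
    v = w / w.sum()
    # exact simplex membership for retained draws
    return v / v.sum()


# ---------------------------------------------------------------------------
# deterministic fixed-M solver

def solve_fixed_M(q, m) -> np.ndarray:
    """Solve q = M'p for p on the simplex, for a known M.

    Uses the exact linear solve when M' is well conditioned and the
    unconstrained solution is feasible; otherwise a simplex-constrained
    least-squares fit.  A numerically singular M raises — run the full
    generalized-Bayes calibration in that case.
    """
    m = as_misclass_matrix(m)
    q = as_composition(q)
    A = m.T
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e10:
        raise np.linalg.LinAlgError(
            "misclassification matrix is numerically singular "
            f"(cond={cond:.2e}); use the generalized-Bayes calibration, "
            "which propagates this uncertainty"
        )
    p = np.linalg.solve(A, q)
    if np.all(p >= -1e-12) and abs(p.sum() - 1.0) < 1e-9:
        p = np.clip(p, 0.0, None)
        return p / p.sum()

    from scipy.optimize import minimize

    C = len(q)
    res = minimize(
        lambda v: 0.5 * np.sum((A @ v - q) ** 2),
        x0=np.full(C, 1.0 / C),
        jac=lambda v: A.T @ (A @ v - q),
        bounds=[(0.0, 1.0)] * C,
        constraints=[{"type": "eq", "fun": lambda v: v.sum() - 1.0,
                      "jac": lambda v: np.ones(C)}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 500},
    )
    p = np.clip(res.x, 0.0, None)
    return p / p.sum()


# ---------------------------------------------------------------------------
# loss evaluation on aggregated sufficient statistics

class _AlgoData:
    """Per-algorithm sufficient statistics for the KL loss.

    Paired records are grouped by their (few) distinct reference encodings
    x, so a loss evaluation costs O(patterns × C) rather than O(n × C).
    """

    def __init__(self, paired_records, survey_records, algorithm: str, C: int):
        xs, ys = [], []
        for r in paired_records:
            y = r.va.get(algorithm)
            if y is None:
                raise ValueError(
                    f"paired record {r.id} lacks scores for {algorithm!r}; "
                    "impute inconclusive records first"
                )
            xs.append(r.x)
            ys.append(y)
        self.X = np.array(xs).reshape(len(xs), C) if xs else np.zeros((0, C))
        self.Y_paired = (np.array(ys).reshape(len(ys), C) if ys
                         else np.zeros((0, C)))

        ys_s = []
        for r in survey_records:
            y = r.va.get(algorithm)
            if y is None:
                raise ValueError(
                    f"survey record {r.id} lacks scores for {algorithm!r}; "
                    "impute inconclusive records first"
                )
            ys_s.append(y)
        self.Y_survey = (np.array(ys_s).reshape(len(ys_s), C) if ys_s
                         else np.zeros((0, C)))
        self.A = self.Y_survey.sum(axis=0)

        # group paired rows by distinct x pattern
        if len(self.X):
            keys = [tuple(np.round(x, 12)) for x in self.X]
            uniq = sorted(set(keys))
            idx = {k: i for i, k in enumerate(uniq)}
            self.Xp = np.array([np.array(k) for k in uniq])
            self.Yp = np.zeros((len(uniq), C))
            for k, y in zip(keys, self.Y_paired):
                self.Yp[idx[k]] += y
        else:
            self.Xp = np.zeros((0, C))
            self.Yp = np.zeros((0, C))

    def paired_loss(self, m: np.ndarray) -> float:
        if not len(self.Xp):
            return 0.0
        pred = np.maximum(self.Xp @ m, 1e-300)
        return float(-np.sum(self.Yp * np.log(pred)))

    def survey_loss(self, m: np.ndarray, p: np.ndarray) -> float:
        if not len(self.A):
            return 0.0
        mp = np.maximum(m.T @ p, 1e-300)
        return float(-self.A @ np.log(mp))


def gb_loss(p, m_by_algo: dict[str, np.ndarray], paired_data, survey_data,
            weights: dict[str, float] | None = None) -> float:
    """Total generalized-Bayes loss for CSMF ``p`` and per-algorithm
    misclassification matrices, summed (or weighted) over algorithms."""
    p = as_composition(p)
    C = len(p)
    total = 0.0
    for algo, m in m_by_algo.items():
        m = np.asarray(m, dtype=float)
        w = 1.0 if weights is None else weights.get(algo, 1.0)
        data = _AlgoData(paired_data, survey_data, algo, C)
        total += w * (data.paired_loss(m) + data.survey_loss(m, p))
    return total


# ---------------------------------------------------------------------------
# sampler

class _Block:
    """One adaptive random-walk Metropolis block on ALR coordinates."""

    def __init__(self, z: np.ndarray, scale: float):
        self.z = z
        self.scale = scale
        self.accepted = 0
        self.attempted = 0
        self._batch_acc = 0
        self._batch_n = 0
        self._n_batches = 0

    def propose(self, rng) -> np.ndarray:
        return self.z + self.scale * rng.standard_normal(len(self.z))

    def record(self, accepted: bool, adapting: bool) -> None:
        self.attempted += 1
        self.accepted += accepted
        if adapting:
            self._batch_acc += accepted
            self._batch_n += 1
            if self._batch_n == 50:
                self._n_batches += 1
                rate = self._batch_acc / self._batch_n
                step = min(0.5, 1.0 / np.sqrt(self._n_batches))
                self.scale *= np.exp(step * (rate - 0.25))
                self._batch_acc = 0
                self._batch_n = 0


def _dirichlet_logmass(v: np.ndarray, alpha) -> float:
    # (alpha - 1) from the prior plus +1 from the ALR Jacobian
    return float(np.sum(np.asarray(alpha) * np.log(np.maximum(v, 1e-300))))


def sample_posterior(paired_data, survey_data, cfg: GBConfig,
                     algorithms: list[str], cause_labels=None,
                     m_init: dict[str, np.ndarray] | None = None,
                     fix_m: dict[str, np.ndarray] | None = None,
                     pointwise: bool = True) -> PosteriorDraws:
    """Draw from the generalized posterior over (p, {M_a}).

    ``fix_m`` pins the misclassification matrices (e.g. the identity for
    the uncalibrated model), in which case only p is sampled.  ``m_init``
    overrides the default initialization at the pseudo-ML fit.
    """
    if not survey_data and not paired_data:
        raise ValueError("no data supplied")
    probe = None
    for r in list(survey_data) + list(paired_data):
        probe = r.va.get(algorithms[0])
        if probe is not None:
            break
    if probe is None:
        raise ValueError(f"no usable scores for algorithm {algorithms[0]!r}")
    C = len(probe)
    if cause_labels is None:
        cause_labels = [f"cause_{j + 1}" for j in range(C)]

    data = {a: _AlgoData(paired_data, survey_data, a, C) for a in algorithms}
    weights = {a: cfg.loss_weights.get(a, 1.0) for a in algorithms}
    alpha_p = np.broadcast_to(np.asarray(cfg.prior_p, dtype=float), (C,))
    alpha_m = np.broadcast_to(np.asarray(cfg.prior_m, dtype=float), (C, C))
    lr = cfg.learning_rate

    sample_m = fix_m is None
    if sample_m:
        if m_init is None:
            m_init = {}
            for a in algorithms:
                d = data[a]
                m_init[a] = fit_multicause_M(
                    d.X, d.Y_paired, cause_labels=cause_labels).m
        m_start = {a: np.clip(np.asarray(m_init[a], dtype=float),
                              EPSILON, None) for a in algorithms}
        m_start = {a: m / m.sum(axis=1, keepdims=True)
                   for a, m in m_start.items()}
    else:
        m_start = {a: np.clip(np.asarray(fix_m[a], dtype=float), EPSILON, None)
                   for a in algorithms}
        m_start = {a: m / m.sum(axis=1, keepdims=True)
                   for a, m in m_start.items()}

    # deterministic start for p: fixed-M solve of the mean raw CSMF
    if any(len(data[a].A) for a in algorithms):
        qbar = np.mean([data[a].A / max(data[a].A.sum(), 1.0)
                        for a in algorithms], axis=0)
        qbar = qbar / qbar.sum()
        mbar = np.mean([m_start[a] for a in algorithms], axis=0)
        try:
            p_start = solve_fixed_M(qbar, mbar)
        except np.linalg.LinAlgError:
            p_start = np.full(C, 1.0 / C)
        p_start = np.clip(p_start, 1e-4, None)
        p_start = p_start / p_start.sum()
    else:
        p_start = np.full(C, 1.0 / C)

    n_kept = cfg.n_iter - cfg.n_burn
    p_out = np.empty((cfg.n_chains, n_kept, C))
    m_out = {a: np.empty((cfg.n_chains, n_kept, C, C)) for a in algorithms}

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    accept_rates = []
    for chain, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        p = p_start.copy()
        M = {a: m_start[a].copy() for a in algorithms}
        pl = {a: data[a].paired_loss(M[a]) for a in algorithms}
        sl = {a: data[a].survey_loss(M[a], p) for a in algorithms}
        if not np.isfinite(sum(pl.values()) + sum(sl.values())):
            raise FloatingPointError("non-finite loss at initialization")

        p_block = _Block(alr(p), cfg.proposal_scale)
        m_blocks = {a: [_Block(alr(M[a][i]), cfg.proposal_scale)
                        for i in range(C)] for a in algorithms} \
            if sample_m else {}

        for it in range(cfg.n_iter):
            adapting = it < cfg.n_burn

            # p block (survey terms only depend on p)
            z_new = p_block.propose(rng)
            p_new = alr_inv(z_new)
            sl_new = {a: data[a].survey_loss(M[a], p_new) for a in algorithms}
            delta = (
                -lr * sum(weights[a] * (sl_new[a] - sl[a]) for a in algorithms)
                + _dirichlet_logmass(p_new, alpha_p)
                - _dirichlet_logmass(p, alpha_p)
            )
            acc = np.log(rng.uniform()) < delta
            if acc:
                p, sl = p_new, sl_new
                p_block.z = z_new
            p_block.record(acc, adapting)

            if sample_m:
                for a in algorithms:
                    for i in range(C):
                        blk = m_blocks[a][i]
                        z_new = blk.propose(rng)
                        row_new = alr_inv(z_new)
                        M_new = M[a].copy()
                        M_new[i] = row_new
                        pl_a = data[a].paired_loss(M_new)
                        sl_a = data[a].survey_loss(M_new, p)
                        delta = (
                            -lr * weights[a] * (pl_a - pl[a] + sl_a - sl[a])
                            + _dirichlet_logmass(row_new, alpha_m[i])
                            - _dirichlet_logmass(M[a][i], alpha_m[i])
                        )
                        acc = np.log(rng.uniform()) < delta
                        if acc:
                            M[a] = M_new
                            pl[a], sl[a] = pl_a, sl_a
                            blk.z = z_new
                        blk.record(acc, adapting)

            if it >= cfg.n_burn:
                k = it - cfg.n_burn
                p_out[chain, k] = p
                for a in algorithms:
                    m_out[a][chain, k] = M[a]

        accept_rates.append(p_block.accepted / max(p_block.attempted, 1))

    diagnostics = _diagnostics(p_out, cause_labels)
    diagnostics["p_accept_rate"] = accept_rates

    pw = None
    if pointwise:
        pw = _pointwise_loss(p_out, m_out, data, algorithms, weights, C)

    return PosteriorDraws(
        p=p_out, m=m_out, pointwise_loss=pw, diagnostics=diagnostics,
        cause_labels=list(cause_labels), algorithms=list(algorithms),
        n_paired=len(paired_data), n_survey=len(survey_data),
    )


def _diagnostics(p_out: np.ndarray, cause_labels) -> dict:
    diagnostics: dict = {"warnings": []}
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            import arviz as az

            idata = az.from_dict(posterior={"p": p_out})
            rhat = az.rhat(idata)["p"].values
            ess = az.ess(idata)["p"].values
        diagnostics["rhat_p"] = rhat
        diagnostics["ess_p"] = ess
        if np.any(rhat > RHAT_WARN):
            bad = [cause_labels[j] for j in np.flatnonzero(rhat > RHAT_WARN)]
            msg = f"split-Rhat > {RHAT_WARN} for p component(s) {bad}"
            diagnostics["warnings"].append(msg)
            logger.warning(msg)
    except Exception as exc:  # diagnostics are advisory, never fatal
        diagnostics["warnings"].append(f"diagnostics unavailable: {exc}")
    return diagnostics


def _pointwise_loss(p_out, m_out, data, algorithms, weights, C) -> np.ndarray:
    """Per-draw, per-record loss contributions (paired records first, then
    survey records), summed over algorithms with their weights."""
    n_chains, n_kept = p_out.shape[:2]
    d0 = data[algorithms[0]]
    n_p, n_s = len(d0.X), len(d0.Y_survey)
    pw = np.zeros((n_chains * n_kept, n_p + n_s))
    k = 0
    for chain in range(n_chains):
        for it in range(n_kept):
            p = p_out[chain, it]
            for a in algorithms:
                d = data[a]
                m = m_out[a][chain, it]
                w = weights[a]
                if n_p:
                    pred = np.maximum(d.X @ m, 1e-300)
                    pw[k, :n_p] += -w * np.sum(
                        d.Y_paired * np.log(pred), axis=1)
                if n_s:
                    mp = np.maximum(m.T @ p, 1e-300)
                    pw[k, n_p:] += -w * (d.Y_survey @ np.log(mp))
            k += 1
    return pw


def summarize_posterior(draws: PosteriorDraws, level: float = 0.95) -> dict:
    """Posterior means and equal-tailed credible intervals for p and for
    each algorithm's misclassification matrix."""
    if draws.p.size == 0:
        raise ValueError("no draws to summarize")
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    pd_ = draws.p_draws
    p_tab = pd.DataFrame({
        "cause": draws.cause_labels,
        "mean": pd_.mean(axis=0),
        "lower": np.quantile(pd_, lo, axis=0),
        "upper": np.quantile(pd_, hi, axis=0),
    })
    m_tabs = {}
    for a in draws.algorithms:
        md = draws.m_draws(a)
        rows = []
        for i, ci in enumerate(draws.cause_labels):
            for j, cj in enumerate(draws.cause_labels):
                rows.append({
                    "true_cause": ci,
                    "va_cause": cj,
                    "mean": md[:, i, j].mean(),
                    "lower": np.quantile(md[:, i, j], lo),
                    "upper": np.quantile(md[:, i, j], hi),
                })
        m_tabs[a] = pd.DataFrame(rows)
    return {"p": p_tab, "M": m_tabs}
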