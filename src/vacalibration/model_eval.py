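"""Model comparison (WAIC) and CSMF accuracy metrics.

WAIC is computed from per-draw, per-observation generalized log-densities.
In the generalized-Bayes setting the pointwise log-density of a record is
the negative of its KL-loss contribution (for one-hot data this is exactly
the multinomial log-likelihood).  The pointwise unit is one death record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .misclassification import EPSILON


@dataclass(frozen=True)
class WaicResult:
    lppd: float
    p_waic: float
    waic: float
    pointwise: np.ndarray  # per-observation waic contributions (-2*(lppd_i - p_i))

    def __post_init__(self) -> None:
        if not np.isclose(self.waic, -2.0 * (self.lppd - self.p_waic)):
            raise ValueError("waic must equal -2*(lppd - p_waic)")


def waic(pointwise_loss: np.ndarray) -> WaicResult:
    """WAIC from a (draws x n_observations) matrix of loss contributions.

    lppd_i = log mean_d exp(-loss_di)  (stabilized log-mean-exp);
    p_waic_i = Var_d(-loss_di); waic = -2 * (lppd - p_waic).
    """
    L = np.asarray(pointwise_loss, dtype=float)
    if L.ndim != 2:
        raise ValueError("pointwise loss must be a draws x n matrix")
    if L.shape[0] < 2:
        raise ValueError("need at least 2 draws to estimate p_waic")
    if not np.all(np.isfinite(L)):
        raise ValueError("non-finite pointwise loss")
    neg = -L
    n_draws = neg.shape[0]
    lppd_i = logsumexp(neg, axis=0) - np.log(n_draws)
    p_i = neg.var(axis=0, ddof=1)
    pointwise = -2.0 * (lppd_i - p_i)
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return WaicResult(lppd=lppd, p_waic=p_waic,
                      waic=-2.0 * (lppd - p_waic), pointwise=pointwise)


def uncalibrated_q_draws(survey_data, algorithm: str, n_draws: int,
                         seed: int = 0, prior: float = 1.0) -> np.ndarray:
    """Posterior draws of q under the no-misclassification model.

    With M fixed at the identity the generalized posterior over p given the
    survey loss is conjugate: Dirichlet(prior + aggregate scores), which for
    one-hot data is the usual Dirichlet-multinomial posterior.
    """
    ys = []
    for r in survey_data:
        y = r.va.get(algorithm)
        if y is None:
            raise ValueError(f"record {r.id} has no scores for {algorithm!r}")
        ys.append(y)
    A = np.sum(np.stack(ys), axis=0)
    rng = np.random.default_rng(seed)
    return rng.dirichlet(prior + A, size=n_draws)


def waic_uncalibrated(survey_data, algorithm: str, draws_of_q: np.ndarray,
                      paired_data=None, epsilon: float = EPSILON,
                      ) -> WaicResult:
    """WAIC of the uncalibrated (identity-misclassification) model.

    Survey records are scored against the drawn q; when ``paired_data`` is
    supplied the paired records are scored against their own reference
    encoding x (the identity-M prediction), epsilon-floored so structural
    zeros stay finite — this puts the comparison with the calibrated model
    on the same set of observations.
    """
    Q = np.atleast_2d(np.asarray(draws_of_q, dtype=float))
    Ys = np.stack([r.va[algorithm] for r in survey_data])
    logq = np.log(np.maximum(Q, 1e-300))
    survey_pw = -(logq @ Ys.T)  # (draws, n_survey)
    if paired_data:
        blocks = []
        for r in paired_data:
            pred = np.maximum(r.x, epsilon)
            pred = pred / pred.sum()
            blocks.append(float(-(r.va[algorithm] @ np.log(pred))))
        paired_pw = np.tile(np.asarray(blocks), (Q.shape[0], 1))
        return waic(np.hstack([paired_pw, survey_pw]))
    return waic(survey_pw)


def csmfa(p_hat, p_true) -> float:
    """Cause-specific mortality fraction accuracy:
    1 - sum_j |p_hat_j - p_j| / (2 * (1 - min_j p_j));
    equals 1 iff the estimate matches the truth, 0 at the worst case."""
    p_hat = np.asarray(p_hat, dtype=float)
    p_true = np.asarray(p_true, dtype=float)
    if p_hat.shape != p_true.shape:
        raise ValueError("CSMF vectors differ in length")
    denom = 2.0 * (1.0 - p_true.min())
    if denom == 0.0:
        raise ValueError("CSMFA undefined: true CSMF is a point mass on "
                         "a single cause list of length 1")
    return float(1.0 - np.abs(p_hat - p_true).sum() / denom)
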