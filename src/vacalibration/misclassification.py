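"""Misclassification-matrix estimation.

The multi-cause misclassification matrix M generalizes the confusion matrix:
M[i, j] is the average score a VA algorithm assigns to cause j among deaths
whose reference cause is i.  With multi-cause reference encodings x the VA
output satisfies E[y | x] = M'x, so M is fit as a compositional regression
of y on x by pseudo-maximum likelihood: minimize the summed KL divergence

    loss(M) = - sum_records sum_j y_j * log( (M'x)_j )

over row-stochastic M (y-entropy terms are constant in M and dropped).  The
minimizer is found by multiplicative expectation-maximisation updates that
stay on the simplex and never increase the loss.  When every x is one-hot
the fit reduces exactly to per-row averages of y — the classical
confusion-matrix estimate for one-hot y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPSILON = 1e-10  # floor on fitted entries: keeps downstream log terms finite


@dataclass
class FitResult:
    m: np.ndarray
    n_effective: np.ndarray  # per-row total x mass
    converged: bool
    iterations: int
    final_loss: float
    loss_trace: np.ndarray | None = None


def kl_loss(m: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> float:
    """Cross-entropy part of the KL loss: -sum y * log(x'M)."""
    pred = xs @ m
    return float(-np.sum(ys * np.log(np.maximum(pred, 1e-300))))


def _init_matrix(C: int) -> np.ndarray:
    m = np.full((C, C), 1.0 / C) + 0.1 * np.eye(C)
    return m / m.sum(axis=1, keepdims=True)


def fit_multicause_M(xs, ys, tol: float = 1e-8, max_iter: int = 10_000,
                     epsilon: float = EPSILON,
                     cause_labels=None) -> FitResult:
    """Fit M by multiplicative EM updates of the KL loss.

    Parameters
    ----------
    xs, ys
        Equal-length sequences of reference encodings and VA compositions
        (or two (n, C) arrays).
    tol
        Convergence threshold on the absolute loss decrease per iteration.
    epsilon
        Entries are floored at this value and rows renormalized after
        convergence, so a structurally-zero column never yields -inf in
        downstream log terms.
    """
    X = np.atleast_2d(np.asarray(xs, dtype=float))
    Y = np.atleast_2d(np.asarray(ys, dtype=float))
    if X.shape != Y.shape:
        raise ValueError(f"xs {X.shape} and ys {Y.shape} differ in shape")
    n, C = X.shape
    mass = X.sum(axis=0)
    if np.any(mass <= 0):
        bad = np.flatnonzero(mass <= 0)
        labels = ([cause_labels[i] for i in bad] if cause_labels is not None
                  else list(bad))
        raise ValueError(
            f"no reference-cause mass for cause(s) {labels}; the "
            "misclassification row is undefined for unobserved causes"
        )

    m = _init_matrix(C)
    loss = kl_loss(m, X, Y)
    trace = [loss]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pred = np.maximum(X @ m, 1e-300)
        # expected per-(reference i, VA j) score mass under current M
        s = X.T @ (Y / pred)          # (C, C)
        m_new = m * s
        rowsums = m_new.sum(axis=1, keepdims=True)
        m_new = m_new / np.maximum(rowsums, 1e-300)
        new_loss = kl_loss(m_new, X, Y)
        m = m_new
        trace.append(new_loss)
        if loss - new_loss < tol:
            loss = new_loss
            converged = True
            break
        loss = new_loss

    m = np.maximum(m, epsilon)
    m = m / m.sum(axis=1, keepdims=True)
    return FitResult(
        m=m,
        n_effective=mass,
        converged=converged,
        iterations=it,
        final_loss=kl_loss(m, X, Y),
        loss_trace=np.asarray(trace),
    )


def fit_singlecause_M(pairs, C: int | None = None) -> np.ndarray:
    """Closed-form confusion-matrix estimate from (true index, predicted
    index) pairs: M[i, j] = count(i -> j) / count(i)."""
    pairs = list(pairs)
    if C is None:
        C = max(max(i, j) for i, j in pairs) + 1
    counts = np.zeros((C, C))
    for i, j in pairs:
        counts[i, j] += 1
    rowsums = counts.sum(axis=1)
    if np.any(rowsums == 0):
        raise ValueError(
            f"true cause(s) {list(np.flatnonzero(rowsums == 0))} never "
            "observed; rows undefined"
        )
    return counts / rowsums[:, None]


def sensitivity_delta(m_single: np.ndarray, m_multi: np.ndarray,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cause single-cause sensitivity (diagonal of m_single) and the
    gain from the multi-cause treatment (diagonal difference)."""
    m_single = np.asarray(m_single, dtype=float)
    m_multi = np.asarray(m_multi, dtype=float)
    if m_single.shape != m_multi.shape:
        raise ValueError("matrices differ in shape")
    d_single = np.diag(m_single).copy()
    return d_single, np.diag(m_multi) - d_single
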