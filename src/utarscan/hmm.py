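"""Two-state Gaussian hidden Markov model for genome segmentation.

The segmenter's core: a 2-state HMM with Gaussian emissions, fitted by
Baum-Welch EM (scaled forward-backward) and decoded with Viterbi.  In
the transcription-calling application the observations are
``log(count + 1)``-transformed bin counts and the two states are
"untranscribed" (state 0, lower emission mean) and "transcriptionally
active" (state 1); the class itself is application-agnostic and works on
any real-valued sequences.

Numerical conventions
---------------------
* Emission variances are floored (default 1e-3).  The floor is a
  constraint on the M-step parameter space, so the EM monotonicity
  guarantee survives it (generalised EM).
* After fitting, states are reordered so state 0 has the smaller
  emission mean.
* Viterbi ties are broken toward state 0 (untranscribed) at every step,
  so ambiguous evidence never creates a transcribed call.

The class follows the scikit-learn estimator idiom (``fit`` /
``predict``, fitted attributes with trailing underscores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["HMMParams", "TwoStateGaussianHMM", "DegenerateDataError"]

_LOG2PI = float(np.log(2.0 * np.pi))


class DegenerateDataError(ValueError):
    """Raised when the data cannot support a two-state fit."""


@dataclass
class HMMParams:
    """Parameters of a fitted two-state Gaussian HMM.

    State 0 is the low-mean ("untranscribed") state.  ``n_iter``,
    ``loglik`` and ``converged`` record how the fit went.
    """

    startprob: np.ndarray          # (2,)
    transmat: np.ndarray           # (2, 2), rows sum to 1
    means: np.ndarray              # (2,), means[0] <= means[1]
    variances: np.ndarray          # (2,), > 0
    n_iter: int | None = None
    loglik: float | None = None
    converged: bool | None = None
    loglik_trace: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not np.isclose(self.startprob.sum(), 1.0):
            raise ValueError("startprob must sum to 1")
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("transmat rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if self.means[0] > self.means[1]:
            raise ValueError("states must be ordered by emission mean")


@njit(cache=True)
def _log_emissions(x, means, variances):  # pragma: no cover - numba
    T = x.shape[0]
    out = np.empty((T, 2))
    for j in range(2):
        c = -0.5 * (_LOG2PI + np.log(variances[j]))
        for t in range(T):
            d = x[t] - means[j]
            out[t, j] = c - 0.5 * d * d / variances[j]
    return out


@njit(cache=True)
def _forward_backward(startprob, transmat, logb):  # pragma: no cover - numba
    """Scaled forward-backward.

    Returns (loglik, gamma[T,2], xi_sum[2,2]).  Emission likelihoods are
    rescaled per timestep by their max before exponentiation, so the
    recursion never underflows as long as one state is plausible.
    """
    T = logb.shape[0]
    b = np.empty((T, 2))
    for t in range(T):
        m = logb[t, 0] if logb[t, 0] > logb[t, 1] else logb[t, 1]
        b[t, 0] = np.exp(logb[t, 0] - m)
        b[t, 1] = np.exp(logb[t, 1] - m)

    alpha = np.empty((T, 2))
    scale = np.empty(T)
    a0 = startprob[0] * b[0, 0]
    a1 = startprob[1] * b[0, 1]
    s = a0 + a1
    if s <= 0.0:
        s = 1e-300
    alpha[0, 0] = a0 / s
    alpha[0, 1] = a1 / s
    scale[0] = s
    for t in range(1, T):
        a0 = (alpha[t - 1, 0] * transmat[0, 0]
              + alpha[t - 1, 1] * transmat[1, 0]) * b[t, 0]
        a1 = (alpha[t - 1, 0] * transmat[0, 1]
              + alpha[t - 1, 1] * transmat[1, 1]) * b[t, 1]
        s = a0 + a1
        if s <= 0.0:
            s = 1e-300
        alpha[t, 0] = a0 / s
        alpha[t, 1] = a1 / s
        scale[t] = s

    beta = np.empty((T, 2))
    beta[T - 1, 0] = 1.0
    beta[T - 1, 1] = 1.0
    xi = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        bb0 = b[t + 1, 0] * beta[t + 1, 0]
        bb1 = b[t + 1, 1] * beta[t + 1, 1]
        beta[t, 0] = (transmat[0, 0] * bb0 + transmat[0, 1] * bb1) / scale[t + 1]
        beta[t, 1] = (transmat[1, 0] * bb0 + transmat[1, 1] * bb1) / scale[t + 1]
        denom = 0.0
        x00 = alpha[t, 0] * transmat[0, 0] * bb0
        x01 = alpha[t, 0] * transmat[0, 1] * bb1
        x10 = alpha[t, 1] * transmat[1, 0] * bb0
        x11 = alpha[t, 1] * transmat[1, 1] * bb1
        denom = x00 + x01 + x10 + x11
        if denom > 0.0:
            xi[0, 0] += x00 / denom
            xi[0, 1] += x01 / denom
            xi[1, 0] += x10 / denom
            xi[1, 1] += x11 / denom

    gamma = np.empty((T, 2))
    for t in range(T):
        g0 = alpha[t, 0] * beta[t, 0]
        g1 = alpha[t, 1] * beta[t, 1]
        s = g0 + g1
        if s <= 0.0:
            s = 1.0
        gamma[t, 0] = g0 / s
        gamma[t, 1] = g1 / s

    loglik = 0.0
    for t in range(T):
        loglik += np.log(scale[t])
        # undo the per-timestep emission rescale
        m = logb[t, 0] if logb[t, 0] > logb[t, 1] else logb[t, 1]
        loglik += m
    return loglik, gamma, xi


@njit(cache=True)
def _viterbi(log_start, log_trans, logb):  # pragma: no cover - numba
    """Max-probability path; ties broken toward state 0 at every step."""
    T = logb.shape[0]
    delta0 = log_start[0] + logb[0, 0]
    delta1 = log_start[1] + logb[0, 1]
    psi = np.zeros((T, 2), dtype=np.int8)
    for t in range(1, T):
        nd = np.empty(2)
        for j in range(2):
            v0 = delta0 + log_trans[0, j]
            v1 = delta1 + log_trans[1, j]
            if v1 > v0:  # strict: ties go to state 0
                psi[t, j] = 1
                nd[j] = v1
            else:
                psi[t, j] = 0
                nd[j] = v0
        delta0 = nd[0] + logb[t, 0]
        delta1 = nd[1] + logb[t, 1]
    states = np.empty(T, dtype=np.int8)
    states[T - 1] = 1 if delta1 > delta0 else 0
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1, states[t + 1]]
    return states


class TwoStateGaussianHMM:
    """Baum-Welch-fitted two-state Gaussian HMM.

    Parameters
    ----------
    tol
        Relative log-likelihood change below which EM stops.
    max_iter
        Iteration cap; non-convergence triggers a warning, not an error.
    var_floor
        Lower bound on emission variances (keeps zero-inflated
        backgrounds from collapsing the low state to a point mass).
    transmat_init, startprob_init
        Deterministic starting values; emission means start at the 25th
        and 90th percentiles of the pooled observations, so the
        initialisation is scale-free.

    Attributes (after ``fit``)
    --------------------------
    params_ : HMMParams
    n_iter_ : int
    loglik_ : float
    converged_ : bool
    loglik_trace_ : ndarray of per-iteration log-likelihoods
    """

    def __init__(
        self,
        tol: float = 1e-6,
        max_iter: int = 1000,
        var_floor: float = 1e-3,
        transmat_init=((0.95, 0.05), (0.10, 0.90)),
        startprob_init=(0.5, 0.5),
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.var_floor = var_floor
        self.transmat_init = transmat_init
        self.startprob_init = startprob_init

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "tol": self.tol,
            "max_iter": self.max_iter,
            "var_floor": self.var_floor,
            "transmat_init": self.transmat_init,
            "startprob_init": self.startprob_init,
        }

    def set_params(self, **params) -> "TwoStateGaussianHMM":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ----------------------------------------------------------------------
    @staticmethod
    def _as_sequences(X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 1:
            X = [X]
        seqs = [np.asarray(x, dtype=float).ravel() for x in X]
        seqs = [s for s in seqs if s.size > 0]
        if not seqs:
            raise ValueError("need at least one nonempty sequence")
        return seqs

    def fit(self, X) -> "TwoStateGaussianHMM":
        """Run EM on one 1-D array or a list of 1-D arrays (pooled fit)."""
        seqs = self._as_sequences(X)
        pooled = np.concatenate(seqs)
        lo, hi = pooled.min(), pooled.max()
        if lo == hi:
            raise DegenerateDataError(
                "observations are constant; a two-state fit is degenerate "
                "(for coverage tracks, consider the presence rule instead)"
            )
        mu = np.array([np.percentile(pooled, 25.0), np.percentile(pooled, 90.0)])
        if mu[1] <= mu[0]:  # heavy zero-inflation: fall back to the range
            mu = np.array([lo, hi], dtype=float)
        var = np.full(2, max(pooled.var(), self.var_floor))
        startprob = np.asarray(self.startprob_init, dtype=float).copy()
        transmat = np.asarray(self.transmat_init, dtype=float).copy()

        trace = []
        prev_ll = -np.inf
        converged = False
        for it in range(1, self.max_iter + 1):
            ll = 0.0
            g_first = np.zeros(2)
            xi_sum = np.zeros((2, 2))
            w = np.zeros(2)
            wx = np.zeros(2)
            wx2 = np.zeros(2)
            for s in seqs:
                logb = _log_emissions(s, mu, var)
                ll_s, gamma, xi = _forward_backward(startprob, transmat, logb)
                ll += ll_s
                g_first += gamma[0]
                xi_sum += xi
                w += gamma.sum(axis=0)
                wx += gamma.T @ s
                wx2 += gamma.T @ (s * s)
            trace.append(ll)

            # M-step
            startprob = g_first / g_first.sum()
            row = xi_sum.sum(axis=1, keepdims=True)
            row[row == 0] = 1.0
            transmat = xi_sum / row
            mu = wx / np.where(w > 0, w, 1.0)
            var = np.maximum(wx2 / np.where(w > 0, w, 1.0) - mu**2,
                             self.var_floor)

            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= self.tol * abs(
                prev_ll
            ):
                converged = True
                break
            prev_ll = ll

        if not converged:
            warnings.warn(
                f"EM did not converge in {self.max_iter} iterations "
                f"(last log-likelihood {trace[-1]:.6g})",
                RuntimeWarning,
            )

        if mu[0] > mu[1]:  # order states: 0 = low mean (untranscribed)
            perm = [1, 0]
            mu = mu[perm]
            var = var[perm]
            startprob = startprob[perm]
            transmat = transmat[np.ix_(perm, perm)]

        self.params_ = HMMParams(
            startprob=startprob,
            transmat=transmat,
            means=mu,
            variances=var,
            n_iter=len(trace),
            loglik=float(trace[-1]),
            converged=converged,
            loglik_trace=np.asarray(trace),
        )
        self.n_iter_ = len(trace)
        self.loglik_ = float(trace[-1])
        self.converged_ = converged
        self.loglik_trace_ = np.asarray(trace)
        return self

    def predict(self, x, params: HMMParams | None = None) -> np.ndarray:
        """Viterbi state path for one observation sequence."""
        if params is None:
            params = self.params_
        x = np.asarray(x, dtype=float).ravel()
        if x.size == 0:
            return np.zeros(0, dtype=np.int8)
        with np.errstate(divide="ignore"):
            log_start = np.log(params.startprob)
            log_trans = np.log(params.transmat)
        logb = _log_emissions(x, params.means, params.variances)
        return _viterbi(log_start, log_trans, logb)
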