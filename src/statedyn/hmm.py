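"""Gaussian-observation hidden Markov model for pooled multi-subject fMRI.

One model is fitted to the time series of all subjects concatenated along
the time axis, with the forward-backward recursions restarted at every
subject boundary so no transition is ever counted across subjects.  States
("networks") are multivariate Gaussians over ROI activity; the decoded
per-volume state path is the input to all occupancy/transition metrics.

Estimation is maximum-likelihood EM (Baum-Welch) with k-means
initialisation and deterministic seeded restarts.  Model order is chosen
by a BIC-style penalised likelihood acting as the free-energy surrogate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .containers import ParcellatedTimeSeries

__all__ = [
    "HMMModel",
    "StatePath",
    "ModelSelectionReport",
    "StateMatch",
    "normalize_timeseries",
    "concatenate_subjects",
    "forward_backward",
    "fit_hmm",
    "select_k",
    "decode",
    "match_states",
    "n_parameters",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class HMMModel:
    """Fitted Gaussian HMM: K state distributions plus Markov dynamics."""

    n_states: int
    means: np.ndarray  # (K, n_rois)
    covariances: np.ndarray  # (K, n_rois, n_rois)
    transition_matrix: np.ndarray  # (K, K), row-stochastic
    initial_probs: np.ndarray  # (K,)
    log_likelihood: float = np.nan
    loglik_trace: list[float] = field(default_factory=list)
    n_em_iterations: int = 0
    converged: bool = False
    seed: int = 0
    covariance_type: str = "full"

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, float))
        self.covariances = np.asarray(self.covariances, float)
        if self.covariances.ndim == 2:  # diagonal supplied as (K, R)
            self.covariances = np.stack(
                [np.diag(d) for d in self.covariances]
            )
        self.transition_matrix = np.atleast_2d(
            np.asarray(self.transition_matrix, float)
        )
        self.initial_probs = np.asarray(self.initial_probs, float).ravel()
        K = self.n_states
        if self.means.shape[0] != K or self.transition_matrix.shape != (K, K):
            raise ValueError("parameter shapes inconsistent with n_states")
        rows = self.transition_matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial_probs.sum(), 1.0, atol=1e-10):
            raise ValueError("initial_probs must sum to 1")
        for k in range(K):  # positive-definiteness check
            sla.cholesky(self.covariances[k], lower=True)

    @property
    def n_rois(self) -> int:
        return self.means.shape[1]


@dataclass
class StatePath:
    """Decoded state sequence (0-based states) with smoothed posteriors."""

    states: np.ndarray  # (T,) ints in [0, K)
    posteriors: np.ndarray  # (T, K), rows on the simplex
    log_likelihood: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, int)
        self.posteriors = np.atleast_2d(np.asarray(self.posteriors, float))


@dataclass
class ModelSelectionReport:
    """Penalised-likelihood sweep over candidate state counts."""

    table: pd.DataFrame  # columns: K, log_likelihood, n_parameters, criterion
    selected_K: int
    models: dict[int, HMMModel] = field(default_factory=dict)
    errors: dict[int, str] = field(default_factory=dict)


@dataclass
class StateMatch:
    """Correspondence between the states of two models."""

    mapping: np.ndarray  # state k of model A -> mapping[k] of model B
    similarity: np.ndarray  # (K_a, K_b) dot products of unit-norm means
    scores: np.ndarray  # similarity along the mapping
    zero_norm_states: list[tuple[str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# preprocessing


def normalize_timeseries(ts: ParcellatedTimeSeries) -> ParcellatedTimeSeries:
    """Z-score every ROI row (mean 0, sd 1) within subject.

    Controls for between-subject amplitude differences.  Constant rows
    cannot be scaled; they are set to zero and recorded in
    ``constant_rois``.  Idempotent.
    """
    data = np.asarray(ts.data, float)
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    constant = np.where(sd.ravel() < 1e-12)[0]
    sd_safe = np.where(sd < 1e-12, 1.0, sd)
    out = (data - mean) / sd_safe
    out[constant] = 0.0
    return ParcellatedTimeSeries(
        subject_id=ts.subject_id,
        group=ts.group,
        data=out,
        tr_seconds=ts.tr_seconds,
        roi_labels=ts.roi_labels,
        normalized=True,
        constant_rois=sorted(set(ts.constant_rois) | set(constant.tolist())),
    )


def concatenate_subjects(
    series: list[ParcellatedTimeSeries],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack subjects along time for a group-level fit.

    Returns (X, boundaries) where X is (T_total, n_rois) and boundaries
    holds the cumulative start/stop indices [0, T1, T1+T2, ...].  The
    recursions restart at every boundary, so no transition is counted
    across subjects.
    """
    if not series:
        raise ValueError("no subjects to concatenate")
    n_rois = series[0].n_rois
    for ts in series:
        if ts.n_rois != n_rois:
            raise ValueError(
                f"subject {ts.subject_id} has {ts.n_rois} ROIs, "
                f"expected {n_rois}"
            )
    X = np.concatenate([ts.data.T for ts in series], axis=0)
    lengths = [ts.n_volumes for ts in series]
    boundaries = np.concatenate([[0], np.cumsum(lengths)])
    return X, boundaries


# ---------------------------------------------------------------------------
# observation densities


def _log_obs(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Log Gaussian density of every volume under every state: (T, K)."""
    T, R = X.shape
    K = means.shape[0]
    logB = np.empty((T, K))
    for k in range(K):
        L = sla.cholesky(covs[k], lower=True)
        diff = X - means[k]
        z = sla.solve_triangular(L, diff.T, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        logB[:, k] = -0.5 * (
            R * np.log(2.0 * np.pi) + logdet + np.sum(z * z, axis=0)
        )
    if not np.all(np.isfinite(logB)):
        t = int(np.argwhere(~np.isfinite(logB))[0][0])
        raise FloatingPointError(
            f"non-finite observation density at volume {t}"
        )
    return logB


# ---------------------------------------------------------------------------
# forward-backward (scaled) and Viterbi


def _fb_kernel(Bs, A, pi):
    """Scaled alpha recursion; returns (alpha, c)."""
    T, K = Bs.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * Bs[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * Bs[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    return alpha, c


def _bw_kernel(Bs, A, c):
    """Scaled beta recursion."""
    T, K = Bs.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (Bs[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


def _vit_kernel(logB, logA, logpi):
    T, K = logB.shape
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best_i = 0
            best = delta[0] + logA[0, j]
            for i in range(1, K):
                v = delta[i] + logA[i, j]
                if v > best:  # strict: ties keep the lowest index
                    best = v
                    best_i = i
            back[t, j] = best_i
            new[j] = best + logB[t, j]
        delta = new
    path = np.empty(T, dtype=np.int64)
    best_k = 0
    for k in range(1, K):
        if delta[k] > delta[best_k]:
            best_k = k
    path[T - 1] = best_k
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


try:  # the recursions dominate runtime; JIT them when numba is present
    from numba import njit

    _fb_kernel = njit(cache=True)(_fb_kernel)
    _bw_kernel = njit(cache=True)(_bw_kernel)
    _vit_kernel = njit(cache=True)(_vit_kernel)
except ImportError:  # pragma: no cover - numpy fallback
    pass


def _forward_backward_segment(
    logB: np.ndarray,
    A: np.ndarray,
    pi: np.ndarray,
    compute_xi: bool = False,
) -> tuple[np.ndarray, float, np.ndarray | None]:
    """Scaled forward-backward on one contiguous segment.

    Returns (gamma, log_likelihood, xi_sum).  Scaling constants make the
    recursion stable for arbitrarily long segments; the per-row max of the
    log-densities is factored out first so the scaled likelihoods stay in
    (0, 1].
    """
    T, K = logB.shape
    m = logB.max(axis=1)
    Bs = np.exp(logB - m[:, None])
    alpha, c = _fb_kernel(Bs, A, pi)
    beta = _bw_kernel(Bs, A, c)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(c)) + np.sum(m))

    xi_sum = None
    if compute_xi and T > 1:
        # sum_t alpha[t] (x) (Bs[t+1] * beta[t+1] / c[t+1]), elementwise A
        W = Bs[1:] * beta[1:] / c[1:, None]
        xi_sum = A * (alpha[:-1].T @ W)
    elif compute_xi:
        xi_sum = np.zeros((K, K))
    return gamma, loglik, xi_sum


def _segments(boundaries: np.ndarray) -> list[tuple[int, int]]:
    b = np.asarray(boundaries, int)
    return [(int(b[i]), int(b[i + 1])) for i in range(len(b) - 1)]


def forward_backward(
    model: HMMModel, ts: ParcellatedTimeSeries | np.ndarray
) -> StatePath:
    """Smoothed state posteriors and exact marginal log-likelihood.

    Accepts a ParcellatedTimeSeries or a raw (n_rois, T) / (T, n_rois)
    array.  The hard path is the per-volume posterior argmax (ties go to
    the lowest state index).
    """
    X = _as_time_major(model, ts)
    logB = _log_obs(X, model.means, model.covariances)
    gamma, ll, _ = _forward_backward_segment(
        logB, model.transition_matrix, model.initial_probs
    )
    return StatePath(states=np.argmax(gamma, axis=1), posteriors=gamma,
                     log_likelihood=ll)


def _as_time_major(model: HMMModel, ts) -> np.ndarray:
    if isinstance(ts, ParcellatedTimeSeries):
        X = ts.data.T
    else:
        X = np.asarray(ts, float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array")
        if X.shape[1] != model.n_rois:
            if X.shape[0] == model.n_rois:
                X = X.T
            else:
                raise ValueError(
                    f"data has {X.shape} but model expects {model.n_rois} ROIs"
                )
    if X.shape[1] != model.n_rois:
        raise ValueError(
            f"data has {X.shape[1]} ROIs but model expects {model.n_rois}"
        )
    return X


def _viterbi_segment(
    logB: np.ndarray, logA: np.ndarray, logpi: np.ndarray
) -> np.ndarray:
    return np.asarray(
        _vit_kernel(
            np.ascontiguousarray(logB, dtype=float),
            np.ascontiguousarray(logA, dtype=float),
            np.ascontiguousarray(logpi, dtype=float),
        ),
        dtype=int,
    )


def decode(
    model: HMMModel,
    ts: ParcellatedTimeSeries | np.ndarray,
    method: str = "posterior_argmax",
) -> StatePath:
    """Hard state path: per-volume posterior argmax (default) or Viterbi."""
    if method not in ("posterior_argmax", "viterbi"):
        raise ValueError(f"unknown decode method {method!r}")
    path = forward_backward(model, ts)
    if method == "viterbi":
        X = _as_time_major(model, ts)
        logB = _log_obs(X, model.means, model.covariances)
        with np.errstate(divide="ignore"):
            logA = np.log(model.transition_matrix)
            logpi = np.log(model.initial_probs)
        vpath = _viterbi_segment(logB, logA, logpi)
        return StatePath(states=vpath, posteriors=path.posteriors,
                         log_likelihood=path.log_likelihood)
    return path


def path_log_probability(
    model: HMMModel, ts, states: np.ndarray
) -> float:
    """Joint log-probability of data and a given state path."""
    X = _as_time_major(model, ts)
    logB = _log_obs(X, model.means, model.covariances)
    states = np.asarray(states, int)
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition_matrix)
        logpi = np.log(model.initial_probs)
    lp = logpi[states[0]] + logB[0, states[0]]
    lp += np.sum(logA[states[:-1], states[1:]])
    lp += np.sum(logB[np.arange(1, len(states)), states[1:]])
    return float(lp)


# ---------------------------------------------------------------------------
# EM fitting


def n_parameters(K: int, n_rois: int, covariance_type: str = "full") -> int:
    """Free parameters of a K-state Gaussian HMM."""
    p = (K - 1) + K * (K - 1) + K * n_rois
    if covariance_type == "full":
        p += K * n_rois * (n_rois + 1) // 2
    elif covariance_type == "diag":
        p += K * n_rois
    else:
        raise ValueError(f"unknown covariance_type {covariance_type!r}")
    return p


def _init_from_kmeans(
    X: np.ndarray,
    boundaries: np.ndarray,
    K: int,
    covariance_type: str,
    reg: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    T, R = X.shape
    km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(X)
    labels = km.labels_
    means = km.cluster_centers_.copy()
    global_cov = np.cov(X.T) if R > 1 else np.atleast_2d(np.var(X))
    global_cov = np.atleast_2d(global_cov)
    covs = np.empty((K, R, R))
    for k in range(K):
        pts = X[labels == k]
        if len(pts) < R + 2:
            covs[k] = global_cov
        else:
            covs[k] = np.atleast_2d(np.cov(pts.T))
        covs[k] = _regularize(covs[k], covariance_type, reg)
    counts = np.ones((K, K))
    starts = np.ones(K)
    for a, b in _segments(boundaries):
        seg = labels[a:b]
        starts[seg[0]] += 1
        np.add.at(counts, (seg[:-1], seg[1:]), 1)
    A = counts / counts.sum(axis=1, keepdims=True)
    pi = starts / starts.sum()
    return means, covs, A, pi


def _regularize(cov: np.ndarray, covariance_type: str, reg: float) -> np.ndarray:
    R = cov.shape[0]
    cov = 0.5 * (cov + cov.T)
    if covariance_type == "diag":
        cov = np.diag(np.diag(cov))
    ridge = reg * max(np.trace(cov), 1e-12) / R
    return cov + ridge * np.eye(R)


def fit_hmm(
    X: np.ndarray,
    boundaries: np.ndarray | None,
    n_states: int,
    covariance_type: str = "full",
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
    reg: float = 1e-6,
    seed: int = 0,
) -> HMMModel:
    """Baum-Welch EM on pooled data with subject-boundary restarts.

    ``X`` is (T, n_rois); ``boundaries`` the cumulative subject indices
    from :func:`concatenate_subjects` (None = one segment).  Each restart
    is seeded deterministically (seed + restart index), initialised by
    k-means, and the restart with the best final log-likelihood wins.
    Covariances carry a ridge of ``reg * trace / n_rois`` on the diagonal.
    """
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be (T, n_rois)")
    T, R = X.shape
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if T <= n_states:
        raise ValueError("need more volumes than states")
    if boundaries is None:
        boundaries = np.array([0, T])
    best: HMMModel | None = None
    for r in range(max(1, n_restarts)):
        model = _fit_once(
            X, boundaries, n_states, covariance_type, max_iter, tol, reg,
            seed + r,
        )
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    return best


def _fit_once(
    X, boundaries, K, covariance_type, max_iter, tol, reg, seed
) -> HMMModel:
    T, R = X.shape
    rng = np.random.default_rng(seed)
    if K == 1:
        means = X.mean(axis=0, keepdims=True)
        cov = _regularize(np.atleast_2d(np.cov(X.T, bias=True)),
                          covariance_type, reg)
        logB = _log_obs(X, means, cov[None])
        ll = float(logB.sum())
        return HMMModel(
            n_states=1, means=means, covariances=cov[None],
            transition_matrix=np.ones((1, 1)), initial_probs=np.ones(1),
            log_likelihood=ll, loglik_trace=[ll], n_em_iterations=0,
            converged=True, seed=seed, covariance_type=covariance_type,
        )

    means, covs, A, pi = _init_from_kmeans(
        X, boundaries, K, covariance_type, reg, seed
    )
    global_cov = _regularize(np.atleast_2d(np.cov(X.T)), covariance_type, reg)
    segs = _segments(boundaries)
    trace: list[float] = []
    converged = False
    reseeded = np.zeros(K, dtype=bool)
    collapsed_twice = False
    it = 0
    for it in range(1, max_iter + 1):
        logB = _log_obs(X, means, covs)
        gamma_sum = np.zeros(K)
        start_sum = np.zeros(K)
        xi_sum = np.zeros((K, K))
        mean_num = np.zeros((K, R))
        S = np.zeros((K, R, R))
        ll = 0.0
        for a, b in segs:
            gamma, seg_ll, seg_xi = _forward_backward_segment(
                logB[a:b], A, pi, compute_xi=True
            )
            ll += seg_ll
            gamma_sum += gamma.sum(axis=0)
            start_sum += gamma[0]
            xi_sum += seg_xi
            seg_X = X[a:b]
            mean_num += gamma.T @ seg_X
            for k in range(K):
                Wx = seg_X * gamma[:, k : k + 1]
                S[k] += Wx.T @ seg_X
        trace.append(ll)

        # empty-state handling: reseed once, then give up on convergence
        empty = gamma_sum < 1e-8
        if empty.any():
            for k in np.where(empty)[0]:
                if reseeded[k]:
                    collapsed_twice = True
                    continue
                reseeded[k] = True
                means[k] = X[rng.integers(0, T)]
                covs[k] = global_cov
                A[k] = np.full(K, 1.0 / K)
            if collapsed_twice:
                break
            continue

        pi = start_sum / start_sum.sum()
        A = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        means = mean_num / gamma_sum[:, None]
        for k in range(K):
            cov = S[k] / gamma_sum[k] - np.outer(means[k], means[k])
            covs[k] = _regularize(cov, covariance_type, reg)

        if len(trace) >= 2:
            prev = trace[-2]
            if ll - prev < tol * abs(prev):
                converged = True
                break

    return HMMModel(
        n_states=K, means=means, covariances=covs, transition_matrix=A,
        initial_probs=pi, log_likelihood=trace[-1] if trace else -np.inf,
        loglik_trace=trace, n_em_iterations=it,
        converged=converged and not collapsed_twice, seed=seed,
        covariance_type=covariance_type,
    )


def select_k(
    X: np.ndarray,
    boundaries: np.ndarray | None,
    k_range=range(3, 21),
    seed: int = 0,
    **fit_kwargs,
) -> ModelSelectionReport:
    """Sweep candidate state counts; pick the penalised-likelihood minimum.

    criterion = -log_likelihood + 0.5 * n_parameters * log(T), a BIC-style
    quantity standing in for variational free energy: lower is better,
    ties go to the smallest K.  A K that fails to fit is recorded with its
    error and skipped.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range must be non-empty")
    T = np.asarray(X).shape[0]
    cov_type = fit_kwargs.get("covariance_type", "full")
    rows = []
    models: dict[int, HMMModel] = {}
    errors: dict[int, str] = {}
    for K in k_range:
        try:
            model = fit_hmm(X, boundaries, K, seed=seed, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 - sweep must survive one K
            errors[K] = f"{type(exc).__name__}: {exc}"
            continue
        p = n_parameters(K, np.asarray(X).shape[1], cov_type)
        crit = -model.log_likelihood + 0.5 * p * np.log(T)
        rows.append(
            {"K": K, "log_likelihood": model.log_likelihood,
             "n_parameters": p, "criterion": crit}
        )
        models[K] = model
    if not rows:
        raise RuntimeError(f"every K failed to fit: {errors}")
    table = pd.DataFrame(rows).sort_values("K").reset_index(drop=True)
    best = table.loc[table["criterion"].idxmin(), "K"]  # first min = smallest K
    return ModelSelectionReport(
        table=table, selected_K=int(best), models=models, errors=errors
    )


# ---------------------------------------------------------------------------
# state matching across estimations


def match_states(
    model_a: HMMModel,
    model_b: HMMModel,
    mode: str = "one_to_one",
) -> StateMatch:
    """Match states across two estimations by dot products of unit-norm means.

    one_to_one uses the optimal assignment maximising total similarity;
    many_to_one (for unequal K) maps each state of A to its best match in
    B by per-row argmax.  Zero-norm means get similarity 0 and are flagged.
    """
    if model_a.n_rois != model_b.n_rois:
        raise ValueError("models have different ROI counts")
    flagged: list[tuple[str, int]] = []

    def _unit(means: np.ndarray, label: str) -> np.ndarray:
        norms = np.linalg.norm(means, axis=1)
        out = np.zeros_like(means)
        for k, n in enumerate(norms):
            if n < 1e-12:
                flagged.append((label, k))
            else:
                out[k] = means[k] / n
        return out

    Ua = _unit(model_a.means, "a")
    Ub = _unit(model_b.means, "b")
    S = Ua @ Ub.T
    if mode == "one_to_one":
        ra, cb = linear_sum_assignment(-S)
        mapping = np.full(model_a.n_states, -1, dtype=int)
        mapping[ra] = cb
        scores = np.array(
            [S[k, mapping[k]] if mapping[k] >= 0 else np.nan
             for k in range(model_a.n_states)]
        )
    elif mode == "many_to_one":
        mapping = np.argmax(S, axis=1)
        scores = S[np.arange(model_a.n_states), mapping]
    else:
        raise ValueError(f"unknown matching mode {mode!r}")
    return StateMatch(mapping=mapping, similarity=S, scores=scores,
                      zero_norm_states=flagged)
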