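"""Synthetic multi-subject datasets with known latent-state ground truth.

The generator emulates the study design this pipeline targets: two age
groups (44 younger, 27 older subjects), runs of 1,440 volumes at TR
475 ms, a leading rest block followed by 24 musical excerpts of 20 s
(6 self-selected / 10 popular / 8 novel) each trailed by a 4 s rating
prompt, and 4-point liking/familiarity ratings whose within-subject
correlation is calibrated per group (older ~= 0.57, younger ~= 0.43).

Hidden dynamics are condition-switched Markov chains: each volume's
transition row comes from the matrix of the condition the volume falls
in, so condition effects on occupancy and transitions are planted by
construction and recoverable downstream.  Default dynamics plant the
qualitative structure the analysis is meant to detect: higher persistence
of (and more transitions into) a designated reward state during
self-selected music, higher persistence of a perception state during
experimenter-selected music, and group-specific biases.

State-index convention at the default K = 4: 0 medial fronto-parietal,
1 temporal (perception), 2 temporal-mesolimbic (reward),
3 fronto-parietal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import brentq

from .containers import EventTable, ParcellatedTimeSeries
from .design import CATEGORIES, StudyDesign, make_design
from .hmm import StatePath
from .metrics import excerpt_windows

DEFAULT_RATING_TARGETS = {"older": 0.57, "younger": 0.43}

CELL_CONDITIONS = CATEGORIES + ("rest",)


@dataclass
class RatingCoupling:
    """Per-group parameters of the latent bivariate rating model.

    Liking and familiarity are thresholded latent Gaussians.  Their means
    shift with the reward-state occupancy of each excerpt window (slope)
    and with a self-selected boost; ``latent_corr`` is the residual latent
    correlation, calibrated numerically so the discretised 1-4 ratings hit
    ``target_corr`` within subject.
    """

    target_corr: float
    slope: float = 1.5
    boost_liking: float = 0.8
    boost_familiarity: float = 1.2
    mu_liking: float = 0.3
    mu_familiarity: float = 0.0
    cut_points: tuple[float, float, float] = (-1.2, 0.0, 1.2)
    latent_corr: float | None = None  # filled by calibration
    fo_center: float | None = None  # filled by calibration

    def __post_init__(self) -> None:
        if not -1.0 < self.target_corr < 1.0:
            raise ValueError("target_corr must lie in (-1, 1)")


@dataclass
class GroundTruth:
    """Generator parameters: state geometry, dynamics, rating model."""

    n_states: int
    n_rois: int
    state_means: np.ndarray  # (K, R)
    state_covs: np.ndarray  # (K, R, R)
    tp_by_cell: dict[tuple[str, str], np.ndarray]  # (group, condition) -> KxK
    initial_probs: np.ndarray
    rating_coupling: dict[str, RatingCoupling]
    reward_state: int
    perception_state: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_means = np.asarray(self.state_means, float)
        self.state_covs = np.asarray(self.state_covs, float)
        self.initial_probs = np.asarray(self.initial_probs, float)
        for k in range(self.n_states):  # SPD check
            try:
                sla.cholesky(self.state_covs[k], lower=True)
            except sla.LinAlgError as exc:
                raise ValueError(
                    f"state {k} covariance is not positive definite"
                ) from exc
        for key, tp in self.tp_by_cell.items():
            rows = np.asarray(tp).sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-12):
                raise ValueError(f"TP rows for cell {key} do not sum to 1")


@dataclass
class SubjectData:
    subject_id: str
    group: str
    timeseries: ParcellatedTimeSeries
    true_path: StatePath
    events: EventTable


@dataclass
class SyntheticDataset:
    design: StudyDesign
    ground_truth: GroundTruth
    subjects: list[SubjectData] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ground truth


def _sticky(persist: np.ndarray) -> np.ndarray:
    """Row-stochastic matrix with the given diagonal, off-mass uniform."""
    K = len(persist)
    if K == 1:
        return np.ones((1, 1))
    tp = np.empty((K, K))
    for i in range(K):
        tp[i] = (1.0 - persist[i]) / (K - 1)
        tp[i, i] = persist[i]
    return tp


def _boost_into(tp: np.ndarray, j: int, factor: float) -> np.ndarray:
    """Scale off-diagonal transitions into state j, renormalising each
    row's off-diagonal mass so planted persistences stay exact."""
    tp = tp.copy()
    K = tp.shape[0]
    for i in range(K):
        if i == j:
            continue
        off = np.arange(K) != i
        mass = tp[i, off].sum()
        tp[i, j] *= factor
        new_mass = tp[i, off].sum()
        if new_mass > 0:
            tp[i, off] *= mass / new_mass
    return tp


def stationary_distribution(tp: np.ndarray) -> np.ndarray:
    """Stationary distribution via the unit eigenvector of TP^T."""
    vals, vecs = np.linalg.eig(np.asarray(tp, float).T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_ground_truth(
    design: StudyDesign,
    n_states: int = 4,
    n_rois: int = 20,
    separation: float = 2.0,
    noise_scale: float = 1.0,
    base_persistence: float = 0.80,
    rating_targets: dict[str, float] | None = None,
    seed: int = 0,
    calibrate: bool = True,
    plant_effects: bool = True,
    group_bias: float = 0.03,
) -> GroundTruth:
    """Draw generator parameters emulating the study's effect structure.

    State means are drawn N(0, separation^2) per ROI, so separation = 0
    collapses all states onto one distribution.  Transition matrices are
    built per (group, condition) cell: self-selected music raises reward-
    state persistence (0.92) and doubles transitions into it; popular and
    novel music raise perception-state persistence (0.90 younger, 0.85
    older); the older group gets extra transitions into the reward state
    during experimenter-selected music (x1.8 novel, x1.3 popular); and a
    small group bias (younger: perception, older: fronto-parietal) plants
    a group main effect on occupancy in every condition.

    ``plant_effects=False`` gives every (group, condition) cell the same
    base sticky matrix — a null world with no group or condition effect,
    used to calibrate the inference machinery.  ``group_bias`` sets the
    persistence bump that carries the group main effect.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    if n_rois < n_states:
        raise ValueError("need n_rois >= n_states")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    if noise_scale <= 0:
        raise ValueError("noise_scale must be positive")
    rng = np.random.default_rng(seed)
    K = n_states
    means = separation * rng.standard_normal((K, n_rois))
    A = 0.1 * rng.standard_normal((K, n_rois, n_rois))
    covs = np.empty((K, n_rois, n_rois))
    for k in range(K):
        covs[k] = noise_scale**2 * (
            np.eye(n_rois) + A[k] @ A[k].T / n_rois
        )

    reward = min(2, K - 1)
    perception = 1 if K > 1 else 0
    fronto = 3 if K > 3 else K - 1

    tp_by_cell: dict[tuple[str, str], np.ndarray] = {}
    for group in design.groups:
        for cond in CELL_CONDITIONS:
            persist = np.full(K, base_persistence)
            if plant_effects:
                # group main effect on occupancy, present in every condition
                if group == "younger":
                    persist[perception] += group_bias
                elif group == "older":
                    persist[fronto] += group_bias
                if cond == "self_selected":
                    persist[reward] = 0.92
                elif cond in ("popular", "novel"):
                    persist[perception] = (
                        0.90 if group == "younger" else 0.85
                    )
            tp = _sticky(np.clip(persist, 0.0, 0.99))
            if plant_effects:
                if cond == "self_selected":
                    tp = _boost_into(tp, reward, 2.0)
                elif cond == "novel" and group == "older":
                    tp = _boost_into(tp, reward, 1.8)
                elif cond == "popular" and group == "older":
                    tp = _boost_into(tp, reward, 1.3)
            tp_by_cell[(group, cond)] = tp

    targets = dict(DEFAULT_RATING_TARGETS)
    if rating_targets:
        targets.update(rating_targets)
    coupling = {
        g: RatingCoupling(target_corr=targets.get(g, 0.5))
        for g in design.groups
    }
    if plant_effects:
        # age difference in brain-behaviour coupling: the younger group's
        # ratings track reward-state occupancy more tightly
        for g, rc in coupling.items():
            if g == "younger":
                rc.slope = 2.2
            elif g == "older":
                rc.slope = 1.0

    gt = GroundTruth(
        n_states=K, n_rois=n_rois, state_means=means, state_covs=covs,
        tp_by_cell=tp_by_cell, initial_probs=np.full(K, 1.0 / K),
        rating_coupling=coupling, reward_state=reward,
        perception_state=perception, seed=seed,
    )
    if calibrate:
        for g in design.groups:
            calibrate_rating_coupling(gt, design, g)
    return gt


# ---------------------------------------------------------------------------
# rating calibration

_CAL_SUBJECTS = 800
_CAL_WINDOWS_PER_CATEGORY = 400


def _window_fo_pool(
    gt: GroundTruth, design: StudyDesign, group: str, rng: np.random.Generator,
    n_windows: int = _CAL_WINDOWS_PER_CATEGORY,
) -> dict[str, np.ndarray]:
    """Reward-state window-FO samples per category.

    Chains start from the rest chain's stationary distribution — excerpt
    windows are preceded by rest or rating gaps, so this matches the state
    distribution at window onset in a real run."""
    if design.excerpts:
        L = int(np.floor(design.excerpts[0].duration_s / design.tr_seconds))
    else:
        L = 42
    L = max(L, 1)
    pools = {}
    pi = stationary_distribution(gt.tp_by_cell[(group, "rest")])
    for cat in CATEGORIES:
        tp = gt.tp_by_cell[(group, cat)]
        cum = np.cumsum(tp, axis=1)
        s = np.searchsorted(np.cumsum(pi), rng.random(n_windows))
        hits = (s == gt.reward_state).astype(float)
        for _ in range(L - 1):
            u = rng.random(n_windows)
            s = np.array(
                [np.searchsorted(cum[si], ui) for si, ui in zip(s, u)]
            )
            hits += s == gt.reward_state
        pools[cat] = hits / L
    return pools


def _pooled_discrete_corr(
    rho: float,
    coupling: RatingCoupling,
    categories: np.ndarray,
    fo: np.ndarray,
    fo_center: float,
    z0: np.ndarray,
    z1: np.ndarray,
) -> float:
    """Mean within-subject Pearson r of the discretised ratings.

    All stochastic ingredients (fo draws, latent normals) are passed in,
    so the statistic is a smooth, monotone function of rho suitable for
    root finding with common random numbers.
    """
    is_ss = (categories == "self_selected").astype(float)[None, :]
    shift = coupling.slope * (fo - fo_center)
    lat_f = coupling.mu_familiarity + shift \
        + coupling.boost_familiarity * is_ss + z0
    lat_l = coupling.mu_liking + shift + coupling.boost_liking * is_ss \
        + rho * z0 + np.sqrt(max(1.0 - rho**2, 0.0)) * z1
    cuts = np.asarray(coupling.cut_points)
    r_l = np.digitize(lat_l, cuts) + 1.0
    r_f = np.digitize(lat_f, cuts) + 1.0
    lc = r_l - r_l.mean(axis=1, keepdims=True)
    fc = r_f - r_f.mean(axis=1, keepdims=True)
    num = (lc * fc).sum(axis=1)
    den = np.sqrt((lc**2).sum(axis=1) * (fc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return float(np.nanmean(r))


def expected_discrete_correlation(
    gt: GroundTruth,
    design: StudyDesign,
    group: str,
    latent_corr: float,
    n_subjects: int = _CAL_SUBJECTS,
    seed: int = 12345,
) -> float:
    """Expected group-mean within-subject rating correlation at a given
    latent correlation, under this ground truth's coupling (Monte Carlo
    with fixed random numbers)."""
    rng = np.random.default_rng(seed)
    coupling = gt.rating_coupling[group]
    categories = np.array([e.category for e in design.excerpts])
    pools = _window_fo_pool(gt, design, group, rng)
    n_exc = len(categories)
    fo = np.empty((n_subjects, n_exc))
    for j, cat in enumerate(categories):
        fo[:, j] = rng.choice(pools[cat], size=n_subjects)
    fo_center = float(
        np.mean([pools[c].mean() for c in categories])
    )
    z0 = rng.standard_normal((n_subjects, n_exc))
    z1 = rng.standard_normal((n_subjects, n_exc))
    return _pooled_discrete_corr(
        latent_corr, coupling, categories, fo, fo_center, z0, z1
    )


def calibrate_rating_coupling(
    gt: GroundTruth,
    design: StudyDesign,
    group: str,
    n_subjects: int = _CAL_SUBJECTS,
    seed: int = 12345,
) -> RatingCoupling:
    """Root-find the latent correlation so discretised ratings hit the
    per-group target within-subject r; stores latent_corr and fo_center
    on the coupling in place."""
    rng = np.random.default_rng(seed)
    coupling = gt.rating_coupling[group]
    if not design.excerpts:
        coupling.latent_corr = coupling.target_corr
        coupling.fo_center = 0.0
        return coupling
    categories = np.array([e.category for e in design.excerpts])
    pools = _window_fo_pool(gt, design, group, rng)
    n_exc = len(categories)
    fo = np.empty((n_subjects, n_exc))
    for j, cat in enumerate(categories):
        fo[:, j] = rng.choice(pools[cat], size=n_subjects)
    fo_center = float(np.mean([pools[c].mean() for c in categories]))
    z0 = rng.standard_normal((n_subjects, n_exc))
    z1 = rng.standard_normal((n_subjects, n_exc))

    def f(rho: float) -> float:
        return (
            _pooled_discrete_corr(
                rho, coupling, categories, fo, fo_center, z0, z1
            )
            - coupling.target_corr
        )

    lo, hi = -0.995, 0.995
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"rating target {coupling.target_corr} unreachable for group "
            f"{group!r} under the current coupling parameters"
        )
    coupling.latent_corr = float(brentq(f, lo, hi, xtol=1e-4))
    coupling.fo_center = fo_center
    return coupling


# ---------------------------------------------------------------------------
# subject simulation


def _path_kernel(cums, cond_idx, u, s0):
    T = cond_idx.shape[0]
    K = cums.shape[1]
    states = np.empty(T, dtype=np.int64)
    states[0] = s0
    for t in range(1, T):
        row = cums[cond_idx[t], states[t - 1]]
        s = 0
        while s < K - 1 and u[t] >= row[s]:
            s += 1
        states[t] = s
    return states


try:
    from numba import njit

    _path_kernel = njit(cache=True)(_path_kernel)
except ImportError:  # pragma: no cover - numpy fallback
    pass


def events_from_design(design: StudyDesign) -> EventTable:
    """Event table of the design's excerpts, ratings still missing."""
    rows = [
        {"onset": e.onset_s, "duration": e.duration_s, "category": e.category,
         "liking": np.nan, "familiarity": np.nan}
        for e in design.excerpts
    ]
    if not rows:
        return EventTable.empty()
    return EventTable(pd.DataFrame(rows))


def simulate_state_path(
    gt: GroundTruth,
    design: StudyDesign,
    group: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the hidden path under condition-switched dynamics.

    The transition row used for the step into volume t is that of the
    condition volume t falls in ('rest' outside excerpt windows).
    """
    if group not in design.groups:
        raise ValueError(f"unknown group {group!r}")
    cond = design.condition_per_volume()
    conds = ["rest", *CATEGORIES]
    cond_idx = np.array([conds.index(c) for c in cond])
    cums = np.stack(
        [np.cumsum(gt.tp_by_cell[(group, c)], axis=1) for c in conds]
    )
    T = design.n_volumes
    u = rng.random(T)
    s0 = int(np.searchsorted(np.cumsum(gt.initial_probs), u[0]))
    return np.asarray(
        _path_kernel(np.ascontiguousarray(cums), cond_idx, u, s0), dtype=int
    )


def simulate_subject(
    gt: GroundTruth,
    design: StudyDesign,
    group: str,
    subject_id: str,
    rng: np.random.Generator | int,
) -> tuple[ParcellatedTimeSeries, StatePath, EventTable]:
    """One subject: hidden path, Gaussian observations, unrated events."""
    rng = np.random.default_rng(rng)
    states = simulate_state_path(gt, design, group, rng)
    T, R, K = design.n_volumes, gt.n_rois, gt.n_states
    chols = [sla.cholesky(gt.state_covs[k], lower=True) for k in range(K)]
    z = rng.standard_normal((T, R))
    Y = np.empty((T, R))
    for k in range(K):
        mask = states == k
        if mask.any():
            Y[mask] = gt.state_means[k] + z[mask] @ chols[k].T
    ts = ParcellatedTimeSeries(
        subject_id=subject_id, group=group, data=Y.T,
        tr_seconds=design.tr_seconds,
    )
    posteriors = np.zeros((T, K))
    posteriors[np.arange(T), states] = 1.0
    path = StatePath(states=states, posteriors=posteriors,
                     log_likelihood=np.nan)
    return ts, path, events_from_design(design)


def simulate_ratings(
    gt: GroundTruth,
    true_path: StatePath | np.ndarray,
    design: StudyDesign,
    group: str,
    rng: np.random.Generator | int,
) -> EventTable:
    """Liking/familiarity ratings coupled to reward-state window occupancy.

    Latent bivariate normals (correlation = calibrated latent_corr) with
    means shifted by slope * (window FO - fo_center) plus the
    self-selected boost are thresholded at the coupling's cut points into
    1-4.  Degenerate all-identical ratings raise a warning.
    """
    rng = np.random.default_rng(rng)
    coupling = gt.rating_coupling[group]
    if coupling.latent_corr is None or coupling.fo_center is None:
        raise ValueError(
            "rating coupling is uncalibrated; run calibrate_rating_coupling"
        )
    states = (
        true_path.states if isinstance(true_path, StatePath) else
        np.asarray(true_path, int)
    )
    events = events_from_design(design)
    if len(events) == 0:
        return events
    windows = excerpt_windows(events, design.tr_seconds, design.n_volumes)
    if max(b for _, b in windows) > len(states):
        raise ValueError("true path does not cover all excerpt windows")
    fo = np.array(
        [np.mean(states[a:b] == gt.reward_state) if b > a
         else coupling.fo_center
         for a, b in windows]
    )
    cats = np.array([e.category for e in design.excerpts])
    is_ss = (cats == "self_selected").astype(float)
    shift = coupling.slope * (fo - coupling.fo_center)
    rho = coupling.latent_corr
    z0 = rng.standard_normal(len(cats))
    z1 = rng.standard_normal(len(cats))
    lat_f = (coupling.mu_familiarity + shift
             + coupling.boost_familiarity * is_ss + z0)
    lat_l = (coupling.mu_liking + shift + coupling.boost_liking * is_ss
             + rho * z0 + np.sqrt(max(1.0 - rho**2, 0.0)) * z1)
    cuts = np.asarray(coupling.cut_points)
    liking = np.digitize(lat_l, cuts) + 1
    familiarity = np.digitize(lat_f, cuts) + 1
    if len(cats) > 1 and (
        np.all(liking == liking[0]) and np.all(familiarity == familiarity[0])
    ):
        warnings.warn(
            f"degenerate ratings for group {group!r}: all excerpts "
            "received identical liking and familiarity",
            stacklevel=2,
        )
    return events.with_ratings(liking.astype(float),
                               familiarity.astype(float))


# ---------------------------------------------------------------------------
# whole datasets


def simulate_dataset(
    design: StudyDesign,
    gt: GroundTruth,
    seed: int | None = None,
) -> SyntheticDataset:
    """Simulate every subject of the design (paths, observations, ratings)."""
    seed = design.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    subjects = []
    i = 0
    for group, n in design.groups.items():
        for _ in range(n):
            i += 1
            sid = f"sub-{i:03d}"
            child = np.random.default_rng(ss.spawn(1)[0])
            ts, path, events = simulate_subject(gt, design, group, sid, child)
            events = simulate_ratings(gt, path, design, group, child)
            subjects.append(
                SubjectData(subject_id=sid, group=group, timeseries=ts,
                            true_path=path, events=events)
            )
    return SyntheticDataset(design=design, ground_truth=gt, subjects=subjects)


def default_dataset(
    n_rois: int = 20,
    n_states: int = 4,
    groups: dict[str, int] | None = None,
    seed: int = 0,
    **gt_kwargs,
) -> SyntheticDataset:
    """Convenience: default design + ground truth + full simulation."""
    design = make_design(groups=groups, seed=seed)
    gt = sample_ground_truth(
        design, n_states=n_states, n_rois=n_rois, seed=seed, **gt_kwargs
    )
    return simulate_dataset(design, gt, seed=seed)
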