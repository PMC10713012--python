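"""Mean-centred partial least squares with resampling inference.

The data matrix stacks subjects within conditions within groups.  A
centering scheme turns the (group x condition) cell means into a matrix M
whose SVD yields latent variables (LVs): design saliences (one weight per
cell), feature saliences, and singular values.  LV significance comes
from permutation of exchangeable labels; salience reliability from
bootstrap resampling of subjects within group, with each bootstrap's
saliences rotated (orthogonal Procrustes) onto the original before the
standard errors are accumulated.  A bootstrap ratio (original weight /
bootstrap SE) is read like a z-score.

Centering schemes
-----------------
group_main      group means minus the grand mean: isolates group effects.
within_group    condition means minus their own group mean: group main
                effect exactly zero, isolates task and task-by-group.
full_factorial  all cell means minus the grand mean: group, task, and
                interaction together.

Cell means are unweighted throughout (the grand mean is the mean of cell
means), so unequal group sizes do not tilt the contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCHEMES = ("group_main", "within_group", "full_factorial")


@dataclass
class StackedDataMatrix:
    """Subject x condition feature rows in canonical order.

    ``tensor`` is (n_subjects, n_conditions, n_features); ``subject_group``
    holds the group index of every subject.  The flat row view (group,
    then condition, then subject) is what LV scores are computed on.
    """

    tensor: np.ndarray
    subjects: list[str]
    subject_group: np.ndarray  # (n_subjects,) indices into group_order
    group_order: list[str]
    condition_order: list[str]
    feature_names: list[str]
    dropped_subjects: list[str] = field(default_factory=list)
    dropped_features: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_features(self) -> int:
        return self.tensor.shape[2]

    def rows(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Flat (X, metadata) in canonical group/condition/subject order."""
        X, meta = [], []
        for g, group in enumerate(self.group_order):
            sidx = np.where(self.subject_group == g)[0]
            for c, cond in enumerate(self.condition_order):
                for i in sidx:
                    X.append(self.tensor[i, c])
                    meta.append(
                        {"group": group, "condition": cond,
                         "subject": self.subjects[i]}
                    )
        return np.asarray(X), pd.DataFrame(meta)


def build_datamat(
    table: pd.DataFrame,
    group_order: list[str] | None = None,
    condition_order: list[str] | None = None,
) -> StackedDataMatrix:
    """Assemble the stacked matrix from a tidy feature table.

    ``table`` needs columns subject, group, condition plus one column per
    feature.  Feature columns containing any NaN are removed (and logged
    on the result); subjects missing any condition are dropped entirely.
    An empty (group, condition) cell after removal is an error.
    """
    needed = {"subject", "group", "condition"}
    if not needed.issubset(table.columns):
        raise ValueError(f"feature table needs columns {sorted(needed)}")
    feature_names = [c for c in table.columns if c not in needed]
    if not feature_names:
        raise ValueError("no feature columns")
    if group_order is None:
        group_order = list(dict.fromkeys(table["group"]))
    if condition_order is None:
        condition_order = list(dict.fromkeys(table["condition"]))

    dropped_features = [
        c for c in feature_names if table[c].isna().any()
    ]
    kept = [c for c in feature_names if c not in dropped_features]
    if not kept:
        raise ValueError("every feature column contains missing values")
    if dropped_features:
        warnings.warn(
            f"dropping {len(dropped_features)} feature(s) with missing "
            f"values: {dropped_features[:5]}...",
            stacklevel=2,
        )

    dup = table.duplicated(subset=["subject", "condition"])
    if dup.any():
        raise ValueError("duplicate (subject, condition) rows")

    by_subject = {s: t for s, t in table.groupby("subject")}
    subjects, groups, blocks, dropped_subjects = [], [], [], []
    for s in sorted(by_subject):
        t = by_subject[s]
        have = set(t["condition"])
        if not set(condition_order) <= have:
            dropped_subjects.append(s)
            continue
        t = t.set_index("condition")
        blocks.append(
            np.stack([t.loc[c, kept].to_numpy(dtype=float)
                      for c in condition_order])
        )
        subjects.append(s)
        groups.append(t["group"].iloc[0])
    if dropped_subjects:
        warnings.warn(
            f"dropping {len(dropped_subjects)} subject(s) missing a "
            f"condition: {dropped_subjects[:5]}...",
            stacklevel=2,
        )
    group_idx = np.array([group_order.index(g) for g in groups])
    for g, group in enumerate(group_order):
        if not np.any(group_idx == g):
            raise ValueError(f"cell ({group!r}, *) is empty after removal")
    return StackedDataMatrix(
        tensor=np.stack(blocks),
        subjects=subjects,
        subject_group=group_idx,
        group_order=list(group_order),
        condition_order=list(condition_order),
        feature_names=kept,
        dropped_subjects=dropped_subjects,
        dropped_features=dropped_features,
    )


# ---------------------------------------------------------------------------
# centering and SVD


def _cell_means(tensor: np.ndarray, group_idx: np.ndarray,
                n_groups: int) -> np.ndarray:
    """(n_groups, n_conditions, n_features) unweighted cell means."""
    out = np.empty((n_groups,) + tensor.shape[1:])
    for g in range(n_groups):
        sel = tensor[group_idx == g]
        if len(sel) == 0:
            raise ValueError(f"group index {g} has no subjects")
        out[g] = sel.mean(axis=0)
    return out


def mean_centre(
    dm: StackedDataMatrix,
    scheme: str,
    tensor: np.ndarray | None = None,
    group_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Centered mean matrix M (cells x features) for a scheme.

    Returns (M, cells) where cells describes each row's group/condition.
    ``tensor``/``group_idx`` override the stored data (used by the
    resampling loops).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown centering scheme {scheme!r}")
    tensor = dm.tensor if tensor is None else tensor
    group_idx = dm.subject_group if group_idx is None else group_idx
    G, C = len(dm.group_order), len(dm.condition_order)
    cells3 = _cell_means(tensor, group_idx, G)  # (G, C, F)
    if scheme == "group_main":
        gmeans = cells3.mean(axis=1)  # (G, F)
        grand = gmeans.mean(axis=0)
        M = gmeans - grand
        cells = pd.DataFrame(
            {"group": dm.group_order, "condition": ["all"] * G}
        )
    elif scheme == "within_group":
        M = cells3 - cells3.mean(axis=1, keepdims=True)
        M = M.reshape(G * C, -1)
        cells = pd.DataFrame(
            [{"group": g, "condition": c}
             for g in dm.group_order for c in dm.condition_order]
        )
    else:  # full_factorial
        grand = cells3.reshape(G * C, -1).mean(axis=0)
        M = cells3.reshape(G * C, -1) - grand
        cells = pd.DataFrame(
            [{"group": g, "condition": c}
             for g in dm.group_order for c in dm.condition_order]
        )
    return np.asarray(M, float), cells


def pls_svd(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the centered mean matrix with a fixed sign convention.

    Returns (U, s, V): design saliences (cells x L), singular values
    (descending), feature saliences (features x L).  Each LV is flipped so
    its largest-magnitude feature salience is positive.
    """
    M = np.asarray(M, float)
    if M.size == 0:
        raise ValueError("empty mean matrix")
    if not np.any(M):
        warnings.warn("mean matrix is all zero; no latent variables",
                      stacklevel=2)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    V = Vt.T
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] *= -1
            U[:, j] *= -1
    return U, s, V


def lv_scores(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """LV scores: dot product of each data row with each feature salience."""
    return np.asarray(X, float) @ np.asarray(V, float)


# ---------------------------------------------------------------------------
# inference


def _perm_group_labels(group_idx: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    return rng.permutation(group_idx)


def _perm_conditions(tensor: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(tensor)
    C = tensor.shape[1]
    for i in range(tensor.shape[0]):
        out[i] = tensor[i, rng.permutation(C)]
    return out


def permutation_test(
    dm: StackedDataMatrix,
    scheme: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Permutation p-value per LV (add-one estimator).

    Exchangeability follows the scheme: group-contrast schemes
    (group_main, full_factorial) permute group labels across subjects;
    within_group permutes condition labels within each subject.
    p_i = (1 + #{s_perm_i >= s_obs_i}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    M, _ = mean_centre(dm, scheme)
    _, s_obs, _ = pls_svd(M)
    L = len(s_obs)
    exceed = np.zeros(L)
    for _ in range(n_perm):
        if scheme == "within_group":
            t = _perm_conditions(dm.tensor, rng)
            Mp, _ = mean_centre(dm, scheme, tensor=t)
        else:
            gi = _perm_group_labels(dm.subject_group, rng)
            Mp, _ = mean_centre(dm, scheme, group_idx=gi)
        s_perm = np.linalg.svd(Mp, compute_uv=False)
        m = min(L, len(s_perm))
        exceed[:m] += s_perm[:m] >= s_obs[:m]
    return (1.0 + exceed) / (1.0 + n_perm)


def _procrustes_rotation(V_ref: np.ndarray, V_boot: np.ndarray) -> np.ndarray:
    """Orthogonal rotation R minimising ||V_boot R - V_ref||_F."""
    P, _, Qt = np.linalg.svd(V_boot.T @ V_ref)
    return P @ Qt


@dataclass
class BootstrapResult:
    bootstrap_ratios: np.ndarray  # (n_features, L)
    salience_se: np.ndarray  # (n_features, L)
    score_ci_low: np.ndarray  # (n_cells, L)
    score_ci_high: np.ndarray  # (n_cells, L)
    cells: pd.DataFrame
    n_boot: int


def bootstrap_test(
    dm: StackedDataMatrix,
    scheme: str,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> BootstrapResult:
    """Bootstrap (subjects resampled with replacement within group).

    Each bootstrap's saliences are aligned to the original solution by
    orthogonal Procrustes rotation before standard errors accumulate;
    this removes the sign/rotation indeterminacy of the SVD.  Score CIs
    are 95% percentile intervals of the cell-mean LV scores (scores under
    the aligned bootstrap saliences).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    counts = np.bincount(dm.subject_group, minlength=len(dm.group_order))
    if (counts < 2).any():
        raise ValueError("need >= 2 subjects per group to bootstrap")
    M, cells = mean_centre(dm, scheme)
    U, s, V = pls_svd(M)
    L = V.shape[1]
    G = len(dm.group_order)
    group_members = [np.where(dm.subject_group == g)[0] for g in range(G)]

    # variability must be assessed on the singular-value-scaled saliences:
    # when L equals the feature count the unscaled V's form complete
    # orthonormal bases and Procrustes would align them perfectly,
    # collapsing the SE to zero.
    Vs = V * s[None, :]
    v_samples = np.empty((n_boot, V.shape[0], L))
    score_samples = np.empty((n_boot, M.shape[0], L))
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(group_members[g], size=len(group_members[g]),
                        replace=True) for g in range(G)]
        )
        tensor_b = dm.tensor[idx]
        gi_b = dm.subject_group[idx]
        Mb, _ = mean_centre(dm, scheme, tensor=tensor_b, group_idx=gi_b)
        _, sb, Vb = pls_svd(Mb)
        m = min(L, Vb.shape[1])
        R = _procrustes_rotation(V[:, :m], Vb[:, :m])
        Vb_al = Vb[:, :m] @ R
        v_samples[b, :, :m] = (Vb[:, :m] * sb[None, :m]) @ R
        if m < L:
            v_samples[b, :, m:] = 0.0
        # centered cell means of the resample, scored with the aligned
        # saliences (same construction as the observed cell scores M @ V)
        score_samples[b, :, :m] = Mb @ Vb_al
        if m < L:
            score_samples[b, :, m:] = np.nan

    se = v_samples.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        br = np.where(
            se > 0, Vs / se, np.where(Vs == 0, 0.0, np.inf * np.sign(Vs))
        )
    lo = np.nanpercentile(score_samples, 2.5, axis=0)
    hi = np.nanpercentile(score_samples, 97.5, axis=0)
    return BootstrapResult(
        bootstrap_ratios=br, salience_se=se, score_ci_low=lo,
        score_ci_high=hi, cells=cells, n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# one-call wrapper


@dataclass
class PLSResult:
    """Full mean-centred PLS output for one analysis."""

    scheme: str
    singular_values: np.ndarray
    design_saliences: pd.DataFrame  # cells x LVs
    feature_saliences: pd.DataFrame  # features x LVs
    subject_scores: pd.DataFrame  # row metadata + LV score columns
    perm_p: np.ndarray
    bootstrap_ratios: pd.DataFrame  # features x LVs
    score_ci_low: pd.DataFrame
    score_ci_high: pd.DataFrame
    n_perm: int
    n_boot: int
    seed: int

    def significant_lvs(self, alpha: float = 0.05) -> list[int]:
        return [i for i, p in enumerate(self.perm_p) if p < alpha]


def run_pls(
    dm: StackedDataMatrix,
    scheme: str,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> PLSResult:
    """Mean-centred PLS with permutation and bootstrap inference."""
    M, cells = mean_centre(dm, scheme)
    U, s, V = pls_svd(M)
    lv_names = [f"lv{i + 1}" for i in range(len(s))]
    X, meta = dm.rows()
    scores = pd.concat(
        [meta, pd.DataFrame(lv_scores(X, V), columns=lv_names)], axis=1
    )
    p = permutation_test(dm, scheme, n_perm=n_perm, seed=seed)
    boot = bootstrap_test(dm, scheme, n_boot=n_boot, seed=seed + 1)
    cell_index = pd.Index(
        [f"{g}|{c}" for g, c in zip(cells["group"], cells["condition"])],
        name="cell",
    )
    feats = pd.Index(dm.feature_names, name="feature")
    return PLSResult(
        scheme=scheme,
        singular_values=s,
        design_saliences=pd.DataFrame(U, index=cell_index, columns=lv_names),
        feature_saliences=pd.DataFrame(V, index=feats, columns=lv_names),
        subject_scores=scores,
        perm_p=p,
        bootstrap_ratios=pd.DataFrame(
            boot.bootstrap_ratios, index=feats, columns=lv_names
        ),
        score_ci_low=pd.DataFrame(
            boot.score_ci_low, index=cell_index, columns=lv_names
        ),
        score_ci_high=pd.DataFrame(
            boot.score_ci_high, index=cell_index, columns=lv_names
        ),
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
    )
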