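"""State-path metrics: fractional occupancy, transitional probability,
per-excerpt summaries, rating correlations, and functional connectivity.

Fractional occupancy (FO) is the proportion of volumes inside a set of
windows spent in each state.  Transitional probability (TP) is the
row-normalised matrix of empirical one-step transitions; its diagonal is
the persistence (probability of staying in a state).  Both are computed
from the hard decoded path, and transitions are only ever counted between
consecutive volumes that lie inside the same window — never across window
or subject boundaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EventTable, ParcellatedTimeSeries
from .design import CATEGORIES

CONDITIONS = ("all",) + CATEGORIES + ("rest",)


# ---------------------------------------------------------------------------
# windows


def excerpt_windows(
    events: EventTable, tr_seconds: float, n_volumes: int
) -> list[tuple[int, int]]:
    """Half-open volume index ranges [floor(onset/tr), floor(end/tr)).

    Rating gaps after each excerpt are not part of any window.  Ranges are
    clipped to [0, n_volumes); a window entirely outside the run is an
    error.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    windows = []
    for i, row in events.frame.iterrows():
        a = int(np.floor(row["onset"] / tr_seconds))
        b = int(np.floor((row["onset"] + row["duration"]) / tr_seconds))
        if a >= n_volumes or b <= 0:
            raise ValueError(
                f"event {i} (onset {row['onset']} s) lies entirely outside "
                f"the run of {n_volumes} volumes"
            )
        windows.append((max(a, 0), min(b, n_volumes)))
    return windows


def _window_union(windows: list[tuple[int, int]]) -> np.ndarray:
    if not windows:
        return np.empty(0, dtype=int)
    idx = np.concatenate([np.arange(a, b) for a, b in windows])
    return np.unique(idx)


# ---------------------------------------------------------------------------
# occupancy and transitions


def fractional_occupancy(
    states: np.ndarray, windows: list[tuple[int, int]], n_states: int
) -> np.ndarray | None:
    """FO over the union of windows; None when the union is empty."""
    states = np.asarray(states, int)
    idx = _window_union(windows)
    if idx.size == 0:
        return None
    counts = np.bincount(states[idx], minlength=n_states)
    return counts / idx.size


def transitional_probability(
    states: np.ndarray, windows: list[tuple[int, int]], n_states: int
) -> tuple[np.ndarray, np.ndarray]:
    """Within-window transition counts and the row-normalised TP matrix.

    Rows with no outgoing transitions are left undefined (NaN), never
    imputed.
    """
    states = np.asarray(states, int)
    counts = np.zeros((n_states, n_states), dtype=int)
    for a, b in windows:
        if b - a >= 2:
            np.add.at(counts, (states[a : b - 1], states[a + 1 : b]), 1)
    row_sums = counts.sum(axis=1)
    tp = np.full((n_states, n_states), np.nan)
    nz = row_sums > 0
    tp[nz] = counts[nz] / row_sums[nz, None]
    return counts, tp


def _condition_windows(
    events: EventTable, tr_seconds: float, n_volumes: int
) -> dict[str, list[tuple[int, int]]]:
    """Volume windows per condition.

    ``all`` is the full run; each category is the union of its excerpt
    windows; ``rest`` is the leading rest block (everything before the
    first excerpt onset, the whole run if there are no excerpts).
    """
    win = excerpt_windows(events, tr_seconds, n_volumes)
    out: dict[str, list[tuple[int, int]]] = {"all": [(0, n_volumes)]}
    cats = list(events.frame["category"]) if len(events) else []
    for c in CATEGORIES:
        out[c] = [w for w, cat in zip(win, cats) if cat == c]
    if win:
        first = min(a for a, _ in win)
        out["rest"] = [(0, first)] if first > 0 else []
    else:
        out["rest"] = [(0, n_volumes)]
    return out


def occupancy_table(
    states: np.ndarray,
    events: EventTable,
    tr_seconds: float,
    n_states: int,
) -> pd.DataFrame:
    """Tidy FO per condition: columns condition, state, fo.

    Conditions with no volumes yield NaN rows (flagged missing).
    """
    states = np.asarray(states, int)
    cond_windows = _condition_windows(events, tr_seconds, len(states))
    rows = []
    for cond in CONDITIONS:
        fo = fractional_occupancy(states, cond_windows[cond], n_states)
        for k in range(n_states):
            rows.append(
                {"condition": cond, "state": k,
                 "fo": np.nan if fo is None else fo[k]}
            )
    return pd.DataFrame(rows)


def transition_table(
    states: np.ndarray,
    events: EventTable,
    tr_seconds: float,
    n_states: int,
) -> pd.DataFrame:
    """Tidy TP per condition: condition, from_state, to_state, count, tp."""
    states = np.asarray(states, int)
    cond_windows = _condition_windows(events, tr_seconds, len(states))
    rows = []
    for cond in CONDITIONS:
        counts, tp = transitional_probability(
            states, cond_windows[cond], n_states
        )
        for i in range(n_states):
            for j in range(n_states):
                rows.append(
                    {"condition": cond, "from_state": i, "to_state": j,
                     "count": counts[i, j], "tp": tp[i, j]}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-excerpt metrics and rating correlations


def per_excerpt_metrics(
    states: np.ndarray,
    events: EventTable,
    tr_seconds: float,
    n_states: int,
    min_volumes: int = 2,
) -> pd.DataFrame:
    """One FO vector and one row-major vectorised TP per excerpt.

    Columns: excerpt, category, liking, familiarity, n_volumes, valid,
    fo_<k> for each state, tp_<i>_<j> row-major (undefined entries NaN).
    Excerpts shorter than ``min_volumes`` are flagged invalid and their
    metrics left missing.
    """
    states = np.asarray(states, int)
    windows = excerpt_windows(events, tr_seconds, len(states))
    rows = []
    for i, ((a, b), (_, ev)) in enumerate(
        zip(windows, events.frame.iterrows())
    ):
        row: dict = {
            "excerpt": i,
            "category": ev["category"],
            "liking": ev["liking"],
            "familiarity": ev["familiarity"],
            "n_volumes": b - a,
            "valid": (b - a) >= min_volumes,
        }
        if row["valid"]:
            fo = fractional_occupancy(states, [(a, b)], n_states)
            _, tp = transitional_probability(states, [(a, b)], n_states)
        else:
            fo = np.full(n_states, np.nan)
            tp = np.full((n_states, n_states), np.nan)
        for k in range(n_states):
            row[f"fo_{k}"] = fo[k]
        for p in range(n_states):
            for q in range(n_states):
                row[f"tp_{p}_{q}"] = tp[p, q]
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_ratings(
    excerpt_metrics: pd.DataFrame,
    method: str = "pearson",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Across-excerpt correlation of each metric column with each rating.

    Returns a frame indexed by feature (fo_*/tp_*) with columns liking and
    familiarity.  Missing entries are pairwise-deleted; columns with fewer
    than ``min_pairs`` complete pairs or zero variance come back NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    feats = [c for c in excerpt_metrics.columns
             if c.startswith("fo_") or c.startswith("tp_")]
    sub = excerpt_metrics.loc[excerpt_metrics["valid"].astype(bool)]
    if len(sub) == 0 or sub[["liking", "familiarity"]].isna().all().all():
        raise ValueError("no rated, valid excerpts to correlate")
    out = {}
    for rating in ("liking", "familiarity"):
        r = sub[rating].astype(float)
        vals = []
        for f in feats:
            x = sub[f].astype(float)
            ok = x.notna() & r.notna()
            if ok.sum() < min_pairs or x[ok].std() == 0 or r[ok].std() == 0:
                vals.append(np.nan)
            elif method == "pearson":
                vals.append(stats.pearsonr(x[ok], r[ok])[0])
            else:
                vals.append(stats.spearmanr(x[ok], r[ok])[0])
        out[rating] = vals
    return pd.DataFrame(out, index=pd.Index(feats, name="feature"))


def rating_summary(
    events_by_subject: dict[str, tuple[str, EventTable]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Behavioural summary.

    Input maps subject_id -> (group, events).  Returns (per_subject,
    per_group): per-subject mean liking, mean familiarity and the
    within-subject liking-familiarity correlation; group means of each,
    with the count of subjects whose correlation was defined.
    """
    rows = []
    for sid, (group, events) in events_by_subject.items():
        f = events.frame
        lik = f["liking"].astype(float)
        fam = f["familiarity"].astype(float)
        ok = lik.notna() & fam.notna()
        if ok.sum() >= 3 and lik[ok].std() > 0 and fam[ok].std() > 0:
            r = float(stats.pearsonr(lik[ok], fam[ok])[0])
        else:
            r = np.nan
        rows.append(
            {"subject": sid, "group": group,
             "mean_liking": lik.mean(), "mean_familiarity": fam.mean(),
             "liking_familiarity_r": r}
        )
    per_subject = pd.DataFrame(rows)
    per_group = (
        per_subject.groupby("group")
        .agg(
            n=("subject", "size"),
            mean_liking=("mean_liking", "mean"),
            mean_familiarity=("mean_familiarity", "mean"),
            liking_familiarity_r=("liking_familiarity_r", "mean"),
            n_r_defined=("liking_familiarity_r", "count"),
        )
        .reset_index()
    )
    return per_subject, per_group


# ---------------------------------------------------------------------------
# connectivity


def connectivity_matrix(ts: ParcellatedTimeSeries) -> np.ndarray:
    """Pearson functional-connectivity matrix across volumes.

    Symmetric with unit diagonal; constant ROIs give NaN rows/columns.
    """
    if ts.n_volumes < 3:
        raise ValueError("need at least 3 volumes for connectivity")
    data = ts.data
    sd = data.std(axis=1)
    constant = sd < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(data)
    C = 0.5 * (C + C.T)
    C[constant, :] = np.nan
    C[:, constant] = np.nan
    np.fill_diagonal(C, np.where(constant, np.nan, 1.0))
    return C


def vectorize_connectivity(C: np.ndarray) -> np.ndarray:
    """Upper triangle (excluding the diagonal), row-major."""
    iu = np.triu_indices(C.shape[0], k=1)
    return C[iu]
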