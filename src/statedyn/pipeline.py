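"""End-to-end orchestration: dataset directory -> fitted model -> metrics
-> configured PLS analyses -> result tables on disk.

The stage order mirrors the analysis this package reproduces:
normalise each subject's ROI rows, concatenate all subjects, fit (or
select the order of) a group-level Gaussian HMM, decode per-subject state
paths, derive occupancy/transition/rating metrics, and run the requested
mean-centred PLS analyses.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hmm, io, metrics, pls
from .containers import EventTable, ParcellatedTimeSeries
from .design import CATEGORIES

log = logging.getLogger("statedyn")

FEATURE_SOURCES = (
    "FO", "TP", "rating_correlation_FO", "rating_correlation_TP",
    "connectivity", "ratings",
)

__version__ = "0.1.0"


@dataclass
class AnalysisSpec:
    """One PLS analysis: which features, which centering."""

    name: str
    feature: str
    scheme: str
    conditions: str = "categories"  # or "all"

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_SOURCES:
            raise ValueError(f"unknown feature source {self.feature!r}")
        if self.scheme not in pls.SCHEMES:
            raise ValueError(f"unknown centering scheme {self.scheme!r}")


@dataclass
class PipelineConfig:
    dataset_dir: str
    out_dir: str
    k: int | None = 4
    k_range: list[int] | None = None
    n_restarts: int = 3
    max_iter: int = 200
    covariance: str = "full"
    n_perm: int = 500
    n_boot: int = 500
    seed: int = 0
    decode_method: str = "posterior_argmax"
    analyses: list[AnalysisSpec] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["analyses"] = [
            a if isinstance(a, AnalysisSpec) else AnalysisSpec(**a)
            for a in d.get("analyses", [])
        ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["analyses"] = [vars(a).copy() for a in self.analyses]
        return d

    def digest(self) -> str:
        """Hash of everything that determines the numbers (out_dir doesn't)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def default_analyses() -> list[AnalysisSpec]:
    """The analysis battery mirroring the study's result structure."""
    return [
        AnalysisSpec("fo_group", "FO", "group_main", conditions="all"),
        AnalysisSpec("fo_task", "FO", "within_group"),
        AnalysisSpec("tp_group", "TP", "group_main", conditions="all"),
        AnalysisSpec("tp_task", "TP", "within_group"),
        AnalysisSpec("rating_corr_fo", "rating_correlation_FO",
                     "full_factorial"),
        AnalysisSpec("rating_corr_tp", "rating_correlation_TP",
                     "full_factorial"),
        AnalysisSpec("ratings", "ratings", "group_main", conditions="all"),
    ]


@dataclass
class ResultsBundle:
    config: PipelineConfig
    model: hmm.HMMModel
    selection: hmm.ModelSelectionReport | None
    state_paths: dict[str, hmm.StatePath]
    occupancy: pd.DataFrame
    transitions: pd.DataFrame
    excerpt_metrics: dict[str, pd.DataFrame]
    rating_correlations: dict[str, pd.DataFrame]
    rating_subjects: pd.DataFrame
    rating_groups: pd.DataFrame
    pls_results: dict[str, pls.PLSResult]
    manifest: dict


# ---------------------------------------------------------------------------
# feature assembly


def _fo_table(occupancy: pd.DataFrame, conditions: str) -> pd.DataFrame:
    conds = list(CATEGORIES) if conditions == "categories" else ["all"]
    sub = occupancy[occupancy["condition"].isin(conds)].copy()
    sub["feature"] = [f"fo_{k}" for k in sub["state"]]
    # unstack keeps NaN values and only observed index combinations
    wide = sub.set_index(
        ["subject", "group", "condition", "feature"]
    )["fo"].unstack("feature")
    return wide.reset_index()


def _tp_table(transitions: pd.DataFrame, conditions: str) -> pd.DataFrame:
    conds = list(CATEGORIES) if conditions == "categories" else ["all"]
    sub = transitions[transitions["condition"].isin(conds)].copy()
    sub["feature"] = [
        f"tp_{i}_{j}" for i, j in zip(sub["from_state"], sub["to_state"])
    ]
    wide = sub.set_index(
        ["subject", "group", "condition", "feature"]
    )["tp"].unstack("feature")
    return wide.reset_index()


def _rating_corr_table(
    rating_correlations: dict[str, pd.DataFrame],
    groups: dict[str, str],
    prefix: str,
) -> pd.DataFrame:
    """Rows: subject x rating-type; features: per-state (or per-edge)
    correlations.  Rating type plays the condition role, giving the
    full-factorial group x rating-type structure."""
    rows = []
    for sid, corr in rating_correlations.items():
        sub = corr[corr.index.str.startswith(prefix)]
        for rating in ("liking", "familiarity"):
            row = {"subject": sid, "group": groups[sid],
                   "condition": rating}
            row.update(sub[rating].to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def build_features(
    spec: AnalysisSpec, bundle_parts: dict
) -> pd.DataFrame:
    occupancy = bundle_parts["occupancy"]
    transitions = bundle_parts["transitions"]
    groups = bundle_parts["groups"]
    if spec.feature == "FO":
        return _fo_table(occupancy, spec.conditions)
    if spec.feature == "TP":
        return _tp_table(transitions, spec.conditions)
    if spec.feature == "rating_correlation_FO":
        return _rating_corr_table(
            bundle_parts["rating_correlations"], groups, "fo_"
        )
    if spec.feature == "rating_correlation_TP":
        return _rating_corr_table(
            bundle_parts["rating_correlations"], groups, "tp_"
        )
    if spec.feature == "connectivity":
        rows = []
        for sid, ts in bundle_parts["timeseries"].items():
            C = metrics.connectivity_matrix(ts)
            v = metrics.vectorize_connectivity(C)
            row = {"subject": sid, "group": groups[sid], "condition": "all"}
            row.update({f"fc_{i}": x for i, x in enumerate(v)})
            rows.append(row)
        return pd.DataFrame(rows)
    if spec.feature == "ratings":
        per_subject = bundle_parts["rating_subjects"]
        t = per_subject.rename(
            columns={"liking_familiarity_r": "lf_corr"}
        ).copy()
        t["condition"] = "all"
        return t[["subject", "group", "condition", "mean_liking",
                  "mean_familiarity", "lf_corr"]]
    raise ValueError(spec.feature)


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute the full analysis sequence on a dataset directory."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("loading dataset from %s", config.dataset_dir)
    pairs = io.read_dataset(Path(config.dataset_dir))
    series = [hmm.normalize_timeseries(ts) for ts, _ in pairs]
    events = {ts.subject_id: ev for ts, ev in pairs}
    groups = {ts.subject_id: ts.group for ts, _ in pairs}
    log.info("loaded %d subjects (%d volumes each)", len(series),
             series[0].n_volumes)

    X, boundaries = hmm.concatenate_subjects(series)
    fit_kwargs = dict(
        covariance_type=config.covariance, n_restarts=config.n_restarts,
        max_iter=config.max_iter,
    )
    selection = None
    if config.k_range:
        log.info("selecting K over %s", list(config.k_range))
        selection = hmm.select_k(
            X, boundaries, config.k_range, seed=config.seed, **fit_kwargs
        )
        model = selection.models[selection.selected_K]
        log.info("selected K = %d", selection.selected_K)
    else:
        if config.k is None:
            raise ValueError("config must set k or k_range")
        log.info("fitting HMM at fixed K = %d", config.k)
        model = hmm.fit_hmm(
            X, boundaries, config.k, seed=config.seed, **fit_kwargs
        )
    log.info("fit done: loglik %.1f, %d EM iterations, converged=%s",
             model.log_likelihood, model.n_em_iterations, model.converged)

    K = model.n_states
    state_paths, occ_rows, tp_rows = {}, [], []
    excerpt_tables, rating_corrs = {}, {}
    for ts in series:
        path = hmm.decode(model, ts, method=config.decode_method)
        state_paths[ts.subject_id] = path
        ev = events[ts.subject_id]
        occ = metrics.occupancy_table(path.states, ev, ts.tr_seconds, K)
        occ.insert(0, "subject", ts.subject_id)
        occ.insert(1, "group", ts.group)
        occ_rows.append(occ)
        tpt = metrics.transition_table(path.states, ev, ts.tr_seconds, K)
        tpt.insert(0, "subject", ts.subject_id)
        tpt.insert(1, "group", ts.group)
        tp_rows.append(tpt)
        if len(ev):
            pem = metrics.per_excerpt_metrics(
                path.states, ev, ts.tr_seconds, K
            )
            excerpt_tables[ts.subject_id] = pem
            rating_corrs[ts.subject_id] = metrics.correlate_ratings(pem)
    occupancy = pd.concat(occ_rows, ignore_index=True)
    transitions = pd.concat(tp_rows, ignore_index=True)
    rating_subjects, rating_groups = metrics.rating_summary(
        {sid: (groups[sid], ev) for sid, ev in events.items()}
    )
    log.info("metrics done (%.1f s elapsed)", time.time() - t0)

    parts = {
        "occupancy": occupancy, "transitions": transitions,
        "rating_correlations": rating_corrs, "groups": groups,
        "timeseries": {ts.subject_id: ts for ts in series},
        "rating_subjects": rating_subjects,
    }
    pls_results: dict[str, pls.PLSResult] = {}
    for spec in config.analyses:
        log.info("PLS analysis %s (%s, %s)", spec.name, spec.feature,
                 spec.scheme)
        table = build_features(spec, parts)
        dm = pls.build_datamat(table)
        pls_results[spec.name] = pls.run_pls(
            dm, spec.scheme, n_perm=config.n_perm, n_boot=config.n_boot,
            seed=config.seed,
        )

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "n_subjects": len(series),
        "n_volumes": int(series[0].n_volumes),
        "selected_K": K,
        "elapsed_s": round(time.time() - t0, 2),
    }
    bundle = ResultsBundle(
        config=config, model=model, selection=selection,
        state_paths=state_paths, occupancy=occupancy,
        transitions=transitions, excerpt_metrics=excerpt_tables,
        rating_correlations=rating_corrs, rating_subjects=rating_subjects,
        rating_groups=rating_groups, pls_results=pls_results,
        manifest=manifest,
    )
    report(bundle, out_dir)
    return bundle


def report(bundle: ResultsBundle, out_dir: Path) -> list[Path]:
    """Write the result tables mirroring the analysis's summary objects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _tsv(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        p = out_dir / name
        frame.to_csv(p, sep="\t", index=index)
        written.append(p)

    _tsv(bundle.occupancy, "occupancy.tsv")
    _tsv(bundle.transitions, "transitions.tsv")
    _tsv(bundle.rating_subjects, "rating_summary_subjects.tsv")
    _tsv(bundle.rating_groups, "rating_summary_groups.tsv")
    if bundle.selection is not None:
        _tsv(bundle.selection.table, "model_selection.tsv")
    for name, res in bundle.pls_results.items():
        _tsv(res.feature_saliences, f"pls_{name}_saliences.tsv", index=True)
        _tsv(res.bootstrap_ratios, f"pls_{name}_bootstrap_ratios.tsv",
             index=True)
        summary = {
            "scheme": res.scheme,
            "singular_values": res.singular_values.tolist(),
            "perm_p": res.perm_p.tolist(),
            "design_saliences": res.design_saliences.to_dict(),
            "n_perm": res.n_perm,
            "n_boot": res.n_boot,
        }
        p = out_dir / f"pls_{name}_summary.json"
        p.write_text(json.dumps(summary, indent=1))
        written.append(p)
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(bundle.manifest, indent=1))
    written.append(p)
    return written
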