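"""On-disk dataset layout and readers/writers.

Layout (BIDS-derivative-like, one directory per subject):

    dataset/
      manifest.json
      ground_truth.json            # synthetic runs only; test-only sidecar
      sub-001/
        timeseries.tsv             # n_rois rows x n_volumes tab-separated
        timeseries.json            # {subject, group, tr_seconds, ...}
        events.tsv                 # onset  duration  category  liking  familiarity
        true_states.tsv            # synthetic runs only; test-only
      ...
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS, EventTable, ParcellatedTimeSeries

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# time series


def write_timeseries(ts: ParcellatedTimeSeries, subject_dir: Path) -> None:
    subject_dir = Path(subject_dir)
    subject_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(subject_dir / "timeseries.tsv", ts.data,
               delimiter="\t", fmt="%.10g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "subject": ts.subject_id,
        "group": ts.group,
        "tr_seconds": ts.tr_seconds,
        "n_rois": ts.n_rois,
        "n_volumes": ts.n_volumes,
        "normalized": ts.normalized,
    }
    (subject_dir / "timeseries.json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_timeseries(subject_dir: Path) -> ParcellatedTimeSeries:
    """Read a matrix + sidecar; malformed cells are reported by position."""
    subject_dir = Path(subject_dir)
    matrix_path = subject_dir / "timeseries.tsv"
    sidecar_path = subject_dir / "timeseries.json"
    if not matrix_path.exists():
        raise FileNotFoundError(f"missing time-series matrix: {matrix_path}")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar: {sidecar_path}")
    try:
        data = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    except ValueError:
        _locate_bad_token(matrix_path)
        raise
    meta = json.loads(sidecar_path.read_text())
    tr = float(meta.get("tr_seconds", 0))
    if tr <= 0:
        raise ValueError(f"sidecar {sidecar_path} has non-positive tr_seconds")
    return ParcellatedTimeSeries(
        subject_id=str(meta.get("subject", subject_dir.name)),
        group=str(meta.get("group", "")),
        data=data,
        tr_seconds=tr,
        normalized=bool(meta.get("normalized", False)),
    )


def _locate_bad_token(path: Path) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh):
            for j, tok in enumerate(line.rstrip("\n").split("\t")):
                try:
                    float(tok)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric token {tok!r} at row {i}, "
                        f"column {j}"
                    ) from None


# ---------------------------------------------------------------------------
# events


def write_events(events: EventTable, path: Path) -> None:
    f = events.frame.copy()
    for col in ("liking", "familiarity"):
        f[col] = f[col].map(
            lambda v: "" if pd.isna(v) else str(int(v))
        )
    f.to_csv(path, sep="\t", index=False)


def read_events(path: Path) -> EventTable:
    """Parse an events TSV; schema and rating range are enforced."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing events file: {path}")
    frame = pd.read_csv(path, sep="\t", dtype={"category": str})
    got = tuple(frame.columns)
    if got != EVENT_COLUMNS:
        raise ValueError(
            f"{path}: header {got} does not match expected {EVENT_COLUMNS}"
        )
    try:
        return EventTable(frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# whole datasets


def write_dataset(dataset, directory: Path) -> dict:
    """Write a synthetic dataset; returns (and writes) the manifest.

    The ground-truth sidecar and true state paths are flagged test-only:
    they exist so recovery tests can compare against the generator, and a
    real analysis must never read them.
    """
    from .synthetic import SyntheticDataset  # local import, avoids cycle

    assert isinstance(dataset, SyntheticDataset)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"schema_version": SCHEMA_VERSION, "subjects": []}
    for sub in dataset.subjects:
        sdir = directory / sub.subject_id
        write_timeseries(sub.timeseries, sdir)
        write_events(sub.events, sdir / "events.tsv")
        np.savetxt(sdir / "true_states.tsv", sub.true_path.states[None],
                   delimiter="\t", fmt="%d")
        manifest["subjects"].append(
            {"subject": sub.subject_id, "group": sub.group,
             "files": ["timeseries.tsv", "timeseries.json", "events.tsv",
                       "true_states.tsv"]}
        )
    if dataset.subjects:
        gt = dataset.ground_truth
        gt_doc = {
            "schema_version": SCHEMA_VERSION,
            "test_only": True,
            "note": "generator ground truth; never an analysis input",
            "n_states": gt.n_states,
            "n_rois": gt.n_rois,
            "reward_state": gt.reward_state,
            "perception_state": gt.perception_state,
            "state_means": gt.state_means.tolist(),
            "state_covs": gt.state_covs.tolist(),
            "initial_probs": gt.initial_probs.tolist(),
            "tp_by_cell": {
                f"{g}|{c}": tp.tolist()
                for (g, c), tp in gt.tp_by_cell.items()
            },
            "rating_coupling": {
                g: vars(rc).copy() for g, rc in gt.rating_coupling.items()
            },
            "seed": gt.seed,
        }
        (directory / "ground_truth.json").write_text(
            json.dumps(gt_doc)
        )
        manifest["ground_truth"] = "ground_truth.json"
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_dataset(
    directory: Path,
) -> list[tuple[ParcellatedTimeSeries, EventTable]]:
    """Load every subject (time series + events) from a dataset directory."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        subject_dirs = [directory / s["subject"]
                        for s in manifest["subjects"]]
    else:
        subject_dirs = sorted(
            p for p in directory.iterdir()
            if p.is_dir() and (p / "timeseries.tsv").exists()
        )
    out = []
    for sdir in subject_dirs:
        ts = read_timeseries(sdir)
        events_path = sdir / "events.tsv"
        events = read_events(events_path) if events_path.exists() \
            else EventTable.empty()
        out.append((ts, events))
    if not out:
        raise FileNotFoundError(f"no subjects found under {directory}")
    return out


def read_true_states(directory: Path, subject_id: str) -> np.ndarray:
    return np.loadtxt(
        Path(directory) / subject_id / "true_states.tsv",
        delimiter="\t", dtype=int, ndmin=1,
    ).ravel()
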