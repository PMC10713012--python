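"""Study design: the timing skeleton of a music-listening fMRI run.

A run is a leading rest block followed by a randomised sequence of short
musical excerpts.  Each excerpt is followed by a fixed gap in which the
subject rates familiarity and liking; those rating prompts are scheduled
(they consume scan time) but are never part of an excerpt's analysis
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CATEGORIES = ("self_selected", "popular", "novel")

#: default number of excerpts per category: 6 self-selected, 10 popular, 8 novel
DEFAULT_CATEGORY_COUNTS = {"self_selected": 6, "popular": 10, "novel": 8}

DEFAULT_GROUPS = {"younger": 44, "older": 27}


@dataclass(frozen=True)
class Excerpt:
    """One scheduled musical excerpt."""

    onset_s: float
    duration_s: float
    category: str
    rating_gap_s: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class StudyDesign:
    """Timing and group structure of one study run.

    groups maps group label -> subject count; excerpt order is a seeded
    permutation so two designs with the same seed are identical.
    """

    groups: dict[str, int]
    tr_seconds: float
    n_volumes: int
    rest_duration_s: float
    excerpts: tuple[Excerpt, ...]
    seed: int = 0

    @property
    def total_duration_s(self) -> float:
        """Run length in seconds (n_volumes x TR)."""
        return self.n_volumes * self.tr_seconds

    @property
    def n_subjects(self) -> int:
        return sum(self.groups.values())

    @property
    def scheduled_s(self) -> float:
        """Rest plus every excerpt and its rating gap, in seconds."""
        return self.rest_duration_s + sum(
            e.duration_s + e.rating_gap_s for e in self.excerpts
        )

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for e in self.excerpts:
            counts[e.category] += 1
        return counts

    def condition_per_volume(self) -> np.ndarray:
        """Condition label for every volume.

        Volumes inside an excerpt window carry that excerpt's category;
        everything else (leading rest, rating gaps, tail) is ``rest``.
        """
        cond = np.array(["rest"] * self.n_volumes, dtype=object)
        for e in self.excerpts:
            start = int(np.floor(e.onset_s / self.tr_seconds))
            stop = int(np.floor(e.end_s / self.tr_seconds))
            cond[max(start, 0) : min(stop, self.n_volumes)] = e.category
        return cond


def make_design(
    groups: dict[str, int] | None = None,
    tr_seconds: float = 0.475,
    n_volumes: int = 1440,
    category_counts: dict[str, int] | None = None,
    excerpt_duration_s: float = 20.0,
    rating_gap_s: float = 4.0,
    rest_duration_s: float | None = None,
    seed: int = 0,
) -> StudyDesign:
    """Build a run schedule: rest block, then shuffled excerpts.

    Defaults reproduce the study protocol: TR 475 ms, 1,440 volumes
    (11.4 min), 24 excerpts of 20 s (6 self-selected / 10 popular /
    8 novel), each followed by a 2 s + 2 s rating prompt.  The rest block
    defaults to whatever run time the stimuli do not use (~108 s).

    Raises
    ------
    ValueError
        If the schedule does not fit in the run, reporting the overflow
        in seconds.
    """
    if tr_seconds <= 0 or n_volumes <= 0:
        raise ValueError("tr_seconds and n_volumes must be positive")
    groups = dict(groups) if groups is not None else dict(DEFAULT_GROUPS)
    if any(n <= 0 for n in groups.values()):
        raise ValueError("every group must have a positive subject count")
    counts = (
        dict(category_counts)
        if category_counts is not None
        else dict(DEFAULT_CATEGORY_COUNTS)
    )
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown excerpt categories: {sorted(unknown)}")
    if any(c < 0 for c in counts.values()):
        raise ValueError("category counts must be non-negative")

    run_s = n_volumes * tr_seconds
    n_excerpts = sum(counts.values())
    stimulus_s = n_excerpts * (excerpt_duration_s + rating_gap_s)
    if rest_duration_s is None:
        rest_duration_s = run_s - stimulus_s
        if rest_duration_s < 0:
            raise ValueError(
                f"schedule overflows the run by {-rest_duration_s:.3f} s "
                f"(stimuli need {stimulus_s:.3f} s, run is {run_s:.3f} s)"
            )
    total = rest_duration_s + stimulus_s
    if rest_duration_s < 0:
        raise ValueError("rest_duration_s must be non-negative")
    if total > run_s + 1e-9:
        raise ValueError(
            f"schedule overflows the run by {total - run_s:.3f} s "
            f"(scheduled {total:.3f} s, run is {run_s:.3f} s)"
        )

    # stimuli presented in randomised order
    labels = [c for c in CATEGORIES for _ in range(counts.get(c, 0))]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    excerpts = []
    onset = rest_duration_s
    for idx in order:
        excerpts.append(
            Excerpt(
                onset_s=onset,
                duration_s=excerpt_duration_s,
                category=labels[idx],
                rating_gap_s=rating_gap_s,
            )
        )
        onset += excerpt_duration_s + rating_gap_s

    return StudyDesign(
        groups=groups,
        tr_seconds=tr_seconds,
        n_volumes=n_volumes,
        rest_duration_s=float(rest_duration_s),
        excerpts=tuple(excerpts),
        seed=seed,
    )
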