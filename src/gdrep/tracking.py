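"""Longitudinal clone tracking across treatment phases.

Clones of one subject are matched across ordered timepoints by the standard
(v_gene, j_gene, cdr3_aa) key.  A clone present at the baseline timepoint is
PreExisted; otherwise it is a Neo clone labeled by the phase of its first
detection: TA (TKI phase), RA (radiotherapy phase), PA (anti-PD-1 phase).
Detection is count >= min_count (default 1); with expanded_only, detection
is membership in that timepoint's expanded set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import normalized_shannon
from .expansion import call_expanded
from .io import Repertoire, SubsetSpec, get_subset
from .io import subset as _subset

Key = tuple[str, str, str]

#: phase -> trajectory label
PHASE_LABELS = {"baseline": "PreExisted", "TKI": "TA", "radio": "RA", "PD1": "PA"}
LABELS = ("PreExisted", "TA", "RA", "PA")


@dataclass
class PhaseSchedule:
    """Ordered timepoints with their treatment phase for one subject."""

    subject_id: str
    timepoints: list[str]
    phases: dict[str, str]

    def __post_init__(self) -> None:
        missing = [t for t in self.timepoints if t not in self.phases]
        if missing:
            raise ValueError(f"timepoint(s) without a phase: {missing}")
        bad = sorted(set(self.phases.values()) - set(PHASE_LABELS))
        if bad:
            raise ValueError(f"unknown phase(s) {bad}; use {sorted(PHASE_LABELS)}")
        baselines = [t for t in self.timepoints if self.phases[t] == "baseline"]
        if not baselines:
            raise ValueError("schedule needs at least one baseline timepoint")
        if self.phases[self.timepoints[0]] != "baseline":
            raise ValueError("the first timepoint must be a baseline")

    @property
    def baseline_timepoints(self) -> list[str]:
        return [t for t in self.timepoints if self.phases[t] == "baseline"]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_id: str) -> "PhaseSchedule":
        """Build from a metadata table with timepoint and phase columns."""
        sub = df[df["subject_id"] == subject_id].sort_values("timepoint")
        return cls(
            subject_id=subject_id,
            timepoints=list(sub["timepoint"]),
            phases=dict(zip(sub["timepoint"], sub["phase"])),
        )


DEFAULT_SCHEDULE = PhaseSchedule(
    subject_id="ATC-06",
    timepoints=["T1", "T2", "T3", "T4", "T5", "T6"],
    phases={
        "T1": "baseline",
        "T2": "TKI",
        "T3": "TKI",
        "T4": "TKI",
        "T5": "radio",
        "T6": "PD1",
    },
)


@dataclass
class CloneTrajectory:
    """Per-clone presence and abundance across ordered timepoints."""

    key: Key
    counts: dict[str, int]
    frequencies: dict[str, float]
    label: str
    first_detected: str

    def present_at(self, timepoint: str) -> bool:
        return self.counts.get(timepoint, 0) > 0


def classify_clones(
    reps: dict[str, Repertoire],
    schedule: PhaseSchedule,
    subset: str | SubsetSpec = "all",
    expanded_only: bool = False,
    min_count: int = 1,
) -> list[CloneTrajectory]:
    """Track and label every clone detected at any scheduled timepoint.

    ``reps`` maps timepoint -> repertoire.  Presence at baseline (union over
    multiple baseline points) gives PreExisted; otherwise the phase of the
    first detection assigns TA/RA/PA.  Labels never change when later
    timepoints are appended.
    """
    missing = [t for t in reps if t not in schedule.phases]
    if missing:
        raise ValueError(f"timepoint(s) not in schedule: {sorted(missing)}")
    spec = get_subset(subset)
    subs = {t: _subset(reps[t], spec) for t in schedule.timepoints if t in reps}

    detected: dict[str, set[Key]] = {}
    counts: dict[str, dict[Key, int]] = {}
    freqs: dict[str, dict[Key, float]] = {}
    for t, sub in subs.items():
        total = sub.total_count
        counts[t] = {c.key: c.count for c in sub.clonotypes}
        freqs[t] = {c.key: c.count / total for c in sub.clonotypes} if total else {}
        if expanded_only and sub.n_unique:
            exp = call_expanded(sub)
            detected[t] = {c.key for c in exp.clonotypes if c.count >= min_count}
        else:
            detected[t] = {k for k, n in counts[t].items() if n >= min_count}

    all_keys = set().union(*detected.values()) if detected else set()
    baseline_keys = set().union(
        *(detected.get(t, set()) for t in schedule.baseline_timepoints)
    )
    trajectories = []
    ordered = [t for t in schedule.timepoints if t in subs]
    for key in sorted(all_keys):
        first = next(t for t in ordered if key in detected[t])
        if key in baseline_keys:
            label, first = "PreExisted", next(
                t for t in schedule.baseline_timepoints if key in detected[t]
            )
        else:
            label = PHASE_LABELS[schedule.phases[first]]
        trajectories.append(
            CloneTrajectory(
                key=key,
                counts={t: counts[t].get(key, 0) for t in ordered},
                frequencies={t: freqs[t].get(key, 0.0) for t in ordered},
                label=label,
                first_detected=first,
            )
        )
    return trajectories


def neo_frequency_series(
    trajectories: list[CloneTrajectory],
    label_set: tuple[str, ...] = ("TA", "RA", "PA"),
    include_undetected: bool = False,
) -> pd.DataFrame:
    """Mean clone frequency (± SE) of labeled clones at each timepoint.

    At each timepoint, the mean is over clones in ``label_set`` already
    detected by then (their frequency may be 0 if they dropped out).  With
    ``include_undetected`` every clone contributes from the start, counting
    0 before first detection.
    """
    if not label_set:
        raise ValueError("label_set must not be empty")
    chosen = [tr for tr in trajectories if tr.label in label_set]
    if not trajectories:
        return pd.DataFrame(columns=["timepoint", "mean", "se", "n"])
    timepoints = list(trajectories[0].counts)
    rows = []
    for i, t in enumerate(timepoints):
        vals = []
        for tr in chosen:
            emerged = timepoints.index(tr.first_detected) <= i
            if include_undetected or emerged:
                vals.append(tr.frequencies.get(t, 0.0))
        n = len(vals)
        mean = float(np.mean(vals)) if n else float("nan")
        se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append({"timepoint": t, "mean": mean, "se": se, "n": n})
    return pd.DataFrame(rows)


def category_composition(trajectories: list[CloneTrajectory]) -> pd.DataFrame:
    """Share of each label among clones present at each timepoint.

    Shares sum to 1 over the labels present; an empty timepoint yields no
    rows.
    """
    if not trajectories:
        return pd.DataFrame(columns=["timepoint", "label", "share", "clones"])
    timepoints = list(trajectories[0].counts)
    rows = []
    for t in timepoints:
        present = [tr for tr in trajectories if tr.present_at(t)]
        if not present:
            continue
        for label in LABELS:
            n = sum(1 for tr in present if tr.label == label)
            if n:
                rows.append(
                    {"timepoint": t, "label": label, "share": n / len(present), "clones": n}
                )
    return pd.DataFrame(rows)


def intersection_counts(
    trajectories: list[CloneTrajectory],
) -> tuple[dict[tuple[str, ...], int], dict[str, int]]:
    """Exclusive timepoint-combination clone counts plus per-timepoint marginals.

    Each clone is counted once, in the combination equal to its exact
    presence pattern (the cells of an upset plot); marginals give the unique
    clone count per timepoint.
    """
    if not trajectories:
        return {}, {}
    timepoints = list(trajectories[0].counts)
    if len(timepoints) < 2:
        raise ValueError("intersection counts need at least 2 timepoints")
    patterns: dict[tuple[str, ...], int] = {}
    marginals = {t: 0 for t in timepoints}
    for tr in trajectories:
        pattern = tuple(t for t in timepoints if tr.present_at(t))
        if not pattern:
            continue
        patterns[pattern] = patterns.get(pattern, 0) + 1
        for t in pattern:
            marginals[t] += 1
    return patterns, marginals


def normalized_shannon_series(
    reps: dict[str, Repertoire],
    schedule: PhaseSchedule,
    subset: str | SubsetSpec = "all",
    expanded_only: bool = True,
) -> pd.Series:
    """Normalized Shannon diversity H/log N per timepoint of the (expanded) subset.

    NaN (undefined) when the set has fewer than 2 clones.
    """
    spec = get_subset(subset)
    out = {}
    for t in schedule.timepoints:
        if t not in reps:
            continue
        sub = _subset(reps[t], spec)
        if expanded_only and sub.n_unique:
            exp = call_expanded(sub)
            counts = np.array([c.count for c in exp.clonotypes], dtype=float)
        else:
            counts = sub.counts
        if counts.size < 2 or counts.sum() == 0:
            out[t] = float("nan")
        else:
            out[t] = normalized_shannon(counts / counts.sum())
    return pd.Series(out, name="normalized_shannon")
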