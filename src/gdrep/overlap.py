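"""Pairwise repertoire comparison: overlap frequency, cosine similarity,
shared-clonotype counts.

Clonotypes are matched across samples by the (v_gene, j_gene, cdr3_aa) key.
Overlap frequency is the intersection size divided by the smaller set size.
Cosine similarity is computed between copy-count vectors built over the
clonotype keys the two expanded repertoires share; with no shared clones it
is 0 by definition, and with all-positive counts over a non-empty
intersection it cannot be 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expansion import ExpandedSet
from .io import Repertoire, SubsetSpec, get_subset
from .io import subset as _subset

Key = tuple[str, str, str]


def overlap_frequency(a: set[Key], b: set[Key]) -> float:
    """|a ∩ b| / min(|a|, |b|), in [0, 1]."""
    if not a or not b:
        raise ValueError("overlap frequency is undefined for an empty clonotype set")
    return len(a & b) / min(len(a), len(b))


def _count_map(x: ExpandedSet | Repertoire) -> dict[Key, int]:
    return {c.key: c.count for c in x.clonotypes}


def cosine_similarity(
    a: ExpandedSet | Repertoire,
    b: ExpandedSet | Repertoire,
    on: str = "intersection",
) -> float:
    """Cosine of the copy-count vectors over shared clonotype keys.

    ``on='union'`` builds the vectors over the key union instead (absent
    clones contribute 0) for sensitivity analysis.
    """
    if on not in ("intersection", "union"):
        raise ValueError("on must be 'intersection' or 'union'")
    ca, cb = _count_map(a), _count_map(b)
    if on == "intersection":
        keys = sorted(set(ca) & set(cb))
    else:
        keys = sorted(set(ca) | set(cb))
    if not keys:
        return 0.0
    va = np.array([ca.get(k, 0) for k in keys], dtype=float)
    vb = np.array([cb.get(k, 0) for k in keys], dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(va @ vb / (na * nb))


def shared_clonotypes(
    a: Repertoire | ExpandedSet,
    b: Repertoire | ExpandedSet,
    subset: str | SubsetSpec = "all",
) -> int:
    """Number of clonotype keys shared within a V-segment subset."""
    spec = get_subset(subset)

    def keys_of(x):
        if isinstance(x, ExpandedSet):
            return {c.key for c in x.clonotypes if spec(c.v_gene)}
        return _subset(x, spec).keys

    return len(keys_of(a) & keys_of(b))


@dataclass
class PairwiseMatrix:
    """A symmetric sample-by-sample metric matrix with group labels."""

    sample_ids: list[str]
    metric: str
    values: np.ndarray
    groups: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def pairs(self, within_group: bool | None = None) -> pd.DataFrame:
        """Long-format unordered pairs; optionally only intra-group pairs."""
        rows = []
        for i in range(len(self.sample_ids)):
            for j in range(i + 1, len(self.sample_ids)):
                same = self.groups[i] == self.groups[j]
                if within_group is True and not same:
                    continue
                if within_group is False and same:
                    continue
                rows.append(
                    {
                        "sample_a": self.sample_ids[i],
                        "sample_b": self.sample_ids[j],
                        "group_a": self.groups[i],
                        "group_b": self.groups[j],
                        "value": self.values[i, j],
                    }
                )
        return pd.DataFrame(rows)


def pairwise_matrix(
    reps: list[Repertoire],
    metric: str = "overlap_frequency",
    subset: str | SubsetSpec = "all",
    expanded: dict[str, ExpandedSet] | None = None,
) -> PairwiseMatrix:
    """All unordered pairwise comparisons over a list of repertoires.

    ``metric`` is one of overlap_frequency, cosine, shared_count.  For
    cosine, pass the per-sample ExpandedSets via ``expanded`` (the metric is
    defined on expanded repertoires); without them the full subsets are used.
    Diagonal is 1 for overlap/cosine and the subset's unique-clone count for
    shared_count.
    """
    if len(reps) < 2:
        raise ValueError("pairwise_matrix needs at least 2 repertoires")
    ids = [r.sample_id for r in reps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in repertoire list")
    spec = get_subset(subset)
    subs = [_subset(r, spec) for r in reps]
    n = len(reps)
    m = np.zeros((n, n))
    if metric == "overlap_frequency":
        key_sets = [s.keys for s in subs]
        for i in range(n):
            m[i, i] = 1.0
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = overlap_frequency(key_sets[i], key_sets[j])
    elif metric == "cosine":
        objs = [expanded[r.sample_id] if expanded else subs[k] for k, r in enumerate(reps)]
        for i in range(n):
            m[i, i] = 1.0
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = cosine_similarity(objs[i], objs[j])
    elif metric == "shared_count":
        key_sets = [s.keys for s in subs]
        for i in range(n):
            m[i, i] = len(key_sets[i])
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = len(key_sets[i] & key_sets[j])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return PairwiseMatrix(
        sample_ids=ids, metric=metric, values=m, groups=[r.group for r in reps]
    )
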