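"""Expanded-clone calling and clonal-space homeostasis.

An expanded clone (TCR_exp) is a clone whose copy number strictly exceeds
half the mean copy number of its repertoire.  Clonal-space homeostasis
partitions relative clone frequencies into Small / Medium / Large /
Hyperexpanded bins and reports the total frequency mass ("occupied space")
and clone count per bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Clonotype, Repertoire, SubsetSpec, get_subset
from .io import subset as _subset


@dataclass
class ExpandedSet:
    """The expanded (TCR_exp) subset of a repertoire with its threshold."""

    sample_id: str
    threshold: float
    clonotypes: list[Clonotype]
    parent: Repertoire
    expanded_fraction_unique: float
    expanded_fraction_reads: float

    @property
    def n_unique(self) -> int:
        return len(self.clonotypes)

    @property
    def keys(self) -> set[tuple[str, str, str]]:
        return {c.key for c in self.clonotypes}


def call_expanded(rep: Repertoire) -> ExpandedSet:
    """Call clones with count > 0.5 x mean copy number (strict inequality).

    When all counts are equal every clone is expanded (c > c/2).  A
    repertoire dominated by one huge clone over singletons can likewise mark
    every clone expanded once the mean is dragged below 2 — a documented
    pathology of the mean-based rule, not an error.
    """
    if rep.n_unique == 0:
        raise ValueError(f"cannot call expanded clones on empty repertoire {rep.sample_id!r}")
    counts = rep.counts
    threshold = 0.5 * counts.mean()
    members = [c for c in rep.clonotypes if c.count > threshold]
    member_reads = sum(c.count for c in members)
    return ExpandedSet(
        sample_id=rep.sample_id,
        threshold=float(threshold),
        clonotypes=members,
        parent=rep,
        expanded_fraction_unique=len(members) / rep.n_unique,
        expanded_fraction_reads=member_reads / rep.total_count,
    )


@dataclass
class HomeostasisBins:
    """Ordered (lower, upper] relative-frequency bins partitioning (0, 1].

    Bins are lower-exclusive / upper-inclusive, so a clone at exactly 1%
    falls in Large, not Hyperexpanded.
    """

    bins: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("Small", 0.0, 1e-4),
            ("Medium", 1e-4, 1e-3),
            ("Large", 1e-3, 1e-2),
            ("Hyperexpanded", 1e-2, 1.0),
        ]
    )

    def __post_init__(self) -> None:
        if self.bins[0][1] != 0.0 or self.bins[-1][2] != 1.0:
            raise ValueError("bins must span (0, 1]")
        for (_, _, hi), (_, lo, _) in zip(self.bins, self.bins[1:]):
            if hi != lo:
                raise ValueError("bins must be contiguous")

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.bins]

    def assign(self, freq: float) -> str:
        for name, lo, hi in self.bins:
            if lo < freq <= hi:
                return name
        raise ValueError(f"frequency {freq} outside (0, 1]")


DEFAULT_BINS = HomeostasisBins()


def homeostasis_occupancy(
    rep: Repertoire, bins: HomeostasisBins | None = None
) -> pd.DataFrame:
    """Occupied space (sum of frequencies) and clone count per homeostasis bin.

    Occupied space sums to 1 over bins; clone counts sum to the number of
    unique clonotypes.  Zero-frequency clones are excluded with a warning.
    """
    bins = bins or DEFAULT_BINS
    freqs = rep.frequencies
    if np.any(freqs == 0):
        warnings.warn("clones with zero frequency excluded from homeostasis", stacklevel=2)
        freqs = freqs[freqs > 0]
    space = {name: 0.0 for name in bins.names}
    count = {name: 0 for name in bins.names}
    for f in freqs:
        name = bins.assign(float(f))
        space[name] += float(f)
        count[name] += 1
    return pd.DataFrame(
        {
            "bin": bins.names,
            "occupied_space": [space[n] for n in bins.names],
            "clone_count": [count[n] for n in bins.names],
        }
    )


def hyperexpanded_share(
    rep: Repertoire,
    subset: str | SubsetSpec = "all",
    bins: HomeostasisBins | None = None,
) -> float:
    """Hyperexpanded occupied space of the renormalized subset, in percent.

    NaN (flagged by warning) for an empty subset.
    """
    spec = get_subset(subset)
    sub = _subset(rep, spec)
    if sub.n_unique == 0:
        warnings.warn(
            f"subset {spec.name} of {rep.sample_id!r} is empty; share undefined",
            stacklevel=2,
        )
        return float("nan")
    occ = homeostasis_occupancy(sub, bins)
    top = occ.loc[occ["bin"] == (bins or DEFAULT_BINS).names[-1], "occupied_space"]
    return float(top.iloc[0]) * 100.0
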