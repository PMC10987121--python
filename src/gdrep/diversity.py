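"""Diversity and evenness indices for clonotype frequency distributions.

All entropies use the natural logarithm (nats).  Clonality and normalized
Shannon entropy are base-invariant, so only raw entropy values depend on
this choice.

Indices
-------
* Rényi entropy of order alpha, with the Shannon limit at alpha=1, richness
  log N at alpha=0, and min-entropy -log(max p) at alpha=inf.
* D50: minimum number of top-ranked clones covering half the reads, and
  DE50 = D50 / N, its normalization by the number of unique clonotypes.
* Clonality = 1 - H/log N (1 - normalized Shannon entropy), 0 for a
  perfectly even repertoire, 1 for single-clone dominance.
* Gini coefficient of the clone frequency distribution, 0 for uniform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Repertoire, SubsetSpec, get_subset
from .io import subset as _subset

_NORM_TOL = 1e-9


def _as_freqs(freqs, check: bool = True) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1:
        raise ValueError("frequency input must be one-dimensional")
    if check:
        if np.any(p < -1e-15):
            raise ValueError("frequencies must be non-negative")
        s = p.sum()
        if p.size and abs(s - 1.0) > _NORM_TOL:
            raise ValueError(f"frequencies must sum to 1 (got {s!r})")
    return p


def shannon_entropy(freqs) -> float:
    """Shannon entropy H = -sum p_i ln p_i in nats; 0*log 0 := 0."""
    p = _as_freqs(freqs)
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-(p * np.log(p)).sum())


def renyi_entropy(freqs, alpha: float) -> float:
    """Rényi entropy of order ``alpha`` >= 0 in nats.

    alpha=0 gives log of the number of clones with positive frequency;
    alpha=1 is the Shannon limit (dispatched, not evaluated at the
    singularity); alpha=inf gives -log(max p).
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    p = _as_freqs(freqs)
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    if alpha == 0:
        return float(np.log(p.size))
    if alpha == 1:
        return float(-(p * np.log(p)).sum())
    if math.isinf(alpha):
        return float(-np.log(p.max()))
    return float(np.log((p**alpha).sum()) / (1.0 - alpha))


def d50(freqs) -> int:
    """Minimum number of clones, ranked by abundance, covering >= 50% of reads."""
    p = _as_freqs(freqs)
    p = p[p > 0]
    if p.size == 0:
        warnings.warn("d50 of an empty frequency vector is 0", stacklevel=2)
        return 0
    ranked = np.sort(p)[::-1]
    cum = np.cumsum(ranked)
    # ties at exactly 0.5 count as reaching it (tolerate fp drift)
    return int(np.searchsorted(cum, 0.5 - 1e-12) + 1)


def de50(freqs) -> float:
    """D50 normalized by the number of unique clonotypes; in (0, 1]."""
    p = _as_freqs(freqs)
    n = int((p > 0).sum())
    if n == 0:
        warnings.warn("de50 of an empty frequency vector is 0", stacklevel=2)
        return 0.0
    return d50(p) / n


def clonality(freqs) -> float:
    """1 - normalized Shannon entropy; by convention 1 for a single clone."""
    p = _as_freqs(freqs)
    n = int((p > 0).sum())
    if n == 0:
        return float("nan")
    if n == 1:
        return 1.0
    value = 1.0 - shannon_entropy(p) / math.log(n)
    return float(min(1.0, max(0.0, value)))


def normalized_shannon(freqs) -> float:
    """H / log N; complements clonality to 1. NaN when N < 2."""
    p = _as_freqs(freqs)
    n = int((p > 0).sum())
    if n < 2:
        return float("nan")
    return shannon_entropy(p) / math.log(n)


def gini(freqs) -> float:
    """Gini coefficient via the sorted-rank formula.

    G = sum_i (2i - N - 1) p_(i) / (N sum p) with p_(i) ascending;
    0 for a uniform distribution, bounded by 1 - 1/N.
    """
    p = _as_freqs(freqs)
    p = np.sort(p[p > 0])
    n = p.size
    if n <= 1:
        return 0.0
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * p).sum() / (n * p.sum()))


@dataclass
class DiversityProfile:
    """All indices of one repertoire (or subset), on copy-number frequencies."""

    sample_id: str
    subset: str
    n_unique: int
    shannon: float
    renyi: dict[float, float] = field(default_factory=dict)
    d50: int = 0
    de50: float = float("nan")
    clonality: float = float("nan")
    gini: float = float("nan")

    def as_dict(self) -> dict:
        out = {
            "sample_id": self.sample_id,
            "subset": self.subset,
            "n_unique": self.n_unique,
            "shannon": self.shannon,
            "d50": self.d50,
            "de50": self.de50,
            "clonality": self.clonality,
            "gini": self.gini,
        }
        for a, v in self.renyi.items():
            out[f"renyi_{a}"] = v
        return out


DEFAULT_ALPHAS = (0.0, 1.0, 2.0, float("inf"))


def diversity_profile(
    rep: Repertoire,
    subset: str | SubsetSpec = "all",
    alphas=DEFAULT_ALPHAS,
) -> DiversityProfile:
    """Compute every index on the copy-number frequencies of a subset.

    An empty subset yields n_unique 0 with NaN indices (flagged undefined).
    """
    spec = get_subset(subset)
    sub = _subset(rep, spec)
    if sub.n_unique == 0:
        return DiversityProfile(
            sample_id=rep.sample_id,
            subset=spec.name,
            n_unique=0,
            shannon=float("nan"),
            renyi={a: float("nan") for a in alphas},
        )
    p = sub.frequencies
    return DiversityProfile(
        sample_id=rep.sample_id,
        subset=spec.name,
        n_unique=sub.n_unique,
        shannon=shannon_entropy(p),
        renyi={a: renyi_entropy(p, a) for a in alphas},
        d50=d50(p),
        de50=de50(p),
        clonality=clonality(p),
        gini=gini(p),
    )
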