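"""CDR3 similarity via the normalized triplet spectrum kernel, similarity
networks, clustered-TCR proportion, and a resampling convergence test.

Two CDR3 amino-acid sequences are compared through their k-mer (default
triplet) count vectors: similarity is the cosine of the two spectra, in
[0, 1], reaching 1 iff the spectra are proportional.  Sequences are
connected in the similarity network when their similarity strictly exceeds
the threshold (default 0.8); a cluster is a connected component of size >= 2.
Convergence of an expanded repertoire is the excess of its clustered
proportion over size-matched uniform random draws of clonotypes from the
full repertoire, summarized as an empirical p-value.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .expansion import ExpandedSet
from .io import Repertoire


def kmer_counts(s: str, k: int = 3) -> Counter:
    """Counts of all overlapping length-k substrings (with multiplicity)."""
    return Counter(s[i : i + k] for i in range(len(s) - k + 1))


def spectrum_similarity(x: str, y: str, k: int = 3, normalize: bool = True) -> float:
    """Normalized spectrum-kernel similarity of two CDR3 sequences.

    <c_x, c_y> / sqrt(<c_x,c_x><c_y,c_y>) over k-mer count vectors.  A
    sequence shorter than k has an empty spectrum; similarity is defined as
    0 with a warning.  ``normalize=False`` returns the raw inner product.
    """
    if len(x) < k or len(y) < k:
        warnings.warn(f"sequence shorter than k={k}; similarity defined as 0", stacklevel=2)
        return 0.0
    cx, cy = kmer_counts(x, k), kmer_counts(y, k)
    dot = sum(cx[m] * cy[m] for m in cx.keys() & cy.keys())
    if not normalize:
        return float(dot)
    nx_ = sum(v * v for v in cx.values())
    ny_ = sum(v * v for v in cy.values())
    return dot / (nx_**0.5 * ny_**0.5)


def _spectrum_matrix(cdr3s: list[str], k: int = 3) -> sparse.csr_matrix:
    """Row-normalized sparse k-mer count matrix (rows: sequences)."""
    vocab: dict[str, int] = {}
    rows, cols, vals = [], [], []
    for i, s in enumerate(cdr3s):
        for mer, c in kmer_counts(s, k).items():
            j = vocab.setdefault(mer, len(vocab))
            rows.append(i)
            cols.append(j)
            vals.append(float(c))
    X = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(cdr3s), max(len(vocab), 1))
    )
    norms = np.sqrt(X.multiply(X).sum(axis=1)).A1
    norms[norms == 0] = 1.0  # too-short sequences keep a zero row
    inv = sparse.diags(1.0 / norms)
    return inv @ X


def _similarity_matrix(cdr3s: list[str], k: int = 3) -> np.ndarray:
    X = _spectrum_matrix(cdr3s, k)
    return np.asarray((X @ X.T).todense())


@dataclass
class SimilarityNetwork:
    """CDR3 similarity graph with its connected-component clusters."""

    graph: nx.Graph
    threshold: float
    clusters: list[set[str]]
    singletons: list[str]

    @property
    def n_clustered(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def clustered_proportion(self) -> float:
        n = self.graph.number_of_nodes()
        return self.n_clustered / n if n else 0.0

    def edge_list(self) -> list[tuple[str, str, float]]:
        return [
            (a, b, d["similarity"]) for a, b, d in self.graph.edges(data=True)
        ]


def build_network(
    cdr3s: list[str], threshold: float = 0.8, k: int = 3
) -> SimilarityNetwork:
    """Build the similarity network over deduplicated CDR3 sequences.

    All O(n^2) pairs are evaluated exactly; an edge is added when similarity
    strictly exceeds ``threshold``.  Node order is the sorted deduplicated
    input, making the result independent of input order.
    """
    nodes = sorted(set(cdr3s))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if len(nodes) >= 2:
        sim = _similarity_matrix(nodes, k)
        ii, jj = np.nonzero(np.triu(sim > threshold, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            g.add_edge(nodes[i], nodes[j], similarity=float(sim[i, j]))
    comps = [set(c) for c in nx.connected_components(g)]
    clusters = sorted((c for c in comps if len(c) >= 2), key=lambda c: (-len(c), min(c)))
    singletons = sorted(s for c in comps if len(c) == 1 for s in c)
    return SimilarityNetwork(
        graph=g, threshold=threshold, clusters=clusters, singletons=singletons
    )


def _clustered_fraction_from_sim(sim: np.ndarray, threshold: float) -> float:
    """Fraction of nodes in components of size >= 2 given a similarity matrix."""
    n = sim.shape[0]
    if n < 2:
        return 0.0
    adj = sparse.csr_matrix(np.triu(sim > threshold, k=1))
    ncomp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=ncomp)
    return float((sizes[labels] >= 2).sum() / n)


def top_cdr3s(exp: ExpandedSet, top_n: int = 500) -> list[str]:
    """Unique CDR3s of the top-n expanded clones by descending copy count.

    Ties broken by ascending CDR3 for determinism; fewer than top_n clones
    means all are used.
    """
    ranked = sorted(exp.clonotypes, key=lambda c: (-c.count, c.cdr3_aa))
    seen: dict[str, None] = {}
    for c in ranked[:top_n]:
        seen.setdefault(c.cdr3_aa, None)
    return list(seen)


def clustered_proportion(
    exp: ExpandedSet | list[str],
    top_n: int = 500,
    threshold: float = 0.8,
    k: int = 3,
) -> float:
    """Fraction of selected unique CDR3s in similarity clusters of size >= 2.

    Accepts either an ExpandedSet (top-n selection by copy count) or an
    explicit list of CDR3 strings.  Fewer than 2 sequences gives 0.
    """
    if isinstance(exp, ExpandedSet):
        cdr3s = top_cdr3s(exp, top_n)
    else:
        cdr3s = sorted(set(exp))
    if len(cdr3s) < 2:
        return 0.0
    sim = _similarity_matrix(sorted(cdr3s), k)
    return _clustered_fraction_from_sim(sim, threshold)


@dataclass
class ConvergenceResult:
    """Observed clustered proportion vs a random-clone null distribution."""

    observed_clustered_proportion: float
    null_proportions: np.ndarray
    resamples: int
    seed: int
    empirical_p: float


def convergence_test(
    exp: ExpandedSet,
    full: Repertoire,
    resamples: int = 200,
    seed: int = 0,
    top_n: int = 500,
    threshold: float = 0.8,
    k: int = 3,
) -> ConvergenceResult:
    """Test whether expanded clones cluster more than random clones.

    The null resamples size-matched uniform draws of unique clonotypes from
    the full repertoire and recomputes the clustered proportion;
    empirical_p = (1 + #{null >= observed}) / (1 + resamples).
    """
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    selection = top_cdr3s(exp, top_n)
    m = len(selection)
    pool = sorted({c.cdr3_aa for c in full.clonotypes})
    if m > len(pool):
        raise ValueError("expanded selection larger than the full repertoire's unique CDR3s")
    # one spectrum matrix over the union; each draw slices it
    universe = sorted(set(pool) | set(selection))
    index = {s: i for i, s in enumerate(universe)}
    X = _spectrum_matrix(universe, k)
    S = np.asarray((X @ X.T).todense())

    def frac(seqs: list[str]) -> float:
        idx = np.array(sorted(index[s] for s in set(seqs)))
        if idx.size < 2:
            return 0.0
        return _clustered_fraction_from_sim(S[np.ix_(idx, idx)], threshold)

    observed = frac(selection)
    rng = np.random.default_rng(seed)
    nulls = np.empty(resamples)
    pool_arr = np.array(pool)
    for r in range(resamples):
        draw = rng.choice(pool_arr, size=m, replace=False)
        nulls[r] = frac(list(draw))
    p = (1 + int((nulls >= observed - 1e-12).sum())) / (1 + resamples)
    return ConvergenceResult(
        observed_clustered_proportion=observed,
        null_proportions=nulls,
        resamples=resamples,
        seed=seed,
        empirical_p=p,
    )
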