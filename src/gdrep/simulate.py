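"""Synthetic γδ-TCR repertoire generator with known ground truth.

Clone-size distributions follow a Zipf law by rank (probability of the
rank-r clone ∝ r^(-s)); a single exponent s spans the observed spectrum
from even healthy-donor-like repertoires (s≈0.5) to the oligoclonal
repertoires of dedifferentiated tumors (s≈2).  CDR3 amino-acid sequences
are framed 'C…F' with uniform interior residues and lengths drawn from a
clipped rounded normal (mean 14, sd 2, clipped to [8, 23]), giving the
bell-shaped length distribution seen in real repertoires.  Optional
structure: public clonotype pools shared across subjects, convergent motif
families (single-substitution variants of a centroid), and longitudinal
emergence of new clones under a treatment-phase schedule.

Every generator is fully determined by its seed, and every output passes
the QC sieves unchanged (no stop codons, in-frame nucleotide sequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .clustering import spectrum_similarity
from .io import Clonotype, Repertoire, chain_of
from .tracking import DEFAULT_SCHEDULE, PHASE_LABELS, PhaseSchedule

AA = "ACDEFGHIKLMNPQRSTVWY"

# one fixed sense codon per amino acid, for a consistent back-translation
_CODON: dict[str, str] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _CODON.setdefault(aa, codon)

V_GENE_PROBS = {
    "TRD": {"TRDV2": 0.60, "TRDV1": 0.30, "TRDV3": 0.10},
    "TRG": {"TRGV9": 0.55, "TRGV2": 0.15, "TRGV4": 0.10, "TRGV5": 0.10, "TRGV8": 0.10},
}
J_GENE_PROBS = {
    "TRD": {"TRDJ1": 0.60, "TRDJ3": 0.20, "TRDJ2": 0.15, "TRDJ4": 0.05},
    "TRG": {"TRGJP": 0.50, "TRGJ1": 0.20, "TRGJ2": 0.20, "TRGJP1": 0.05, "TRGJP2": 0.05},
}


def back_translate(aa_seq: str) -> str:
    return "".join(_CODON[a] for a in aa_seq)


@dataclass
class SimConfig:
    """Parameters of one synthetic repertoire."""

    n_clones: int = 1000
    zipf_exponent: float = 1.0
    total_reads: int = 100_000
    chain: str = "TRD"
    cdr3_len_mean: float = 14.0
    cdr3_len_sd: float = 2.0
    cdr3_len_range: tuple[int, int] = (8, 23)
    v_gene_probs: dict[str, float] | None = None
    j_gene_probs: dict[str, float] | None = None
    n_families: int = 0
    family_size: int = 0
    mutations_per_member: int = 1
    emit_nt: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_gene_probs is None:
            self.v_gene_probs = dict(V_GENE_PROBS[self.chain])
        if self.j_gene_probs is None:
            self.j_gene_probs = dict(J_GENE_PROBS[self.chain])
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if self.n_families * self.family_size > self.n_clones:
            raise ValueError("motif families exceed the clone budget")


def zipf_probabilities(n: int, s: float) -> np.ndarray:
    """Rank probabilities ∝ rank^(-s); s=0 gives the uniform distribution."""
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks**(-s)
    return w / w.sum()


def _sample_length(rng: np.random.Generator, cfg: SimConfig) -> int:
    lo, hi = cfg.cdr3_len_range
    length = int(round(rng.normal(cfg.cdr3_len_mean, cfg.cdr3_len_sd)))
    return min(max(length, lo), hi)


_AA_ARR = np.frombuffer(AA.encode(), dtype="S1")


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    interior = _AA_ARR[rng.integers(0, 20, size=length - 2)].tobytes().decode()
    return "C" + interior + "F"


def _categorical(rng: np.random.Generator, probs: dict[str, float]) -> str:
    names = list(probs)
    p = np.array([probs[n] for n in names], dtype=float)
    p /= p.sum()
    return names[int(rng.choice(len(names), p=p))]


#: shortest centroid for which one interior substitution keeps the triplet
#: cosine above 0.8: a substitution touches up to 3 of the L-2 triplets, so
#: (T-3)/T > 0.8 needs T > 15, i.e. L >= 18.
MIN_FAMILY_LENGTH = 18


def _family_cdr3s(
    rng: np.random.Generator, cfg: SimConfig, n_members: int, threshold: float = 0.8
) -> list[str]:
    """A motif family: a centroid plus mutated members staying above threshold.

    Membership is verified at generation time and resampled otherwise; an
    infeasible configuration (too many mutations for the length budget)
    raises instead of looping.
    """
    lo, hi = cfg.cdr3_len_range
    length = min(max(MIN_FAMILY_LENGTH, _sample_length(rng, cfg)), hi)
    centroid = _random_cdr3(rng, length)
    members = [centroid]
    attempts = 0
    while len(members) < n_members:
        attempts += 1
        if attempts > 200 * n_members:
            raise ValueError(
                f"cannot place {cfg.mutations_per_member} substitution(s) in a "
                f"length-{length} centroid while keeping similarity > {threshold}"
            )
        seq = list(centroid)
        for _ in range(cfg.mutations_per_member):
            pos = int(rng.integers(1, length - 1))
            seq[pos] = str(rng.choice(list(AA)))
        cand = "".join(seq)
        if cand != centroid and spectrum_similarity(cand, centroid) > threshold:
            members.append(cand)
    return members


def _make_clones(
    rng: np.random.Generator,
    cfg: SimConfig,
    n: int,
    used_keys: set,
    family_offset: int = 0,
) -> tuple[list[dict], int]:
    """Draw n unique clones (keys unique within used_keys); families first.

    Family members occupy the first ranks so that top-abundance (expanded)
    selections are enriched for convergent motifs; the remainder is
    independent random CDR3s.
    """
    records: list[dict] = []
    fam_id = family_offset
    pending: list[tuple[str, int]] = []
    for _ in range(cfg.n_families):
        for seq in _family_cdr3s(rng, cfg, cfg.family_size):
            pending.append((seq, fam_id))
        fam_id += 1
    while len(pending) < n:
        pending.append((_random_cdr3(rng, _sample_length(rng, cfg)), -1))
    for seq, fid in pending[:n]:
        while True:
            v = _categorical(rng, cfg.v_gene_probs)
            j = _categorical(rng, cfg.j_gene_probs)
            key = (v, j, seq)
            if key not in used_keys:
                break
            seq = _random_cdr3(rng, _sample_length(rng, cfg))
        used_keys.add(key)
        records.append(
            {"v_gene": v, "j_gene": j, "cdr3_aa": seq, "family_id": fid, "public_id": -1}
        )
    return records, fam_id


def _to_repertoire(
    records: list[dict], counts: np.ndarray, cfg: SimConfig, sample_id: str, **meta
) -> Repertoire:
    clonotypes = [
        Clonotype(
            cdr3_aa=r["cdr3_aa"],
            cdr3_nt=back_translate(r["cdr3_aa"]) if cfg.emit_nt else None,
            v_gene=r["v_gene"],
            j_gene=r["j_gene"],
            chain=chain_of(r["v_gene"]),
            count=int(c),
        )
        for r, c in zip(records, counts)
        if c > 0
    ]
    return Repertoire(sample_id=sample_id, clonotypes=clonotypes, chain=cfg.chain, **meta)


def simulate_repertoire(
    cfg: SimConfig, sample_id: str = "sim", **meta
) -> tuple[Repertoire, pd.DataFrame]:
    """One repertoire with Zipf clone sizes plus its ground-truth table.

    Returns the observed repertoire (multinomial counts at the configured
    depth; unobserved clones dropped) and a DataFrame with every planted
    clone's rank, true probability, family id (-1 for none) and count.
    """
    rng = np.random.default_rng(cfg.seed)
    records, _ = _make_clones(rng, cfg, cfg.n_clones, used_keys=set())
    probs = zipf_probabilities(cfg.n_clones, cfg.zipf_exponent)
    counts = rng.multinomial(cfg.total_reads, probs)
    truth = pd.DataFrame(records)
    truth["rank"] = np.arange(1, cfg.n_clones + 1)
    truth["true_p"] = probs
    truth["count"] = counts
    rep = _to_repertoire(records, counts, cfg, sample_id, **meta)
    return rep, truth


def simulate_cohort(
    cfg: SimConfig,
    n_subjects: int,
    public_pool_size: int = 0,
    public_fraction: float = 0.0,
    groups: list[str] | None = None,
) -> tuple[list[Repertoire], pd.DataFrame]:
    """A cohort sharing a public clonotype pool.

    Each subject draws round(public_fraction * n_clones) clones (identical
    keys) from a shared pool and fills the rest with private clones; public
    clones are placed at random ranks.  Ground truth records each clone's
    subject, rank, true probability and public-pool id.
    """
    if not 0.0 <= public_fraction <= 1.0:
        raise ValueError("public_fraction must be in [0, 1]")
    n_public = round(public_fraction * cfg.n_clones)
    if n_public > public_pool_size and n_public > 0:
        raise ValueError("public pool smaller than the per-subject public draw")
    rng = np.random.default_rng(cfg.seed)
    pool_keys: set = set()
    pool, _ = _make_clones(rng, cfg, public_pool_size, used_keys=pool_keys) if public_pool_size else ([], 0)
    for pid, rec in enumerate(pool):
        rec["public_id"] = pid
    reps, truths = [], []
    probs = zipf_probabilities(cfg.n_clones, cfg.zipf_exponent)
    for s in range(n_subjects):
        chosen = (
            [dict(pool[i]) for i in rng.choice(public_pool_size, size=n_public, replace=False)]
            if n_public
            else []
        )
        private, _ = _make_clones(
            rng, replace(cfg, n_families=0), cfg.n_clones - n_public, used_keys=set(pool_keys)
        )
        records = chosen + private
        order = rng.permutation(cfg.n_clones)
        records = [records[i] for i in order]
        counts = rng.multinomial(cfg.total_reads, probs)
        sample_id = f"S{s + 1:02d}"
        group = groups[s] if groups else "other"
        truth = pd.DataFrame(records)
        truth["rank"] = np.arange(1, cfg.n_clones + 1)
        truth["true_p"] = probs
        truth["count"] = counts
        truth["sample_id"] = sample_id
        reps.append(
            _to_repertoire(records, counts, cfg, sample_id, subject_id=sample_id, group=group)
        )
        truths.append(truth)
    return reps, pd.concat(truths, ignore_index=True)


@dataclass
class LongitudinalSimConfig:
    """Longitudinal series: a base repertoire plus per-phase clone emergence."""

    base: SimConfig = field(default_factory=SimConfig)
    schedule: PhaseSchedule = field(default_factory=lambda: DEFAULT_SCHEDULE)
    #: phase -> (number of new clones, (low, high) target frequency per clone)
    emergence: dict[str, tuple[int, tuple[float, float]]] = field(
        default_factory=lambda: {
            "TKI": (40, (1e-4, 1e-3)),
            "radio": (30, (1e-4, 1e-3)),
            "PD1": (50, (1e-3, 1e-2)),
        }
    )
    persistence: float = 1.0
    noise: str = "multinomial"  # or "none" for deterministic counts

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")
        if self.noise not in ("multinomial", "none"):
            raise ValueError("noise must be 'multinomial' or 'none'")
        bad = sorted(set(self.emergence) - set(PHASE_LABELS))
        if bad:
            raise ValueError(f"emergence phases {bad} not in {sorted(PHASE_LABELS)}")


def simulate_longitudinal(
    cfg: LongitudinalSimConfig,
) -> tuple[dict[str, Repertoire], pd.DataFrame]:
    """Per-timepoint repertoires plus the planted clone labels.

    Baseline clones are PreExisted; at the first timepoint of each phase
    with configured emergence, fresh clones are injected at target
    frequencies and labeled with that phase's TA/RA/PA tag.  Existing clones
    persist to the next timepoint with probability ``persistence``.  With
    ``noise='none'`` counts are max(1, round(p * reads)), so presence equals
    the planted truth exactly.
    """
    base = cfg.base
    rng = np.random.default_rng(base.seed)
    used_keys: set = set()
    records, fam_off = _make_clones(rng, base, base.n_clones, used_keys)
    weights = {i: p for i, p in enumerate(zipf_probabilities(base.n_clones, base.zipf_exponent))}
    labels = {i: "PreExisted" for i in range(base.n_clones)}
    emerged_at = {i: cfg.schedule.timepoints[0] for i in range(base.n_clones)}
    all_records: dict[int, dict] = dict(enumerate(records))
    next_id = base.n_clones

    reps: dict[str, Repertoire] = {}
    alive = set(all_records)
    prev_phase = None
    for t in cfg.schedule.timepoints:
        phase = cfg.schedule.phases[t]
        if phase != prev_phase and phase in cfg.emergence and phase != "baseline":
            n_new, (lo, hi) = cfg.emergence[phase]
            new_recs, fam_off = _make_clones(
                rng, replace(base, n_families=0), n_new, used_keys, fam_off
            )
            target = rng.uniform(lo, hi, size=n_new)
            live_mass = sum(weights[i] for i in alive)
            scale = (1.0 - target.sum()) / live_mass
            for i in alive:
                weights[i] *= scale
            for rec, f in zip(new_recs, target):
                all_records[next_id] = rec
                weights[next_id] = float(f)
                labels[next_id] = PHASE_LABELS[phase]
                emerged_at[next_id] = t
                alive.add(next_id)
                next_id += 1
        prev_phase = phase

        ids = sorted(alive)
        w = np.array([weights[i] for i in ids])
        p = w / w.sum()
        if cfg.noise == "multinomial":
            counts = rng.multinomial(base.total_reads, p)
        else:
            counts = np.maximum(1, np.rint(p * base.total_reads)).astype(int)
        reps[t] = _to_repertoire(
            [all_records[i] for i in ids], counts, base, sample_id=f"{cfg.schedule.subject_id}_{t}",
            subject_id=cfg.schedule.subject_id, timepoint=t,
        )
        if cfg.persistence < 1.0:
            keep = rng.random(len(ids)) < cfg.persistence
            alive = {i for i, k in zip(ids, keep) if k}
            if not alive:  # never let the repertoire die out entirely
                alive = {ids[int(np.argmax(w))]}

    truth = pd.DataFrame(
        {
            "clone_id": list(all_records),
            "v_gene": [r["v_gene"] for r in all_records.values()],
            "j_gene": [r["j_gene"] for r in all_records.values()],
            "cdr3_aa": [r["cdr3_aa"] for r in all_records.values()],
            "label": [labels[i] for i in all_records],
            "emerged_at": [emerged_at[i] for i in all_records],
        }
    )
    return reps, truth


def subsample(rep: Repertoire, depth: int, seed: int = 0) -> Repertoire:
    """Resample a repertoire to a target read depth (multinomial thinning)."""
    rng = np.random.default_rng(seed)
    p = rep.frequencies
    counts = rng.multinomial(depth, p)
    clonotypes = [
        Clonotype(
            cdr3_aa=c.cdr3_aa, cdr3_nt=c.cdr3_nt, v_gene=c.v_gene,
            j_gene=c.j_gene, chain=c.chain, count=int(n),
        )
        for c, n in zip(rep.clonotypes, counts)
        if n > 0
    ]
    return Repertoire(
        sample_id=rep.sample_id, clonotypes=clonotypes, subject_id=rep.subject_id,
        group=rep.group, timepoint=rep.timepoint, chain=rep.chain,
    )
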