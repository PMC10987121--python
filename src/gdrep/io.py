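"""Clonotype table IO, QC sieves, V-segment subsetting and usage summaries.

Clonotype tables come in two tab-separated dialects:

* ``airr`` — AIRR-Rearrangement-style columns ``junction_aa``, ``junction``,
  ``v_call``, ``j_call``, ``locus``, ``duplicate_count``.
* ``mixcr`` — MiXCR-export-style columns ``aaSeqCDR3``, ``nSeqCDR3``,
  ``allVHitsWithScore``, ``allJHitsWithScore``, ``cloneCount``.

Gene names are normalized by stripping allele suffixes (``*01``) and score
annotations (``(1250)``); multi-hit fields keep the first listed hit.  A
clonotype is identified by the ``(v_gene, j_gene, cdr3_aa)`` key everywhere
in the package; rows sharing a key are aggregated by summing counts.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from Bio.Seq import Seq

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

#: canonical column order for the package's own clonotype TSV
CANONICAL_COLUMNS = [
    "sample_id",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3_aa",
    "cdr3_nt",
    "count",
    "frequency",
]

_DIALECT_COLUMNS = {
    "airr": {
        "cdr3_aa": "junction_aa",
        "cdr3_nt": "junction",
        "v_gene": "v_call",
        "j_gene": "j_call",
        "chain": "locus",
        "count": "duplicate_count",
    },
    "mixcr": {
        "cdr3_aa": "aaSeqCDR3",
        "cdr3_nt": "nSeqCDR3",
        "v_gene": "allVHitsWithScore",
        "j_gene": "allJHitsWithScore",
        "chain": None,
        "count": "cloneCount",
    },
}


class FormatError(ValueError):
    """A required column is missing or a field cannot be parsed."""


def normalize_gene(name: str) -> str:
    """Strip allele (``*NN``) and score (``(...)``) suffixes; keep first hit.

    >>> normalize_gene("TRGV9*00(1250)")
    'TRGV9'
    """
    if not isinstance(name, str):
        return ""
    first = name.split(",")[0].strip()
    for sep in ("*", "("):
        idx = first.find(sep)
        if idx >= 0:
            first = first[:idx]
    return first.strip()


def chain_of(v_gene: str) -> str:
    """Infer the locus (TRG/TRD) from the V-gene prefix."""
    if v_gene.startswith("TRG"):
        return "TRG"
    if v_gene.startswith("TRD"):
        return "TRD"
    return "other"


@dataclass(frozen=True)
class Clonotype:
    """One rearrangement: CDR3 (aa, optionally nt), V/J gene, chain, copies."""

    cdr3_aa: str
    v_gene: str
    j_gene: str
    chain: str
    count: int
    cdr3_nt: str | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_gene, self.j_gene, self.cdr3_aa)


@dataclass
class Repertoire:
    """A sample's clonotype multiset with metadata and derived frequencies.

    ``clonotypes`` is kept aggregated: the (v_gene, j_gene, cdr3_aa) keys
    are unique and counts are summed over rows sharing a key.
    """

    sample_id: str
    clonotypes: list[Clonotype] = field(default_factory=list)
    subject_id: str = ""
    group: str = "other"
    timepoint: str | None = None
    chain: str = "other"

    def __post_init__(self) -> None:
        self.clonotypes = _aggregate(self.clonotypes)

    # -- derived views ---------------------------------------------------
    @property
    def n_unique(self) -> int:
        return len(self.clonotypes)

    @property
    def total_count(self) -> int:
        return int(sum(c.count for c in self.clonotypes))

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.count for c in self.clonotypes], dtype=float)

    @property
    def frequencies(self) -> np.ndarray:
        """Copy-number frequencies p_i = count_i / total; sums to 1."""
        counts = self.counts
        total = counts.sum()
        return counts / total if total > 0 else counts

    @property
    def keys(self) -> set[tuple[str, str, str]]:
        return {c.key for c in self.clonotypes}

    def to_frame(self) -> pd.DataFrame:
        total = self.total_count
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "chain": [c.chain for c in self.clonotypes],
                "v_gene": [c.v_gene for c in self.clonotypes],
                "j_gene": [c.j_gene for c in self.clonotypes],
                "cdr3_aa": [c.cdr3_aa for c in self.clonotypes],
                "cdr3_nt": [c.cdr3_nt or "" for c in self.clonotypes],
                "count": [c.count for c in self.clonotypes],
                "frequency": [c.count / total if total else 0.0 for c in self.clonotypes],
            },
            columns=CANONICAL_COLUMNS,
        )


def _aggregate(clonotypes: Iterable[Clonotype]) -> list[Clonotype]:
    merged: dict[tuple[str, str, str], Clonotype] = {}
    for c in clonotypes:
        prev = merged.get(c.key)
        if prev is None:
            merged[c.key] = c
        else:
            merged[c.key] = replace(prev, count=prev.count + c.count)
    return list(merged.values())


# ---------------------------------------------------------------------------
# subset specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetSpec:
    """A named V-segment membership rule defining a repertoire subset.

    The canonical subsets partition each chain: Vd2pos/Vd2neg split TRD on
    TRDV2 usage; Vg9pos/Vg9neg split TRG on TRGV9 usage.
    """

    name: str
    chain: str | None
    predicate: Callable[[str], bool]

    def __call__(self, v_gene: str) -> bool:
        return self.predicate(v_gene)


SUBSETS: dict[str, SubsetSpec] = {
    "all": SubsetSpec("all", None, lambda v: True),
    "Vd2pos": SubsetSpec("Vd2pos", "TRD", lambda v: v == "TRDV2"),
    "Vd2neg": SubsetSpec("Vd2neg", "TRD", lambda v: v != "TRDV2"),
    "Vg9pos": SubsetSpec("Vg9pos", "TRG", lambda v: v == "TRGV9"),
    "Vg9neg": SubsetSpec("Vg9neg", "TRG", lambda v: v != "TRGV9"),
}


def get_subset(spec: str | SubsetSpec) -> SubsetSpec:
    if isinstance(spec, SubsetSpec):
        return spec
    try:
        return SUBSETS[spec]
    except KeyError:
        raise ValueError(
            f"unknown subset {spec!r}; choose from {sorted(SUBSETS)}"
        ) from None


def subset(rep: Repertoire, spec: str | SubsetSpec) -> Repertoire:
    """Restrict a repertoire to a V-segment subset.

    The subset is a repertoire in its own right: frequencies are
    recomputed over its own total when derived.
    """
    spec = get_subset(spec)
    if spec.chain is not None and rep.chain not in ("other", spec.chain):
        raise ValueError(
            f"subset {spec.name} is defined on {spec.chain} but repertoire "
            f"{rep.sample_id!r} has chain {rep.chain}"
        )
    kept = [c for c in rep.clonotypes if spec(c.v_gene)]
    return Repertoire(
        sample_id=rep.sample_id,
        clonotypes=kept,
        subject_id=rep.subject_id,
        group=rep.group,
        timepoint=rep.timepoint,
        chain=rep.chain,
    )


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_clonotype_table(
    path: str | Path,
    dialect: str = "airr",
    sample_id: str | None = None,
    **meta,
) -> Repertoire:
    """Read a clonotype TSV in the ``airr`` or ``mixcr`` dialect (pre-QC).

    Counts are preserved exactly; gene names are normalized; the chain is
    taken from the locus column when present, else inferred from the V gene.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}; use 'airr' or 'mixcr'")
    cols = _DIALECT_COLUMNS[dialect]
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    required = [c for c in cols.values() if c is not None]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required {dialect} column(s): {', '.join(missing)}"
        )
    clonotypes: list[Clonotype] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        raw_count = rec[cols["count"]]
        try:
            count_f = float(raw_count)
            if count_f != int(count_f):
                raise ValueError
            count = int(count_f)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-integer count {raw_count!r} at row {idx}"
            ) from None
        v_gene = normalize_gene(rec[cols["v_gene"]])
        j_gene = normalize_gene(rec[cols["j_gene"]])
        if cols["chain"] is not None and isinstance(rec.get(cols["chain"]), str):
            chain = rec[cols["chain"]].strip()
        else:
            chain = chain_of(v_gene)
        nt = rec.get(cols["cdr3_nt"])
        nt = nt.upper() if isinstance(nt, str) and nt else None
        clonotypes.append(
            Clonotype(
                cdr3_aa=str(rec[cols["cdr3_aa"]]).strip() if isinstance(rec[cols["cdr3_aa"]], str) else "",
                cdr3_nt=nt,
                v_gene=v_gene,
                j_gene=j_gene,
                chain=chain,
                count=count,
            )
        )
    chains = {c.chain for c in clonotypes}
    rep_chain = chains.pop() if len(chains) == 1 else "other"
    return Repertoire(
        sample_id=sample_id or Path(path).name.split(".")[0],
        clonotypes=clonotypes,
        chain=meta.pop("chain", rep_chain),
        **meta,
    )


def write_clonotype_table(rep: Repertoire, path: str | Path) -> None:
    """Write the canonical clonotype TSV (gzip-transparent by suffix)."""
    df = rep.to_frame()
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            df.to_csv(fh, sep="\t", index=False)
    else:
        df.to_csv(path, sep="\t", index=False)


def read_canonical(path: str | Path, **meta) -> Repertoire:
    """Read back the canonical TSV written by :func:`write_clonotype_table`."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"cdr3_nt": str}, keep_default_na=False)
    clonotypes = [
        Clonotype(
            cdr3_aa=r.cdr3_aa,
            cdr3_nt=r.cdr3_nt or None,
            v_gene=r.v_gene,
            j_gene=r.j_gene,
            chain=r.chain,
            count=int(r.count),
        )
        for r in df.itertuples(index=False)
    ]
    sample_id = meta.pop("sample_id", df["sample_id"].iloc[0] if len(df) else Path(path).stem)
    chains = {c.chain for c in clonotypes}
    chain = meta.pop("chain", chains.pop() if len(chains) == 1 else "other")
    return Repertoire(sample_id=sample_id, clonotypes=clonotypes, chain=chain, **meta)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, subject_id, group, timepoint, phase)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata table lacks a sample_id column")
    return df


# ---------------------------------------------------------------------------
# QC sieves
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Removal tallies of the productive-rearrangement sieves."""

    stop_codon_removed: int = 0
    stop_codon_copies: int = 0
    out_of_frame_removed: int = 0
    out_of_frame_copies: int = 0
    translation_mismatch_removed: int = 0
    translation_mismatch_copies: int = 0
    kept: int = 0
    kept_copies: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _translate(nt: str) -> str | None:
    try:
        return str(Seq(nt).translate())
    except Exception:
        return None


def qc_filter(rep: Repertoire) -> tuple[Repertoire, QCReport]:
    """Keep only productive clonotypes.

    Removes clones whose CDR3 amino-acid sequence contains a stop codon
    ('*'), clones whose CDR3 nucleotide sequence is out of frame (length not
    a multiple of 3, or a '_' frameshift marker in the aa sequence), and
    clones whose nucleotide translation disagrees with the reported amino
    acids.  Never fails; idempotent.
    """
    report = QCReport()
    kept: list[Clonotype] = []
    for c in rep.clonotypes:
        if "*" in c.cdr3_aa:
            report.stop_codon_removed += 1
            report.stop_codon_copies += c.count
            continue
        if "_" in c.cdr3_aa or (c.cdr3_nt is not None and len(c.cdr3_nt) % 3 != 0):
            report.out_of_frame_removed += 1
            report.out_of_frame_copies += c.count
            continue
        if c.cdr3_nt is not None:
            aa = _translate(c.cdr3_nt)
            if aa is None or aa != c.cdr3_aa:
                report.translation_mismatch_removed += 1
                report.translation_mismatch_copies += c.count
                continue
        kept.append(c)
        report.kept += 1
        report.kept_copies += c.count
    out = Repertoire(
        sample_id=rep.sample_id,
        clonotypes=kept,
        subject_id=rep.subject_id,
        group=rep.group,
        timepoint=rep.timepoint,
        chain=rep.chain,
    )
    return out, report


# ---------------------------------------------------------------------------
# usage & length summaries
# ---------------------------------------------------------------------------

def vj_usage(rep: Repertoire, level: str = "V") -> pd.Series:
    """Copy-frequency usage per V segment (level='V') or V-J pair ('VJ')."""
    if level not in ("V", "VJ"):
        raise ValueError("level must be 'V' or 'VJ'")
    total = rep.total_count
    acc: dict = {}
    for c in rep.clonotypes:
        key = c.v_gene if level == "V" else (c.v_gene, c.j_gene)
        acc[key] = acc.get(key, 0) + c.count
    ser = pd.Series(acc, dtype=float).sort_index()
    return ser / total if total else ser


def cdr3_length_distribution(rep: Repertoire, weighting: str = "copy") -> pd.Series:
    """CDR3 amino-acid length distribution, copy- or unique-clone-weighted."""
    if weighting not in ("unique", "copy"):
        raise ValueError("weighting must be 'unique' or 'copy'")
    acc: dict[int, float] = {}
    for c in rep.clonotypes:
        w = c.count if weighting == "copy" else 1
        acc[len(c.cdr3_aa)] = acc.get(len(c.cdr3_aa), 0) + w
    ser = pd.Series(acc, dtype=float).sort_index()
    total = ser.sum()
    return ser / total if total else ser
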