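import numpy as np
import pytest

from gdrep import Clonotype, Repertoire


def make_repertoire(counts, chain="TRD", v_genes=None, j_gene=None, sample_id="S1", **meta):
    """A tiny repertoire with distinct CDR3s and the given copy counts."""
    v_default = "TRDV2" if chain == "TRD" else "TRGV9"
    j_default = "TRDJ1" if chain == "TRD" else "TRGJP"
    clones = []
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for i, c in enumerate(counts):
        # base-20 encoding of i: unique CDR3 per clone
        interior = "".join(alphabet[(i // 20**d) % 20] for d in range(10))
        clones.append(
            Clonotype(
                cdr3_aa=f"C{interior}F",
                v_gene=(v_genes[i] if v_genes else v_default),
                j_gene=j_gene or j_default,
                chain=chain,
                count=int(c),
            )
        )
    return Repertoire(sample_id=sample_id, clonotypes=clones, chain=chain, **meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def airr_table(tmp_path):
    rows = [
        "junction_aa\tjunction\tv_call\tj_call\tlocus\tduplicate_count",
        "CASSLGF\tTGTGCCAGCAGCCTGGGCTTT\tTRDV1*01\tTRDJ1*01\tTRD\t10",
        "CAAWDTF\tTGTGCCGCCTGGGACACCTTT\tTRDV2*01\tTRDJ1*01\tTRD\t4",
        "CALGELF\tTGTGCCCTGGGCGAGCTGTTT\tTRDV3*01\tTRDJ3*01\tTRD\t1",
    ]
    path = tmp_path / "sample.airr.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def mixcr_table(tmp_path):
    rows = [
        "aaSeqCDR3\tnSeqCDR3\tallVHitsWithScore\tallJHitsWithScore\tcloneCount",
        "CASSLGF\tTGTGCCAGCAGCCTGGGCTTT\tTRGV9*00(1250)\tTRGJP*00(800)\t10",
        "CAAWDTF\tTGTGCCGCCTGGGACACCTTT\tTRGV2*00(900),TRGV4*00(100)\tTRGJ1*00(500)\t4",
    ]
    path = tmp_path / "sample.mixcr.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path


def random_simplex(rng, n):
    """A random frequency vector of length n (Dirichlet(1))."""
    p = rng.dirichlet(np.ones(n))
    return p / p.sum()


def random_cdr3(rng, length):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "C" + "".join(rng.choice(list(aa), size=length - 2)) + "F"
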