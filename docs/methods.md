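# Methods

## Clonotype model and QC

A clonotype is a unique rearrangement identified by the triple
(V gene, J gene, CDR3 amino-acid sequence); rows of an input table sharing
that key are aggregated by summing copy counts, and the same key is used
for every cross-sample and cross-timepoint match.  The CDR3 nucleotide
sequence, when present, is carried along but deliberately excluded from the
identity key: bulk TCR data often collapse synonymous rearrangements, and
the amino-acid key is the most conservative choice consistent with V–J
usage analyses.  Gene names are normalized by stripping allele (`*NN`) and
alignment-score (`(…)`) suffixes and keeping the first hit of multi-hit
fields, which makes MiXCR-style and AIRR-style exports land on the same
vocabulary.  The chain is taken from the locus column when present and
otherwise inferred from the V-gene prefix.

The QC sieves keep only productive rearrangements: a clone is removed if
its CDR3 contains a stop codon (`*`), if its nucleotide CDR3 is out of
frame (length not divisible by 3, or a `_` frameshift marker), or if the
nucleotide translation (standard codon table, via Biopython) disagrees with
the reported amino acids.  The filter never fails and is idempotent.

V-segment subsets (Vδ2⁺/Vδ2⁻ on TRD, Vγ9⁺/Vγ9⁻ on TRG) are treated as
repertoires in their own right: frequencies are renormalized within the
subset before any index is computed, because each subset is analyzed as an
independent compartment.

## Diversity and evenness

All entropies are in nats.  The choice of base is irrelevant for clonality
and normalized Shannon entropy (ratios of logarithms) and rescales only raw
entropy values.  Rényi entropy is evaluated by dispatch at its special
orders — α = 0 → log N⁺ (richness over clones with positive frequency),
α = 1 → Shannon, α = ∞ → −log max pᵢ — rather than through the singular
formula.  D50 ranks clones by descending abundance and returns the smallest
k whose cumulative frequency reaches 0.5; a cumulative sum within 1e-12 of
0.5 counts as reaching it, so exact ties behave deterministically.  DE50 is
defined here as D50/N (a normalization that makes single-clone dominance 
1/N and perfect evenness ≈ 0.5); the name is used loosely in the field and
this definition is stated wherever the value is reported.  Clonality is
1 − H/log N, with the N = 1 case fixed at 1 by convention (maximal
dominance) and the result clamped to [0, 1] against floating-point drift.
The Gini coefficient uses the sorted-rank formula
G = Σᵢ (2i − N − 1) p₍ᵢ₎ / (N Σ p); tests cross-check it against the
pairwise mean-absolute-difference definition.

## Expansion and clonal-space homeostasis

Expanded clones (TCR_exp) are those whose copy count strictly exceeds half
the repertoire's mean copy count.  The rule is scale-invariant and has two
documented boundary behaviours: equal counts make every clone expanded
(c > c/2), and a single dominant clone over many singletons can drag the
mean low enough that every clone qualifies.  Homeostasis bins are
lower-exclusive/upper-inclusive — Small (0, 10⁻⁴], Medium (10⁻⁴, 10⁻³],
Large (10⁻³, 10⁻²], Hyperexpanded (10⁻², 1] — so a clone at exactly 1 %
is Large.  The notation "1–100 %" found in figure legends is ambiguous at
the boundary; the upper-inclusive reading was chosen and the bins are
configurable.  Occupancy is computed on copy-number frequencies (clonal
proportions), and per-subset occupancy is computed after renormalization.

## Overlap and cosine similarity

Overlap frequency is |A∩B| / min(|A|, |B|) over clonotype keys.  Cosine
similarity between two expanded repertoires is computed over the
*intersection* of their keys: two count vectors over the shared clones in a
fixed key order, then the cosine.  With a non-empty intersection and
positive counts the value cannot be 0; it is 0 exactly when no clones are
shared.  "Detected number of times" is read as copy counts, not binary
presence.  A union-based variant (absent clones contributing 0) is exposed
for sensitivity analysis but is not the default.

## CDR3 spectrum kernel, networks, convergence

Similarity between CDR3 amino-acid sequences is the normalized spectrum
kernel at k = 3: cosine of the k-mer count vectors over all overlapping
triplets, counted with multiplicity.  Counting with multiplicity (multiset
rather than set) matches the spectrum-kernel definition and makes
self-similarity exactly 1.  Sequences shorter than k have an empty spectrum
and are assigned similarity 0 with a warning.  The similarity network
connects sequences whose similarity strictly exceeds the threshold
(default 0.8); all O(n²) pairs are evaluated exactly (no approximate
neighbour search at the default scale of ≤ 500 selected sequences), and a
cluster is a connected component of size ≥ 2.  The "clustered proportion"
of an expanded set is the fraction of its top-500 (by copy count, ties by
lexicographic CDR3) unique CDR3s that fall in such components; alternative
summaries (component counts) exist in the literature but the
fraction-in-components definition is used throughout.

The convergence test compares the observed clustered proportion of an
expanded selection with size-matched uniform draws of unique clonotypes
from the full repertoire, with
empirical p = (1 + #{null ≥ observed}) / (1 + resamples).  The null
similarity matrix is computed once over the union of candidate sequences
and sliced per draw, so 200 resamples on 500-sequence selections run in
seconds.  Because the statistic is discrete, ties make the test
conservative; with an entirely unstructured sequence pool both observed and
null proportions are almost surely 0 and the p-value is 1, so calibration
is only meaningful when the background pool contains some similarity
structure.

## Longitudinal tracking

A phase schedule orders a subject's timepoints and maps each to baseline,
TKI, radiotherapy or anti-PD-1.  The default schedule is six timepoints
T1–T6 with T1 baseline, T2–T4 TKI, T5 radiotherapy, T6 anti-PD-1.  A clone
detected at baseline is PreExisted regardless of its later behaviour;
otherwise its label is the phase of first detection (TA/RA/PA).  Detection
is copy count ≥ 1 by default — sequencing depth is not normalized for
detection, only for the frequency summaries — and a configurable minimum
count guards against index-hopping artifacts; with `expanded_only`,
detection means membership in that timepoint's expanded set.  Labels are
stable under appending later timepoints.  The Neo mean-frequency series
averages, at each timepoint, clones of the requested labels already
detected by then (dropped-out clones contribute 0); a flag switches to
including all eventually-Neo clones from the start.  Intersection counts
are exclusive presence patterns (the cells of an upset plot) plus
per-timepoint marginals.

## Synthetic repertoires

The generator is the package's test bed and defines the conditions every
property is demonstrated under:

* **Clone sizes** follow a Zipf law by rank, p(r) ∝ r^(−s); s = 0 is
  uniform and a single exponent spans the observed range from even
  healthy-donor-like repertoires to oligoclonal dedifferentiated-tumor-like
  ones.  Zipf-by-rank was preferred to a log-normal clone-size model
  because one parameter cleanly orders the skew for monotonicity checks.
  Observed counts are multinomial at the configured read depth (default
  10⁵ reads over 1000–2000 clones; the analysis drivers use 2000 clones,
  matching the scale at which all indices are well resolved while keeping
  whole-cohort runs under a few seconds).
* **CDR3 sequences** are framed C…F with uniform interior residues and
  lengths from a rounded normal (mean 14, sd 2) clipped to [8, 23] — the
  framing is cosmetic realism (canonical junction boundaries) and has no
  effect on the statistics; the length law reproduces the bell-shaped
  spectra of real repertoires.  Nucleotide CDR3s are emitted by fixed-codon
  back-translation so generated tables pass QC unchanged.
* **V/J usage** defaults: TRD — TRDV2 0.60, TRDV1 0.30, TRDV3 0.10 and
  TRDJ1-skewed J usage; TRG — TRGV9 0.55 with TRGJP 0.50.  These mimic the
  Vδ2/Vγ9 dominance of healthy peripheral blood γδ T cells.
* **Motif families** (convergent clusters) sample a centroid and mutate
  single interior residues, verifying at generation time that every member
  stays above the 0.8 similarity threshold.  One substitution alters up to
  3 of the L−2 triplets of a length-L sequence, so (T−3)/T > 0.8 requires
  T > 15: family centroids are therefore drawn at length ≥ 18, and
  infeasible mutation budgets raise an error instead of resampling forever.
  Families occupy the top clone ranks so that expanded (top-abundance)
  selections are enriched for convergent motifs, emulating antigen-driven
  expansion.
* **Cohorts** share a public clonotype pool: each subject draws
  `public_fraction · n_clones` keys from the pool and fills the rest with
  private clones, with public clones placed at random ranks.  Expected
  pairwise sharing for draws of size m from a pool of P is m²/P.
* **Longitudinal series** inject fresh clones at the first timepoint of
  each treatment phase at target frequencies (defaults: 40 TKI clones and
  30 radiotherapy clones at 10⁻⁴–10⁻³, 50 anti-PD-1 clones at 10⁻³–10⁻² —
  a deliberate late surge), renormalizing existing clone weights; clones
  persist between timepoints with configurable probability (default 1).
  `noise="none"` makes counts deterministic (max(1, round(p·reads))) so
  planted presence is exact; the default multinomial mode and the
  `subsample` utility model finite-depth detection.

What the generator does **not** model: sequencing error and PCR bias, UMI
structure, germline VDJ recombination (segments are names only, with no
junctional biology), HLA/antigen specificity, and biological covariance
between diversity and V usage.  Tests passing on these synthetics therefore
demonstrate the correctness and sensitivity of the *computations* under
controlled conditions, not the biological claims one would test on real
patient repertoires.

## Numerical choices and degenerate inputs

Frequency vectors must sum to 1 within 1e-9; zero frequencies contribute 0
to entropies (0·log 0 := 0) and are excluded from richness.  Empty
repertoires/subsets yield flagged-undefined (NaN) indices rather than
errors wherever the operation is a summary, and errors where the operation
is undefined (expanded-clone calling, overlap of empty sets).  Network node
ordering is the sorted deduplicated input, making component extraction
independent of input order.  All generators and resampling loops take
explicit integer seeds through `numpy.random.default_rng`; fixed seeds make
every output byte-identical across runs.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
diversity oracle checks use up to 1000-clone frequency vectors; the
clone-size-skew gradient uses 2000 clones × 10⁵ reads × 20 seeds per
exponent; convergence testing uses 1000-clone repertoires with 200
resamples (and 99 resamples × 100 replicates for the calibration check);
longitudinal recovery uses 300 baseline clones over six timepoints with
subsampling to 10⁴ reads.  These sizes resolve every index and keep the
full suite in the tens of seconds on one CPU.
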