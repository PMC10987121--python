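# gdrep — γδ T-cell receptor repertoire analysis

`gdrep` analyzes bulk γδ-TCR (TRG/TRD chain) clonotype repertoires of the
kind produced by MiXCR-style assembly of immune-repertoire sequencing: it is
aimed at immunologists studying how the γδ compartment — in particular the
innate-like Vγ9/Vδ2 and adaptive-like Vδ2⁻ subsets — reshapes itself across
disease states and over a course of treatment.

The package covers the full analysis chain:

* **IO & QC** — clonotype tables in AIRR-Rearrangement-like and
  MiXCR-export-like TSV dialects; removal of unproductive rearrangements
  (stop codon in the CDR3, out-of-frame CDR3); V-segment subsetting
  (Vδ2⁺/Vδ2⁻, Vγ9⁺/Vγ9⁻); V and V–J usage and CDR3 length spectra.
* **Diversity & evenness** — Rényi entropy
  `H_α = log(Σᵢ pᵢ^α) / (1 − α)` with the Shannon limit at α = 1
  (`H = −Σᵢ pᵢ log pᵢ`, natural log), D50 and DE50 = D50/N, clonality
  `1 − H/log N`, and the Gini coefficient of the clone-frequency
  distribution.
* **Expansion & homeostasis** — expanded clones (TCR_exp: copy number
  strictly above 50 % of the repertoire's mean copy number) and
  clonal-space homeostasis over Small (0, 0.01 %], Medium (0.01, 0.1 %],
  Large (0.1, 1 %] and Hyperexpanded (1, 100 %] frequency bins.
* **Overlap & similarity** — overlap frequency `|A∩B| / min(|A|,|B|)`,
  cosine similarity of copy-count vectors over the clonotypes two expanded
  repertoires share, and shared-clonotype counts, all keyed on
  (V gene, J gene, CDR3 aa).
* **CDR3 clustering & convergence** — the normalized triplet spectrum
  kernel `⟨c_x,c_y⟩ / √(⟨c_x,c_x⟩⟨c_y,c_y⟩)` over overlapping amino-acid
  3-mers, similarity networks with edges at similarity > 0.8, the clustered
  proportion of an expanded set, and an empirical resampling test of
  convergence against size-matched random clone draws.
* **Longitudinal tracking** — clones matched across timepoints of one
  subject and labeled PreExisted (present at baseline) or Neo by first
  detection phase: TKI-associated (TA), radiotherapy-associated (RA),
  anti-PD-1-associated (PA); mean Neo frequency series, label composition,
  and upset-style intersection counts.
* **Synthetic repertoires** — a seed-deterministic generator (Zipf
  clone-size law, bell-shaped CDR3 lengths, public clone pools, convergent
  motif families, longitudinal emergence) providing ground truth for every
  step above.

## Worked example

```python
from gdrep import (SimConfig, simulate_repertoire, diversity_profile,
                   call_expanded, hyperexpanded_share, convergence_test)

cfg = SimConfig(n_clones=1000, zipf_exponent=1.5, total_reads=100_000,
                n_families=20, family_size=5, seed=7)
rep, truth = simulate_repertoire(cfg)

prof = diversity_profile(rep)
print(f"N={prof.n_unique}  H={prof.shannon:.3f}  clonality={prof.clonality:.3f}  "
      f"gini={prof.gini:.3f}  D50={prof.d50}")
print(f"hyperexpanded space: {hyperexpanded_share(rep):.2f}%")

exp = call_expanded(rep)
res = convergence_test(exp, rep, resamples=200, seed=1)
print(f"expanded clones: {exp.n_unique} ({exp.expanded_fraction_unique:.1%} of unique)")
print(f"clustered proportion {res.observed_clustered_proportion:.3f}, "
      f"empirical p = {res.empirical_p:.4f}")
```

prints

```
N=917  H=2.907  clonality=0.574  gini=0.951  D50=2
hyperexpanded space: 79.45%
expanded clones: 82 (8.9% of unique)
clustered proportion 0.951, empirical p = 0.0050
```

A Zipf exponent of 1.5 yields an oligoclonal repertoire: two clones cover
half the reads and the hyperexpanded bin (> 1 % frequency) holds ~79 % of
the clonal space.  The 100 motif-family clones planted at the top ranks
make the expanded set far more self-similar than random clone draws, so the
convergence test rejects at its resolution limit (p = 1/201).

## Analysis drivers

Numbered scripts under `analysis/` run the study end to end on synthetic
cohorts and write tables under `results/`:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_diversity_gradient.py
python analysis/03_overlap_similarity.py
python analysis/04_cdr3_clustering.py --seed 1
python analysis/05_longitudinal_tracking.py
```

`01` generates a cross-sectional cohort whose clone-size skew rises along
the HC → miPTC → wiPTC → PDTC → ATC group gradient, a cohort sharing a
public clonotype pool, and a six-timepoint treatment series; `02`–`05`
compute the diversity gradient, sharing matrices, convergence networks and
longitudinal trajectories from those tables.

A thin CLI mirrors the library (`gdrep simulate|diversity|homeostasis|
overlap|cluster|track --help`).

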