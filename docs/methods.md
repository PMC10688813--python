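# Methods

## Problem setting

A mock (positive-control) community has a known membership of $N$
species and a stated theoretical composition (percent per species,
summing to 100). After sequencing and denoising, the control sample is
an ASV count table: amplicon sequence variants, identified by their DNA
sequence, with read counts per sample. `mockqc` answers two questions
per control sample: *does the observed species ranking match the
expected one* (Spearman's rho), and *how much of the signal belongs to
no expected member at all* (the Unknown percent, a contamination and
artifact diagnostic).

The tool assumes ASV sequences and references are in the same
orientation (denoiser output normally is; `--both-strands` unions
reverse-complement k-mers into each species' index as an escape hatch)
and supports bacterial and archaeal 16S references only. 16S copy-number
correction and genomic-vs-amplicon abundance conversion are out of
scope: the theoretical table is taken to be on the same scale as
sequencing output.

## Classification model

Taxonomic assignment uses word-presence naive Bayes with bootstrap
confidence, the scheme family of RDP-style k-mer classifiers. Each
species $s$ is summarized by the set of distinct k-mers occurring in any
of its reference records. For a query with distinct k-mer set $Q$:

    score(s) = sum_{w in Q} log( (m_s(w) + p_w) / 2 ),
    p_w      = (n_w + 0.5) / (N + 1)

with $m_s(w) = 1$ iff $w$ is in species $s$'s index, and $n_w$ the
number of species containing $w$. The prior $p_w$ downweights words
shared by many species; the denominator 2 is the per-species record
normalizer of the presence model (each species contributes one word
set).

Bootstrap: 100 rounds, each drawing `ceil(subsample_fraction * |Q|)`
k-mers with replacement and voting for the arg-max score; confidence is
the plurality fraction. Two guard rules precede thresholding:

* a query sharing **zero** k-mers with every species is called
  `(Unknown, 0.0)` outright — otherwise the all-tie case would elect a
  spuriously confident lexicographic winner;
* score ties within a round break to the lexicographically smallest
  species label, which is deterministic and seed-independent.

Calls whose confidence falls below the threshold become `Unknown` but
keep their confidence value, so raising the threshold can only demote
species calls, never promote them (tested as a monotonicity property).

Parameters, defaults, and rationale:

| parameter            | default | meaning                                         |
|----------------------|---------|-------------------------------------------------|
| k                    | 8       | word size (allowed 4–12); classifier convention |
| n_bootstraps         | 100     | voting rounds                                   |
| subsample_fraction   | 1/8     | share of query k-mers drawn per round           |
| confidence_threshold | 0.60    | below this a call becomes Unknown               |
| rng_seed             | 0       | bootstrap randomness                            |

Each ASV's bootstrap RNG is a substream keyed by `(rng_seed, row
index)`, so classification results are independent of processing order
and reproduce byte-for-byte.

This module is an explicit, testable contract of its own; it does not
attempt to numerically reproduce any external classifier's output.

## Comparison statistics

ASV counts are summed per species call; calls to species absent from
the theoretical table fold into Unknown (they are, by definition, not
expected). Percents are `100 * count / sample depth`; zero-depth
samples are dropped with a warning rather than failing the run.

Spearman's rho is computed as Pearson correlation of midranks (average
ranks on ties) rather than the `6*sum(d^2)` shortcut, because mock
profiles routinely contain ties — typically zeros for dropped-out
members. A constant rank vector makes rho undefined; this is surfaced
as an explicit `None` / `NA`, never a propagated NaN. At least three
expected species are required.

The Unknown percent is **excluded** from the correlation vector: the
theoretical table has no Unknown entry, and padding one with 0 would
inflate rho. The observed vector is not renormalized after the
exclusion — Spearman is rank-based, so renormalization is a no-op.

## Synthetic data generator

The generator emulates an 8-species bacterial DNA-standard-style mock
and a nine-step (D0–D8) three-fold dilution series, in which
progressively lower input biomass lets contaminant reads take over.
What it models, and how:

* **References**: i.i.d. uniform-random DNA of length 1500 nt
  (full-length-16S-like). Pairwise k-mer Jaccard similarity is enforced
  below 0.05 by regeneration, guaranteeing classifier separability.
* **Theoretical percents**: random values on a 0.1 grid with exact sum
  100, every value ≥ 1 and pairwise separation ≥ 1 point (the floor
  shrinks automatically for panels beyond ~13 species). Construction is
  exact integer arithmetic in tenths: a base ladder plus sorted random
  extras, shuffled onto species. The separation floor makes the
  expected ranking unambiguous: multinomial noise at typical depths
  moves a percent by well under a point, so a rank swap indicates real
  bias, not sampling jitter.
* **ASV variants**: per species, the reference itself plus
  substitution-mutated copies (per-base rate 0.02 by default, uniform
  choice among the three alternative bases; no indels). All variants
  are unique; with error rate 0 the set deduplicates to one exact copy
  per species.
* **Contaminants**: sequences built base-by-base so that *no* k-mer
  occurs anywhere in the panel (a dead end restarts the attempt). True
  Unknown mass is therefore exactly the contaminant read fraction.
  Contaminant phylogenetic realism is a non-goal.
* **Read sampling**: one multinomial draw of the sample depth (default
  100 000) over variants + contaminants. Variant *i* of species *s* has
  probability `(1-c) * pct_s/100 / n_variants_s`; the contaminant pool
  shares `c` equally. `--exact-counts` replaces the draw with
  `round(depth * p)` — a noise-free surface on which the pipeline must
  return rho = 1 and Unknown = 0 exactly.
* **Dilution schedule**: `c_i = 1 - (1 - c0) * g^i` with `c0 = 0.01`
  and `g` solved so `c8 = 0.6`; strictly increasing, constant depth.

What the generator does **not** emulate: PCR bias and chimeras,
indels and quality-dependent errors, phylogenetically related
contaminants, 16S copy-number variation, or batch effects. Passing
tests therefore demonstrate the pipeline's correctness and its
qualitative contamination response, not classifier performance on real,
evolutionarily structured communities — where k-mer sets of distinct
species overlap far more than the enforced Jaccard ceiling allows here.

## Numerical and design choices

* TSV everywhere (no BIOM in v1); FASTA via Biopython; integers
  round-trip exactly, floats render at 6 decimals (round-trip to 1e-6).
* Theoretical percents must sum to 100 within 1e-6 and are never
  renormalized — an off-sum table surfaces a configuration mistake.
* Species profiles must sum to 100 within 1e-9 (conservation is
  asserted, not assumed).
* The pipeline refuses to run when the training set contains species
  missing from the theoretical table; the reverse (an expected species
  with no reference) only warns, as that species simply cannot be
  observed.
* Plots are pure views of the comparison outputs; SVG is canonical
  because, with a fixed hash salt and the date stripped, it is
  byte-deterministic and diffable in tests.
* Figure test and demonstration sizes — 4–8 species, 300–1500 nt,
  depths of 5 000–100 000, 10–20 generator seeds for statistical
  properties — were chosen so the full suite runs in seconds while
  leaving multinomial noise far smaller than the 1-point percent
  separation.

## Known limitations

* Species-level flat assignment only; no ranked lineage, no genus
  rollup.
* Forward-strand matching by default; mixed-orientation tables need
  `--both-strands`.
* Spearman's rho is reported without a significance test; with 8 taxa a
  p-value would be nearly meaningless anyway.
* No distance-based composition metrics (Bray–Curtis, Aitchison) and no
  cross-batch statistics in v1.
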