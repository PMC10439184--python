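# Methods

## Scope and data model

`pprscope` covers the downstream half of a size-fractionated
metatranscriptome rhodopsin analysis: it consumes assembled unigene
sequences and per-library expression tables (TPM or counts) and produces a
rhodopsin catalog, spectral calls, merged lineage contributions and
distance-matrix statistics. Read QC, assembly, clustering and read
quantification are upstream of this package; a standard TPM-from-counts
helper (`compute_tpm`) is provided as plumbing.

A *water sample* is one (station, depth layer, replicate) event; each water
sample has up to two sequenced libraries, the small (0.22–3 µm) and large
(3–200 µm) filter fractions, each with an RNA yield per liter of seawater.

## Reference panel

All annotation is anchored to a curated panel of reference rhodopsins
(FASTA + TSV), each entry carrying: family (PR, XR, GR, BR, SRI, ActR, ESR,
other), proton-pump status, the 1-based spectral-tuning-site coordinate
(PR-family entries only), the inclusive helix C–F residue span, λmax where
known, domain of life, and source taxon. Helix spans are stored per entry
rather than predicted, keeping the package deterministic and
self-contained; no transmembrane prediction is performed.

The coordinate system for "position 105" is pinned by `canonical_pr_id`
(default: the first green-absorbing PR in the panel, Leu105). The choice is
configurable because PR numbering conventions differ between reference
sequences; all residue coordinates in the package are 1-based inclusive.

The bundled panel is **synthetic**: entry IDs mirror the accessions that
conventionally delimit the PR/XR/GR families, but the sequences were
generated by seeded mutation from a synthetic canonical PR (within-family
divergence ~10–18%, between-family divergence ~50–70%). It exists so the
package is runnable and testable offline; real analyses should supply a
real panel through the same two-file interface.

## Identification

Queries are translated in six frames; ORFs are stop-terminated,
stop-to-stop segments above a length cutoff (no start-codon requirement,
since assembled transcript fragments routinely lack 5′ ends). Each protein
is locally aligned (affine-gap Smith–Waterman, BLOSUM62, gap open 11 /
extend 1) against every panel entry. E-values come from Karlin–Altschul
statistics with fixed constants for gapped BLOSUM62 (λ = 0.267, K = 0.041)
and search space = query length × total panel residues; with a desk-scale
panel this is a calibrated, reproducible ranking rather than a
database-size-dependent one. Hits are screened with the conventional
cutoffs, both strict: E-value < 10⁻⁵ and identity > 40% (identity =
matches / alignment columns).

The best hit per query is the maximal bitscore, ties broken by minimal
E-value then lexicographic reference ID; the query inherits the
reference's family, domain and taxon. A hit satisfies the completeness
criterion when its reference span fully contains the reference's helix C–F
span (inclusive); sequences failing it are excluded from classification
but remain in the catalog, flagged.

The low-expression filter removes a unigene only when its TPM is strictly
below 0.1 in **every** sample; a single sample at exactly 0.1 keeps it. It
is applied after annotation.

## Spectral classification

Family and pump status are inherited from the best hit. For PR-family
calls (optionally XR/GR via a flag, off by default — the blue/green
dichotomy is defined for proteorhodopsins), the query is globally aligned
(Needleman–Wunsch, BLOSUM62, gap open 10 / extend 1) to the canonical PR
and the query symbol in the column of the canonical tuning site is read
off: `'-'` if the query gaps that column. Determinism comes from taking
the aligner's first enumerated optimal alignment, which is fixed for fixed
inputs; an independent dynamic-programming oracle in the test suite
confirms the mapped column on constructed indel fixtures.

The residue rule is case-insensitive: Q → (BPR, 490 nm); M or L →
(GPR, 525 nm); anything else, including `X`, gaps and non-pump or non-PR
families → unclassified. Classification is a pure function of
(residue, family, pump status).

Overrides: a TSV of (pattern, forced class, note) rows, matched
case-insensitively as substrings against the call's source taxon or
unigene ID. The default table contains exactly the two documented
dinoflagellate corrections (*K. micrum*, *C. fusus* → BPR). Application is
idempotent; unmatched patterns warn rather than fail.

## Quantification

The size-fraction merge is a weighted mean with RNA-yield-per-liter
weights (formula in the README). Only yield *ratios* matter, so the unit
(µg/L in the fixtures) cancels. Because the formula is linear in each TPM
argument, the package applies it per unigene and aggregates; this is
algebraically identical to merging group sums:

```
merge(Σᵢ tᵢˢ, Σᵢ tᵢˡ) = Σᵢ merge(tᵢˢ, tᵢˡ)   (fixed yields)
```

— the weighted mean distributes over sums. Property tests assert
boundedness (merged value between the two fraction values) and this
additivity at 10⁻⁹ relative tolerance.

Replicates stay separate through merging; averaging happens only at
reporting time. A water sample missing one fraction is computed from the
present fraction alone and flagged (`fractions_present`). Merged values
are labelled "merged TPM contribution" because they are TPM-equivalent
mixtures, not the TPM of any single library.

## Statistics

Distances: Bray–Curtis (default) or Euclidean for abundance matrices, with
the convention that an all-zero sample is at distance 1 from any occupied
sample and 0 from another all-zero one; Euclidean over per-variable
z-scores (sample SD) for the environmental matrix, zero-variance variables
excluded with a warning. The environmental variable set is NO₂⁻, PO₄³⁻,
NO₃⁻+NO₂⁻, SiO₃²⁻ (µmol/L), depth (m), temperature (°C), salinity (PSU)
and the N:P ratio.

Mantel: r = Pearson correlation of strictly-off-diagonal triangle vectors;
p = (1 + #{r_perm ≥ r_obs}) / (1 + n_permutations), one-tailed for
positive association, permuting rows and columns of the second matrix
jointly under a seeded generator (999 permutations by default; the add-one
correction keeps p > 0). An exhaustive mode enumerates all n! relabelings
and returns the exact fraction. A tie epsilon of 10⁻¹² ensures the
identity relabeling counts as ≥ the observed statistic despite float
noise between scalar and vectorized code paths.

Partial Mantel controls a third matrix via the standard partial-correlation
identity on the triangle vectors (equivalent to correlating residuals of
simple regressions on the control triangle); permutations shuffle the
second matrix with the x–z correlation held fixed. Exactly collinear
control matrices are rejected — controlling for a perfect copy of either
argument leaves the statistic undefined (0/0), so near-copies are the
user-facing way to express "controlling for essentially itself".

Expression–abundance fits are ordinary least squares with Pearson r and
R² = r², for taxon-level scatter panels.

## Synthetic-data generator

The generator emulates the full sampling design — 2 stations (shelf C6,
slope C9) × 3 depths (SUR, DCM, BOT) × 2 fractions × 2 replicates = 24
libraries over 12 water samples — and plants recoverable structure:

* **Sequences.** Each unigene descends from a panel entry (sources drawn
  ~72% prokaryote / 28% eukaryote, PR-family-weighted) by per-site
  substitution at `divergence_pct` (default 10%), tuning site protected so
  the planted spectral label survives. Substitutions always pick a
  different residue. Generation is at the protein level; nucleotide
  fixtures are back-translated with a fixed codon per amino acid (enough
  to exercise ORF translation deterministically; no codon-usage model). A
  configurable fraction of sequences is truncated at a point inside the
  helix C–F span, for testing the completeness criterion.
* **Expression.** TPM = per-unigene lognormal abundance (µ = 3, σ = 1.5 on
  the log scale — heavy dominance, as in real transcript pools) × per-cell
  lognormal sample noise (σ = 0.4) × a spectral depth trend (3-fold per
  layer step; BPR up, GPR down, mirroring light attenuation) × a
  domain-by-fraction affinity (free-living bacteria enriched small,
  protists large), then rescaled. Every library column sums to exactly
  10⁶.
* **Planted shares.** In `exact` mode the per-fraction eukaryote share is
  solved jointly with the drawn RNA yields so the *merged*
  prokaryote:eukaryote split equals `planted_shares` (default 70:30) to
  float precision while the large fraction stays eukaryote-enriched; the
  generator verifies this internally. `noisy` mode multiplies cells by
  lognormal noise (σ = 0.05, ~5% technical variation) afterwards, so
  recovery holds only to sampling noise (≲1.5 percentage points at 400
  unigenes — lognormal dominance makes the effective number of unigenes
  much smaller than the nominal one).
* **Environment.** Depth, temperature and salinity follow fixed
  station/depth profiles with small measurement noise. The four nutrient
  variables are log-normal with surface-ocean magnitudes and are coupled
  to the *realized* eukaryotic-PPR community gradient (the standardized
  first principal coordinate of the Bray–Curtis matrix over merged
  eukaryotic PPR profiles). `env_effect_r` is defined on the
  distance-matrix scale — the scale a Mantel test estimates: the latent
  mixing weight is solved per realization so that the correlation between
  the community distance triangle and the z-scored Euclidean nutrient
  distance triangle equals `env_effect_r`. This compensates the two known
  attenuations (Gaussian |difference| shrinkage, and the imperfect
  one-dimensionality of Bray–Curtis) that would otherwise make a
  value-level copula parameter of 0.6 appear as a distance correlation of
  ~0.25. At `env_effect_r = 0` the weight is zero and nutrients are
  independent. Replicate casts are treated as independent water parcels
  (their own gradient draws); sharing a gradient across replicates makes
  samples non-exchangeable and inflates Mantel type-I error.
* **Taxon abundances.** A 16S/18S-style relative-abundance table whose
  per-taxon values track that taxon's merged PPR expression at
  `abundance_effect_r` (default 0.9) plus noise and an "Other" filler.

Everything is drawn from one `numpy` generator seeded by `config.seed`;
written bundles are byte-identical across runs.

### What the generator does *not* emulate

No read-level errors, assembly chimeras, codon usage, strain
microdiversity, inter-family homologous recombination, compositional
coupling between nutrient variables and depth, or rDNA copy-number bias in
the taxon table. Passing tests therefore demonstrate that the pipeline's
logic recovers planted structure under its stated assumptions — not that
the annotation screen is well-calibrated for real database searches.

## Numerical choices and degenerate inputs

* Alignment scoring: BLOSUM62 everywhere; local 11/1 (search), global 10/1
  (coordinate mapping); biopython's convention (first gap residue charged
  the open score) is adjusted so a length-k gap costs open + k·extend in
  the search path.
* TPM of an all-zero count vector is all-zero (not an error); zero or
  negative effective lengths are errors.
* Merge with both yields zero, or negative TPM, is an error; one missing
  *fraction* (not yield) falls back to the present fraction, flagged.
* Bray–Curtis zero-sample conventions as above; Mantel requires ≥ 4
  samples and errors on zero-variance triangles; exhaustive enumeration is
  intended for n ≤ 8.
* Spectral classification of `X` or gap at the tuning site: unclassified.

## Problem sizes used in tests

The suite and the acceptance script run communities of 120–500 unigenes,
detection experiments at 300 unigenes × 100 replicates, type-I calibration
at 1000 replicate pairs × 999 permutations (vectorized), and exhaustive
Mantel checks at n = 5 (120 relabelings). These sizes give stable
statistics for every contract while keeping a full run in the order of a
minute or two on one CPU; all of them scale up linearly via
`SimulationConfig`.

## Known limitations

* The E-value calibration is fixed, not fitted to the panel's score
  distribution; it ranks and screens correctly but absolute E-values for a
  28-entry panel should not be compared with database-search E-values.
* Spectral classification covers the position-105 dichotomy only; the
  secondary tuning site (Cys189-type effects) is deliberately out of
  scope, as is any structural modelling of the retinal pocket.
* The best-hit taxonomy is only as good as the panel: real communities
  contain rhodopsins without close panel homologs, which are silently
  absent from the catalog (as with any cutoff-based annotation).
* Partial Mantel permutes the second matrix only; other permutation
  schemes (e.g. residual permutation) are not implemented.
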