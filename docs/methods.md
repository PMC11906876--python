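# Methods

This note documents the models, conventions and design choices behind
`mutstab`, and what the synthetic cohorts do and do not establish about
real data.

## Stability classification and the Instability Heat Score

Stability change is the difference in folding free energy between variant
and wild-type protein (ΔΔG, kcal/mol; positive destabilising). A missense
substitution is a Disruption-of-Stability (DoS) variant when ΔΔG lies
outside the tolerated interval, by default (−0.5, 0.5) kcal/mol.
Boundaries are strict: a ΔΔG exactly at a cut-off is tolerated. The
convention is chosen for consistency with the Instability Heat Score's
"strictly above threshold" qualifying rule; for real-valued predictions
the boundary set has measure zero, so the choice is immaterial in
practice, but it is stated and applied uniformly (classification, tail
survival functions in the threshold scan, observed DoS counting, expected
DoS counting). Asymmetric tolerated intervals are supported in
classification; the IHS uses a single symmetric |ΔΔG| cutoff.

The IHS of a protein is the mean of |ΔΔG| over all possible substitutions
with |ΔΔG| strictly above the threshold, computed from an L×20 grid in
which wild-type cells and missing predictions are excluded. When no cell
qualifies the score is 0 with a qualifying count of 0 — unambiguous as a
sentinel, because any nonzero IHS necessarily exceeds the threshold. The
per-position profile reports (mean |ΔΔG| over qualifying cells, count) per
residue; its count-weighted mean recombines to the total IHS exactly, a
property the tests assert to machine precision.

ΔΔG grids are consumed, never computed: the exchange format is a long TSV
(`protein_id, position, ref_aa, alt_aa, ddg`, 1-based positions), with the
protein sequence reconstructed from the `ref_aa` column. Positions absent
from the table become all-missing rows (residue `X`); conflicting
duplicate keys or inconsistent references are errors.

## Threshold derivation by depletion scan

The tolerated interval is derived from the depletion of large-|ΔΔG|
missense variation in constrained relative to unconstrained genes.
Writing P̂ for the empirical survival probability within a stratum, the
upper cut-off is the smallest grid value t > 0 with

P̂_constrained(ΔΔG > t) / P̂_unconstrained(ΔΔG > t) ≤ depletion_cutoff,

and symmetrically on the left tail. Grid points where the unconstrained
tail holds fewer than `min_tail_n` (default 50) variants are not
evaluated; if no evaluated point qualifies the scan returns a sentinel
with diagnostics rather than a threshold.

Defaults: grid step 0.05 kcal/mol over (0, 3], `depletion_cutoff` 0.1.
The cutoff value was fixed analytically, before any end-to-end runs, by
requiring that the scan invert the generative model it is meant to
detect: if the constrained stratum is the unconstrained distribution
hard-truncated at the true tolerated bound b, the survival ratio is
positive below b (for Normal(0, 0.6) truncated at ±0.5 it is ≈0.47
already at t = 0.35, and ≈0.18 at t = 0.45) and exactly 0 at t ≥ b. A
permissive cutoff (e.g. 0.5) therefore stops on the shoulder below the
truncation point, while any cutoff below the near-boundary ratio — 0.1
comfortably so — recovers b itself. Both parameters are configurable, and
the scan is a formalisation of what was originally a choice made by
inspecting depletion plots; on real cohorts the ratio does not drop to
exactly zero, so recovered cut-offs sit at the first grid point of strong
depletion and should be read with the scan report (`threshold_scan.tsv`)
alongside.

The false-discovery rate of DoS classification is the fraction of
benign-labelled variants called DoS. Quantiles everywhere (box summaries,
group tables) use linear interpolation between order statistics so
summaries are bit-reproducible; whiskers extend 1.5·IQR, clipped to the
data range.

## Expected variants and constraint scores

All 3L possible SNVs of a coding sequence are enumerated with their
trinucleotide context (the reference base plus 5′/3′ neighbours) and
codon-translated consequence. Expected counts for a variant class are

E = k · Σ_{SNV ∈ class} rate(context, alt),

where the rate table holds relative per-site rates for all 64×3 (or,
strand-collapsed, 32×3) context/alternate pairs, and k is a calibration
scale fitted on synonymous variation — assumed neutral — as the
least-squares-through-origin slope Σ observed / Σ rate-sums across genes.
Edge codons lacking a flanking base get partial contexts; the default
policy imputes the table's mean rate (tallied), with a strict error mode
available. The default bundled rate table is a caricature of empirical
human trinucleotide rates (transitions 4× transversions, CpG C→T and its
reverse complement boosted 12×, normalised to mean 1); real analyses
should supply an empirical table in the same TSV format.

The constraint score for a gene is the upper bound of the 90% confidence
interval of the Poisson rate ratio O/E: with a flat prior on the ratio r,
the posterior is Gamma(shape O+1, rate E) and the bound is its 95%
quantile, capped at 2.0 (the published convention; configurable). For
O = 0 this is −ln(0.05)/E in closed form. A grid evaluation of the same
quantile (step 0.001 over the normalised Poisson likelihood) is provided
as a numerical cross-check and must agree within 0.002; the grid extends
past the cap far enough to cover the likelihood mass before capping,
since truncating the likelihood at the cap would bias the quantile
whenever the uncapped bound exceeds it.

pLoF observed/expected counts cover SNV nonsense only: frameshifts need
an indel model and canonical splice sites need intron context, both
outside a CDS-only SNV model. This understates absolute pLoF expectation
but leaves the DoS-vs-pLoF comparison interpretable, since both classes
are counted under the same enumeration. Observed counting uses distinct
(gene, position, ref, alt) variants with allele count ≥ 1 and no
allele-frequency ceiling by default. Deciles are ascending-rank bins of
the score (bin 0 = most constrained), sizes equal up to the remainder
(which goes to the lowest bins), ties broken by gene identifier.

## Structure metrics

Per-residue confidence values are read from the Cα B-factor field of
PDB/mmCIF files (first polypeptide chain by default; residues without a
Cα fall back to the mean over their atoms, logged). Predicted models
store pLDDT in that column; the ordered fraction counts residues with
pLDDT strictly above 70 on the 0–100 scale, and tracks whose maximum is
≤ 1 are auto-rescaled, reconciling the two conventions in circulation.
Experimental structures are summarised by the median B-factor (Å²); when
several partial structures exist for one gene, the median over all
residues of all supplied structures is used. Constraint groupings:
published-LOEUF deciles mapped to Most (bins 0–2), Intermediate (3–6) and
Least (7–9) constrained; S_het categories; or a binary pLi split at 0.5.

## The synthetic cohort generator

The generator's defaults are the study conditions for all shipped tests
and the acceptance script: 200 genes (300 for the constraint-recovery
experiment), log-normal protein lengths with median ≈ 400 amino acids
(log-mean 6.0, log-sd 0.45, floor 60), per-gene selection strength
s ~ Beta(0.6, 0.6), cohort of 1000 individuals with a per-site
observation scale of 5·10⁻⁵, and a tolerated bound of ±0.5 kcal/mol.

Mechanisms, each targeting a feature of the real data:

* **Disorder increases with constraint.** Expected disordered fraction is
  0.10 + 0.40·s, laid out as contiguous blocks (a two-state segment
  model) whose pLDDT is low (≈45) against high (≈88) ordered blocks.
* **Stability effects are muted in constrained proteins.** Disordered
  cells draw ΔΔG ~ Normal(0, 0.15) — essentially never DoS — and ordered
  cells Normal(0, 1.0·(1 − 0.5·s)), so IHS declines with s through both
  channels. Wild-type cells are exactly 0.
* **Purifying selection.** Every possible SNV becomes an observed
  candidate with probability 1 − exp(−rate·cohort·scale); candidates that
  are nonsense, stop-loss, or missense beyond the tolerated bound survive
  with probability (1 − s), all others survive. Hard thinning rather than
  a population-genetic diffusion: it creates exactly the depletion signal
  the threshold scan measures and is analytically checkable (the s = 0
  class proportions and s = 1 eliminations are asserted in tests).
* **Clinical labels.** Benign variants are sampled from SNV-reachable
  tolerated substitutions with 6% contamination from DoS cells — matching
  the false-discovery rate measured against curated benign variants, a
  stated condition of the study design — and pathogenic variants put 80%
  of their mass on destabilising (ΔΔG > 0.5) cells, reproducing the
  destabilising skew of curated pathogenic variation.

Everything is deterministic under a fixed seed, to the byte in written
fixtures. ΔΔG draws are independent across cells (no epistasis or
contact correlation); there is no demography, linkage or genotype
structure; allele counts are a convenience geometric draw. Consequently,
passing tests establish that the estimators invert the generative
mechanisms they target — truncation bounds, selection strength, class
abundances — not that real cohorts satisfy those mechanisms; rate-model
misspecification, coverage artefacts and prediction error in real ΔΔG
tables are all outside what the generator emulates.

## Pipeline

The full analysis runs: input generation or loading → synonymous
calibration → pLoF constraint (deciles define the strata) → threshold
scan (decile 0 vs decile 9; falls back to the configured ±0.5 with a
warning if the scan returns the sentinel) → IHS at the derived upper
cutoff → DoS constraint → decile confusion, LOEUF-difference ranking,
FDR against benign labels, per-decile ΔΔG summaries → report. Simulate
mode writes its fixtures to `inputs/` and reads them back through the
real readers, so both modes exercise identical downstream code; a test
feeds the generated fixtures through the real-data entry point and
asserts byte-identical outputs. Partial failure leaves completed stage
outputs plus an error manifest naming the failed stage. Provenance
(config hash, seed, library versions) is embedded in every report;
reruns are byte-identical.

Problem sizes in the shipped tests and acceptance script (200–300 genes,
10,000-variant strata, 20-seed threshold recovery, 50,000 benign labels)
were chosen as the smallest scales at which the targeted effects are
decisively resolved — e.g. the sign test on DoS-vs-pLoF abundance is
conclusive with ~60 unconstrained genes, and the threshold scan's
recovery error is governed by the 0.05 grid, not the sample — keeping a
full run in the tens of seconds on one CPU.

## Known limitations

* pLoF misses frameshift and splice variation (SNV nonsense only).
* Calibration assumes synonymous neutrality and uniform detectability;
  no coverage or quality corrections are modelled.
* The depletion scan needs well-populated unconstrained tails; with
  `min_tail_n` unmet everywhere it abstains rather than guessing.
* A single symmetric IHS threshold; length-dependent thresholds are
  supported only via user-supplied per-protein values.
* Structure handling reads the first model of a file and ignores NMR
  ensembles and normalised (z-scored) B-factors.
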