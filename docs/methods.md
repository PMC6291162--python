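# Methods

## De novo burden (`burden_stats`)

The null model treats each transmitted chromosome in a screened trio
cohort as an independent Bernoulli trial for a qualifying de novo event
(missense, nonsense or in-frame deletion) in the gene, with success
probability μ, the gene's published per-chromosome mutation rate from
trinucleotide-context models. The rate is an input, never recomputed.
With `N` probands the allele count is `n = 2N` (autosomal; X-linked
handling is out of scope) and the expected count is `nμ`.

The test statistic is the exact binomial upper tail `P(X ≥ k)` including
the observed count, one-sided, without mid-p correction. It is computed
through the regularized incomplete beta function (`scipy.stats.binom.sf`),
which is accurate at tail masses far below double-precision underflow of
term-by-term summation; unit tests verify agreement with exact rational
summation to 1e-12 relative for n ≤ 50 and with a direct-summation
Poisson oracle. The Poisson tail at λ = nμ is reported alongside; in the
regime of interest (n ≥ 1e4, nμ ≤ 1) the two agree within 2%.

The observed count is the number of qualifying de novo alleles at the
*family* level: monozygotic twins share one germline event and collapse
to a single allele, and variants of unknown inheritance are excluded.
When a site table is supplied, families from sites outside the screened
denominator are excluded from the numerator as well — observations
recruited outside the systematically screened cohorts would otherwise
inflate the test. The packaged site table's per-site proband split is
synthetic (only the 16,086 total is real) and is labelled as such.

Because the test is discrete and one-sided, its type-I error is at or
below nominal; the acceptance script verifies this on 10,000 simulated
null cohorts at study scale (with that cohort size and rate, rejection at
α = 0.05 occurs only for counts ≥ 2, giving an empirical level near
0.017).

## Regional depletion (`regional_constraint`)

The unit of analysis is the residue: a residue either carries at least
one high-quality (PASS-filter) population missense variant or it does
not, and either lies in the annotated binding region or does not. The
2×2 table with fixed margins is tested by Fisher's exact test. The
two-sided p follows the minimum-likelihood ("twin-tail") convention:
enumerate the top-left cell's support, sum hypergeometric point
probabilities not exceeding the observed table's (relative tie tolerance
1e-7). The one-sided lower tail — fewer variant-bearing residues inside
the region than chance — is always reported alongside, since the
sidedness convention materially changes the number (0.0168 vs 0.0099 on
the reference table). Note the two-sided p can be *smaller* than a
one-sided p when the observed table sits in the opposite tail; the
invariant is `p_two ≥ min(p_lower, p_upper)`.

The implementation enumerates with `scipy.stats.hypergeom.pmf` and is
cross-checked in tests against an exact rational-arithmetic enumeration
(exhaustive for all tables with total ≤ 16, sampled to cell counts of 60)
and against `scipy.stats.fisher_exact`.

Recurrence is reported descriptively: family-level de novo alleles per
codon (in-frame deletions counted at the first deleted residue), the
top-k codons (count-descending, index-ascending ties) and the allele
count they hold. An optional uniform-reassignment permutation test is
provided but is an extension beyond the core report, and includes the
observed arrangement in its tail so p is never zero.

## Contact annotation (`structure_contacts`)

A residue belongs to the binding region when any of its atoms (backbone
or side chain) lies within a distance threshold of any atom of any copy
of the requested ligand het code (union over copies; boundary-inclusive
comparison). The default threshold is 1.5 Å but is deliberately
configurable: over heavy atoms 1.5 Å is physically very tight (heavy-atom
hydrogen-bond distances run 2.5–3.5 Å), and region definitions published
at such cutoffs generally presuppose hydrogen-added models. For that
reason no authoritative residue set is hard-coded; regions derived
elsewhere are accepted as plain residue lists, and the packaged
24-residue list is an explicitly synthetic stand-in (G-box motifs mapped
onto the 206-residue chain) used only to exercise the pipeline.

Parsing uses gemmi. Waters are never ligands; hydrogens are dropped
unless requested; altloc duplicates keep the highest-occupancy location
(selected explicitly — gemmi's own pruning keeps the first conformer).
A configurable integer offset bridges structure numbering and sequence
numbering. BED export uses 0-based half-open intervals over maximal
consecutive runs.

Correctness is established by construction: the synthetic structure
generator places residues on a rigid backbone with 6 Å spacing and plants
one ligand atom opposite each declared contact residue at a randomized
distance strictly inside the threshold (clamped above an 0.8 Å atomic
overlap limit), applies a random rigid motion, and emits the declared set
as ground truth. Tests require exact recovery across 100 seeded
geometries plus threshold-monotonicity and rigid-motion invariance.

## Paralog mapping (`paralog_map`)

Homologous-position claims are made explicit through optimal global
alignment (Biopython `PairwiseAligner`, BLOSUM62, gap open 11 / gap
extend 1 — ubiquitous protein defaults, configurable). The alignment
yields a column map; `map_position` is injective over non-gap columns and
composes with the reversed map to the identity. On synthetic pairs with
tracked substitutions and short indels, mapped positions match the
generator's correspondence for ≥ 99% of residues at ≤ 10% divergence.
Canonical paralog sequences are not bundled as authoritative data; a
UniProt fetch helper is provided and the canonical-anchor tests (query 25
→ KRAS 14, query 128 → HRAS 117) run only when the sequences are present.

## Assay normalization (`assay_norm`)

GTPase luminescence measures *remaining* GTP, so the NTC mean is first
rescaled to 100 (making the raw values a percent-remaining scale — the
reading under which "subtracted from 100" makes the NTC the zero-activity
anchor) and activity is `100 − scaled signal`. Effector binding is
`raw / NTC-mean`, optionally divided by a per-construct western-blot
intensity factor. Both normalizations are scale-invariant, and NTC
activity = 0 / binding = 1 hold exactly by construction.

Group comparisons use Welch's unequal-variance t-test (two-sided) against
a chosen reference (wild type or NTC), with star tiers ****/***/**/* at
p < 1e-4 / 1e-3 / 1e-2 / 5e-2. Means, sd and sem are all reported since
published error bars are often ambiguous between the two. With
triplicates the Welch degrees of freedom can fall toward 2, so the tier
reached at a given group separation is draw-dependent; tests therefore
check the p-value against the closed-form Welch statistic (1e-10
relative) and tier-consistency rather than a fixed star count. Groups
with one replicate are skipped with a warning.

## Synthetic data (`synthetic_data`)

One root seed fans out to per-generator PRNG streams via fixed stream
identifiers, so adding a generator never perturbs existing draws; every
generator is a pure function of (config, seed). Defaults are the study
conditions: 16,086 probands, rate 6.16e-6, 206-residue protein,
24-residue region, 34 variant residues outside it, triplicate wells.
The cohort generator draws the allele count from Binomial(2N, μ) and
places alleles uniformly (or at configured hotspot codons); the
population generator scales in-region placement odds by a depletion
factor (0 = absolute depletion, 1 = uniform null). The generators
emulate the *statistical* structure of real inputs, not their artifacts:
no sequencing noise, no allele-frequency spectrum, no crystallographic
disorder — so passing tests establish the statistics and the geometry
rules, not robustness to dirty real-world files.

## Pipeline (`pipeline`, `cli`)

`run_all` executes whichever stages have configured inputs, skips the
rest with a logged reason, aborts with a stage-named error on hard
failure, and emits a schema-versioned JSON report carrying each statistic
with its inputs and conventions, full-precision values plus paper-style
renderings (3 significant figures for p-values, integer percents).
Reports are identical across reruns apart from the timestamp.

## Numerical and design notes

* The exact binomial tail for the reference inputs (8 events, 32,172
  alleles, μ = 6.16e-6) evaluates to 4.945e-11 (confirmed by exact
  rational summation and by R's `binom.test`); published renderings near
  this value may differ in the third significant figure due to
  intermediate rounding.
* A premature stop at codon 176 of a 206-residue protein removes 31
  residues counting the stop codon's residue and 30 strictly after it;
  the truncation report emits both conventions with a consistency flag.
* Percentages in cohort summaries are rounded to integers; denominators
  exclude not-reported entries; an empty denominator yields an undefined
  percent rather than 0.
* Phenotype values serialize as `+` / `-` / `NR`; the parser accepts both
  compact (`p.(V25M)`, legacy `R176X` stops, `A158del`) and three-letter
  (`p.(Arg176Ter)`) protein-change notation. Full HGVS (frameshifts,
  splice, intronic) is out of scope.
* Problem sizes: suites run ~100 seeded synthetic structures, 2,000–4,000
  simulated cohorts and 10,000 null replicates in the acceptance script;
  exhaustive Fisher enumeration covers all tables with total ≤ 16 plus
  seeded random tables to cell counts of 60.

## Known limitations

* The binding-region residue set for a real structure depends strongly on
  whether hydrogens are present and on the threshold; the tool makes the
  rule explicit and reproducible but does not claim to reproduce any
  particular published residue set from heavy atoms alone.
* The burden test conditions on a single gene; genome-wide
  multiple-testing correction across genes is out of scope.
* Mutation rates are consumed as constants; no trinucleotide model is
  fit.
* The assay module handles long-format CSV exports, not vendor plate
  formats, and does no dose–response modeling.
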