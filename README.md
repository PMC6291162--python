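# ralascope

Statistical and structural analyses for establishing a small GTPase as a
dominant developmental-disorder gene from a shared-cohort case series —
built around the RALA DD/ID cohort (11 probands, 10 families) but usable
for any gene with the same evidence structure.

When de novo variants in one gene surface across sequencing sites, the
case for causality rests on a handful of quantitative claims:

1. **Burden** — the de novo count exceeds what the gene's mutation rate
   predicts. With `N` screened trio probands (so `n = 2N` chromosomes)
   and a published per-chromosome missense+LoF rate `μ`, the null is
   `X ~ Binomial(n, μ)` and the evidence is the exact upper tail
   `P(X ≥ k)` (a Poisson tail with `λ = nμ` is reported alongside).
2. **Regional depletion** — population missense variation avoids the
   functional region. Each residue is in/out of the annotated
   nucleotide-binding region and does/doesn't carry a high-quality
   population missense variant; the 2×2 table is tested with Fisher's
   exact test (two-sided, minimum-likelihood convention).
3. **Clustering** — de novo alleles recur at few codons, counted at the
   family level (monozygotic twins = one mutational event).
4. **Structure** — the binding region itself is derived from a ligand-bound
   structure: a residue is annotated when any of its atoms lies within a
   distance threshold of any ligand atom.
5. **Paralogy** — affected residues are mapped onto disease-associated
   positions in paralogs via explicit global alignment (BLOSUM62,
   affine gaps).
6. **Function** — plate assays (GTPase luminescence, effector-binding
   absorbance) are normalized to a no-template control and compared by
   Welch's t-test with conventional star tiers.

A synthetic-data module generates cohorts, population-variant placements,
ligand-bound structures with declared ground-truth contacts, and replicate
plate signals, so the whole pipeline is testable offline.

## Worked example

The package ships a transcription of the cohort's genotype/phenotype
table, a synthetic site split of the 16,086 screened trio probands, and a
synthetic stand-in binding-region list (see file headers for what is
literal and what is invented). Running the pipeline:

```bash
ralascope burden --rate 6.16e-6 --probands 16086 --observed 8
```

prints (abridged):

```json
{
  "expected_denovo": 0.19817952,
  "fold_enrichment": 40.36747738342306,
  "observed_denovo": 8,
  "p_binomial_upper": 4.9450457456486193e-11,
  "p_poisson_upper": 4.949137827565768e-11
}
```

Eight de novo events where 0.198 were expected is a ~40-fold enrichment
with a tail probability of ~4.9e-11: far beyond any genome-wide
multiple-testing burden. The other stages:

```bash
ralascope recurrence --cohort src/ralascope/data/table1_variants.tsv
# -> 9 de novo family alleles, 6 at the two top codons (25 and 128)

ralascope depletion --region src/ralascope/data/region_rala_synthetic.txt \
    --population-variants pop_residues.txt --protein-length 206
# -> table [[0,24],[34,148]], two-sided Fisher p = 0.0168,
#    lower-tail p = 0.0099
```

No variant-bearing residues among the 24 in-region positions, against 34
of 182 outside, is unlikely under uniform placement (p ≈ 0.017): the
binding region is selectively depleted. Annotating a region from a
structure and mapping residues onto paralogs:

```bash
ralascope annotate-region --structure complex.pdb --ligand GDP --threshold 1.5
ralascope paralog --query RALA.fa --targets KRAS.fa HRAS.fa \
    --positions 25 128 158 \
    --known-positions src/ralascope/data/known_disease_positions.tsv
```

Canonical paralog sequences are not bundled; fetch them once with
`ralascope.paralog_map.fetch_uniprot_fasta` (RALA P11233, KRAS P01116,
HRAS P01112) and the paralog integration tests will pick them up from
`tests/data/paralog_sequences/`.

A full run from one YAML config (`ralascope run --config run.yaml`)
executes every stage with configured inputs, skips the rest with logged
reasons, and writes a versioned JSON report.

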