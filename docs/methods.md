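# Methods

## Model

The per-variant score is `−D · log10(f1 · f2)`, summed per gene per
individual. The model's premises: variant deleteriousness and population
rarity multiply into evidence of pathogenic burden; zygosity enters through
the allele-frequency pair, so for a rare allele (frequency `f_a → 0`) a
heterozygote contributes `−D·log10(f_a·(1−f_a)) ≈ −D·log10(f_a)` and a
homozygote exactly twice that. Homozygous-reference and missing genotypes
contribute exactly zero rather than a small positive term, keeping the
absence of qualifying variants at score 0. Scores are additive within a
gene, comparable across individuals for the same gene, and deliberately not
comparable across genes (gene length and constraint dominate between-gene
differences); all downstream use is within-gene ranking.

### Deleteriousness weight D

The raw metric is CADD-phred-scaled. The mapping to the unit interval is
configurable (`d_transform`):

- `clip_scale` (default): `D = min(raw, d_cap)/d_cap` with `d_cap = 40` —
  CADD 40 corresponds to the top 0.01% of possible substitutions, so the cap
  loses essentially no dynamic range while bounding a single variant's
  contribution;
- `raw`: no transform, for users who want phred units to flow through;
- `rank_unit`: empirical rank of the raw score among the cohort's scored
  variants mapped to (0, 1], an alternative normalization that is robust to
  the metric's scale but cohort-dependent (it is the one fitted state of
  `GenePyScorer.fit`).

### Allele frequency

Frequencies come from an external reference population (gnomAD-style
annotation column), not from the cohort itself, so one sample's score never
depends on the others' genotypes. Absent frequencies and frequencies below
`af_floor = 1e-5` are floored there — about a singleton in a 50k-genome
reference — which bounds a single homozygous variant's summand at
`−log10(1e-10) = 10` under the default transform. The frequency is also
capped at `1 − af_floor` so the heterozygote's reference-allele factor stays
positive. `af_floor` must lie in (0, 0.5).

### max_variant_mode

An optional dominant-disease mode scores each gene by its single
highest-scoring variant instead of the sum, preventing long genes from
accruing high scores out of many modest rare variants. Default off; the
recessive workflow relies on additivity.

## Quality control

Order of operations: genotype masking, then site filters, then scoring
selection.

- Genotype masking: calls with depth < 10 or GQ < 20 become missing.
  Thresholds are inclusive minima (a DP-10/GQ-20 call survives). Masking is
  idempotent and total.
- Site filters: mean GQ over non-missing calls must exceed 35 strictly;
  call rate (non-missing / all VCF samples) must reach 0.70 inclusively.
  Mean GQ is computed after masking by default (a masked call's GQ is not
  trustworthy); `mean_gq_post_mask=False` restores the pre-masking mean for
  pipelines that filter sites first. The call-rate denominator is every
  sample in the VCF, including those the mask removed.
- Scoring selection: variants coding ±8 bp on any transcript (a boolean
  input annotation; this package never computes consequences) with raw
  deleteriousness ≥ 15, inclusive. Variants with absent deleteriousness are
  excluded and counted separately. The CADD-15 floor exists to stop long
  genes accumulating noise from many low-scoring rare variants.

## Ranking, triage, prioritization

Competition ("min") ranking: rank 1 is the highest score, tied scores share
the minimal rank, the next distinct score's rank is the count of strictly
higher scorers plus one. Top-N selection keeps every entry with rank ≤ N
(ties straddling the cutoff are all kept — the only reading under which
"retain all with rank ≤ 5" is coherent) but never entries with score 0: a
zero score means no qualifying variant, which cannot be a missed biallelic
diagnosis. Within a tie, output order is by sample id purely for
reproducibility.

Triage of selected entries is a partition: unaffected; affected-solved
(split by whether the established diagnostic gene is the ranked gene);
affected-unsolved with zero HPO terms; with fewer than `min_hpo_terms`
(default 2, operationalizing "insufficient phenotypic data" — judging terms
*non-specific* is clinical review and out of scope); else assessable.

For each assessable (participant, gene): all non-reference genotypes with
deleteriousness ≥ 15 qualify. The candidate is a homozygous variant when one
sits in the top two by variant score; otherwise the two highest-scoring
heterozygous variants (a putative compound het), extras reported as context.
The score-aware homozygote rule matters: a common, weakly scoring background
homozygote must not displace a rare damaging het pair.

Trio phasing from parental genotypes: each het variant traced to a different
single parent → trans; both to the same single parent and absent from the
other → cis; anything uninformative (missing parents or genotypes, both
variants in both parents) → unknown; a child variant absent from both
parents → unknown with a de-novo/Mendelian-inconsistency note. No read-backed
or population phasing is attempted.

Deprioritization flags: MANE-noncoding (any candidate variant explicitly
flagged non-coding on the MANE transcript), common-in-call-set (cohort
alt-allele frequency computed from the cohort's own genotypes > 5%;
allele — not genotype — frequency), non-segregating (an affected relative in
the same pedigree family with complete genotypes lacks the candidate
configuration; relatives with missing genotypes are uninformative),
in-cis, and no-second-hit (a solitary heterozygous variant).

Tier policy, in precedence order: CLOSED (withdrawn participant) →
EXCLUDE (any of common/non-segregating/cis/single-het) → LOW (MANE-noncoding,
even for otherwise pathogenic pairs — weak evidence, not a hard exclusion) →
TOP (homozygous P/LP, or P/LP pair phased in trans) → MIDDLE (everything
else: VUS-containing pairs, unphased pairs). Per variant the effective class
is the more pathogenic of the ClinVar and ACMG/AMP input annotations (both
are consumed, never computed). The policy is a small configurable rules
object (`TierRules`, YAML-loadable) because the full decision table is a
matter of laboratory policy; the defaults make the tier function total and
deterministic over the whole flag × class × phase space, with TOP reachable
only with zero hard flags.

## Synthetic cohorts

The generator emulates what the method assumes about real data: site allele
frequencies log-uniform on [1e-5, 0.5]; genotypes drawn under Hardy-Weinberg
at each site's frequency; deleteriousness a bulk-plus-tail mixture (90%
uniform on [0, 20], 10% on [20, 45]) so roughly a third of sites clear the
CADD-15 floor and the filters do non-trivial work; 70% of sites coding ±8 bp,
90% of those MANE-coding; ~30% of samples arranged in Mendelian-consistent
trios (child drawn one transmitted allele per parent); per-call DP ~
Poisson(35) and GQ mostly 60–99 with 5% low outliers, plus rare site-wide
pathologies (2% low-GQ sites, 2% dropout sites) to exercise the site
filters. Gene lengths are log-uniform over 5–50 sites, probing the long-gene
noise concern.

Plants: each planted sample is a trio child, affected and unsolved with
three HPO terms, carrying a biallelic genotype at frequency 1e-5 with raw
deleteriousness 40 and ClinVar class P by default — homozygous, compound het
in trans, or in cis, per configuration. Parents carry the expected single
alleles so phase is recoverable. A truth table records every plant with its
expected phase and tier.

Not emulated: linkage disequilibrium and haplotype structure, sequencing
error and genotyping bias, population stratification, relatedness beyond
nuclear trios. Passing tests therefore demonstrate the pipeline's arithmetic
and decision logic under the model's own assumptions, not robustness to the
artefacts of real call-sets.

## Numerical and design notes

- VCF positions are 1-based, BED intervals 0-based half-open; conversion
  happens once at read time. A variant on an interval's end coordinate is
  outside the gene.
- Multi-allelic records are decomposed into one biallelic record per
  alternate allele, keeping the original call's DP/GQ on each (the filters
  are per-genotype and allele-agnostic). A variant overlapping two gene
  intervals contributes to both genes independently.
- Genotype calls are stored as per-variant numpy arrays aligned to the
  cohort's sample order; this keeps masking and scoring vectorised over
  samples and makes the 200-replicate recovery check cheap on one CPU.
- Matrix TSVs print cells with `%.17g` and are re-read with the round-trip
  float parser, so write/read is bit-exact; each matrix carries a
  fingerprint hashed from its filter and score configs, and ranking a new
  matrix against a reference with a different fingerprint is an error.
- Hemizygous-style single-allele calls are not modelled separately; the
  simulator emits diploid genotypes only, and a real chrX male call coded
  1/1 scores as homozygous (the maximally informative reading).
- Problem sizes used in validation: the oracle-equivalence check runs a
  500-sample, 25-gene cohort; the recovery property 200 replicates of the
  default 1000-sample, 50-gene cohort; the reference-ranking check a
  1010-sample cohort split 1000 + 10. Each was chosen as the smallest size
  at which the property is meaningfully exercised (cohort-level filters,
  ties, phase and tier routing all active).

## Known limitations

- Phasing uses parental genotype presence/absence only; a variant carried by
  both parents leaves phase unknown even when transmission could sometimes
  be resolved from homozygosity patterns.
- The candidate is limited to the top-two-by-score variants; genuinely
  triallelic-plus configurations surface only as context.
- Phenotype-to-gene semantic matching (HPO overlap with the gene's disease)
  is deliberately not automated; triage stops at "assessable".
- Between-gene score comparison and pathway-level aggregation are
  unsupported by design.
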