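# Methods

This note documents the models, procedures, parameter choices and known
limitations of `synoribo`. It is the package's own account of its science;
every empirical number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## The question and the design

A heterozygous tumor-specific synonymous site carries an ancestral and a
derived allele in the same tumor library. Because both alleles share the
library, the cell population, and the trans-acting environment (tRNA pools,
initiation factors), the ratio of A-site footprint density between alleles
isolates the *cis* effect of the base change on local elongation speed.
`synoribo` asks whether optimality-increasing synonymous changes (A/T → C/G)
speed elongation, whether optimality-decreasing ones (C/G → A/T) slow it,
and whether these two mutation classes distribute differently over oncogenes
and tumor suppressor genes (TSG).

All coordinates are transcript-space, 0-based, half-open, one isoform per
gene. This removes genome alignment, liftOver and splicing from scope while
preserving every downstream quantity; consumers of real data are expected to
deliver pileup count tables and read alignments already projected onto
transcripts (base/mapping-quality filtering is assumed done upstream and is
recorded, not enforced).

## Variant polarization and the two filter tiers

A site is polarizable only when the transcript reference base equals the
outgroup base; then ancestral = reference and derived = the single
non-reference base observed (count > 0) in tumor RNA. Departures are
classified, never silently dropped: `non_ancestral_ref` (reference disagrees
with outgroup), `missing_outgroup` (outgroup base N), `multiallelic` (two or
more observed non-reference bases — a site where support is split is treated
as unreliable rather than resolved by majority), and `monomorphic` (no
non-reference base at all; these arise naturally from binomial sampling and
are reported for accounting). The per-stage report reconciles input rows
against these categories exactly.

*Loose tier*: normal RNA coverage ≥ 5 with zero derived reads, and the tumor
shows both alleles (derived fraction strictly < 1; a 100%-derived tumor site
is indistinguishable from a reference error). "Zero derived" is exposed as
`max_derived_in_normal` (default 0) for libraries with known contamination.

*Strict tier*, five criteria evaluated on the same counts: (1) normal RNA
≥ 20, zero derived; (2) normal A-site coverage ≥ 20, zero derived in the
A-site tri-nucleotide; (3) tumor RNA ≥ 20 with both alleles ≥ 3; (4) tumor
A-site ≥ 20 with both alleles ≥ 3; (5) absence from the known-SNP panel
(membership is by site, not by allele). Strict-pass ⊂ loose-pass by
construction, and the implementation is checked against an independent
scalar re-application of the five criteria (exact set equality on 1,000
synthetic sites).

Consequence annotation translates the ancestral and derived codons directly
(5′/3′ UTR by position; synonymous ⟺ identical amino acid; stop gained or
changed → nonsense; otherwise missense). Per-patient variant sets are merged
as a union keyed by (gene, position, derived allele); the same site with
different derived alleles in different patients stays as separate entries.

## P-site offsets and the A-site

Initiating ribosomes pile up with their P-site on the start codon, so the
histogram of footprint 5′ ends relative to `cds_start` (window −40..+10)
peaks at `−offset` for each read length. The offset is the argmax of that
metagene, independently per length (no smoothing across lengths — real
libraries show length-specific offsets), ties broken toward the smaller
offset. A length is QC-flagged and its reads dropped (never given a default
offset) when it has < 200 in-window reads, when the peak is below 2× the
median window bin, or when the dominant-frame fraction is below 0.6 — note
the dominant frame is `(−offset) mod 3`, not necessarily frame 0, which is
why the concentration and not the frame-0 fraction is tested. The A-site
interval of a read is `[5′ + offset + 3, 5′ + offset + 6)`; only reads whose
A-site covers a site contribute footprint counts to it.

On simulated reads with offsets {28: 12, 29: 12, 30: 13, 31: 13}, frame
fidelity 0.9 and 2,000 reads per length, recovery is exact (integer
equality); this is asserted in the acceptance suite.

## Allele-specific A-site density and its statistics

Density is the raw ratio `A-site count / RNA count` per allele per sample.
No within-sample library normalization is applied — both alleles share the
library, so the tumor ancestral-vs-derived comparison is unbiased as is.
Cross-sample comparisons (normal vs tumor) are computed and reported but
explicitly labelled "not library-size normalized".

Group tests per optimality class, pooled across patients: two-sided
two-sample KS tests between the three density distributions, and a paired
t-test of (tumor-ancestral, tumor-derived) across sites, applied to the
untransformed densities (a log2 option exists but is off by default; the
plain test is the primary procedure and its calibration is verified
empirically). Under null speed factors the paired test's empirical type-I
error at α = 0.05 over 1,000 replicates of 100 sites sits inside
[0.03, 0.07] (the acceptance suite computes it each run; a 20,000-replicate
check during development put it at ≈ 0.050).

## Gene level

SNP density is `1000 × count / CDS length` per optimality class, using the
merged (union across patients) variant sets, at both filter tiers.
Enrichment is tested by two-sided KS between the per-gene density vectors of
oncogenes and TSG, plus an optimal-vs-non-optimal comparison within the
remaining genes as a negative control. Genes annotated as both oncogene and
TSG should be excluded upstream in the class table; unlisted genes default
to "other". Top-gene rankings sort by density, break ties by raw count then
gene id.

TE is `RPKM_RPF / RPKM_mRNA` with `RPKM = 10⁹ × count / (length × library
size)`; genes with zero mRNA RPKM are undefined and excluded. The regression
response is `log2(TE_tumor / TE_normal)` — the log form symmetrizes up- and
down-regulation and leaves all sign conclusions unchanged; the raw ratio is
available via `log_response=False`. Predictors (optimal count, non-optimal
count, gene length, dN, expression, GC content) are min-max scaled to
[−1, 1] via `x′ = 2(x − min)/(max − min) − 1`, the minimal transform that
achieves the stated range, then fit by OLS with intercept. Rank-deficient
designs abort with the list of collinear predictors. The gene-level counts
in the bundled generator are single pooled normal and tumor libraries, so TE
is computed once per condition rather than per patient and averaged; with
per-patient gene counts the same functions apply per patient.

## The synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions every recovery property is measured under:

| parameter | default | meaning |
|---|---|---|
| `n_genes`, `n_onco`, `n_tsg` | 500, 60, 60 | gene panel and class sizes |
| `cds_len_range` | 300–2400 nt | CDS lengths (multiples of 3) |
| `n_patients` | 10 | tumor/normal pairs |
| `rna_depth` | 50 | mean RNA reads per site (Poisson) |
| `tumor_allele_fraction` | 0.5 | derived fraction in tumor (binomial) |
| `base_density` | `rpf_depth/rna_depth` = 0.5 | ancestral A-site/RNA ratio |
| `speed_factor_optimal` | 0.5 | derived-allele density factor, optimal |
| `speed_factor_nonoptimal` | 2.0 | derived-allele density factor, non-optimal |
| `mut_rate_per_kb` | 1.0 | baseline synonymous rate per class per kb |
| `enrich_opt_onco`, `enrich_nonopt_tsg` | 3.0 | class enrichments |
| `offset_by_length` | {28:12, 29:12, 30:13, 31:13} | true P-site offsets |
| `frame_fidelity` | 0.9 | 5′ ends on the true frame (±1 nt otherwise) |
| `panel_fraction` | 0.2 | injected variants also placed in the SNP panel |

Injected variants are third-codon-position changes inside four-fold
degenerate codon families, so every injected change is synonymous by
construction; A↔T / C↔G changes (5% of the rate) exercise the unclassified
path, and small decoy fractions produce `non_ancestral_ref` and
`missing_outgroup` sites so the exclusion paths are testable. Normal samples
never receive a derived allele. Footprint counts per allele are
`Poisson(RNA count × base_density × speed factor)`, which makes the expected
derived/ancestral density ratio equal the speed factor exactly — the
closed form the recovery tests check (e.g. mean derived density 0.25 at
base density 0.5 and factor 0.5, within 10% at ≥ 200 sites). Reads place
their P-site on the start codon with probability 0.25 (the initiation
pile-up the calibration needs) and uniformly on CDS codons otherwise.
The heterozygous allele fraction of 0.5 is a modeling choice (tumor purity
and copy number are not modeled) and is exposed as a parameter.

What the generator does **not** emulate: sequencing error beyond allele
sampling, indels, splicing, isoform mixtures, mappability artefacts,
position-dependent footprint biases, or correlated noise between RNA and
footprint libraries. Passing recovery tests therefore demonstrates the
correctness of the inference machinery under the stated generative model,
not robustness to every artefact of real libraries.

## Problem sizes and determinism

Simulation-backed checks use 100–200 sites per class, 1,000 replicates for
null calibration, 100 replicates at 240/242 gene-set sizes for enrichment,
and 1,000 genes for regression recovery — sizes at which every targeted
effect is overwhelmingly resolved (paired-test p < 1e−6 for the 2× speed
factors) while the full suite runs in seconds. All randomness flows through
`numpy.random.default_rng` seeded from a single integer; the pipeline writes
no timestamps, so rerunning with the same seed and config is byte-identical,
which the acceptance suite asserts on the whole output tree.

## Known limitations

- Optimality is the GC-ending direction rule; a frequency-derived optimal
  codon table (species-specific) is a plausible extension, not attempted.
- Panel exclusion is by site, so a known SNP with a different ALT allele at
  the same position is also excluded (conservative).
- The paired t-test on raw density ratios is slightly heavy-tailed at low
  coverage; the strict filter's coverage floors keep it calibrated, and the
  log2 option offers a robust alternative.
- Multiallelic tumor sites are excluded outright rather than resolved;
  genotype-likelihood modeling is out of scope.
- TE fold changes use pooled libraries in the bundled generator; patient
  fixed effects are not modeled.
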