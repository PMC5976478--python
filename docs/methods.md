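# Methods

`lumdriver` re-implements, as a tested library, the downstream analysis of
somatic single-nucleotide variants (SNVs) in a small luminal (HER2-negative)
early-onset breast-cancer exome cohort: evidence-based driver-candidate
scoring, trinucleotide mutational-spectrum profiling, mutation-load and
recurrence statistics, a background-rate gene-significance test with FDR
control, and the cohort cross-tabulations of DNA-repair and
transcription-regulation genes. Upstream steps (alignment, somatic calling,
annotation) are out of scope; the package starts from called, annotated SNV
tables.

## Data model

An SNV observation carries its sample, gene, 1-based position, ref/alt
alleles, the two flanking reference bases, and a consequence class. Flanks
are explicit columns so no reference genome is needed (an optional helper
fills them from a user FASTA). The surveyed territory is a scalar, 62 Mbp by
default (the exome capture footprint); it is a parameter because capture
intervals differ between designs. Evidence vectors mirror the cohort's
published evidence table: Cancer Gene Census (CGC) membership, CCGD mouse
insertional-mutagenesis ranks (A–D/NR), a functional-domain flag, prior
reports of the same variant, gene-level SNV frequencies, and the calls of
five assessment algorithms (FATHMM, PolyPhen, SIFT, Align-GVGD, CHASM).
Missing evidence is an explicit state, never an implicit zero.

Gene symbols are keyed upper-case on the pre-slash token of aliases
("RBM16/SCAF8" keys as RBM16) while the verbatim alias is preserved in
stored tables.

## Driver-candidate scoring

Both rubrics are additive: CGC membership 3 pts; best CCGD rank A/B/C/D →
2/1.5/1/0.5 pts (NR unscored); functional domain 0.5; gene SNV frequency
≥ 1 % in all cancers and in breast cancer 0.5 each; the same variant
previously reported in breast **or** other cancers 0.5 (a single bonus —
this, rather than a cumulative one, reproduces the known-hotspot rows);
nonsense/frameshift consequence 1.5. System 1 adds 1 pt when ≥ 3 of the five
algorithms call the variant pathogenic; System 2 drops Align-GVGD and awards
0.5 for exactly 2 of 4 calls, 1.0 for 3–4. Labels: `CGC` if census-listed,
else `PD` (candidate driver) at ≥ 3.5, `pd` (possible driver) at ≥ 2,
`Neutral` below.

Vote conventions the source rubric leaves implicit, fixed here because they
reproduce the printed worked examples:

* Align-GVGD votes pathogenic at class ≥ C35 (needed for the CIITA 4.5 row;
  consistent with every reproducible row).
* CHASM votes pathogenic at p < 0.05 (CHASM is a driver classifier; small p
  supports driver status; needed for the 7.5-point hotspot rows).
* Missing calls contribute no vote and thresholds are absolute counts.

The packaged evidence table's domain free-text is pre-resolved to a boolean:
named functional/Pfam domains are true; "no functional domain", repeat
annotations, low-complexity/disorder/coiled-coil tracks are false. Two
columns of softer evidence (survival association, literature support) carry
configurable weights defaulting to 0; the published point list omits them,
and several printed totals evidently draw on such unstated points. Those
rows cannot be reproduced by any single consistent rubric and are excluded
from exact-match tests; the label bands are still verified against every
printed total. Under the default weights the score ceiling is 8.0 for a
missense variant and 9.5 with the truncating bonus (asserted by exhaustive
enumeration of the evidence lattice). All weights/thresholds live in
`RubricConfig`, overridable from YAML.

## Trinucleotide spectrum, loads, recurrence

Substitutions are strand-normalized to a pyrimidine reference (COSMIC
convention): purine-reference observations are reverse-complemented,
including their flanks. 6 classes × 16 flank pairs give the 96 trinucleotide
mutation types; zero categories are retained. "Non-silent" excludes
{synonymous, intron, utr3, utr5, intergenic} by default and is configurable,
since the source does not enumerate the set. Mutation rate is count /
territory(Mbp); the source's printed ~1.9/Mbp mean rate uses an unstated
(likely depth-covered) denominator, so rates here are exposed as a
parameterized computation, not a pinned constant. Recurrence identity is
positional — (chrom, pos, ref, alt), not gene + protein change — matching
the stated dedup rule; the multiplicity histogram satisfies
total = Σ k·hist[k] and unique = Σ hist[k] by construction.

## Background-rate significance

The published pipeline's significance stage is unpublished in detail; the
implementation here is a re-derivation from its stated assumptions —
per-patient mutations independent and homogeneous over coding territory,
combined by "the convolution law" — not a byte-level port. For gene *g* of
coding length *L* in territory *T*, patient *i* with non-synonymous load
*n_i* hits the gene at least once with probability 1 − (1 − L/T)^{n_i}
(heterogeneous across patients, homogeneous within, since each patient's own
background rate is used). The number of patients hit is Poisson-binomial;
its exact tail P(X ≥ k) is computed by iterative convolution of the count
distribution, appropriate when samples are few and normal approximations
unreliable. Gene p-values are corrected with Benjamini–Hochberg step-up
q-values (computed via `statsmodels.stats.multitest`; tests verify it
against a direct transcription of the step-up definition) and flagged at
FDR < 10 %.

Whether the statistic should count patients or mutations is ambiguous in the
source; both are implemented (`statistic="patients"` default,
`"mutations"` convolves the per-patient binomial counts with tail-mass
folding, exact at the tested k). On sparse cohorts the two agree closely.
Numerical notes: the hit probability uses `expm1`/`log1p` to avoid
cancellation at tiny L/T; the tail complements the lower-tail sum, keeping
absolute error ≲ 1e−15 for cohort-sized inputs; BH ties are resolved
stably and q-values clipped to [0, 1].

## Cohort cross-tabulations

The combined cohort (8 in-house + 29 literature/COSMIC tumors = 37) is
summarized with an explicit denominator, because the source tables list only
affected samples. The DNA-repair cross-tab projects per-sample gene lists
onto a packaged gene → mechanism map over {BER, NER, MMR, HRR, NHEJ, DDC,
TLS}; genes outside the map never appear. The truncating summary flags each
sample's nonsense/frameshift genes for CCGD-A/B and
positive-regulation-of-gene-expression membership; the expression set is a
packaged static list transcribed from the published table (the original was
a live enrichment-service query). Two literature samples print only gene
counts, not lists; the fixture carries those counts and sample-level flags
use them. Printed percentages round half-up to one decimal, with the
unrounded fraction carried alongside (the source itself prints both 43 %
and 43.2 % for 16/37).

## Synthetic cohorts

The generator's defaults are the emulated study conditions: 8 samples,
297 private variants plus five variants shared by two samples and one shared
by three (310 observations, 303 unique), per-sample loads confined to 19–74,
C>T fraction 0.39 with the other five classes equal, flank contexts uniform
within class (the source gives only class-level structure; context
enrichment is an optional parameter, off by default), consequences drawn
from a categorical resembling an exome consequence mix, territory 62 Mbp.
Private variants are allocated multinomially with rejection until loads fall
in range; shared variants and gene "spikes" (a gene forced into *m* samples,
for signal-recovery tests) are constructed exactly. Evidence fields are
independent draws from categorical priors shaped like the packaged evidence
table, with degenerate presets (`all_negative`, `forced_driver`) for
boundary tests. A single seeded `numpy` generator drives each run; identical
parameters and seed give byte-identical files.

What the generator does **not** emulate: positional clustering along
chromosomes, signature-specific context enrichment, correlated evidence
fields, and germline variation. Passing tests therefore demonstrate
correctness of the arithmetic and error control under the stated model, not
robustness to those real-data features.

## Problem sizes used in the test and acceptance runs

Worked-example scoring and cross-tabs run on the packaged tables (42
evidence rows, 37-tumor denominator). Property tests use 2 000–10 000
simulated variants; the exactness of the Poisson-binomial tail is checked
against full 2^n enumeration up to n = 12; null error-control uses 500
seeded replicates of 150 genes × 8 patients. These sizes give 3-standard-
error resolution on every recovered parameter while keeping the whole suite
under a minute.

## Known limitations

* The published 55-mutation/53-gene significant list and the 1.9/Mbp rate
  depend on unavailable per-sample raw calls and an unstated rate
  denominator; they are replaced by exactness and error-control properties.
* Roughly half of the printed evidence-table totals include unstated
  literature/survival points and are reproduced only at the label level.
* The VCF reader is deliberately minimal (biallelic SNVs, one sample,
  documented INFO keys); it is a convenience, not a general VCF stack.
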