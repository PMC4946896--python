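# Methods

`cystseq` implements an ultra-sensitive mutation assay for ovarian cyst fluid
as three connected layers: a molecular-barcode (UID) error-corrected mutation
caller for multiplex amplicon sequencing, a synthetic-data generator that
stands in for the study's raw reads and clinical cohort, and a diagnostic
statistics layer. This note records the model, its assumptions, the defaults
and why, and what the simulations do and do not demonstrate.

## The error-correction model

The assay attaches a random 14-base unique identifier (UID) to every template
DNA molecule before amplification, so all reads sharing a UID at one amplicon
descend from one original molecule. True mutations are present in the
founding template and therefore appear in essentially every read of the
family, while PCR and sequencing errors arising later appear in only a
subset. The caller encodes this as a cascade:

1. **Quality gates.** A read is discarded if any UID base has Phred quality
   below 15 (a miscalled UID would place the read in the wrong family); a
   template base with quality below 20 is masked — it cannot vote at that
   position, but the rest of the read still can. Masking rather than
   discarding follows from the gates applying to different read parts: the
   UID gate protects family identity, the variant gate protects votes.
2. **Template matching.** The template portion is assigned to the panel
   insert with the fewest mismatches, requiring a mismatch fraction of at
   most 10% of the insert length; ties are left unmatched. Equal-length
   comparisons use vectorised Hamming distance; reads whose length differs
   from every insert (indel haplotypes) fall back to gapped edit distance.
3. **UID families.** Reads are partitioned by (amplicon, UID). Families
   below `min_family_size = 2` are dropped: a singleton read has no internal
   redundancy and cannot error-correct. The assay description is silent on a
   minimum size; the value is configurable and logged.
4. **Supermutant consensus.** For a candidate allele, a family counts as a
   *supermutant* (one mutant template molecule) when strictly more than 90%
   of its voting reads carry the alternate allele, as wildtype when the
   reference fraction strictly exceeds 90%, and as ambiguous otherwise —
   including families with no voting reads at the position. The comparison
   is exact (integer counts), so 9/10 fails and 10/11 passes.
5. **MAF and calling.** The mutant allele fraction is the number of
   supermutant families over the eligible (supermutant + wildtype) families;
   ambiguous families are excluded from the denominator and reported
   separately. A candidate becomes a final call only if (i) MAF > 0.1%,
   (ii) MAF strictly exceeds the control threshold mean + 5·SD for that
   exact allele, estimated from ≥2 mutation-free control samples (alleles
   never seen in controls get mean = SD = 0, so the floor is the binding
   gate), and (iii) the consequence is neither silent nor intronic, with the
   canonical splice-site positions (the ±1, ±2 intronic bases at exon
   boundaries) retained as callable.

Candidate alleles are enumerated from observed family consensus only — any
(position, base) where some family's voting majority is non-reference, and,
for indels, the canonical prefix/suffix-trimmed difference between an
odd-length family consensus and the insert. For indel candidates every read
votes for the uniquely nearest haplotype (by gapped edit distance) among the
reference and all candidate alternates jointly; ties abstain. Joint voting
prevents a spurious candidate derived from one noisy consensus from
capturing reads that match another haplotype strictly better. The indel
quality gate uses the minimum quality over the event's two flanking bases,
keeping the Q20 rule meaningful where no single "mutant base" exists.

Degenerate inputs: zero eligible families yield an undefined (NaN) MAF and
can never pass the gates; exonic substitutions whose codon is truncated at
the amplicon edge cannot be translated and are classified `noncoding`
(conservatively uncallable); variants extending past the amplicon edge are
rejected as errors.

## Consequence annotation

Substitutions are translated through the standard codon table in the
amplicon's frame, reverse-complemented for minus-strand CDS. Codon numbering
comes from a per-amplicon `codon_offset` supplied by the panel, because an
amplicon is a transcript fragment and protein-level labels such as V600E
presuppose transcript numbering the fragment alone cannot provide. Indels
with a net length change divisible by three, fully inside one exon, are
in-frame; other coding indels are frameshifts. Stop-gains are nonsense and
callable; stop-loss is treated as missense-like and callable. Protein labels
follow the compact literature style (`R280K`, `V600_S605>D`,
`F458_S459del`), not full HGVS nomenclature.

## What the simulator emulates

**Reads.** Each template receives an independent uniform-random 14-mer UID
(collisions are possible and deliberately not prevented — the 4^14 space
makes them rare, and preventing them would hide a real failure mode; a
collision rate above 1% is logged). Family sizes follow a zero-truncated
Poisson with mean 10 by default (5 in the cohort pipeline to keep run sizes
moderate); nothing is claimed about the real assay's family-size
distribution, which is not public. Two error processes are modelled:
*early-PCR errors* (default 3×10⁻⁶ per base per template) mutate the
template once and propagate to the whole family, creating the rare artifact
supermutants that make the control mean + 5·SD threshold non-trivial; and
*sequencing errors* (default 10⁻³ per base per read) hit individual bases.
Correct bases get quality Q30 and erroneous bases Q12, so the Q15/Q20 gates
are exercised; both are configurable. Errors are substitution-only and reads
are single-ended — polymerase-specific error spectra, indel sequencing
artifacts, paired-end structure and the three physical PCR pools are out of
scope.

**Cohort.** The generator draws a five-class surgical cohort
(non-neoplastic, benign, borderline, type I, type II) with per-class sample
counts (6, 12, 23, 13, 18 by default — the published samples with DNA
sufficient for sequencing), detection probabilities (0, 0, 19/23, 10/13, 1),
and mutation identities: detected borderline samples carry BRAF V600E with
probability 12/19 and a KRAS mutation otherwise; type I samples draw their
gene from the published type-I spectrum (KRAS 5 : TP53 3 : BRAF/NRAS/
PIK3R1/PPP2R1A/PTEN 1 each, with PIK3R1 drawn as an in-frame deletion);
type II samples carry a TP53 mutation with probability 0.94. One mutation
is drawn per detected sample; the study's four dual-mutation patients are
not emulated, so the per-sample summary MAF is simply that mutation's MAF.

Per-class MAF distributions are log-normal, moment-matched on the log scale
to the published medians and interquartile ranges (borderline 2.4%
[1.5–10.8], type I 7.8% [3.3–28.7], type II 60.3% [31.3–70.8]) and clipped
to [0.01%, 98%]. Clipping (rather than truncated resampling) preserves the
target medians, since both clipped tails stay on their own side of the
median; the type II log-normal places ~21% of its mass at the upper clip,
reflecting near-pure-tumor-DNA cysts. DNA yields are wide log-normals:
median 400 ng, σ = 2.3 for the surgical classes and median 44 ng, σ = 0.85
for the benign classes. A naive moment match to the published surgical-class
mean ± SD (4453 ± 6428 ng) would place the two classes ~4 log-SDs apart —
near-perfect separation that contradicts both the published pooled median
of 222 ng and the published multivariate structure, in which DNA amount is
univariately significant by rank test yet adds essentially nothing once
mutation status is known. The wide-σ parameterization keeps the rank-test
contrast strong (AUC ≈ 0.85) while making the distributions overlap heavily,
so the qualitative published pattern (mutation dominant, DNA multivariately
uninformative) emerges from the fitted model rather than being imposed.
CA-125 is log-normal with medians 70 vs 15 U/mL (σ = 1.2 / 0.7) for
surgical/non-surgical classes, placing roughly 28% vs 89% of samples
below the 35 U/mL normal cutoff — a moderate association. HE4 is
class-independent (median 70 pmol/L, σ = 0.55), emulating its published
non-association. Menopausal status is Bernoulli(½) and sets which HE4
cutoff (92 vs 121 pmol/L) applies. Stages: borderline tumors stage I;
type I cancers early (I/II) with probability 8/13; type II early with
probability 3/18.

**What passing tests do not show.** The generator reproduces the class
structure, marginal distributions and one plausible dependence structure of
the study — it does not model contamination, FFPE damage, primer bias,
strand artifacts, per-amplicon depth variation or inter-patient biological
heterogeneity beyond the class labels. Recovery of the simulated truth
therefore validates the calling logic and its statistics, not performance
on real cyst-fluid libraries.

## Diagnostic statistics

Confidence intervals for detection fractions are Clopper–Pearson exact
intervals from Beta quantiles. The original report does not name its CI
method, but Clopper–Pearson reproduces every printed bound (0/6 → 46%,
0/12 → 26%, 18/18 → 81%, 47/54 → 75–95%); displayed percentages round half
away from zero. One published inconsistency is knowingly not reproduced:
the specificity CI is printed as 74–100% for n = 18 negatives, but 74% is
the n = 12 exact lower bound; `cystseq` reports the n = 18 value (81–100%).
Per-class MAF medians and IQRs are computed over mutation-positive samples
(0 when none are positive); with zeros included, the published per-class
medians would be arithmetically unreachable given the published detection
fractions. When a sample has several final calls the maximum MAF represents
it, and this choice is flagged in the output.

The DNA-yield comparison uses the Wilcoxon rank-sum test: exact enumeration
when the pooled sample is ≤12 and untied, otherwise the normal approximation
with tie and continuity corrections.

The multivariate analysis is Firth's penalized-likelihood logistic
regression of the need for surgery on mutation presence, log₁₀ DNA (ng) and
indicators for *normal* CA-125 (<35 U/mL) and HE4 (<92 / <121 pmol/L for
pre-/post-menopausal women). The fit maximizes
l*(β) = l(β) + ½ log det I(β) by Newton iteration on the Firth-adjusted
score U*ⱼ = Σᵢ (yᵢ − πᵢ + hᵢ(½ − πᵢ)) xᵢⱼ with step-halving on l*,
converging (max |U*| < 10⁻⁶) even under complete separation — which is the
realistic regime here, since mutation presence perfectly predicts surgery
in the study. Per-predictor p-values are penalized likelihood-ratio tests
(refit without the predictor, 2·Δl* against χ²₁): Wald tests are
anti-conservative under separation and cannot yield the near-zero p-value a
perfectly separating predictor deserves. Collinear designs raise an error
naming the offending columns; constant predictors (possible in very small
cohorts) are dropped with a warning and reported with NaN p-values.
Replicate concordance is the median (and IQR) of |a−b| / ((a+b)/2) over
replicate MAF pairs, a symmetric scale-free measure; the reference against
which differences are measured is not defined in the original report.

## Problem sizes and numerical choices

The cohort pipeline simulates 3000 templates per amplicon with mean family
size 5 over an 8-gene toy panel (≈90k reads per sample, 93 samples
including 8 controls); the sensitivity-floor experiment uses 10,000
templates so that the 0.1% MAF floor is resolvable at a 0.2% spike
(expected 20 supermutant families against a floor of ~11 — at 3000
templates the floor sits within one Poisson standard deviation of the
expectation and the experiment would measure quantization, not chemistry).
These sizes are the package's defaults for its own demonstrations; all are
configuration fields. Supermutant comparisons use exact integer arithmetic
at the default 0.9 concordance; the random stream is split hierarchically
(`numpy.SeedSequence`) per control, per sample and per covariate block, so
adding a sample or changing a covariate distribution never perturbs another
sample's reads — this also makes the caller's blindness to clinical labels
testable as byte-identical variant tables under covariate changes.

## Known limitations

- Single-strand consensus only; duplex (two-strand) designs are out of scope.
- No genome liftover: coordinates are amplicon-local, and the VCF export
  uses amplicon ids as contigs.
- The panel model carries one transcript per amplicon; multi-isoform
  annotation is unsupported.
- UTR/noncoding positions are excluded from calling; whether the original
  analysis allowed them is unknown.
- The real 133-amplicon panel is supported as an input format but not
  redistributed; the shipped panels are synthetic toys.
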