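# Methods

## Problem setting

Sequencing picogram DNA inputs (20–30 cells) requires whole-genome
amplification (WGA), and WGA chemistry copies damaged template bases
into stable artefacts that are indistinguishable from real mutations in
a single pooled library. Compartmentalised sequencing sidesteps this:
~200 pg of template is distributed over a 384-well plate before
amplification, so each well receives at most about one molecule per
locus. A real variant (present in many template molecules) then shows
up in many wells, while an amplification artefact (created inside one
well, on one strand of one molecule) is confined to a single well whose
reads support *both* alleles — a dual-allelic compartment. `wellmut`
implements the downstream analysis: per-well evidence filtering, a
41-feature representation of each candidate, a noisy-label neural
ensemble with dropout-based uncertainty, and adaptive thresholding, plus
a plate simulator so every stage is testable without sequencing data.

## Candidate filtering and training labels (`wellmut.welldata`)

Candidates come from joint calling over the 384 well-level alignments
plus one merged alignment. Three filter stages:

* caller quality: QUAL > 60, FR > 0.1, HP ≤ 4, QD > 10, SbPval ≤ 0.95
  (strict inequalities as written; a missing annotation fails — the
  conservative choice for malformed records);
* well counts: with Tw = wells covering the locus and Vw = wells
  supporting the variant (≥ 1 read, the per-well evidence threshold),
  require Tw > 5, Vw > 2, Vw/Tw > 0.1;
* mappability: drop candidates touching a masked BED interval. Masking
  is conservative at interval edges: the variant is removed if the mask
  covers either its 0-based coordinate or the boundary base after it.

Training labels come from genotyping the same sites in bulk tumor and
bulk normal WGS. "Confidently unsupported" and "confidently present"
are operationalised as: **UTD** (label 0) iff both bulk samples are 0/0
with zero variant reads at depth ≥ 10; **HET_SNP** (label 1) iff the
blood sample is 0/1 with GQ ≥ 30; everything else is **OTHER** and
excluded. UTDs are mostly artefacts salted with an unknown fraction of
true clone-specific mutations, so the 0 labels are noisy by
construction.

## Feature representation (`wellmut.features`)

41 values per candidate: the 14 caller annotations; three cumulative
flanking-nucleotide frequencies F20_1..3 (proportions of the 20 bases
around the site, ambiguity codes pooled as a fifth symbol — low
complexity contexts are artefact-prone); merged-sample read support
(ref+var, var); eight well counts conditioned on read support and
genotype; the W[ref=0, var>n] ladder for n = 0..5; the top-3 per-well
read counts for the variant allele and for ref+var; and the row/column
concentration pair Max_c + Max_r and W[var>0] − (Max_c + Max_r), which
flags evidence smeared along one plate row or column (index hopping).
The enumerated read-rank features are taken at ranks 1..3 per allele
class so the vector is exactly 41 wide; a configuration switch
(`n_rmax_ranks=4`) exposes the 43-wide alternative reading.

Features are min–max scaled to [0, 1] on the training pool; values
outside the fitted range are clipped and missing annotations are imputed
at the training minimum (the most pessimistic value after scaling).
Whether the original pipeline scaled or standardised is not documented;
min–max is chosen because most features are bounded counts and the
network inputs stay in a fixed range.

## Classifier (`wellmut.nn`, `wellmut.mutlx`)

Each ensemble member is a multilayer perceptron — input 41, two hidden
ReLU layers, sigmoid output — trained with Adam (learning rate 0.001),
batch size 8, 10 epochs, binary cross-entropy. Hidden sizes default to
(64, 32). The width matters for the uncertainty mechanism below: with
80% first-layer dropout only ~13 of 64 units survive a pass, and
narrower layers leave too few active units for the variance signal to
be meaningful (at (32, 16) the signal inverts). Larger sizes change
nothing measurably except runtime.

Training uses 25 balanced subsets (all UTDs + an equal-sized SNP sample
without replacement; with replacement, with a warning, only when SNPs
are scarcer than UTDs). Because the 0 labels are noisy, each member is
trained in two steps: an initial model on its balanced subset; that
model is applied to the full pool and apparently mislabeled rows are
pruned — UTDs predicted > 0.7 and SNPs predicted < 0.3 (strict, per-
member, temporary; the global pool is never mutated); a fresh balanced
subset is drawn from the pruned pool and the final model trained on it.
If pruning empties the UTD side the member falls back to its initial
model with a warning.

Per candidate: the **probability score** is the mean of the 25 member
predictions. The **uncertainty score** is the mean over members of the
variance (population variance, n = 100) of 100 test-time-dropout
predictions, with dropout rates 0.8 and 0.7 on the hidden layers. Each
pass draws one keep-mask per layer, shared across candidates — one
random neuronal subset of the trained network — and kept activations
are rescaled by 1/keep as in standard inverted dropout. The rescaling
is essential: it preserves the logit scale, so a prediction backed by a
saturated distributed representation stays saturated under most masks
(variance → 0) while a borderline prediction swings across the sigmoid
(variance up to 0.25). Without rescaling every logit collapses toward
mid-scale and the variance ranking inverts (confident predictions get
the *largest* variance) — measured directly during development, AUC
0.03 on a pure-artefact plate versus 0.99 with rescaling.

## Putative ROC, adaptive cutoff, final calls

Candidates with probability score > 0.2 are eligible. Sweeping an
uncertainty cutoff over [0, 0.25] (251-point grid), the fraction of
eligible SNPs at or below the cutoff (TPR) is plotted against the
eligible-UTD count normalised by its maximum; the AUC is the trapezoidal
area. When no true clone-specific variants are present this is a
genuine ROC and a good model scores near 1; true clone-specific
variants among the UTDs behave like SNPs (low uncertainty) and drag the
AUC down, which is itself a diagnostic. If no UTD is eligible the AUC
is defined as 1.0, with a warning.

Cutoff selection is adaptive: AUC < 0.9 (true UTDs likely present) →
the smallest cutoff reaching 95% SNP TPR, favouring recovery; AUC ≥ 0.9
→ the grid point closest to the ideal corner (utd_norm 0, TPR 1),
favouring artefact elimination. The "threshold curve" whose
intersection defines the original high-AUC rule is not documented;
closest-to-corner is the concrete reading used here. Final call:
probability score > 0.2 AND uncertainty score ≤ cutoff.

Seeding fans out from one master seed through `numpy` `SeedSequence`
spawning (subset sampling, weight initialisation, epoch shuffling,
dropout masks), so every run is exactly repeatable.

## Plate simulator (`wellmut.simulate`)

The generative model mirrors the assay: `genome_copies = 60` copies of
each locus (2 alleles × ~30 cell equivalents in ~200 pg) are allocated
multinomially over 384 wells, which keeps the double-occupancy
probability of an occupied well at 7.6%, under the assay's 10% design
bound. Per-molecule read counts are Poisson with mean
`mean_reads_per_well_per_locus = 4`, modulated by two Gamma(mean 1)
yield factors: per locus (shape 1.3; GC content and template
accessibility) and per well × allele (shape 1.2; hyperbranching MDA
treats molecules unevenly). These tails matter: they produce the
low-coverage germline SNPs and ambiguous artefacts that make the
classification problem realistically hard rather than trivially
separable. Genotypes are called from the read counts (0/0, 0/1, 1/1)
and flipped with probability 0.05, the realistic miscall rate for 1–4
read genotypes.

Variant classes: **HET_SNP** and **CLONAL** put the variant on half the
copies (~28 variant wells); **CLONE_SPECIFIC** on
`clone_cell_fraction` of the cells — default 1.0, since a mutation
private to the sequenced clone is carried by essentially all of its
~30 cells (that is what makes it clone-specific yet invisible to bulk
WGS); **ARTEFACT** arises during amplification. The artefact class is a
mixture: 96% single-well damage events (variant reads =
Binomial(depth, 0.5) in one origin well — dual-allelic), 2%
contaminated (the damage additionally smears 4 + Poisson(4) wells of
low-level variant reads along the origin's row or column, emulating
index hopping and exercising the Max_c/Max_r features) and 2%
mismapped (reads from a diverged paralog on one haplotype bleed ~0.4
variant reads per paralog molecule into its wells). The multi-well
minority is what survives the well-count filters, as the thousands of
filter-surviving UTDs in real runs attest; without it the classifier
faces no residual artefacts at all. Under the defaults ≥ 95% of
artefacts still have Vw ≤ 2.

Quality annotations are drawn from class-conditioned, heavily
overlapping distributions (artefact shifts are mild, reflecting
populations that already passed the scalar quality filters upstream),
so the scalar filters alone cannot separate the classes — separation
must come from the plate-distribution features, which is the method's
premise.

What the simulator does **not** model: read-level errors and alignment,
copy-number landscape, well-to-well library-size variation beyond the
yield factors, correlated damage hotspots, and real genomic context
(contexts are uniform random 21-mers). Passing benchmarks on simulated
plates therefore demonstrates the pipeline's behaviour under the stated
generative assumptions, not performance on any particular real dataset.

## Benchmarks (`wellmut.benchmarks`)

The simulated plate stands for the post-calling candidate set, and the
training pool is built from the simulator's truth labels (artefacts and
clone-specific variants as UTDs, germline SNPs as 1s); the evidence
filters are validated separately in their module tests and in the VCF
round-trip test. 20% of the SNPs are held out of the pool entirely and
only scored, so reported SNP sensitivity reflects variants no member
ever trained on. Truth-resolved outputs: artefact pass-rate,
clone-specific recovery, held-out SNP sensitivity, AUC and cutoff.

The spiking study relabels floor(ratio · |UTD|) high-confidence clonal
somatic variants (Tw > 6, Vw/Tw > 0.45) as UTD* at ratios up to 10%,
ten replicates per ratio, and tracks their recovery — an overfitting
probe: a classifier that memorised its noisy 0 labels would lose UTD*
recovery as the ratio grows. "Does not significantly affect" is
operationalised as a ≤ 10 percentage-point drop between the means at
ratios 0.01 and 0.10. The AUC-vs-fraction study plants clone-specific
variants at target UTD-pool fractions {0, 0.05, 0.1, 0.2} (artefact
count fixed, n_cs = f/(1−f) · n_artefacts) and reports the Spearman
correlation between fraction and the replicate-averaged AUC. The
design is matched: within a replicate, all fractions share one base
plate and one training seed, and the planted sets are nested (the 5%
set is a prefix of the 10% set, and so on). Pairing removes the
plate-to-plate and ensemble-seed variance from the contrast — in an
unpaired design that variance is comparable to the effect itself at
desk scale.

Problem sizes: the pure-artefact and clone-specific benchmarks run at
1500 artefacts / 3000 SNPs (200 clone-specific planted in the latter);
the spiking study at 320 artefacts / 800 SNPs / 240 clonal with
3-epoch training; the fraction sweep at 800 artefacts / 1500 SNPs,
five replicates. These are desk-scale choices that keep a full
single-CPU evaluation of all suites in the tens of minutes while
leaving every statistic comfortably clear of its margin.

## Kataegis reports (`wellmut.reports`)

Rainfall points record, per contig and from the second mutation on, the
distance to the previous mutation, labelled by the second mutation's
substitution type both as written on the reference strand and
pyrimidine-collapsed (the strand-coordinated C>T/C>G signature of
APOBEC kataegis is only visible in the strand-specific labels).
Clusters are maximal runs of ≥ 5 mutations with successive distances
≤ 1000 bp — common practice; the thresholds are configurable because
published kataegis calls vary.

## Numerical and degenerate-input conventions

Sigmoids are computed via tanh with logits clipped at ±60; training
aborts with diagnostics on non-finite predictions. A feature constant
across the training set scales to 0. Uncertainty is computed only for
probability-eligible candidates (others cannot pass and never enter the
ROC; their score is NaN). An empty UTD pool yields an empty benchmark
result; a pool with no eligible SNPs is an error. BED masks are merged
per contig; unsorted input is accepted.
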