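# Methods

This note documents the models, conventions and numerical choices behind
`rarecnv`, and what the synthetic-data experiments do and do not show.

## Signal model and artefact taxonomy

The per-sample, per-marker Log-R ratio is modelled (and simulated) as

    LRR(s, m) = μ_cohort + μ_plate + w_s · g(m) + Σ_k u_{s,k} v_{m,k}
                + δ_state(s, m) + ε_{s,m},      ε ~ N(0, σ_s²)

* `μ_cohort`, `μ_plate` — constant intensity offsets shared by a typing
  centre or a 96-well plate (simulated SDs 0.03 and 0.02).
* `w_s · g(m)` — the genomic wave: `g` is the manifest's GC profile
  standardised to zero mean and unit variance, so the expected magnitude of
  the wave-factor metric is proportional to the per-sample amplitude `w_s`
  (simulated SD 0.01, with a 1% outlier tail at 0.10).
* `u v'` — latent linear batch components.  The loading profiles `v_{m,k}`
  are regionally smooth (Mb-scale sinusoids, amplitude 0.08 by default)
  because spatially correlated batch structure is what manufactures
  artificial CNV calls; the sample scores `u_{s,k}` have cohort-specific
  means (SD 0.5 across cohorts), so batch structure is *confounded with
  phenotype*, as it is when cases and controls are typed at different
  centres.
* `δ_state` — the copy-number shift inside spiked CNVs.  By default the
  simulator uses the caller's emission means, so simulator and caller share
  one parameterisation; pass different `HmmParams` to study mismatch.
* `σ_s` — per-sample noise, 0.16 by default with a 2% high-noise tail at
  0.35.

BAF is generated from genotypes drawn at the population B-allele frequency
(PFB), normal band noise SD 0.04 clipped to [0, 1] (clipping produces the
point masses at exactly 0/1 that the emission model treats as censoring).
Inside CNVs the band structure is transformed: copy-1 removes the
heterozygous band, copy-0 leaves uniform noise, copy-3/4 move bands to
k/3 and k/4.

All random draws flow from a single seeded generator in a fixed stream
order (cohort structure, loading profiles, per-sample parameters, baseline
matrices, CNV spikes, aberrations), so identical configurations are
bit-identical.

## Quality-control conventions

* **Call rate** (default 0.95, strict `<` excludes): samples first, SNP
  rates recomputed on the survivors.
* **HWE**: exact conditional test on the heterozygote count given the
  allele counts; two-sided p sums outcome probabilities no larger than the
  observed one.  The threshold (default 1e−10, controls only) is
  deliberately conservative: common copy-number polymorphisms violate HWE
  for genuine reasons.  No MAF filter is applied — monomorphic SNPs still
  carry intensity information.
* **DLRS**: sample SD (n−1) of successive-marker differences divided by √2;
  differences never cross chromosome boundaries (joins are artificial
  jumps) and skip missing values.  Fence: cohort mean + 3.5 SD, per cohort,
  because noise levels differ systematically between typing centres.
* **Wave factor**: per-sample median LRR in non-overlapping 1 Mb autosomal
  windows; magnitude is the *unscaled* MAD of the window medians (no 1.4826
  factor — a fixed, documented convention), signed by the Pearson
  correlation with window mean GC.  Fence: mean + 3.5 SD of |SWF|, global.
* **Mean fence**: Tukey fences Q1 − 1.5·IQR / Q3 + 1.5·IQR with
  linearly-interpolated quantiles; values exactly on a fence are retained.
* **Chromosome aberrations**: a chromosome is flagged when its mean LRR
  deviates from the sample's median-of-chromosome-means by more than 5
  robust (MAD-scaled) cohort SDs *and* same-direction window deviations of
  at least half that size cover ≥ 50% of the chromosome.  The robust centre
  and spread keep a trisomy from masking itself; the persistence rule keeps
  multi-Mb focal CNVs from being mistaken for aneuploidy.  The thresholds
  are configurable; they are calibrated to flag whole-chromosome events at
  the simulator's state shifts.
* **Plates**: excluded when > 40% of members fail sample QC, or when the
  mean CNV count per sample exceeds the global mean + 3 SD (applied at the
  CNV-QC stage).
* Exclusion order is fixed — call-rate → mean → DLRS → wave → aberration →
  plate — and idempotent: re-running on the survivors is a no-op.

## PC correction

Scores are the leading k = 24 left singular vectors of the column-centred
samples × subset matrix; the subset masks immunoglobulin/telomere/
centromere/MHC regions and thins uniformly to 15% (floor rounding, seeded).
Every manifest SNP is then regressed on the scores plus an intercept and
replaced by its residual; the intercept is removed too (per-SNP centring),
since sub-1%-carrier signal perturbs a SNP mean negligibly while centring
removes per-SNP miscalibration.  Missing entries are mean-imputed for
fitting, fitted on observed entries per column, and stay missing.

A quantified limitation: the top singular vectors partially align with a
CNV locus in proportion to (carrier count × subset SNPs in the locus)
relative to the noise eigenvalue edge `σ²(√n + √m)²`.  Thinning and the
rare-variant target keep this leakage small — at 0.4% carriers and 6–10-SNP
events the recovered state shift stays within 10% of the injected value
after 24 components — but it grows with carrier frequency and event length,
which is exactly why common copy-number polymorphisms are outside this
pipeline's scope (their detection after correction is poor and biased by
construction).

## The HMM caller

Five states, copy numbers 0–4; copy-neutral LOH is intentionally absent
(the target is rare DEL/DUP).  Emissions: LRR Gaussians with means
(−3.5, −0.67, 0, 0.40, 0.68) and SDs (1.3, 0.28, 0.16, 0.21, 0.24) —
the PennCNV convention, all configurable; BAF densities are binomial
(in PFB) mixtures of bands at k/c with SD 0.04, censored at 0/1 (boundary
observations compare point masses computed from the tail probabilities),
mixed with a uniform outlier weight ε = 0.01; copy-0 BAF is uniform.
Missing LRR or BAF contributes only the non-missing term.  Transitions
decay with inter-marker distance d: `a_ij(d) = π_j (1 − e^{−d/D})`,
D = 100 kb, with a diploid-dominant stationary prior
π = (1e−4, 9e−4, 0.998, 9e−4, 1e−4); each row sums to one for every d.

Decoding is per chromosome, in log space, vectorised across samples.
Viterbi ties resolve to the lower copy number, then the earlier state
index (the natural `argmax` order).  Maximal non-diploid runs become calls
bounded by their first/last SNP.  Adjacent same-copy-number calls merge
when gap/(left + gap + right) < 0.2 (strict), iterated to a fixed point;
merging recounts supporting SNPs from the manifest.  Quality is the mean
forward–backward posterior of the called state over the call's SNPs — a
[0, 1] score thresholded at 0.95 downstream.

Parental-evidence vetting replaces a full trio joint-HMM: a child call is
re-tested on each parent's intensities by summing the per-SNP
log-likelihood ratio of the called state versus diploid; any positive
evidence (LLR > 0) counts as support.  This is deliberately lenient — a
de novo claim requires *both* parents to fail even this relaxed re-test —
because false de novos arise mainly from detection failures in a carrier
parent.

## CNVRs and statistics

CNVR grouping sweeps position-sorted same-class calls maintaining the
running common intersection; when an incoming call cannot join, the group
closes and the new group is seeded with the incoming call plus any members
of the closed group that overlap it, so one call can belong to two regions.
On random instances the emitted families of member sets equal the
brute-force maximal point-cover sets (tested).  Carriers are counted per
sample.  Rarity is two-stage: calls are retained up to 5% frequency
upstream (to avoid boundary artefacts near common variants), regions above
1% are removed at the analysis stage; member calls below quality 0.95 are
dropped and regions with > 20% failing members are discarded.  The
per-sample/per-plate CNV-count fences (mean + 3 SD) never drop below one
event: at desk-scale call rates the naive fence can fall under 1 and would
label every carrier an outlier.

Exact 2×2 machinery: two-sided Fisher p by the minimum-likelihood
convention; both the cross-product ("sample") odds ratio and the
conditional MLE of the noncentral hypergeometric odds ratio are reported —
published tables mix the two conventions — with exact conditional CIs by
tail inversion (absent on a zero cell, where only a p-value is defined).
The burden 2×2 counts CNV events versus remaining samples; when event
counts exceed sample totals (only in heavily artefactual uncorrected runs)
the exact test is undefined and the plain rate ratio is reported instead.
Length strata are half-open (lo, hi] with bins 0–20/20–400/>400 kb for
deletions and 0–50/50–400/>400 kb for duplications (duplication lengths
distribute differently), Bonferroni m = 6.  The TDT is the exact binomial
against ½ with tail doubling capped at 1, always reported beside the
unaffected-sibling transmission rate because detection sensitivity, not
biology, can displace both.  Transmission denominators are children ×
carrier parents per family per CNV; "same CNV" across individuals means
≥ 1 shared bp *and* ≥ 50% reciprocal overlap (a documented default — no
universal definition exists).  Power grids report the smallest total N
(units of 10,000, 1:1) reaching 80% power at α = 5e−5 by a normal
approximation on the log odds ratio, with a Monte-Carlo exact-test search
as the cross-check; the power criterion behind published grids is not
fully specified, so comparisons are qualitative.

## Null-control and recovery experiments

The negative-control experiment simulates 2,000-sample cohorts
(1,000 + 1,000) with fully confounded cohort/plate/latent structure,
40 CNV loci at 1% carriers and 8–25 SNPs, runs the pipeline with
24-component correction, and checks that the all-CNV burden CMLE OR lies
in [0.9, 1.1].  Two deliberate design choices isolate pipeline bias:
carriers are assigned in exactly balanced counts per phenotype group
(otherwise carrier-sampling noise alone spans the band at this scale), and
the burden set is the ≥ 6-SNP, quality ≥ 0.95 calls while the count-based
sample/plate fences are off (integer fences at ~0.4 events/sample
quantise harshly; at study-scale event rates they are not binding).
Recovery on the same panels — sensitivity ≥ 0.85, precision ≥ 0.90 for
≥ 6-SNP planted events — is measured before the quality cut.  Uncorrected
runs (k = 0) on the same panels show inflated call counts, lower mean
quality and larger burden bias, reproducing the quality-versus-bias trade
the QC sweep harness (3 sample-QC × 3 SNP-QC × 3 PC × 2 CNV-QC = 54
configurations) is built to expose.

What these experiments do **not** show: the simulator draws marker
positions and GC as smooth random profiles rather than a real manifest's
spatial layout, injects strictly linear batch structure (real plate
chemistry can be nonlinear), contains no mosaicism, sex chromosomes,
ancestry structure or runs of homozygosity, and its BAF/LRR noise is
Gaussian.  Passing tests therefore demonstrate the pipeline's mechanics
and its behaviour under the modelled artefact classes, not performance on
any particular array product.

## Problem sizes

Unit and property tests run on panels up to a few hundred samples and a
few thousand markers; the null-control and recovery experiments use
2,000 × 2,000; one end-to-end run at 2,000 samples × 20,000 markers
exercises the full scale (about five minutes and ~3 GB on one CPU, the
HMM decoding vectorised across samples per chromosome).  The acceptance
script pools two independent 2,000-sample panels for its simulated
quantities.
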