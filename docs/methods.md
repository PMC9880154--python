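# Methods

## The measurement model

Direct bisulfite Sanger sequencing reads the pooled PCR product of
bisulfite-converted genomic DNA. Per molecule, an unmethylated cytosine
deaminates to uracil (read T) with the kit's conversion efficiency; a
methylated CpG cytosine is protected and stays C. The pooled chromatogram
therefore carries, at each CpG, a C/T peak mixture whose amplitude ratio is a
plug-in estimator of the methylated fraction of molecules:

    methylation% = 100 · I_C / (I_C + I_T).

The bounded C/(C+T) form (rather than a raw C/T ratio) is used because it
maps directly to a percentage, is invariant to global trace rescaling, and
degrades gracefully when one channel is near zero. Channel amplitudes are
taken at the called peak scan (no area integration): the downstream ratio
only needs relative channel heights at the same scan, and peak shape is
common to all four channels on one instrument.

Reads are aligned to the in-silico converted reference (every C→T), not the
native reference, because a fully converted read matches it everywhere except
methylated CpGs. Alignment is affine-gap global (match +2, mismatch −1, gap
open −5, extend −1) with free end gaps, since each sequencing read covers only
part of the region (the design uses two overlapping PCR amplicons). Identity
is computed over aligned columns, with a read C aligned to a reference-C
position counted as a match so heavily methylated samples are not penalised;
samples under 80 % identity fail with an explicit alignment error.

Coverage: a site is reported only when the alignment maps it and its combined
C+T amplitude reaches `min_total_intensity`, which defaults to 10 % of the
read's median per-base total amplitude. This reproduces the real-world
phenomenon of individual CpGs dropping out of analysis (in the emulated study,
one of 32 sites) without inventing an absolute instrument-specific threshold.
When two amplicons cover the same site, their percentages are averaged and an
`ok` value always beats an `insufficient` one.

Conversion QC: non-CpG cytosines should read T after conversion, so their mean
T/(C+T) across the read estimates conversion efficiency; below 0.95 the sample
is flagged (incomplete conversion inflates apparent methylation). Fewer than
five covered non-CpG cytosines renders the QC not evaluable.

## CpG islands and islets

A 100 bp window slides in 1 bp steps; a window passes when GC ≥ 50 % and
observed/expected CpG = N_CpG·L/(N_C·N_G) ≥ 0.6 (obs/exp defined as 0 when the
window lacks C or G; a CpG counts only when both bases are inside the window).
A maximal run of passing starts spans `first_start … last_start + window − 1`;
runs separated by fewer than `window` failing starts would overlap, so they
are merged into one call. Calls at least `minlen` long are reported; 100–199 bp
calls are classed *islets*, ≥ 200 bp *islands*. This run-of-passing-windows
rule is deliberately simpler than EMBOSS Cpgplot's internal smoothing: it is
deterministic and testable, at the price of not matching EMBOSS base-for-base
on edge cases. Count-monotonicity under threshold changes holds in containment
form (every stricter call lies inside a default-threshold call); merging makes
a strict count inequality unattainable.

## TFBS scanning

JASPAR count matrices are normalised with a total pseudocount of 0.8 split by
a uniform background (0.2 per cell) — a common JASPAR-practice default. Each
column gets an information weight I(i) = Σ_b f(i,b)·ln(4 f(i,b)); a site scores
current = Σ_i I(i)·f(i, site_i), min–max-normalised to the matrix similarity
score MSS ∈ [0,1]. A scan accepts windows with MSS ≥ 1 − deficit
(deficit = 0.15 by default, the conventional 0.85 cut-off), positive strand
only by default as promoter analyses typically restrict to the sense strand;
minus-strand scanning scores the reverse complement. The core-region
sub-score used by some MATCH implementations is omitted: it introduces an
extra unpublished parameter and the plain MSS already reproduces
planted-motif recovery at ≥ 95 % over 100 random backgrounds. Multiple hits
and multiple matrix versions of one factor collapse to one factor for
counting; regulators are classified activator/repressor/both from an
annotation table and the repressor focus list keeps those with
nTPM ≥ `min_ntpm` (default 1.0).

## Statistics

* **Site-wise screening**: two-sided Welch t per CpG per stage pair, reported
  unadjusted — a screen mirroring the observation that single-CpG shifts of a
  few points are undetectable at n = 3. Welch is preferred over the pooled t
  as the safer default at these group sizes. Zero-variance degeneracies
  follow p = 1 (equal means) / p → 0 flagged (unequal means).
* **Region ANOVA** (default mode `mixed`): stage is a between-animal factor,
  CpG site the repeated measure within each animal; sites not covered in
  every animal are dropped from the omnibus. In the balanced case the
  between-animal F equals a one-way ANOVA on animal-level region means, which
  keeps the test exactly calibrated (verified: null rejection 0.05 ± 0.03
  over 500 simulated cohorts). An `oneway` mode on animal-level means is
  provided because study write-ups sometimes describe the same comparison
  either way. Pairwise stage contrasts always use animal-level region means,
  Welch t × number of comparisons (Bonferroni, capped at 1).
* **Expression**: replicate Ct wells averaged per sample and gene;
  ΔCt = Ct_target − Ct_reference; ΔΔCt against the calibrator-stage mean ΔCt;
  RQ = 2^−ΔΔCt (calibrator mean ΔΔCt = 0 by construction, and RQ is invariant
  to plate-wide Ct shifts). One-way ANOVA plus Tukey HSD across stages.
* **Correlation**: Pearson r between animal-level region methylation and the
  same animal's RQ, paired per animal (n = 9 in the default design) rather
  than per stage mean — three stage means would make r degenerate.

## The synthetic cohort

The generator's defaults encode the emulated study design:

| parameter | default | meaning |
|---|---|---|
| stages | PND14, PND35, PND56 | pre-/at-/post-puberty |
| animals_per_stage | 3 | cohort size |
| promoter | 1080 bp, TSS at 842 | 841 bp upstream + 239 bp downstream |
| CpGs | 32 (7 in islet) | catalogued 5′→3′ |
| islet | −200..−81, GC 55 %, obs/exp ≥ 0.75 | ~120 bp planted islet |
| region 2 means | 0.42 / 0.47 / 0.48 | +5/+6 pp pubertal shift |
| regions 1,3,4,5 | 0.65 / 0.48 / 0.67 / 0.69, flat | 48–69 % band, no stage effect |
| animal_sd | 0.05 | per-animal, per-CpG Gaussian scatter (truncated to [0,1]) |
| conversion_rate | 0.99 | bisulfite efficiency (a choice; not a published value) |
| n_molecules | 2000 (CLI default) | pooled molecules per trace |
| expression fold | 1.0 / 0.3 / 0.3 | ~70 % pubertal drop, sustained |
| Ct noise | 0.15 cycles, triplicate wells | qPCR replicate scatter |

Sequence construction: an AT-rich (~30 % GC), CpG-free background with
isolated CG dinucleotides planted at 2.6 per 100 bp outside the islet; the
islet span is filled from an exact base-composition budget (CG blocks plus
single-base tokens, shuffled with a repair pass so no uncatalogued CpG is
minted) and embeds one literal TFBS consensus (`GTAGGCA`) as scan ground
truth. The construction is verified against its own contract — every 100 bp
window inside the islet passes both composition thresholds, and the whole
sequence yields exactly one sub-200 bp islet call overlapping the planted
span — and deterministically rebuilt from the same seed stream on the rare
unlucky draw. The AT-rich background keeps partially overlapping windows
below the GC threshold so the islet call cannot bleed past 200 bp.

Traces are rendered one Gaussian peak per base (spacing 12 scans, peak sd 2),
channel amplitudes proportional to pooled base frequencies summing to 1000
before noise; additive Gaussian noise (sd 5) clipped at zero. This models
what the estimator consumes — relative peak heights — not scan-level
instrument physics.

What the generator does *not* emulate: PCR amplification bias between
methylated and unmethylated templates, primer effects, heteroduplexes,
reverse-strand (G/A) reads, dye blobs/mobility artefacts, and biological
autocorrelation of methylation along the molecule (sites are drawn
independently per animal). Passing tests therefore demonstrate correctness of
the computational pipeline under a faithful signal model, not robustness to
every wet-lab artefact.

## Numerical and design choices

* Coordinates are 1-based inclusive; TSS-relative positions skip 0
  (−1 is immediately upstream of +1).
* Base-calling ties break by fixed channel order A < C < G < T; secondary
  calls (threshold 0.33 of the primary amplitude, a common heterozygote
  default) are reported but the estimator uses raw amplitudes.
* All generators are bit-reproducible from a seed; the pipeline stamps each
  run with a config hash and seed and re-runs are byte-identical.
* Problem sizes used by the test suite and the acceptance script (e.g.
  10 000 molecules per pooled trace for recovery, 100 cohorts for power,
  300–500 for type-I calibration) were chosen to make Monte-Carlo error small
  relative to the asserted margins while keeping a full run in tens of
  seconds.

## Known limitations

* The island caller is parameter-compatible with, but not output-identical
  to, EMBOSS Cpgplot (different smoothing/joining rules on edge cases).
* The MSS omits the MATCH core-similarity filter, so hit lists can be
  slightly more permissive than MATCH-family tools at the same cut-off.
* With n = 3 animals per stage, pairwise contrasts on animal means have few
  degrees of freedom; the mixed-model omnibus is the better-powered test and
  the per-animal correlation (n = 9) should be read as exploratory.
* Replicate-mode inputs assume forward-strand reads covering the catalogued
  region; clone-based (per-molecule) bisulfite data are out of scope.
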