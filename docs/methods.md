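# Methods

## The inference problem

Cell-free seminal DNA (cfsDNA) is a mixture of DNA shed by the testis and
epididymis (TE) and by the accessory glands. Vasectomy removes the TE
contribution entirely, so contrasting promoter methylation of
normozoospermic (Nor) and post-vasectomy (PV) cfsDNA isolates the TE-derived
methylome. The cohort arithmetic motivating the mixture weight: with mean
cfsDNA concentrations c_Nor and c_PV, the TE-derived fraction of Nor cfsDNA
is (c_Nor − c_PV)/c_Nor; at the measured 1.23 and 0.33 µg/ml this is 0.73.

## Peak calling

Profiles are probe-level scaled log2(IP/Input) values from one pooled
hybridization per condition, centered so the robust location (Tukey
biweight mean, c = 9·MAD, iterated to |Δt| < 1e−13; median fallback when
MAD = 0) is zero. Centering is per profile; method and parameters are
recorded in the profile's provenance.

Peak detection slides a window of width 750 bp, one window centered on each
probe midpoint, and tests the window's values for being stochastically
greater than the array-wide background (all other probes) with a one-sided
two-sample Kolmogorov–Smirnov statistic
D = max_x [ECDF_bg(x) − ECDF_win(x)], clipped to [0, 1]. Probes belonging
to any window with −log10 p ≥ 2 are significant; maximal runs of
significant probes with inter-probe (midpoint) spacing ≤ 500 bp and ≥ 2
members become peaks, spanning first to last member probe and scored with
the best window centered on a member (the peakscore). Defaults
(750 / 2 / 2 / 500) are the standard NimbleScan-style settings for this
assay and are all configurable.

### Exact p-values for small windows

At 100-bp probe spacing a 750-bp window holds at most 8 probes, far outside
the regime where the asymptotic one-sided tail exp(−2D²mn/(m+n)) is
trustworthy. Whenever min(m, n) ≤ 8 the p-value is therefore computed
exactly under the permutation null — all C(m+n, m) reassignments of the
pooled values to window/background labels, p = P(D ≥ D_obs) — without
enumerating them:

* **Tie-free pools.** A label assignment is a monotone lattice path from
  (0,0) to (N, m) in (items-seen, window-items-seen) coordinates, and
  D ≥ D_obs iff the path touches the barrier i·m − w·(m+n) ≥ d, where d is
  the integer numerator of D_obs over m·n. The barrier can be touched first
  only by a background step, and for each window-count level w the first
  reachable barrier cell is unique, so absorbed paths decompose over ≤ m+1
  first-passage cells. Path counts use exact Python integers (no floating
  cancellation at any significance level); cost is O(m²) per window.
* **Pools with ties.** The decomposition's item-level barrier is invalid
  when values repeat, so a dynamic program walks the distinct-value groups,
  weights within-group label choices binomially, and checks the barrier only
  at group boundaries — exactly the right-continuous ECDF convention used
  for D itself. Cost O(N·m), exact integer arithmetic.

Both routes return the identical value brute-force enumeration returns; the
test suite enforces this over every split of 12-value pools (with and
without ties) and cross-checks tie-free cases against an independent exact
implementation. p-values are clipped into (1e−300, 1]; beyond
min(m, n) = 8 the asymptotic tail is used. Because the permutation null for
a fixed array depends only on (m, d), results are memoized per profile,
which keeps a 27 000-probe scan around two seconds.

Window membership uses probe midpoints in a closed ±375-bp span; windows
are emitted even when geometry degenerates to single-probe membership. A
profile must hold ≥ 10 probes so the background defines a meaningful null.
Emitted peaks always satisfy the probe-count/spacing/cutoff constraints; in
degenerate parameter regimes (max spacing far below the window width) runs
that contain no qualifying member-centered window are dropped rather than
emitted with an inconsistent score.

## Classification and gene summarization

A peak is assigned to a promoter when their intervals overlap by ≥ 1 bp;
a promoter's per-condition peakscore is the maximum over assigned peaks and
0 when none overlaps — the only reading under which a vasectomy-abolished
signal counts as absent. Classification uses strict inequalities:
TE-specific hypomethylated = peakscore > 3.0 (P < 0.001) in PV *and* < 2.0
(P > 0.01) in Nor; hypermethylated is the mirror image. Scores in
[2.0, 3.0] are deliberately indeterminate. The rule is label-symmetric:
swapping the two input conditions exactly swaps the two classes.

Genes with several promoters take the unique differential class any
promoter carries; genes whose promoters carry both differential classes are
neutralized to unclassified with a conflict flag — a conservative,
symmetric rule, recorded in output headers.

Class-proportion tables report two denominators: promoters overlapped by at
least one peak in either condition ("identified in cfsDNA", the natural
denominator for an array where most promoters are never detected) and all
annotated promoters (the denominator against which the simulator's planted
fractions are defined). Peakscore histograms bin the present-condition
score on [3.0, 3.5, 4.0, …).

## Validation-assay calculators

MeDIP-qPCR percent IP/Input = 2^−(Ct_IP − Ct_Input) × dilution × 100;
MethyLight percent of methylated reference = 2^−ΔΔCt × 100 with
ΔΔCt = (Ct_target − Ct_reference)_sample − (Ct_target − Ct_reference)_fully-methylated.
Both assume perfect doubling per cycle (efficiency 2); replicate Cts are
averaged on the Ct scale; values above 100% are reported with a flag, not
clipped. The dilution factor is a required input column, never defaulted.
Control checks flag a negative-control locus quantifying above 0.01% and
any reaction whose unmethylated-vs-fully-methylated Ct margin is below
5 cycles. The synthetic Ct generator inverts these formulas exactly —
ct_ip = ct_input + log2(dilution) − log2(enrichment) and
ΔΔCt = −log2(methylation) — so noise-free tables round-trip to machine
precision; a planted methylation of exactly 0 has no finite Ct and is
emitted as a censored row.

## Enrichment

One-sided over-representation p = P(X ≥ k) from the hypergeometric
distribution (scipy), with Benjamini–Hochberg q-values (statsmodels) and
fold enrichment (k/n)/(K/N). The universe defaults to all genes in the
category map and should be overridden with the array's gene set, since
enrichment is sensitive to the background. Annotation-cluster "enrichment
scores" of interactive GO tools depend on proprietary clustering and are
deliberately not reproduced.

## The synthetic-data generator

The generator emulates the study's measurement design, not its sequences:
`n_genes` promoters (−2200 to +500 bp around the TSS in transcription
orientation) placed non-overlapping on synthetic chromosomes chrS1…k with
≥ 5-kb gaps, tiled by 50-bp probes every 100 bp (≈ 27 probes/promoter,
close to the real array's ~21 per promoter). Each gene carries one
methylation state per source; planted class fractions default to 9.71%
TE-hypomethylated and 3.53% TE-hypermethylated (the study's reported
promoter classes), and 9.6% of the remaining genes are methylated in both
sources so that ≈ 22.8% of promoters carry signal somewhere — the fraction
of array promoters with detectable peaks in the study (4111/18028).

A probe's value is Normal(µ_mix, σ) with
µ_mix = f·µ(state_TE) + (1−f)·µ(state_bg), f = 0.73 for Nor and 0 for PV,
µ_methylated = +1.5, µ_unmethylated = 0, σ = 0.4 — an additive mixture on
the log-ratio scale chosen so every expectation is available in closed form
for testing (e.g. hypomethylated promoters average 0.27 × 1.5 = 0.405 in
Nor). Cohort concentrations are drawn at the published group means/SDs
(1.23 ± 0.32, n = 12; 0.33 ± 0.09, n = 11), truncated positive.

What the generator does **not** model: sequence content and CpG density,
dye bias, spatial artifacts, probe-specific affinity, replicate arrays, and
— importantly — any nonlinearity of MeDIP capture. Passing recovery tests
therefore show the pipeline's stages compose correctly and detect what the
mixture model plants; they do not certify performance on real arrays, whose
noise is heavier-tailed and probe-correlated.

### A structural consequence of the additive mixture

Because the mixture acts additively on mean log-ratios, a TE-hypomethylated
promoter retains a +0.405 residual across all ~27 Nor probes. A correctly
calibrated enrichment test *detects* such a residual — more reliably the
smaller the noise — so these promoters frequently fail the strict
"peakscore < 2 in Nor" arm: measured P(Nor peakscore < 2) is ≈ 0.23 at
σ = 0.4 and ≈ 0 at σ = 0.2, while all detection arms are essentially
perfect (hypermethylated recovery and overall precision are 1.0). Gene-level
sensitivity for TE-specific genes is therefore ≈ 0.40 at σ = 0.4 and
≈ 0.27 at σ = 0.2, concentrated entirely in the hypomethylated class, and
*decreases* with cleaner data. In the real assay this residual is largely
invisible — antibody capture of sparsely methylated fragment populations is
strongly sub-linear, which is precisely why the published criteria work —
but modeling that nonlinearity would sacrifice the closed-form expectations
the test suite relies on. The limitation is inherent to the chosen
simulation model, is reported honestly by the acceptance script, and should
be kept in mind when reading the recovery numbers.

## Reproducibility machinery

All generators are pure functions of (config, seed); the pipeline derives
per-stage seeds from one master seed via `numpy.random.SeedSequence.spawn`,
logs probe/peak/class counts at each stage (making every denominator
auditable), formats numeric output at fixed precision so identical
config+seed gives byte-identical TSVs, and writes a manifest with a SHA-256
digest of every output. Problem sizes used by the acceptance script —
1000 genes (27 000 probes) per planted run and 10 × 5000 windows for the
null calibration — were chosen to put Monte-Carlo error well below the
effects being measured while keeping a full run in seconds on one core.
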