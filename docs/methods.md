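# Methods

## Measurement model

The assay counts circularizable probes that tiled a telomere tract and maps
the count to length. Three modelling layers are implemented:

**Occlusion calculus.** With saturating hybridization, probes pack the
tract end to end. One probe hybridizes a footprint of f = 32 bases; where
two probes abut, each consumes an occlusion width of w = 48 bases (the
footprint plus stem-loop exclusion). The circle count N therefore maps to
length as TL = w(N − 1) + f, and conversely a tract of length L carries
floor((L − f)/w) + 1 probes. Counts are carried as reals throughout (a Cq
implies a population-average count) and rounded only at final bp reporting;
the two maps are exact inverses on the lattice {w(N − 1) + f : N ≥ 1}, and
off-lattice lengths quantize down by strictly less than w per template.

**Probe anatomy.** The default probe is the published 88-mer against the
human telomere G strand. The printed oligo admits exactly one segmentation
consistent with its interior primer and hydrolysis-probe sequences: a 17-nt
5' arm, the 19-nt reverse complement of the reverse primer, the 21-nt
forward primer, a 17-nt hydrolysis-probe region and a 14-nt 3' arm. The
arms then sum to 31 hybridized bases rather than the nominal 16 + 16 = 32;
because the quantification is driven by the geometry constants (f, w), not
by the segmentation, the package stores segment boundaries explicitly
(defaults reproduce the printed strings byte for byte) and keeps f = 32 as
an independent constant. Ligation is modelled as requiring Watson–Crick
pairing of both target bases spanning the nick — the TA of GGGTTAGGG under
the default design — so a single variant base there (subtelomeric
(TTXAGGG)n) aborts circularization; the simulator adds a configurable leak
probability (default 0.01) for mismatched junctions, since discrimination
is strong but not absolute.

**Calibration.** Two parameterizations of Cq-to-copies coexist: a
log-linear standard curve fitted by least squares to (copies, Cq) dilution
points, with efficiency 10^(−1/slope) − 1, and the fixed exponential form
N = 4×10¹¹·exp(−0.691·Cq). The exponential constants are a rounded
transform of a fitted slope (0.691 vs ln10/3.3649 = 0.684), so the two
forms drift by up to ~1% over the working Cq range; when calibration
points are available the fitted curve is preferred, otherwise the fixed
constants are used. Replicates aggregate as mean Cq with the Cq standard
deviation propagated to length by the first-order delta method
(sd(TL) ≈ w·k·N·sd(Cq) under the exponential form); per-replicate lengths
are also reported. Wells at Cq ≥ 40 (the observed negative-control band) or
with no detection are gated as background before quantification.

## Mean telomere length and ploidy

Total length per cell divides by the telomere count: 2 per chromosome
(one end pair), doubled again in G2/M for sister chromatids. Bundled
karyotype presets carry low/modal/high chromosome counts (CP-A 47/47/47,
HEK-293 64/64/64, MDA-MB-231 52/64/68, MCF-7 66/82/87, K-562 67/67/67);
unstable aneuploid lines report all three scenarios, ordered
mtl(low) ≥ mtl(modal) ≥ mtl(high) for a fixed total. The K-562 count (134)
is derived from its karyotype rather than independently reported, and its
preset is flagged accordingly. Cell-cycle stage comes from single-copy-gene
DNA content: a log-linear pg-versus-Cq calibration, referenced to 6.6 pg
for a diploid G1 genome; the G1/G2M threshold is 1.5× with an ambiguous
dead zone of [1.4, 1.6], all configurable, since no principled boundary
exists between partially replicated states — callers must resolve
ambiguous cells before counting telomeres.

## TRF densitometry

Gel migration is calibrated as log10(length) linear in position (a
reciprocal-fit mode exists as an alternative); the fit refuses ladders
whose fitted length increases with migration. Lane background is a
constant offset, estimated from the profile tails by default (5% tails)
and clipped subtraction. The lane mean uses the hybridization-corrected
estimator MTL = ΣOD / Σ(OD/L): probe binds in proportion to fragment
length, so the naive OD-weighted mean over-weights long fragments and the
corrected value is strictly smaller on any non-degenerate profile. Bins
outside the ladder's calibrated range are excluded by default and their
presence flagged; extrapolation is opt-in because the top marker
(23.13 kbp) bounds trustworthy calibration.

## Forward simulator

The simulator generates what the pipeline inverts: per replicate it tiles
each template (deterministic saturating packing, or random sequential
adsorption with occlusion-width exclusion for the kinetic limit), draws
binomial ligation successes at match/mismatch probabilities, adds Poisson
background circles, and maps the circle count to Cq by inverting the
log-linear calibration and adding Gaussian Cq noise. Circle counts below
one report as non-detect. Negative controls: with the Poisson switch off,
the expected fractional background count is used directly, modelling the
sub-single-copy effective template of a blank; under the default
calibration a background of 0.2–0.4 expected circles reads out at
Cq 40–42, the observed negative-control band. Stochastic tiling jams below
the saturating density (typically ~70% on an 800 bp tract), which is why
saturating mode is the default for validating the length formula — the
assay's slow hybridization ramp with excess probe is designed to approach
saturation. Recovery applies the calculus per template copy
(n = circles/templates, then w(n − 1) + f), so noiseless recovery is exact
on lattice lengths; the pooled path (formula on the summed count, then
divide) matches the plasmid worked example and carries a +(w − f)(1 − 1/M)
≈ 16 bp offset per template for M templates.

## Synthetic data

The lane synthesizer emits OD proportional to fragment number density
times length on a migration grid spanning the ladder; a log-normal smear
(or a delta spike) stands in for a telomere length distribution, with
optional Gaussian OD noise and constant baseline, deterministic under a
seed. The single-cell fixture batch draws 10 per-cell totals around 500 kb
(sd 30 kb) — a realistic diploid-line scale — and reads them out through
the default calibration with 0.05-cycle Cq noise. These synthetic inputs
exercise the full numeric chain but idealize real data: gel lanes have
spatially structured background and lane distortion, real Cq noise is not
exactly Gaussian or homoscedastic, and real telomere tracts contain variant
repeats interrupting perfect tiling. Passing tests therefore demonstrate
correctness of the calculus and its inversion, not instrument-level
accuracy.

## Numerical choices and problem sizes

Least-squares fits use scipy's linear regression; standard-curve fitting
requires ≥ 3 distinct positive copy levels. Counts below one probe return
zero length with no error. The tiling count uses integer floor division
and accepts vector inputs; the full-range inverse check in the test suite
runs all counts up to 10⁶ vectorized. Simulator recovery tests use 10
replicates at 10²–10³ template copies and tract lengths ≤ 1600 bp, sizes
chosen so the entire suite completes in seconds while still exercising
every stochastic branch. Melting temperatures are nearest-neighbour
estimates (two parameter sets cross-checked) and are advisory only: the
assay fixes hybridization empirically by a slow temperature ramp.

## Known limitations

- The per-copy length of a multi-template sample inherits the ~(w − f)
  pooled-formula offset noted above; per-template recovery avoids it when
  the copy number is known.
- Junction discrimination is modelled as a hard verdict with a scalar
  leak; real ligases show sequence-context-dependent fidelity.
- Karyotype presets bracket ploidy but cannot capture cell-to-cell
  chromosome-number variation within an unstable line.
- TRF comparison operates on 1-D traces; blot image processing (lane
  finding, 2-D background) is out of scope, as are restriction-digest
  simulation and subtelomeric-fragment corrections.
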