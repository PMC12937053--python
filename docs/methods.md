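# Methods

## Peptide chemistry

All masses are monoisotopic.  Residue masses come from the standard
amino-acid table in `pyteomics.mass`; water is 18.0105647 Da and the proton
1.00727646688 Da.  Heavy-label shifts are computed from isotope mass
differences rather than hard-coded: ¹³C−¹²C = 1.0033548 Da and
¹⁵N−¹⁴N = 0.9970349 Da give +8.014199 Da for ¹³C₆¹⁵N₂-lysine and
+6.013809 Da for ¹³C₅¹⁵N₁-glutamic acid.  With these constants the
2-decimal display m/z of the benchmark peptides (ITDFGRAK 2+: 454.25 light
/ 458.26 heavy; ELREATSPK 2+: 515.78 / 519.79) fall out of the arithmetic;
they are frozen in the tests against an independent elemental-composition
oracle.  Full precision is kept internally; rounding (half-even via Python's
`round`) is a display convention only.

Fragment series are singly charged b/y by default:
b_i = Σresidues(1..i) + z·proton, y_j = Σresidues(n−j+1..n) + water +
z·proton, with the label shift added when the fragment span contains the
labelled residue.  The complementarity identity
b_i + y_{n−i} = M + 2·proton is property-tested.  A C-terminal label
therefore shifts every y ion and no b ion — the chemical fact the window
design exploits: under coisolation the shared ions are exactly the b
series, under separate isolation all 2(n−1) fragments of each channel are
usable.

A fixed methylthio-Cys modification (+45.98772 Da) is available on the mass
table but off by default; none of the benchmark target peptides contain
cysteine.

Digestion uses regex cleavage rules through `pyteomics.parser.icleave`:
trypsin/P (after K/R, including before proline — the specificity modern
search engines use) with classical no-P trypsin as a named alternative;
LysC (after K); GluC (after E only, the specificity in bicarbonate-style
buffers), with an E+D variant (`gluc_de`) for phosphate buffers.  At zero
missed cleavages the peptides partition the protein (property-tested); with
k missed cleavages all concatenations of ≤ k+1 adjacent fragments are
emitted with 1-based inclusive coordinates.

Variant panels substitute or delete residues in the wild-type sequence,
digest mutant and wild type with each requested protease, and keep peptides
whose span contains the variant site (for deletions, both residues flanking
the novel junction, clipped at the termini).  Heavy labels are assigned to
the protease-determined C terminus (K → heavy-Lys, E → heavy-Glu);
candidates outside the 7–52-residue length window, without a labelable
terminus, or with no charge-2/3 precursor inside the scan range are excluded
with a recorded reason rather than dropped silently.

## Window-scheme design

Windows are half-open `[start, end)` intervals so adjacent windows share
boundaries unambiguously; a precursor exactly on a boundary belongs to the
right-hand window.

**Narrow target windows.** A single global grid of width w (default 4 Th)
anchored at offset 1.0 Th (boundaries ≡ 1 mod 4) determines each
precursor's window.  This anchor is the simple rule consistent with both
benchmark placements (453–457/457–461 and 513–517/517–521); it is fully
configurable.  A heavy-Lys 2+ pair is spaced 8.0142/2 = 4.0071 Th > 4 Th
apart, so the grid alone always separates the channels (property-tested
over random m/z).  When a pair's spacing is below the window width (e.g.
heavy-Glu at 2+, spacing 3.007 Th), the pair's two windows are re-anchored
locally so their shared boundary is the light/heavy midpoint, and both are
flagged `off_grid` — separation of the pair is the design's defining
guarantee and takes precedence over grid regularity.  Identical windows
arising from distinct pairs are merged; partially overlapping narrow
windows are an error (targets too crowded for the narrow width).

**Wide profile windows.** The m/z gaps left between narrow blocks are tiled
by a fixed budget of wide windows.  The budget is allocated across gaps by
largest-remainder apportionment on each gap's density mass (gap width when
no density reference is supplied), with a final adjustment guaranteeing
every gap at least one window; the allocation conserves the total count
exactly (property-tested under random densities).  Within a gap, boundaries
sit at equal cumulative-density quantiles: the supplied precursor-density
points (m/z, weight) are linearly interpolated onto a fine grid (2049
points), integrated by trapezoid, and the cumulative curve inverted at
k/n · total.  A tiny uniform floor (10⁻⁹ of the density maximum) keeps the
cumulative strictly increasing across zero-density stretches without
visibly moving the quantiles.  Uniform density therefore reduces to the
equal-width scheme (oracle-tested).  Optional width bounds are enforced by
iteratively pinning violating widths at the bound and re-spreading the
remaining span over the free windows; an infeasible gap (span outside
[n·min, n·max]) raises an error naming the gap.  No width bounds are
applied by default — a single pair in a 600 Th scan range legitimately
leaves one very wide flanking window.

The reference schemes used for comparison are `equal_width_scheme`
(e.g. 40 × 15 Th over 400–1000 m/z, which coisolates the 515.78/519.79
pair in its 505–520 window) and `variable_width_scheme` (pure quantile
windows, the density-balanced DIA baseline).  `validate_scheme` reports
coverage, overlap, width-bound compliance, per-kind counts, and per-pair
separation (light and heavy in different windows) machine-readably.
Acquisition order is ascending m/z; the window budget (narrow count is
2 × pairs; wide count a parameter, default 20) is configuration, not a
constant.

## Absolute quantification

The L/H ratio is Σ(light areas)/Σ(heavy areas) over a selected fragment
set.  Under a coisolating scheme the selection is forced to the
channel-unique fragments (the y series for C-terminal labels); an empty
unique set is an error that names the cause.  Summation (rather than a
per-fragment median) is used because the ratio of proportional channels is
invariant under any fragment subset, which is also property-tested.

Calibration is unweighted ordinary least squares of the replicate-mean L/H
ratio against nominal amount (replicate-level fit available); blanks
(nominal 0) enter the fit and, with ≥ 2 replicates, define
S_a = sd(blank ratios), hence LOD = 3·S_a/m and LOQ = 10·S_a/m
(LOQ/LOD ≡ 10/3).  Without blanks the limits are reported unavailable, not
imputed.  S_y|x = √(Σr²/(n−2)).  A negative slope yields a warning flag
rather than rejection.  Interpolated amounts are (ratio − b)/m; negative
amounts (response below the blank line) are reported as-is with a
`below_lod` flag, and amounts beyond the calibrated range carry an
`extrapolated` flag — auditability over tidiness.

A note on precision at low QC levels: with multiplicative 5 % CV noise and
an unweighted fit over 0.5–500 fmol, the intercept variance is dominated by
the top calibrators, and Monte-Carlo simulation (1000 reps) shows a median
interpolation error near 18 % at a 2.5 fmol QC.  The closure tests
therefore bound the seeded run by the simulation's own 99 % error envelope
instead of a fixed invented tolerance, and verify separately that the slope
estimate is unbiased to < 1 %.  A 1/x-weighted fit is the standard remedy
and is exposed as an option upstream of these defaults.

Mutant metrics are ratio = mutant/WT and fraction = mutant/(mutant+WT)
(the protein-level analogue of a variant allele frequency); display rounds
the ratio to one decimal and the fraction to integer percent.

## Spectrum and chromatogram metrics

Cosine similarity matches peaks greedily within a 0.02 Th tolerance
(closest pair first, each peak used once); unmatched peaks contribute zero
to the cross term but full weight to the norms.  The score is symmetric,
scale-invariant and bounded in [0, 1].  Plain intensities are used (no
square-root weighting).

XIC areas are trapezoidal over the peak bounds with an optional linear
baseline drawn between the boundary intensities (on by default; additivity
over adjacent bounds holds with the baseline off).  The signal-to-noise
estimator is (apex − median(background)) / max(1.4826·MAD(background), ε)
with ε = 10⁻⁶ and ≥ 5 flanking background points per side.  This is an
artifact definition — robust and deterministic — and its absolute values
are not comparable to S/N figures produced by vendor peak-integration
software.

## Profiling statistics

Abundance matrices are pandas DataFrames (proteins × samples, log2,
NaN = missing, pairwise deletion; imputation is a pluggable upstream step,
none by default).  `median_center` subtracts each sample's median and is
applied *before* z-scoring in the CLI pipeline; `pathway_zscore` itself
only z-scores each protein across samples (sample sd, ddof = 1;
zero-variance proteins contribute 0 with a warning) and averages member
proteins per sample.  The differential-expression filter runs a two-sided
Wilcoxon rank-sum (Mann–Whitney, exact where possible) per protein with
Benjamini–Hochberg adjustment across all tested proteins; survivors need
|log2 FC| ≥ log2(threshold) (default 2-fold) *and* adjusted p ≤ 0.05.
With exact rank tests this implies ≥ 5 samples per group for any protein
to survive at conventional thresholds; the test fixtures are sized
accordingly.

## The simulator

`synth_panel` draws tryptic-like sequences (7–16 residues, interiors free
of K/R/E, C-terminal anchor matching the label) and rejection-samples until
all pairs fit the scan range with a minimum light-m/z separation
(default 12 Th).  `simulate_acquisition` assigns each species to the single
window isolating its precursor and sums theoretical fragment spectra,
intensities proportional to amount times a fixed per-sequence fragment
profile (drawn once per sequence from a seeded RNG, so light and heavy
channels share a profile — the property that makes the summed-fragment L/H
ratio equal the amount ratio exactly in the noise-free limit).  The
interference report lists, per pair, the fragments whose light/heavy m/z
collide within tolerance while both precursors share a window: all n−1 b
ions under a coisolating scheme, none under a pair-separating one.

Calibration series use the spike-in design the workflow targets: light at
0.5–500 fmol (six levels, triplicate) against a fixed 25 fmol heavy spike,
multiplicative lognormal noise of unit mean and 5 % CV, and blanks
normal(intercept, blank_sd) truncated at zero.  Chromatograms are Gaussian
peaks of area equal to the amount with optional additive noise and a
constant baseline.  All generators are deterministic under an integer seed.

What the simulator does **not** emulate: real fragmentation intensities
(no HCD model), isotope envelopes, retention-time drift, chemical
background and ion suppression, or detector saturation.  Passing closure
tests therefore demonstrate the internal consistency of the
design→acquire→ratio→calibrate→quantify chain, not instrument-level
figures of merit; quantities that depend on acquired raw data (absolute
LOD/LOQ in the attomole range, instrument S/N, proteome coverage counts)
are out of scope by construction.

## Problem sizes and numerics

Default test and acceptance workloads are desk-scale: panels of 4–8 pairs,
schemes of ≤ 40 windows, calibration fits of ≤ 21 points, and Monte-Carlo
envelopes of 1000 replicate fits — each fit is a 7-point OLS, so the whole
suite runs in seconds.  Tolerances: m/z assertions at the 2-decimal display
precision; tiling identities at 10⁻⁶ Th; noise-free closures at 10⁻⁶
relative; stochastic closures at oracle-derived envelopes as described
above.  Ties and degenerate inputs: boundary m/z resolves to the right
window (half-open rule); duplicate target windows merge; all-zero densities
are rejected; zero heavy denominators and zero-mean CVs raise explicit
errors.
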