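# Methods

## Scope and data model

`roifuse` operates on centroided MS1 data only. Profile-mode spectra are
rejected at import: the ROI search assumes at most one centroid per
analyte per scan, and centroiding belongs to the instrument software.
Times are minutes everywhere (retention time for LC, migration time for
CE); m/z is in Da. A run must be single-polarity — mixed-polarity files
raise an error rather than being split silently. MS/MS scans are dropped
on import. The crop filter treats both its time and m/z intervals as
closed, so centroids exactly at the instrument scan-range limits (e.g.
100 and 700 m/z) survive a crop to that range.

mzXML and mzML (optionally gzipped) are read; mzXML through pyteomics,
mzML through a compact reader over the standard PSI-MS controlled
vocabulary (64/32-bit floats, zlib or no compression, MS1/centroid/
polarity/scan-start-time terms), because the installed pyteomics build
delegates mzML parsing to an optional dependency. The synthetic-data
module writes both formats, which keeps the import path under test.

## ROI search

Centroids with intensity ≥ `intensity_threshold` are grown into traces
scan by scan. Within a scan, centroids are processed in descending
intensity so that strong centroids claim their nearest open trace first;
this makes the result independent of within-scan centroid ordering. A
centroid joins the open trace whose consensus m/z is nearest within
`mz_error`; the consensus is updated as a running intensity-weighted
mean, which anchors it to the well-determined high-intensity points. Each
trace accepts at most one centroid per scan; each centroid joins at most
one trace (a partition of the admitted centroids). Traces silent for more
than `max_gap` scans (default 2) are closed; closed traces shorter than
`min_roi_size` scans are discarded.

Two deliberate choices: gaps inside a kept trace stay absent — no
synthetic noise points are interpolated into the chromatogram/
electropherogram, since padding distorts peak tips, induces peak
splitting, and destabilizes apex times across replicates; and
`min_roi_size` must be chosen per method, below the expected peak width
in scans (broad HILIC peaks tolerate 15, sharp CE peaks need < 10).

A practical threshold heuristic is exposed as `recommend_threshold`:
a fraction (5–10 %) of the lowest base-peak-trace maximum over the
group's runs.

## Baseline, isotope, adduct, contaminant filters

Baseline drift is estimated by linear interpolation through the minima of
consecutive `window`-scan blocks and subtracted (clipped at zero); traces
shorter than the window lose their global minimum. The isotope filter
removes a trace when a co-eluting, stronger, correlated (Pearson r over
the shared scan range ≥ `corr_min`) trace exists at m/z − 1.00336/z for
z ∈ {1, 2} — charges above 2 are irrelevant in the 100–700 m/z metabolite
range. The adduct filter removes the weaker of two co-eluting traces
separated by a configured adduct offset (defaults: ESI+ Na−H +21.9819,
K−H +37.9559, NH₄ +17.0265; ESI− Cl +34.9689, formate +46.0055; all
user-overridable as CSV). The contaminant filter removes traces matching
a listed m/z that persist over more than a configured fraction (default
0.8) of the run — background ions are present throughout a separation,
analytes are not. All three filters partition their input into
(kept, removed); they never modify traces. They run before peak
detection by default and can be applied post hoc instead.

## Peak detection and delimitation

Each trace is smoothed by local quadratic least squares
(Savitzky–Golay, order 2; window 7 for CE, 15 for HILIC — roughly half
the expected peak FWHM in scans). The noise level is the robust SD of
the smoothing residual, 1.4826 × median |raw − smoothed|, insensitive to
the peaks themselves dominating a few residuals.

Candidate apexes are found with a continuous wavelet transform using the
Mexican-hat mother wavelet over five logarithmic scales spanning
[min_width, max_width] (converted to scans), with per-scale maxima linked
into ridge lines (gap tolerance 2 scales). A ridge's best position must
coincide, within one scale width, with a negative minimum of the second
derivative of the smoothed trace — the classic signature of a peak apex —
otherwise it is discarded. The candidate's height is measured above the
trace's 10th-percentile level, so ripples on an elevated flat trace do
not fake a high signal-to-noise ratio; candidates below `min_snr` are
dropped. Provisional borders sit at the nearest flanking zero-crossings
of the second derivative (≈ ±1 σ for a Gaussian), with the shared valley
splitting overlapping neighbours.

Real peaks are rarely symmetric, so borders are refined in two steps:

1. **Friction walk** (smoothed trace): from each provisional border walk
   outward while the trace still falls by more than a friction fraction
   `f` (default 0.05) of the local height per step; stop when the descent
   stalls or the trace reaches the noise floor. This follows a tailing
   flank down without running into baseline.
2. **Moving-SD walk** (raw trace): keep walking outward while the raw
   trace's SD in a `w`-point window (default 5) exceeds `k` × noise
   (default k = 2); the border is the last point at or below that level.

Borders never cross the apex nor the valley shared with an adjacent
peak; an apex at the trace edge is clamped and flagged. The free
constants (f, w, k) are exposed in the configuration. Area is the
trapezoidal integral of the raw intensities between the borders
(counts·min); height is the maximum in-border intensity and defines the
apex time. Optionally the ROI intensity threshold is subtracted from
every point before integration (the historical behaviour of the
reference workflow, responsible for a known ~10 % underestimation versus
manual integration); a switch disables it, and the synthetic-study
evaluation runs with it off so areas are comparable to closed-form truth.

## Feature filters and the entropy filter

Peaks are kept when their width lies in [min_width, max_width], height ≥
`min_intensity`, SNR ≥ `min_snr`, and height ≥ `min_rel_height` (default
25 %) of the tallest peak in the same trace. The defaults
(max_width 2 min, min_intensity 5 × 10⁴) mirror the reference criteria
for Orbitrap metabolomics data; groups with deliberately broad peaks
(e.g. a tailing-HILIC simulation with σ up to 0.4 min, base width
≈ 3 min) must raise `max_width` accordingly — per-group parameterization
is the point of the tool.

The entropy filter scores slope consistency. For an ideal peak every
point rises strictly before the apex and falls strictly after it
(*normal* points); zero or wrong-signed incoming slopes mark *variant*
points (a flat step is not a constant positive/negative slope; the first
point and the apex carry no violation). With p and q the variant and
normal fractions (p + q = 1),

    H = −p·log₂(p) − q·log₂(q),   0·log₂(0) := 0,

so H ∈ [0, 1], H = 0 for a perfectly monotone peak, H = 1 at p = 0.5.
H is invariant under intensity rescaling, since only slope signs enter.
Peaks with H strictly above the median over the run's peaks are
discarded — by construction at most half, and a lone peak survives. The
median is computed per run (not per trace or per group). The filter is
an additional, optional noise rejector aimed at data where many detected
peaks are noise; on clean data the median rule necessarily discards good
peaks, so it is off by default and enabled per group.

## Alignment, cube, scaling

CE migration times shift between replicates by up to around ±1 min,
HILIC retention times by ~±0.1 min. Time alignment is a per-replicate
global shift: landmark features matched to a reference replicate (by m/z
and time tolerance) define a median time offset, which is subtracted.
A global shift is the simplest model consistent with a common
electroosmotic-flow change; nonlinear warping is noted as an extension
and deliberately not implemented. Fewer than 3 landmarks ⇒ no shift,
with a warning. Mass alignment (for drifting calibrations) shifts each
replicate's masses by the chosen quantile (default 0.95) of its offsets
against the cross-replicate consensus.

Features are matched across replicates by greedy nearest-neighbour
clustering in (m/z, time), m/z first, ties to the smaller time gap, over
a pooled list in deterministic (m/z, time, replicate) order — hence the
result cannot depend on file order. A cluster holds at most one
detection per replicate. Matched sets become cells of the `N × M × S`
cube; replicates without a detection store **zero**, not missing — this
carries the presence/absence semantics ("knock out"/"induced") into the
statistics. The minimum occurrence count for a relative occurrence r is
`max(1, ceil(r·S))` (all printed anchor cases — 3/6 at 50 %, ≥1/6 at
0 %, 6/6 at 100 % — are integer-exact; ceiling is chosen for the
non-integer cases).

Scaling acts per feature across the S replicate layers with the standard
formulations: center x−m; auto (x−m)/s; Pareto (x−m)/√s; vast
((x−m)/s)·(m/s); range (x−m)/(max−min); level (x−m)/m (s = sample SD).
A zero divisor leaves the feature centered only. All six are affine per
feature and hence exactly invertible. Log transforms lift zeros by the
smallest nonzero cube value unless an offset is given; normalization
divides each replicate layer by a positive factor (explicit, e.g. cell
counts, or the replicate's mean internal-standard area).

## Augmentation, matching, annotation, coverage

Mid-level fusion concatenates per-group feature tables after each group
has been extracted, filtered, and scaled independently; rows are never
merged, so group blocks stay intact and row counts are conserved.
Features are named `"{mz:.4f} @{time:.1f}, {group}"` (rounding
configurable; the defaults follow the reference table's printed
precision). Cross-group links require m/z agreement within a tolerance
(default 0.01 Da — "identical mass" needs an operational tolerance) AND
an equal number of detections within each group; time is never compared,
because migration and retention times are not commensurable. Ambiguous
multi-way candidates resolve toward the smallest Δm/z; the rest stay
unlinked and are logged.

Target annotation labels a row when its m/z and its group's method-
specific expected time both match a reference entry (references without
a time for that method fall back to m/z-only, flagged low-confidence).
Suspect screening labels rows within ±0.03 m/z (default) of a candidate
list, recording every hit.

Coverage counting operates on the shipped detection-flag table
(`data/table1_flags.csv`: 40 analytes × 5 methods, flags detected /
failed / comigrating / absent): an analyte counts when at least one of
the chosen methods detects it, excluding the internal standards
(analytes 17–20) and — unless requested — co-migrating detections, which
are seen only at the electroosmotic-flow front and are not separated.
On this table the three ESI− methods cover 30 of the 36 standard
metabolites and the two ESI+ methods 23; both counts are recomputed, not
stored. Ion m/z values derive from neutral monoisotopic masses with the
hydrogen-atom convention (±1.00783 Da, electron mass neglected), which
reproduces the reference table to four decimals; the proton convention
(±1.00728) would not.

## Statistics

Fold change is mean(treated)/mean(reference) over per-replicate areas.
Classes: FC < 0.50 down; 0.50 ≤ FC ≤ 2.00 stable; FC > 2.00 up. The
printed class boundaries overlap at 2.00; here 2.00 is stable, and an
exact 2.00 is flagged in the output. Knock-out requires presence
(occurrence ≥ the group threshold) in the reference and zero detections
under treatment; induced is the mirror image; partial presence on both
sides falls back to fold-change classification with zeros included, so
the classification is scale-invariant throughout. P-values come from a
two-sample Welch t-test, by default on log₁₀ areas (zeros lifted by the
smallest nonzero value); the choice of test and the log switch are
configuration, since only the volcano/FDR machinery is fixed by the
workflow. Benjamini–Hochberg adjustment uses the statsmodels step-up
implementation; the test suite checks it against a brute-force
evaluation of q₍ᵢ₎ = min₍j≥i₎ m·p₍ⱼ₎/j on all inputs of length ≤ 8.
PCA runs on the scaled samples × features matrix (scores centred,
explained fractions non-increasing, summing to 1 at full rank); heatmap
rows are ordered by average-linkage hierarchical clustering on Euclidean
distances. Volcano exports are (log₂ FC, −log₁₀ p, q < α), with zero
p-values clipped to the smallest positive float.

## Synthetic data and what passing tests show

The generator plants Gaussian (CE) or exponentially-modified-Gaussian
(HILIC, τ = σ by default — HILIC peaks tail) features on a regular scan
grid. Method profiles: CE — σ ∈ [0.02, 0.1] min, one migration-time
shift per replicate ~N(0, 0.3 min), scan interval 0.005 min, 10 min run;
HILIC — σ ∈ [0.1, 0.4] min, shift ~N(0, 0.03 min), interval 0.02 min,
15 min run with linear baseline drift. Both add a constant baseline
(200 counts), white noise (SD 500), and per-centroid m/z jitter
(SD 0.001 Da). Feature heights are log-uniform in [2×10⁵, 2×10⁶]
counts; a strongly down-regulated low-abundance feature can therefore
fall near the 5×10⁴ minimum-height criterion and drop out — a realistic
detectability limit that bounds regulation-class recovery just below
100 %. m/z values are spaced ≥ 0.05 Da so traces never merge. The study design is two phenotypes (mock/treated)
× six replicates × both methods, with 10 % knocked-out, 10 % induced,
15 % up- (×2.5–8) and 15 % down-regulated (×0.125–0.4) features.
Ground truth records the realized apex time, m/z, and closed-form area
(h·σ·√(2π) for Gaussians; dense noiseless integration for EMG, whose
height-normalized form has no simple closed form).

The reference evaluation (`roifuse.benchmark.evaluate_study`) simulates
such a study, runs the complete pipeline (threshold subtraction off),
and scores planted-feature recall at 50 % occurrence, the median
relative area error, and regulation-class recovery. These synthetic
conditions emulate peak shape, time jitter, noise, and baseline — not
chemical background, co-eluting isomers, ion suppression, detector
saturation, or isotope envelopes. Passing therefore demonstrates the
correctness of the extraction/fusion machinery under its stated model,
not instrument-grade performance on real extracts.

## Numerical choices and degenerate inputs

- Savitzky–Golay smoothing reproduces constants and linear ramps
  exactly; traces shorter than the window are returned unchanged.
- Noise estimation on < 3 points returns 0 with a warning.
- Entropy uses the 0·log₂0 := 0 convention; a single peak in a run is
  always kept (its H equals the median, and removal requires strictly
  greater).
- Scaling with a zero divisor (constant feature) degrades to centering;
  variance-based methods use the sample SD (ddof = 1).
- The occurrence ceiling uses a 10⁻¹² guard against float noise in r·S.
- PCA requests beyond the matrix rank are truncated with a warning.
- All simulation randomness flows through one seeded NumPy generator;
  per-replicate seeds are drawn from it and recorded in the truth table.
- Deterministic stages rerun bit-identically; group processing order and
  file order within a group do not affect any output.

## Known limitations

- No nonlinear time warping; a global per-replicate shift only.
- No effective-mobility axis for CE; migration times are used as-is.
- No charge-state deconvolution, MS/MS identification, spectral
  networking, or database lookup.
- The cross-group match rule (equal m/z and equal occurrence) can link
  coincidental pairs and can miss true pairs whose occurrence differs by
  a single missed detection; time cannot disambiguate across methods by
  design.
- Isotope-pattern fidelity in the generator is limited to the +1 peak
  spacing used by the filter; no full envelopes.
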