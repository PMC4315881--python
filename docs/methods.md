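# Methods

## Problem and model

An interventional instrument carries N fiducial markers (resonant
microcoils filled with a high proton-density gel). A tracking readout
acquires n one-dimensional projections: each is the inverse Fourier
transform of a readout with a single frequency-encoding gradient, a
magnitude profile of total signal versus position along a known unit
direction **N**ₖ. A marker at position **P** (mm, scanner frame with the
isocentre as origin) produces a peak at the scalar offset pₖ = **N**ₖ·**P**,
so each detected peak constrains the marker to the plane **N**ₖ·**P** = pₖ.

Three projections with non-coplanar normals intersect in

P = [p₁(**N**₂×**N**₃) + p₂(**N**₃×**N**₁) + p₃(**N**₁×**N**₂)] / det(**N**₁,**N**₂,**N**₃),

and because the map is linear, peak errors Δpₖ propagate with the same
kernel, scaled by 1/|det|. The localization algorithm is:

1. **Peak detection** per projection: local maxima by first-difference
   sign change; ghost suppression (of two maxima exactly one pixel apart
   the smaller is dropped); the N largest maxima are gated by an SNR
   threshold λ (amplitude over the standard deviation of the background,
   which excludes ±4 samples around each peak); accepted peaks are refined
   by three-point Gaussian interpolation
   X̂ = x − ½ (ln c − ln a)/(ln a + ln c − 2 ln b), which is exact for
   Gaussian peaks and bounded by half a pixel.
2. **Reference selection**: all C(n,3) direction triples are ranked by
   decreasing |det|; the first triple whose three projections each show
   exactly N peaks separated by more than d is the reference.
3. **Candidate generation**: all N³ one-peak-per-projection plane
   intersections.
4. **Elimination**: remaining projections, ordered by decreasing minimum
   peak separation (projections with fewer than N peaks last), remove any
   candidate whose projected value has no peak within ε; on projections
   with fewer than N peaks the tolerance is enlarged to ε_merged. Success
   requires exactly N survivors (points closer than 1e-6 mm are first
   deduplicated); anything else discards the frame.

Pose registration assigns the surviving points to the instrument's
nominal marker model (all pairwise distances distinct by design): for
three markers by the A/B/C largest-distance rule, for more by exhaustive
permutation search on the pairwise-distance profile. A proper rigid
transform (Kabsch via `scipy.spatial.transform.Rotation.align_vectors`,
reflection excluded) maps the model onto the observations, and the needle
tip/axis follow from the known probe geometry. A causal five-sample
moving average is provided for display smoothing.

## Parameters, units, defaults

| parameter | default | meaning / rationale |
|---|---|---|
| FOV | 300 mm | tracking readout field of view |
| n_samples | 320 | readout samples; pixel = 0.9375 mm. The readout count is taken equal to the stated phase-encode count; it is exposed as configuration |
| coordinate of sample i | (i + 0.5 − n/2)·pixel | sample centres, isocentre at FOV midpoint |
| λ (SNR threshold) | 5 | conservative gate; the reference work determined it experimentally without printing it |
| background half-width | 4 samples | excluded on either side of each peak for the noise estimate |
| σ_peak | 0.08 mm | standard deviation of the sub-pixel peak estimate over repeated acquisitions (upper end of the experimentally observed 0.03–0.08 mm) |
| ε | 10·σ_peak = 0.8 mm | elimination tolerance; ten standard deviations absorb the stochastic peak spread |
| ε_merged | 2 pixels = 1.875 mm | tolerance on projections with < N peaks, matching the scale at which peaks merge |
| d | 2 pixels | minimum intra-projection peak separation for a reference projection; the smallest separation at which peaks are reliably distinct |
| marker volume | cube of half-width 150 mm, ≥ 30 mm apart | robustness-study placement constraint |
| pose ranges | sagittal 30–80°, coronal ±25° | targeting-study probe rotations, composed sagittal-then-coronal about the isocentre |
| T1, T2 | 160 ms, 14 ms | water-gel filling of the microcoils |
| TE, TR | 3.5 ms, 5.6 ms | tracking sequence timing |
| Q | 120 | loaded microcoil quality factor; α_eff = Q·α_app |

## Direction sets

Projection directions come from the voxel neighbourhoods of discrete
geometry: integer offsets in {−1,0,1}³ \ {0}, antipodal pairs collapsed
(first nonzero component positive), normalized. Levels 6/18/26 give
3/9/13 lines. Canonical order is by class (axes, face diagonals, cube
diagonals) then lexicographic on offsets; the reference work fixes no
order, and any fixed order is equivalent. For studies with n < 13
projections the subset is the prefix of a greedy max-min-angle ordering
of the 13 (axes first, then cube diagonals, ...). This yields nested,
deterministic, well-spread subsets; a naive prefix of the canonical order
would put two face diagonals in the same coordinate plane at n = 5,
leaving one coordinate unconstrained by every test projection and making
localization impossible by construction.

|det| ranking of the reference triples is a conditioning heuristic, not a
strict optimum: for equal per-projection errors the top-ranked
(orthonormal) triple amplifies the error by √3, which is near — but not
exactly at — the minimum over all 286 triples (≈ 1.13 of it), and far
below the worst usable triple. The test suite asserts this weaker, true
property.

## Synthetic data

Two generators stand in for the scanner:

* `synth_projection` builds magnitude profiles as Gaussian bumps plus
  i.i.d. Gaussian noise, rectified to non-negative values. It emulates
  peak shapes, background noise, peak merging of nearby markers, and the
  determinism needed for fixtures. It does **not** model Rician noise
  statistics, k-space truncation ringing, off-resonance or
  susceptibility-induced peak shifts, or the orientation dependence of
  the marker signal; conclusions from passing tests therefore concern the
  algorithmic pipeline, not those acquisition physics.
* `project_markers` skips the signal level entirely and perturbs exact
  projected positions with Gaussian errors of standard deviation σ_peak —
  the regime in which the Monte Carlo studies are defined. This is
  justified by the repeated-acquisition experiment the studies mirror:
  the sub-pixel peak estimate of a static marker is normally distributed
  (the suite re-verifies this on `synth_projection` with a binned
  chi-square test at α = 0.01).

Peak merging is emulated by collapsing projected positions closer than
two pixels into a single peak at the **cluster centroid**. The centroid
(rather than one member's position) is the physically sensible limit —
the superposition of two comparable Gaussians peaks between the centres —
and it keeps every merged marker within half the merge distance of the
surviving peak. Representing the cluster by one member while the merged
tolerance equals the merge threshold would create a zero-margin knife
edge that eliminates true markers in a few percent of frames, a behaviour
the published robustness table rules out.

Whether the published robustness table included merge emulation is not
stated. Both modes are supported (`merging on|off`, default on). The
table-reproduction study runs with merging **off**, because the published
success rates — in particular the near-saturated 13-projection column —
are statistically consistent with pure Gaussian position noise and
inconsistent with deterministic two-pixel merging; with merging on, the
5-projection rates drop several points further (enlarged tolerances on
short test projections keep more fictitious candidates).

## Monte Carlo studies and problem sizes

* Robustness: the 4×4 grid (3–6 markers × 5/7/10/13 projections) at
  σ_peak = 0.08 mm is run at 10⁴ trials per cell, the package's
  desk-scale default (the original study used 10⁵–10⁶); full-scale runs
  are a configuration change. Success rates at 10⁴ trials carry a
  standard error of ≲ 0.5 points, comfortably inside the comparison
  bands. Trials are coupled across cells by common random numbers: marker
  placements are drawn point-sequentially (the first N markers coincide
  across marker counts) and peak noise is drawn once for the full
  13×6 direction-marker grid and sliced, so the monotone trends in the
  table are not masked by sampling noise.
* Accuracy: the same protocol on a (n_projections, σ_peak) grid,
  reporting max/mean/SD of per-marker errors after minimum-cost
  assignment to the truth (`scipy.optimize.linear_sum_assignment`).
* Targeting: the synthetic probe (six markers, all prefix subsets with
  distinct pairwise distances; needle tip ≈ 130 mm from the marker
  cluster) is rotated uniformly in the stated sagittal/coronal ranges,
  localized, labeled, rigidly fitted, and the tip error recorded;
  3 000 trials per marker count by default. The probe marker coordinates
  of the original instrument are not published, so absolute targeting
  errors are specific to this synthetic geometry; only the trend with
  marker count (and the zero-noise limit) is comparable.

All randomness descends from one integer seed through per-trial
`numpy.random.default_rng([seed, trial, stream])` generators: every study
is bit-reproducible and independent of execution order.

## Signal model

The excitation series uses the standard ideally spoiled recursion: an
instantaneous nutation by α_eff about a transverse axis, T2 decay to the
echo at TE, T1 recovery over TR, transverse magnetization zeroed by the
spoiler before the next pulse, on-resonance (magnitudes only, phase
irrelevant). The matrices of the general rotation–relaxation recursion
are not printed in the reference work; this recursion is the standard
reading consistent with it, and its fixed point is the closed-form
spoiled steady state M₀(1−E1)sin α/(1−E1 cos α)·e^(−TE/T2), which the
suite checks to 1e-9. The oscillating experimental echo trend attributed
to marker asymmetry is deliberately not modelled.

## Numerical choices and degenerate inputs

* Degeneracy floor |det| ≥ 1e-6 for a usable triple; intersecting a
  near-coplanar triple raises an error.
* Sub-pixel interpolation falls back to the maximum-sample position when
  any of the three amplitudes is non-positive or the log-denominator is
  below 1e-12 (flat top).
* A zero-variance background yields infinite SNR (noiseless fixtures pass
  any threshold) rather than an error.
* Surviving candidates closer than 1e-6 mm are deduplicated before the
  final count — the success contract compares distinct points.
* A test projection with zero peaks eliminates nothing and is counted in
  the diagnostics.
* Labeling raises an explicit error when pairwise distances (or
  permutation costs) tie within 1e-6 mm.
* R² uses the standard coefficient-of-determination denominator
  Σ(yᵢ−ȳ)².

## Known limitations

* The elimination soundness guarantee ("true markers survive") is
  conditional: the candidate inherits the reference triple's
  error amplification, so it holds when ‖A⁻¹‖·√3·|Δp| + |Δp| ≤ ε, not for
  arbitrary errors up to ε.
* No multi-frame track association or Kalman filtering; each frame is
  localized independently.
* No modelling of needle deflection, marker orientation to B₀, gradient
  waveform feasibility of the direction sets, or scanner timing;
  experimental quantities that depend on those are out of scope here.
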