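# Methods

## The measurement problem

Dislocations in beam-sensitive molecular crystals (pharmaceutical compounds,
waxes, acenes) cannot be characterised by conventional multi-exposure
diffraction-contrast TEM: the crystals fade after a few electrons per
square Angstrom. Scanning electron diffraction (SED, a low-dose flavour of
4D-STEM) records a full diffraction pattern at every probe position of a
single scan, so *every* reflection's dark-field image can be reconstructed
afterwards from one exposure.

In a gently bent thin crystal each reflection g produces a *bend contour* —
the bright band in its virtual dark-field (VDF) image where the local
curvature brings the (hkl) planes exactly to the Bragg condition. A
dislocation distorts the lattice around its line **u**; where a contour
crosses the line it is broken and displaced. The displacement, measured as
a distance *along* the line between the middles of the two contour
segments, varies with the azimuth phi of g as

    f(phi) = A * arctan(B * cos^2(phi - C))

with A an amplitude set by the effective curvature (nm), B a dimensionless
shape factor and C the azimuth of the projected Burgers vector **B**. The
displacement vanishes at `phi = C +/- 90` — the `g.B = 0` invisibility
criterion — and peaks at `phi = C`. Fitting |displacement| versus phi over
the recorded reflections therefore recovers the Burgers-vector direction
(mod 180 deg) without prior knowledge of the structure. Comparing C with
the line direction classifies the dislocation (B || u screw, B ⊥ u edge,
otherwise mixed); the twist sense of the contours whose g lies along u
gives the screw handedness (the Cherns–Preston construction); and matching
C to projected low-index lattice directions in the indexed zone identifies
the slip system [uvw](hkl).

## Pipeline and estimators

1. **Centering** — the direct beam is located in every pattern by
   cross-correlation with a soft disc template (sub-pixel via a parabolic
   fit of the correlation peak) and moved to the geometric detector centre
   by Fourier-shift interpolation; a user-supplied 2x2 affine matrix then
   corrects residual elliptical distortion. A correlation peak below 5
   standard deviations of the correlation map raises a centering failure
   naming the offending scan positions.
2. **Disc detection** — difference-of-Gaussians maxima (sigma pair tied to
   the diffraction-disc radius: 0.4x and 1.2x) refined by an iterated local
   centre of mass; discs found on a seeded random subsample of patterns
   (default 5%) are greedily clustered by position (tolerance 0.01 1/A in
   response rank order) into a scan-wide g-vector list; Friedel pairs are
   linked, azimuths reported after applying the scan–detector rotation.
3. **VDF construction** — integrated counts in a circular aperture (default
   radius 0.02 1/A, working range 0.016–0.026, below the 0.08 1/A disc
   diameter at 300 kV). A g-vector is usable for metrology when its VDF
   99th percentile exceeds 5x the median background.
4. **Contour metrology** — the centerline of each contour segment is traced
   by marching along the band orientation (structure tensor of the smoothed
   image) and re-centring every step on the perpendicular cut. The band is
   *located* on the smoothed profile with weights `max(profile -
   half_level, 0)` (continuous at the band edges, so no
   support-quantisation jitter); the centroid itself is then *refined on
   the raw counts* with an iterated symmetric Gaussian window (mean
   shift) — the smoothed field acquires a one-sided kernel bias near any
   mask or image boundary, the raw mean-shift estimate does not. Cuts whose
   band is clipped by the image border, the cut window or the dislocation
   line are rejected. When measuring a crossing, each side's trace is
   restricted to its side of the line (smoothing by normalized masked
   convolution so no intensity mixes across the line), a total-least-squares
   axis is fit to the 24 clean points nearest the junction (standoff
   0.25 x band width + one smoothing sigma), and the crossing is the
   intersection of that axis with the line polyline. Displacement = signed
   arclength between the two crossings along `positive_sense`; uncertainty
   combines the per-cut Poisson centroid error, the axis-direction error
   times the extrapolation lever — inflated by a correlated-cuts factor of
   3, since successive cuts share intensity through the detection smoothing
   and the linear part of a correlated drift is absorbed by the fitted
   axis, hence invisible in its residuals — and the 1/sin(chi)
   amplification of the crossing angle chi. Crossings shallower than
   15 deg are flagged unusable (the distance along the line is
   ill-conditioned), exactly the blind spot manual tracing has.
5. **Reorientation flagging** — a mid-scan stage/beam reorientation shifts
   the whole contour pattern by one rigid vector delta, seen by reflection
   g as an across-band shift `delta . g_hat`. For each pair of consecutive
   scan rows the per-VDF row-profile shift is measured by 1D
   cross-correlation and a single delta is fitted by least squares; a row
   is flagged when |delta| >= 1.5 px and >= 90% of the informative VDFs are
   consistent with it. (A literal per-VDF threshold count cannot work:
   contours with g perpendicular to delta see no shift; in the vector fit
   they are consistent evidence instead of missing votes.) Flagged rows act
   as barriers: centerline points separated from their line projection by a
   flagged row belong to the shifted regime and are excluded.
6. **Azimuthal fit** — weighted (1/sigma^2) nonlinear least squares of
   |displacement| versus phi with `A0 = max|d|, B0 = 1` and a multistart
   over `C0 = phi_at_max + {0, 45, 90, 135}` deg; confidence intervals by a
   seeded residual bootstrap (199 refits, percentile intervals, C handled
   as an axial quantity). A profile whose displacements are individually
   (<= 2 sigma each) or collectively (mean squared z <= 4) consistent with
   zero — or whose fitted lobe amplitude `A*arctan(B)` stays below 2x the
   median uncertainty — is reported as *no resolvable distortion* rather
   than fitted.  Two small-sample corrections keep the 95% intervals
   honest: bootstrap residuals are rescaled by sqrt(n/(n-3)) before
   resampling (residuals of a 3-parameter fit under-represent the noise
   variance), and the resulting quantile half-widths are inflated by
   t(n-3)/z with the phase interval symmetrized (C errors are symmetric;
   equal-tailed percentile intervals of an axial quantity under-cover).
   Without the corrections the nominal 95% interval covers only ~85%;
   with them, 92-94%.
7. **Assignment** — Burgers azimuth `C mod 180` (the 180 deg ambiguity is
   intrinsic); invisibility set = usable g within 10 deg of C+90 with
   |d| <= 2 sigma; character from the acute angle between C and u (screw
   and edge tolerances 15 deg); handedness from the contour twist at the
   line for the Friedel pair nearest u, using the chirality invariant
   `sign(displacement) x sign(t_near x t_far)` with branch directions
   oriented away from the line — mirror-odd, rotation-even and independent
   of which side is labelled near (both factors flip together). The
   right/left labels are anchored to the generator's twist convention, not
   to the original dynamical-contrast derivation. Crystal matching ranks
   coprime [uvw] (|index| <= 2) by projected-azimuth mismatch in the
   indexed zone (default tolerance 3 deg); the slip plane is the coprime
   integer cross product b x u when the line matches a low-index direction.

## Crystal geometry

All reciprocal arithmetic uses the direct metric tensor G and its inverse;
d = 1/sqrt(h G* h). The zone plane carries a single orthonormal 2D basis
(e1 along the lowest-index in-zone reciprocal vector, canonical sign) used
by both reflections and projected real directions, so detector azimuths and
crystal azimuths are commensurable after the in-plane rotation found by
indexing. The indexing assist scores candidate zones rotation-invariantly
by the fraction of observed g matched in magnitude (0.03 1/A) and azimuth
(4 deg); structure factors are deliberately ignored — kinematic intensities
are not needed for contour metrology, and extinct reflections simply fail
to match. Dislocation density is total projected line length / (area x
thickness), reported at both thickness bounds; the out-of-plane inclination
bound of a line of projected length L in a film of thickness t is
arctan(t/L).

## The synthetic scene

The generator renders the study conditions used by every closed-loop test:

| parameter | default | why |
|---|---|---|
| scan | 64 x 64 at 4 nm/px | desk-scale version of a 256 x 256 acquisition; keeps a full pipeline run near ten seconds |
| detector | 96 x 96 at 0.012 1/A/px | holds reflections to 0.38 1/A with 6.8 px discs |
| dose | current*dwell/e ≈ 6.24e3 e-/pattern | 1 pA x 1 ms counting dose (≈8.8 e-/A^2 per scan at 300 kV) |
| reflections | 10 azimuths over [0,180) + the Friedel partner nearest u | "8–12 reflections" working range; slots forced exactly at C and C+90 so the invisibility geometry is testable |
| contour width | 16 nm Gaussian sigma | 4 scan px, comparable to the planted displacements |
| per-reflection strength | 5% of dose at band centre | leaves >= 45% in the direct beam |
| dislocation | straight line through the field centre, azimuth 20 deg | avoids axis-aligned degeneracies |
| curvature anisotropy | contour orientation skewed uniformly +/-35 deg about the perpendicular to g | only pure spherical bending puts contours exactly perpendicular to g; generic slowly-varying curvature decorrelates the orientation — and makes which azimuths cross the line shallowly a seed-dependent draw instead of a fixed censored band |
| displacement law | A = 12 nm, B = 2.5, planted directly from f(phi) | max displacement 14.3 nm = 3.6 px |
| anchors | drawn on the central 38–62% of the line | contours crossing mid-field, as an experimenter selects |
| handedness twist | 10 deg for g within 20 deg of +/-u | |
| low-dose fixture | dose x 5/8.8 | the ~5 e-/A^2 fluence-equivalent case |
| reorientation fixture | rigid 3 px jump at row 54, azimuth 35 deg | placed away from the junction band like the reported mid-scan events |

Each reflection's deviation from the Bragg condition is a linear ramp
across the field, zero on a straight contour roughly perpendicular to the
scan-frame g direction (up to the per-reflection curvature skew) and
anchored at a seeded point on the dislocation line; intensity is Gaussian in the
deviation; the far side of the line carries the locus rigidly displaced by
f(phi) along u; counts are Poisson with the expected per-pattern total
equal to the dose exactly (the direct beam absorbs the residual).

The displacement law is planted *directly* rather than derived from an
elastic displacement field: the generator's purpose is closed-loop
validation of the measurement-and-fit chain, and an elasticity-based scene
(isotropic straight-dislocation tilt field) would be a stricter future
oracle, not a requirement. Likewise absent: dynamical diffraction,
thickness fringes, inelastic background, detector point spread, drift.
Passing the closed loop therefore demonstrates that the *metrology and
inference* are correct at realistic counting statistics — not that every
feature of experimental data is handled.

## What limits the azimuth recovery

At these desk-scale conditions a single crossing is measured to
~0.2–0.9 nm (1 sigma), and the three-parameter azimuthal model is locally
sloppy: A and B trade against C, so sigma_C of one profile is a few
degrees even with well-calibrated points. The median closed-loop recovery
error over seeds sits near 1.4 deg; individual seeds can still draw
several shallow crossings at once and land ~10 deg off — a heavy tail of
the geometry draw that the per-seed error lists report rather than hide.
More azimuths, finer scans or repeated anchors per azimuth sharpen C
accordingly.

## Numerical conventions and degenerate inputs

Arrays are `[row, col]`; points are (x, y) with y increasing down in
storage, and every reported azimuth uses the mathematical y-up frame
(degrees in [0, 360), axial quantities in [0, 180)). The "far" side of a
dislocation line follows the stored point order only, so flipping
`positive_sense` negates displacements without relabelling sides.
Annulus/aperture membership is by pixel-centre radius. Electron wavelengths
use CODATA constants at full precision; rounding is display-only. Ties in
DoG maxima resolve by response then raster order; the consolidation
clusters in response rank order with a fixed seed — all randomness in the
package flows from explicit integer seeds. Degenerate inputs raise typed
errors (`FormatError`, `DataError`, `CenteringError`, `TraceError`,
`GeometryError`, `FitRefusedError`, `EmptyProfileError`,
`NoResolvableDistortion`) rather than returning silently wrong numbers.
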