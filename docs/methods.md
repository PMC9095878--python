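# Methods

This note records the models, conventions and numerical choices behind
`poremorph`, in the order the pipeline runs. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic topograph model

A scene is a flat membrane at a reference level with membrane-inserted
oligomers on it. Each oligomer is a set of isotropic Gaussian bumps — one
per protomer — placed at angles 2πk/N on the crest circle; arcs are
contiguous index ranges of such a ring, and a slit is an arc plus its image
under a two-fold rotation, shifted so the terminal subunits face at one
crest spacing. Bumps are **max-combined**, not summed, so the crest height
equals the configured protrusion height exactly; with zero noise and zero
tip radius the global maximum of a render equals membrane level + height to
machine precision, which anchors all round-trip tests.

Open pores carve a lumen: a plateau at the configured floor (default
−3.0 nm, deliberately deeper than the 2.0 nm call threshold so
classification is exercised away from the boundary) that tapers to the
membrane over one subunit width, ending two widths inside the crest so bump
peaks are unaffected. The lumen is added *after* the bumps are max-combined
with the membrane; combining it earlier would clip the negative floor at 0.

Imaging artefacts are applied in physical order: tip convolution (grayscale
dilation with a spherical structuring element — the standard AFM forward
model; the recorded height is the apex of a sphere lowered until first
contact), then slow-axis drift as a pure y stretch (the one drift mode that
is quantitatively invertible), then per-pixel and per-scan-line Gaussian
noise. All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, so the noise streams are independent
and renders are bit-reproducible.

Generator defaults are the study conditions the analysis is validated
against: ring crest diameters Normal(26.3, 2.2²) nm, protrusion heights
3.4 nm for arcs and rings and 3.5 nm for slits (set exactly, height SD 0,
unless configured otherwise), stoichiometries tied to the diameter through
the default crest spacing π·26.3/30 ≈ 2.75 nm, pixel size 0.5 nm/px. The
protomer bump width (Gaussian σ, default 1.1 nm) is a free parameter
nowhere fixed by the measured quantities; it was chosen once so that ~30
bumps on a 26 nm crest remain individually resolvable at ≈2 nm lateral
resolution, and the stoichiometry-detection conditions are defined relative
to the crest modulation this width produces.

What the generator does **not** emulate: tip asymmetry and double-tip
artefacts, scan-line streaks and feedback ringing, bilayer elasticity and
deformation under load, protein flexibility, and spatially correlated
noise. Passing tests therefore demonstrate that the measurement chain
recovers known ground truth under idealised imaging physics — not that it
is robust to every artefact of a real instrument.

## Pseudo-monomer fixture

The coordinate fixture stands in for a pore-forming protomer: two
antiparallel pseudo-β strands along z (the hairpin), an ellipsoidal head
block above the membrane plane, and a short connector. Two constructions
make downstream angle tests exact rather than approximate:

* the head atom cloud is rotated into its own principal frame and rescaled
  to exact per-axis variances, and every off-axis contact atom comes with
  moment-balancing partner atoms, so the head covariance is exactly
  diagonal and its principal axes are exactly (z, x, y) in the untilted
  pose;
* only the CA trace carries the strand pleat, with opposite phase on the
  two strands at each height, cancelling the hairpin cross-covariances.

Consequently the untilted pose yields τ = 0°, χ = 90°, α = 0° to numerical
precision, and constructed head tilts/rolls are recovered exactly.

Chemistry is by atom naming: N atoms with an H in the same residue donate
hydrogen bonds, O atoms accept, NZ/NH\* are positive and OE\*/OD\* negative
charged groups. The donor edge of the hairpin faces +y (the ring tangent),
the acceptor edge −y, so two subunits placed one design spacing apart
(default 1.6 nm) form exactly one hydrogen bond per strand residue, plus
one head–head bond and one salt bridge — known counts for the interaction
tests. The design spacing is a property of this synthetic fixture, not an
estimate of the real protein's subunit spacing.

## Preprocessing

*Leveling.* Best-fit plane removal followed by pinning the membrane to
0 nm, where the membrane level is the mode of the height histogram
(0.05 nm bins, refined to the mean of the mode bin; an exact two-way tie
picks the lower mode with a warning). The plane is then re-fit on pixels
within ±0.5 nm of the mode so particles cannot tilt the baseline, and the
mode is recomputed. The operation is idempotent and exactly invariant to
added planes. It assumes the membrane occupies the plurality of pixels.

*Unwarping.* Drift is corrected by resampling the slow axis with a cubic
spline; `scale` is the stretch applied during correction, so a scene
stretched by drift factor s is corrected with scale = 1/s. When unknown,
the scale is estimated as the median over detected particles of
√(var_x/var_y) of their above-threshold pixels — exact for circular
particles under a pure y stretch. Estimates outside [0.5, 2.0] are
rejected as violations of the drift model.

*Calibration.* Ring diameters cluster by stoichiometry; the mean measured
diameter of the class matching an atomic model of known stoichiometry
fixes a global scale factor (model diameter / measured class mean). The
reference model diameter is configuration — by default the diameter of a
ring built by this package's own builder.

## Morphometry

*Maximum height.* Not the raw pixel maximum: the maximum of a noisy field
carries a positive extreme-value bias of roughly 2 noise SDs (≈0.3 nm at
the 0.15 nm study noise), which would dominate the 0.1 nm height-recovery
budget. Instead the apex is located on a strongly smoothed copy (σ = 2 px,
so the selected bump is nearly independent of the local noise), and the
height is refined by a log-quadratic fit to the raw 5×5 patch around that
point — exact for Gaussian crests, unbiased under pixel noise, with
fallbacks to the patch centre when the fit is not concave or its
stationary point leaves the patch.

*Crest diameter.* For rings, twice the peak radius of the azimuthally
averaged radial profile about the crest centroid, with parabolic sub-bin
refinement — robust to single-pixel noise. For arcs and slits, the maximal
separation of crest pixels (via the convex hull). Crest pixels are those
above 40% of the apex on the lightly smoothed image; the threshold sits
below the ~46% saddle between adjacent protomer bumps at the default
width, so the crest stays connected.

*Shape class.* Rings close ≥330° of angular coverage about the crest
centroid and are round (second-moment aspect ratio < 1.25); slits are
closed or nearly closed (≥300°) but elongated; anything with a larger
angular gap is an arc. An earlier rule that looked for two angular gaps at
the slit joints cannot fire on faithful renders — the two arcs of a slit
touch at exactly one crest spacing, the same spacing as any intra-arc
neighbour pair, so no gap exists — hence the elongation criterion.

*Pore call.* `pore` iff the deepest interior height ≤ −2.0 nm, threshold
inclusive; monotone in lumen depth by construction.

*Gaussian fits.* Default is the ML fit on raw values (sample mean/SD);
a histogram least-squares mode mirrors how distribution figures are
annotated. *Spacing conventions:* circumferential πD/N (default), chord
D·sin(π/N), and the literal ratio D/N kept for comparability with the
figure-caption wording even though it is not a geometric spacing.

*Tracking.* Greedy nearest-neighbour linking within a radius; a track is
mobile if it moves more than a threshold (default: its own mean crest
diameter — no quantitative criterion exists to inherit) or appears or
disappears mid-series.

## Stoichiometry detection

The crest annulus (half-width 1.5 nm about the crest radius) is unwrapped
onto a polar grid with angular sampling 4× the highest order searched
(default range N ∈ [14, 40], covering the observed 18–36 with margin),
radially averaged, and Fourier-transformed; power(k) is the squared
magnitude of the k-th angular coefficient.

Two numerical choices matter and were set by measurement on the generator:

* **Centre.** The particle centre is the crest centroid refined to the
  peak of the two-fold rotational autocorrelation (sub-pixel, parabolic).
  A centre error δ phase-modulates the order-N signal with index ≈ Nδ/R,
  smearing power into adjacent orders; the autocorrelation centre is
  accurate to ~0.01 nm under the study noise. An alternative refinement
  that minimises order-1 power was implemented and rejected: its minimum
  sits on the interpolation noise floor and wanders ~0.6 nm off-centre on
  noisy data. The image is also lightly smoothed (σ = 1 px) before polar
  operations.
* **Distinct-peak criterion.** A stoichiometry is reported only when the
  in-range peak exceeds the runner-up by ≥4× and the median in-range power
  by ≥50×. Calibrated on the generator before freezing the acceptance
  checks: featureless white-noise annuli exceed prominence 2.6 in <5% of
  cases (99th percentile of the median ratio ≈ 32), while genuine crest
  modulation at amplitude SNR 3 never fell below prominence ~60 (median
  ratio ~600), so both thresholds sit in a wide empty margin.

## Correlation averaging and symmetrization

Alignment searches a rotation grid (default 3°) with an FFT translation
search per rotation and parabolic sub-grid refinement; the correlation is
the Pearson coefficient of the transformed image against the reference.
Averaging iterates align → reject (< 0.9 by default) → average →
re-reference until membership and correlations stabilise; the initial
reference is the member with the highest mean pairwise correlation (the
iteration's fixed point does not depend on it, but a good start converges
in fewer cycles). Symmetrization averages the image over rotations by
k·360/N about the particle centre — located by the same two-fold
autocorrelation, since rotating about a point off-centre (even by the
half-pixel difference between array centre and particle centre) leaks
power into non-multiple orders.

Pseudo-topographs from coordinates assign each pixel the top of the
highest atom sphere above it (radius = atom radius + probe radius, default
0.2 nm + 0), clipped below at the membrane plane z = 0; frames average
pixel-wise.

## Oligomer builder

Rings place the monomer at radius R on +x (monomer frame: z = membrane
normal and hairpin axis, +x radial-outward, +y tangential) and copy it by
exact rotations, so N-fold symmetry holds to machine precision. The radius
is the grid argmin (with parabolic refinement) of a surrogate potential:
quadratic soft-core repulsion inside 0.25 nm between all atom pairs of
adjacent subunits, plus a Gaussian contact well (depth 1, centre 0.30 nm,
width 0.15 nm) across designated interface atoms — by default the hairpin
donor/acceptor edge atoms. Only nearest neighbours contribute, matching
the strictly adjacent inter-subunit bond topology of these oligomers. The
surrogate reproduces the *procedure* of radius selection (a clash/contact
trade-off with an interior minimum); its absolute energies are
dimensionless and its optimal radii are properties of the synthetic
fixture, not predictions for the real protein — a force-field minimisation
is out of scope. For a potential whose pair minimum is at neighbour
distance d\*, the optimum obeys R = d\*/(2 sin(π/N)) and the implementation
matches that closed form to <0.5% across N = 8..40.

Slits map the second arc by a two-fold rotation about the point that puts
both terminal-centroid pairs exactly at the requested gap; two copies of
one arc therefore have an exact two-fold axis. A monotone energy grid (no
interior minimum) and steric overlap of slit arcs are errors, not
warnings. PDB output is one chain per subunit (Å at the boundary, nm
internally); >62 subunits split into segmented files because the PDB
chain-id alphabet ends there.

## Structure metrics

Principal axes are covariance eigenvectors ordered by falling variance;
eigenvalue ties within 1e-9 (relative) are an error because the
orientation is undefined. Axes carry an intrinsic sign ambiguity; signs
are fixed against reference directions (P1 toward the membrane normal, P2
toward radial-outward, P3 = P1×P2). In `head_angles` the hairpin's
smallest axis PB3 is sign-fixed directly against the radial reference so
that the reference pose gives α = 0 with τ = 0 and χ = 90°. α is the
signed angle, about PB1, from PB3 projected into the plane ⊥ PB1 to PH2
projected into the same plane; it is well defined on (−180°, 180°] as long
as PH2 keeps a positive projection on its sign reference — beyond ±90°
from the reference the axis sign flips and α folds back, an unavoidable
consequence of axes being lines rather than vectors.

Hydrogen bonds use the trajectory-analysis convention: donor–acceptor
≤ 0.35 nm and H–donor–acceptor angle ≤ 30°, one count per (donor,
acceptor) pair, both donation directions between two regions. Donors
without hydrogens fall back to a distance-only criterion (hydrogen
idealised along D→A) and the report flags it. Salt bridges: opposite
charged groups with minimum heavy-atom distance ≤ 0.40 nm, one count per
residue pair. The domain partition (head/hairpin/connector residue sets)
is required configuration; the synthetic fixture ships its own. Cα RMSD
uses least-squares superposition (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) when `fit=True`.
Interaction reports emit both per-frame series and Q1/median/Q3/mean
summaries, because whether published per-subunit counts are means or
medians is generally unstated.

## Problem sizes and runtime

The validation suite and the acceptance script run on single-particle
scenes of 82–166 px at 0.5 nm/px: 150 rings for diameter recovery, 100
arcs for height recovery, a 19-point noiseless stoichiometry sweep plus
100 seeded particles at amplitude SNR 3 for each of N ∈ {22, 27, 30},
class averages of ~11 members, and oracle comparisons on ≤64×64 images.
These sizes give the statistical resolution the tolerances require (e.g.
SE of the diameter mean ≈ 0.18 nm at n = 150) while the whole suite runs
in well under a minute of compute.

## Known limitations

* The forward model is geometric; no cantilever dynamics, tip elasticity
  or force-dependent sample deformation.
* Shape classification is tuned to the generator's morphology; real
  topographs with clustered or fused oligomers would need a detection
  stage this package deliberately does not provide (ROIs come from ground
  truth or external seeding).
* Absolute interaction counts and optimal radii of the pseudo-monomer are
  fixture properties; reproducing published per-subunit bond counts would
  require the real force-field trajectories, which are out of scope.
* α inherits the principal-axis sign ambiguity described above.
* The drift model is a pure y stretch; shear or nonlinear drift is not
  correctable here.
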