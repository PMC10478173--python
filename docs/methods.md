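# Methods

This note documents the models, conventions and design choices behind
`myoscreen`, and what the synthetic studies do and do not establish.

## Conventions

Angles are degrees in [0, 180), measured from the +x (column) axis toward
+y (row); the contraction/nanofiber axis of an aligned culture maps to 90°.
Movies are (t, y, x); stacks are (c, z, y, x) with 0-based voxel indexing.
All outputs are in physical units (µm, µm², µm³, µm/s, kPa, nN). Every
generator is a pure function of its spec, including the seed: identical
spec + seed gives bit-identical output.

## Synthetic scenes

**Contraction movies.** A dense Gaussian speckle texture (default 40 specks
per 1000 px², σ = 1.2 px) stands in for the myofiber sheet; dense speckle
makes PIV accuracy limited by the algorithm rather than by texture
sparsity. The sheet moves by an analytic displacement field
`d(x, t) = A · s(t) · w(x) · u`, where `s(t)` is the activation waveform
(raised-cosine pulses at the stimulation onsets, or a sinusoid), `w(x)` a
smooth radial taper that pins the sheet at the well border (mimicking a
suspended, edge-anchored sheet and avoiding boundary artifacts), and `u` a
unit direction carrying a fraction `axis_anisotropy` of displacement energy
on the principal axis. Frames are rendered by backward warping with
bilinear interpolation, so the ground truth is exact at every pixel; the
frame-pair truth is the difference of consecutive per-frame fields and
telescopes exactly to the total drift. Additive Gaussian noise (σ = 0.01 of
an intensity range of ~1) is applied last. The default frame rate is
20 fps. The speckle texture is a stand-in: no claim is made about real
image appearance (no vignetting, photobleaching or field stitching).

**IF stacks.** Four channels on a 5-plane stack with 2 µm plane spacing and
0.65 µm in-plane pixels (a 20× high-content geometry). Myofibers are 3D
capsules (default 70 × 6 µm, realistic for 2-week hiPSC myotubes) with
axial von Mises orientations (double-angle construction, mean 90°,
κ = 8); capsules are rejection-sampled against a guard-widened occupancy
mask so that no two fibers touch after PSF blur — object counts are then
recoverable exactly, which is what makes count-recovery tests sharp.
Axons are persistent random-walk filaments; synaptic puncta are 1 µm
spheres. A chosen fraction of SV2 puncta is placed on an AChR partner
(same z plane, sub-radius jitter); the rest are kept at least six radii
from every AChR punctum so accidental overlaps cannot occur, and punctum
centres are snapped to the nearest z plane so a punctum smaller than the
plane spacing cannot fall between planes. Channels are blurred with a
Gaussian PSF (σ = 0.5 µm) and corrupted with Poisson noise (300 photons per
unit intensity over a 5-photon background) plus Gaussian read noise
(σ = 2). These are deliberately clean, well-separated scenes: passing the
exact-recovery tests shows the pipeline is correct, not that it is robust
to crowding, debris or staining variability.

## PIV

Time-resolved pairing (A+B, B+C, …) with multipass interrogation, default
windows 64/32/16 px at 50 % overlap. Each pass correlates zero-mean
windows by FFT; the zero-padded (linear) correlation is divided by the
per-lag overlap area — without this the triangular padding weight drags
wide correlation peaks toward zero lag and the estimator loses linearity in
the displacement. The integer argmax is searched within a third of the
window size; ties break deterministically toward the smaller displacement.
Subpixel refinement is a three-point Gaussian fit per axis with a parabolic
fallback when a log is undefined. Coarse-pass displacements, rounded to
integers, are interpolated onto the finer grid as predictors; a predictor
that would push a window outside the frame is clamped to the largest
feasible offset so edge vectors stay valid at large displacements (dropping
them would bias mean speeds upward in strongly contracting movies). Edge
windows that do not fit entirely inside the frame are dropped, not padded.
Window deformation is not implemented: at the sub-5 px/frame displacements
of these scenes plain multipass is sufficient.

Everything is computed in px/frame and converted to µm/s once, at field
construction. Vector validation is a single-pass n-SD filter (default 7)
applied per frame pair and per velocity component around the component mean
over valid vectors; whether such a filter should act on components or
magnitudes, and whether it iterates, is an open choice — both are
configurable and only the default documented here is asserted by tests.
Invalid vectors are excluded from all summaries, never interpolated.

Trace summaries per pair: mean speed, signed component means, and means of
|v_x| and |v_y|. The absolute-component means are what the force chain
consumes: on a recoiling sheet the two halves move in opposite directions
and signed means would cancel. Their noise floor does not average to zero,
so an axis-pure movie shows a small but nonzero orthogonal channel. Peak
detection uses prominence on the mean-speed trace, with the trace padded by
its own minimum so boundary maxima are detectable without acquiring
infinite prominence. Note that one displacement pulse produces two velocity
peaks (contraction and recoil).

## Force estimation

At the frame pair of peak mean speed, per axis: `d = v·t`, `ε = d/L`,
`σ = ε·E` (E = 30.5 kPa, a literature average modulus for cultured skeletal
muscle), `F_x = σ_x·A_yz`, `F_y = σ_y·A_xz`. Unit bookkeeping:
1 kPa·µm² = 1 nN exactly, so forces are reported in nN. Specific force in
kN m⁻² equals the stress in kPa by definition. Two quantities are assay
conventions rather than measurements and are therefore explicit,
configurable parameters: the gauge length L (default: the physical length
of the finest interrogation window, 16 px × pixel size — the displacement
gradient scale of the PIV grid) and the cross-sectional areas (default:
field-of-view extent × a nominal 30 µm sheet thickness). Absolute force
values depend on these conventions; only relative contrasts between
conditions are supported claims.

## Directionality

The image is Hann-windowed (suppressing the edge-discontinuity spectral
cross that masquerades as 0°/90° structure) and Fourier transformed;
spectral power concentrates perpendicular to elongated structures, so each
non-DC frequency sample votes for the orientation (frequency angle + 90°)
mod 180°. Samples are restricted to the inscribed frequency disk and
soft-assigned to 2° bins with linear interpolation, and each bin is
normalized by its sample occupancy — the square grid and the Hermitian-
redundant zero-frequency column otherwise populate bins unevenly and bias
isotropic images toward the axes. The histogram is therefore spectral
energy density per orientation, a proxy for (not a count of) structures per
direction. The dominant angle is the period-180 circular weighted mean
within ±10° of the maximum bin (ties break to the lower angle); the
alignment index is the energy fraction within ±10° of that angle, so a
uniform histogram scores ≈ 0.12.

## 3D quantification

Per channel: Gaussian smoothing (0.4 µm), thresholding (Otsu by default,
fixed-value override — thresholds are explicit configuration because in
high-content practice they are tuned per experiment), 26-connected 3D
labelling, optional watershed splitting seeded at distance-transform maxima
deeper than a configurable depth. Otsu assumes a bimodal histogram and
splits pure background in half on a signal-free stack, so the threshold is
floored at median + 5 robust SDs (MAD-based). Objects are measured in
physical units; sphericity is `π^(1/3)·(6V)^(2/3) / A` with the surface
area from a marching-cubes mesh in physical coordinates (voxel-count
surrogates are badly biased at 5 × 2 µm anisotropy), with an ellipsoid
fallback for objects too small to mesh.

NMJ objects are derived from the voxelwise SV2 ∩ AChR intersection of the
filtered masks, evaluated per (pre object, post object) pair with a minimum
overlap (default 1 voxel). The pairs form a bipartite overlap graph and the
NMJ set is a maximum matching of it: each pre object pairs with at most one
post object and vice versa. This was chosen over raw connected components
of the intersection because interlocking objects can intersect in more
pieces than either channel has objects, which would break the invariant
`nmj_count ≤ min(SV2 count, AChR count)`; the matching definition
guarantees it for any input and coincides with component counting on
blob-like objects. NMJ size is the matched pair's intersection volume
(the only size computable from the colocalization definition alone; the
union volume is available via the object tables).

Axon outgrowth has no single operational definition, so two are reported
side by side: the z-projected mask area (µm², the default comparison
metric) and the skeleton length of the projection (µm), computed by summing
physical distances over 8-adjacent skeleton pixel pairs.

## Plate statistics

One row per well; a failing well is flagged and never aborts the plate, and
wells with missing metrics are excluded listwise per metric. The two-group
test is Mann–Whitney U (the conventional reading of an "unpaired
non-parametric" comparison; Welch's t is a config switch). Dose–response
uses parametric Dunnett many-to-one comparisons against the shared control
(p-values family-adjusted by construction; the numerical integration is run
with a fixed rng so plate outputs are bit-reproducible), plus a trend flag:
whether group means are monotone in dose, anchored at the control. Group
summaries are mean ± SEM. Significance stars (<0.05, <0.01, <0.001,
<0.0001) appear in report output only and are never used in logic. The
well, not the field, is the statistical unit.

## Study sizes

The replicated statistical studies (effect-size power, type-I error,
dose–response recovery) run on reduced geometry — 64×64 px, 10-frame movies
analysed with 32/16 px windows — chosen so each study draws thousands of
fresh movies through the full PIV path while remaining comfortably
desk-scale. Within-group variation in these studies comes from texture and
noise seeds only; group separations are generator amplitude ratios. The
acceptance script reports each quantity with the problem size used.

## Known limitations

No window deformation or ensemble correlation; no GPU path; no field
stitching, flatfield correction or machine-learned segmentation; no
constitutive model beyond linear elasticity; synthetic scenes do not
emulate myofiber collapse, debris, or non-specific staining.
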