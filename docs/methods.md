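# Methods

`detrack` simulates and evaluates real-time markerless lung-tumor
monitoring with a room-mounted stereoscopic kV imaging system, including
dual-energy (DE) bone suppression and monoscopic 3D estimation during the
periods when the rotating linac gantry blocks one imaging view. Everything
runs against a synthetic digital thorax, so the full chain is testable
without measured data. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Imaging geometry

Two fixed source/flat-panel assemblies view the treatment isocenter: source
to isocenter 3435 mm, isocenter to detector 2185 mm (magnification 1.636),
512 x 512 panels at 0.4 mm pitch. The source directions sit at polar angle
48 degrees from the vertical with azimuths of +/-45 degrees; sources are
below the couch (posterior-inferior), panels opposite. Room coordinates are
right-handed with origin at the isocenter and axes (LR, AP, SI); all errors
are reported per axis in this frame. Pixel (0, 0) is centered at a panel
corner and the detector center falls at ((rows-1)/2, (cols-1)/2);
continuous pixel coordinates are used throughout.

The nominal panel parameters imply a field of view at the isocenter of
20.48 cm / 1.636 = 12.5 cm; the implementation always derives the FOV from
panel size and magnification rather than treating it as an independent
parameter.

Stereoscopic 3D localization uses the midpoint of the common perpendicular
between the two back-projected rays; half the length of that segment is
kept as a triangulation-quality residual. Rays with a direction
cross-product norm below 1e-9 are rejected as parallel.

## Digital thorax and tumor models

The phantom stands in for an anthropomorphic chest phantom resting on a
flat resin plate, with the tumor model aligned to the room lasers (so the
tumor reference position *is* the isocenter). Its torso is therefore a
flat-walled slab (170 x 105 mm half-widths, offset 55 mm laterally so the
tumor-side lung surrounds the isocenter): under the oblique beams a slab
gives a spatially uniform background thickness, which is what the real
tumor-centered field of view sees; an elliptical torso at this FOV scale
would add strong wedge gradients near the image borders that the physical
images do not contain. Inside the slab sit two elliptical-cylinder lungs
(HU -740), a posterior-midline spine modeled as a stack of vertebral-body
cylinders (radius 16 mm, 20 mm bodies separated by 4 mm soft discs), and
rib plates (8 mm deep, 8 mm wide bands with a 22 mm SI period) just inside
the anterior and posterior walls, overlying the lung periphery as the bony
cage does in a radiograph. The default grid is 2 x 2 x 2.5 mm (the SI
spacing matching a typical lung CT protocol slice thickness), 340 x 230 x
300 mm. The geometry is arranged — and verified by ray tracing in the test
suite — so that the Tube-A line of sight to the tumor crosses ribs and the
Tube-B line of sight crosses the spine.

Tumor models are asymmetric connected blobs: a random ellipsoid (semi-axis
ratios 0.7-1.0) perturbed by a few smooth angular lobes, scaled so the
maximum axis-aligned caliper extent equals the requested diameter (1.0,
2.0, 2.6, 3.3 cm by default), with per-voxel HU drawn from N(mean, sd)
clipped to [-1000, 3000]. The printed-density conditions are 140+/-35,
-212+/-246 and -434+/-277 HU. Tumors live on their own 1 mm grid; the
acquisition simulator projects them at their continuous per-frame pose, so
tumor motion is not quantized to the thorax grid. `place_tumor` (used to
build the planning CT for template generation) instead stamps the tumor by
nearest-voxel resampling with the displacement quantized to whole voxels,
which keeps the stamped voxel count identical for every in-lung placement.

## Breathing trajectories

The SI waveform is `-A cos^4(pi t / T)`: it dwells near end-exhale and dips
to -A at peak inhale, with period T = 4 s by default. AP and LR are exactly
proportional scaled copies — the rigid phantom-arm coupling (a pitched and
yawed arm produces proportional AP/LR motion). Default peak-to-peak
amplitudes are (5, 5, 20) mm (LR, AP, SI). Optional per-cycle amplitude and
period jitter (fractional sd, default 0.05 in the evaluation harness) and a
linear SI baseline drift (default 0) are available. Each axis is rescaled
so the realized sampled peak-to-peak equals the configured amplitude
exactly, making the amplitude contract independent of jitter and sampling
phase. Acquisitions are 100 frames at 1.67 Hz (about 60 s). An external
trajectory can replace the generator via a CSV with columns `time_s,
LR_mm, AP_mm, SI_mm`.

## Projection physics

Per-material path lengths are accumulated with exact Siddon voxel
traversal, vectorized over rays (all grid-plane crossing parameters are
clipped to the ray's bounding-box interval, sorted, and segment midpoints
mapped to voxels). Each polyenergetic kVp setting is reduced to one
effective monoenergy: 60 kVp -> 40 keV (LE), 120 kVp -> 60 keV (SE),
140 kVp -> 70 keV (HE). The built-in attenuation table uses water-scaled
coefficients for lung (0.26 g/cc) and soft tissue, and models rib and
spine as soft tissue plus a mineral fraction of cortical bone (0.20 and
0.25 of the cortical excess respectively) — vertebral bodies and ribs are
mostly marrow and trabecular bone, far below cortical density, and a
single mineral component means one weighting factor cancels both bone
types in the log subtraction. Tumor voxels attenuate as soft tissue scaled
by (1 + HU/1000), so the printed-density sweep changes projection contrast
within the simplified physics.

Expected counts are `I0_per_mAs * mAs * exp(-sum_m mu_m L_m)`, with
detector counts drawn Poisson (an ideal photon-counting panel: no blur,
scatter, lag or beam hardening). The gain default `I0_per_mAs = 4200` was
calibrated once so the median lung-region SNR at the nominal single-energy
technique (120 kVp, 16 mAs) is about 50, and then frozen. Nominal
techniques are HE 8 mAs / LE 25 mAs (DE) and SE 16 mAs; the mAs sweep
halves and doubles these. DE frames are generated with HE and LE at
identical trajectory phases (the idealization of two separate but
identical breathing cycles); a phase-offset parameter exists to study
HE/LE misregistration but defaults to zero.

The static thorax is traced once per view and cached; only the tumor's
detector-footprint window is re-traced per frame, which is what makes
100-frame series cheap.

## Dual-energy image formation

Soft-tissue and bone images are weighted log subtractions,

    log I_DEST = log I_HE - ws log I_LE
    log I_DEB  = -log I_HE + wb log I_LE

with intensities floored at one count before the log (Poisson zeros occur
at low mAs). Anti-correlated noise reduction adds a Gaussian-high-pass
filtered bone image: `log I_DE,ACNR = log I_DEST + wn * (log I_DEB *
h_HPF)` with wn = 0.9 and a 0.2 cycles/pixel lower cutoff, interpreted as
the half-power point (`H(f) = 1 - exp(-f^2/(2 sigma_f^2))`, H(cutoff) =
0.5, exact zero at DC, symmetric boundary padding). The quantum noise of
the soft and bone images is anti-correlated by construction, so the sum
cancels high-frequency noise while the high-pass keeps the bone image's
low-frequency anatomy out.

With raw intensities the bone-cancelling weight is `ws* = mu_mineral(HE) /
mu_mineral(LE)` (about 0.33 with the default table), below one. Published
weighting-factor ranges above one correspond to the swapped subtraction
order (`log I_LE - ws log I_HE`); a `swap_order` switch exposes that
convention, and the package's tests assert exact cancellation under its
own default convention.

`ws` is selected per frame by minimizing the bone contrast-to-noise ratio
`|mean(bone ROI) - mean(soft ROI)| / sd(soft ROI)` over a grid (default
0.2-2.5 in steps of 0.02, ties toward the smaller value). The quality of
this search depends entirely on the ROI pair: the two windows must differ
by bone and by nothing else. The automated ROI chooser therefore picks, on
the noiseless per-material path images of the static thorax (the
simulator's stand-in for a physicist outlining regions), a high-bone
window near the tumor projection and a bone-free window whose
water-equivalent background — soft path + 0.26 x lung path + bone path,
the last counted as the soft tissue it displaces — matches the bone
window's. `wb` is selected symmetrically by minimizing the bone image's
standard deviation inside a soft-structure window (one that contains a
real lung/soft boundary, picked as the bone-free window with maximal
background variance; a uniform window would let quantum noise drive the
search toward zero, which erases soft-tissue structure from the ACNR
image). Both searches run on ROI statistics only, so per-frame selection
costs microseconds. Spine-obstructed view B uses the same automated
machinery as view A.

## Template matching

Templates are noiseless attenuation-line-integral DRRs of the tumor-only
volume (planning CT thresholded halfway between lung HU and the tumor's
mean HU, largest 6-connected component, everything else set to air),
cropped to the footprint with a two-pixel margin; the intensity
center-of-mass offset from the correlation anchor pixel is stored so a
correlation peak maps back to the tumor center on the panel. Matching
maximizes the normalized cross-correlation over all placements, computed
with FFT local sums and checked in the tests against a brute-force
double-loop evaluation (1e-10) and skimage's `match_template`. The search
image is zero-padded by half the template size so the map keeps the image
size; zero-variance windows get correlation 0; ties break toward the
smallest row then column and are flagged. Matching operates on
attenuation-polarity images (`-log` counts for SE, negated log-domain DE
images) so template and image share contrast polarity. Localization is the
integer-pixel global maximum; one static template per (tumor, view) built
at the reference pose (rigid-motion assumption). A 3x3 parabolic sub-pixel
refinement exists but is off by default.

## 3D localization and the motion PDF

A linear gantry sweep from -180 to +10 degrees is mapped to per-frame
modes: STEREO when neither tube is blocked, MONO_A/MONO_B when the gantry
blocks Tube B/Tube A. The default blocking sectors ([-150, -95] for Tube
B, [-60, -5] for Tube A) give the qualitative alternation of stereoscopic
and monoscopic periods of an ipsilateral VMAT arc; they are configuration,
not physics.

STEREO frames triangulate the two matched rays. MONO frames cast the
single measurement ray and return the point on it maximizing a 3D Gaussian
motion PDF: for ray `x(t) = p + t d` and PDF N(mu, S), `t* = d'S^-1(mu-p)
/ (d'S^-1 d)` — the closed form is verified against dense grid search. The
PDF is fitted online from all stereoscopic estimates accumulated in the
session (sample mean/covariance, eigenvalues floored at 0.01 mm^2 so the
phantom's near-line motion stays invertible); before a minimum of 5
stereoscopic samples exist, a prior fitted from the planning trajectory is
used and the record is flagged. Online fitting was chosen because the
default arc begins with a stereoscopic period; a pre-fitted PDF can be
supplied instead.

A frame is a success when the 3D error is strictly below 3 mm; signed
per-axis errors (accuracy = mean, precision = sd) are recorded against the
continuous ground-truth trajectory, not the voxelized stamp.

## Evaluation harness and problem sizes

The experiment matrix crosses tumor size (1.0/2.0/2.6/3.3 cm), density
(140/-212/-434 HU at 2.6 cm) and mAs (half/nominal/double at 2.6 cm) with
both techniques over the full arc schedule. The harness runs each
condition with five seed replicates — seeds vary the breathing jitter and
the quantum noise; DE and SE replicates share the trajectory (the
separate-but-identical-cycles acquisition) with independent noise — and
reports success rate (mean +/- sd across seeds), per-axis accuracy and
precision, and mean absolute SI error, per region (STEREO/MONO_A/MONO_B)
and overall.

The harness samples the same 20.48 cm panel at 128 x 128 (1.6 mm pixels)
rather than 512 x 512. This keeps a full sweep in minutes on one CPU and
leaves the physics unchanged (the FOV, magnification and noise per unit
area are identical); its cost is coarser spatial quantization of the 2D
match, about 1 mm at the isocenter, which is visible in the precision but
comfortably inside the 3 mm success criterion.

## What the synthetic data does and does not show

The generator reproduces the features the method exploits: bone
obstructing the tumor differently in the two views, energy-dependent
bone/soft contrast enabling DE cancellation, quantum-limited noise scaling
with mAs, rigid coupled 3-axis breathing motion, and the
stereoscopic/monoscopic alternation of an arc delivery. It does not
reproduce scatter, beam hardening, detector blur or lag, deformable or
hysteretic tumor motion, cardiac motion, lung texture (vessels, airways),
or the specific ground-truth breathing recording used with a physical
motion stage; success rates measured here characterize the algorithm chain
under the stated phantom conditions, not clinical performance. The
discrete-voxel phantom also makes bone edges artificially clean, which if
anything flatters both techniques equally.

## Numerical choices and degenerate inputs

Intensities are floored at 1 count before logs; NCC windows with zero
variance return 0; weighting-factor ties resolve to the smaller grid
value; a flat CNR profile (no bone in the ROI) resolves to the grid
minimum; covariance eigenvalues are floored at 0.01 mm^2; near-parallel
rays and both-views-blocked schedules raise errors rather than guessing.
Every stochastic component (tumor shape, HU texture, breathing jitter,
quantum noise, replicate seeds) is driven by explicit integer seeds, and
sweep reports are bitwise reproducible under a fixed master seed.
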