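# Methods

This note records the modelling choices, defaults and limitations of the
package, in the order data flows through the pipeline.

## Synthetic phantoms

The generator (`pddc.phantom`) produces 3D multi-contrast brain-like
volumes: a smooth head ellipsoid with internal random ellipsoids of mild
intensity contrast (lightly Gaussian-smoothed so the background is
piecewise-smooth and spectrally compressible), plus three implanted object
classes recorded in a ground-truth table:

* **Microbleeds** — spheres of 1.5–6.5 mm diameter (specs outside the band
  are rejected, matching the detector's definition), attenuating the
  magnitude by the contrast factor and carrying a constant negative phase
  offset.  A full dipole-field simulation is deliberately not attempted:
  the constant negative offset is sufficient to exercise the negative-phase
  mask, which is all the downstream chain requires.
* **Veins** — tubes along polylines with the same magnitude/phase treatment.
  The rasterization radius is floored at the voxel half-diagonal so a
  sub-voxel vein stays voxel-connected along its course, emulating partial-
  volume darkening; without this floor a thin vein renders as a chain of
  disconnected blobs that are indistinguishable from microbleeds by any
  detector.
* **Lacunes** — cavities < 15 mm, hypointense on the T1-like and
  hyperintense on the T2-like volume.

Geometry is in mm, origin at the volume corner, voxel `i` at `i·spacing`.
Complex Gaussian noise (σ = 0.01 against a tissue magnitude of ≈ 0.8) is
the only degradation model; motion, bias fields and coil profiles are out
of scope.  Identical spec + seed reproduces volumes bit-identically.

Default grids are 64×64×32 at 2 mm isotropic — small enough that the full
detection benchmark (20 subjects) runs in seconds while every lesion spans
at least ~2 voxels.

**Cohorts.**  The two-group generator draws per-subject lacune counts from
a Poisson, or a negative binomial when a per-group SD implying
overdispersion is configured (the default case/control means 2.400/0.672
with SDs 3.358/1.252 are overdispersed, so the negative binomial is used);
CMB positivity is Bernoulli (defaults 14/30 and 4/30) with zero-truncated
Poisson counts given positivity; dominance and curvature abnormality are
Bernoulli per group.  Only count/flag distributions are modelled — the
cohort table is the statistical layer's input, and full volumes are only
built on request.

## Fourier and sampling conventions

All transforms are centered and orthonormal (`norm="ortho"`), so Parseval
holds exactly and the data-consistency algebra is unitary.  Masks
undersample one phase-encode axis (Cartesian): a fully sampled central band
(default 8% of lines) plus variable-density random lines drawn without
replacement under a quadratically decaying profile, so the kept fraction is
exactly `round(n/acceleration)/n`.  Data consistency defaults to hard
replacement of measured samples; a soft mode `(k_pred + λ·k_meas)/(1 + λ)`
is available.

## The reconstruction cascade

Five stages; stages 1–4 structurally identical, stage 5 adds an output-head
convolution (its fusion module is "slightly different") before one terminal
data-consistency application.  Per stage and domain, the feature extractor
is a stack of same-padded 3×3 convolutions with ReLU (default 5 layers × 32
channels; the telescoping/gradient analysis is independent of depth), the
last layer linear with 2 output channels (real/imaginary).  Cross-fusion
concatenates the native residual estimate with the transformed other-domain
output and applies a 1×1 convolution.  The k-space branch re-imposes
measurements immediately after its extractor and again after fusion, so
sampled locations are exact after every stage.

Fusion and head weights initialize at zero: the untrained cascade is then
exactly the zero-filled reconstruction, and training can only improve on
the baseline.  An `identity_fusion` switch bypasses fusion and head,
exposing the pure residual telescoping `a_M = a_1 + Σ K(a_m, c_m)` for
diagnostics and tests.

The network runs on a small reverse-mode automatic-differentiation core
over numpy (`pddc.autodiff`): conv2d via im2col, ReLU, concatenation,
centered orthonormal FFT pairs whose backward pass is the adjoint
(= inverse) transform, and an MSE loss, optimized with Adam.  Gradient
correctness is verified against central differences in the test suite.

**Training experiment sizes.**  The package's desk-scale experiment trains
a 5-stage model with 3-layer × 8-channel extractors on 24 phantom slices of
64×64 at 4× acceleration for 30 epochs (180 Adam steps, lr 1e-3, MSE on the
complex image), then evaluates PSNR/SSIM on 16 held-out slices from unseen
phantoms under the same sampling mask — the mask is treated as part of the
acquisition protocol, as in clinical deployments of learned reconstruction,
so train and test share it while phantoms are disjoint.  This configuration
trains in about a minute on one CPU and beats zero-filling by well over
2 dB mean PSNR.

## SWI processing

Homodyne high-pass correction: per axial slice, the complex image is
divided by its low-pass version computed from a Hann-apodized central
k-space window (32×32 or 64×64; other sizes warn).  Hann apodization
suppresses the ringing a hard window would introduce; the homodyne
(complex-division) reading is used rather than filtering the phase image
directly, because it is the standard operational form and is wrap-safe.
The phase mask is the negative-phase convention, `w = (π + φ)/π` on
`[−π, 0)` and 1 elsewhere, raised to `m = 4` (the field-standard number of
mask multiplications).  "Minimum density reconstruction" is implemented as
minimum-intensity projection, default slab 8 slices.

## Lesion detection

Detection is confined to an eroded head mask (threshold at 25% of the
99.5th percentile, closed, hole-filled — dark cavities are inside the head
— then eroded by the background-kernel radius): outside the head there is
only noise and at the boundary the local-background estimate breaks down.

CMBs: robust z-score of the SWI volume against a 10 mm median-filtered
background; the noise scale is a MAD estimate floored at 8% of the tissue
median so ordinary texture never registers as lesion contrast.  Voxels
below z = −3 are grouped by 26-connectivity; equivalent diameter is that of
the equal-volume sphere; components are microbleeds when the diameter is in
1.5–6.5 mm and elongation (max bounding-box extent / equivalent diameter)
is ≤ 3.  Vessel exclusion implements course tracing two ways: an elongated
component is excluded directly, and a compact component whose connected
component *at half the threshold* is elongated (the vessel's dark track
reconnects at the laxer threshold) is excluded as well.  Calcification
exclusion by bilateral symmetry is reduced to an off-by-default flag — the
phantom does not model calcifications.

Lacunes: joint criterion (T1-hypo and T2-hyper at |z| = 3) against the
*global* foreground tissue median, because lacunes can exceed any local
background kernel; kept below 15 mm equivalent diameter.

On 20 seeded default phantoms the detector reaches ≥ 90% microbleed recall
(≥ 3 mm lesions) with ≤ 1 false positive per subject.  This shows the
criteria are implemented coherently, not that the detector would reach this
performance on scanner data: the phantoms have no susceptibility artifacts,
no calcifications, no cortical vessels, and idealized lesion contrast.

## Vertebrobasilar morphometry

Diameters: vessel width sampled at arc positions 0, 3, 6 mm from the
confluence and averaged.  Dominance at ≥ 0.3 mm difference; grading bands
partition [0.04, 2.67] mm with half-open midpoint boundaries
(I = [0.04, 0.705), II = [0.705, 1.175), III = [1.175, 2.67]) so the
printed band edges 0.70/0.71 and 1.17/1.18 resolve without gaps.  Grading
and dominance are deliberately decoupled: differences in [0.04, 0.3) are
graded but not dominant, because the two stated thresholds conflict.

BL is read as the *maximum* perpendicular distance of the centerline from
the endpoint chord (the "most bending point" is a single point, so the
extremal reading is the only self-consistent one); on a circular arc this
equals the sagitta `R − √(R² − c²/4)` exactly, which the tests verify.
Curvature typing uses the signed lateral deviation (positive toward the
subject's left, radiological convention): one-sided excursion beyond the
threshold (default 2 mm, configurable — no clinical value is established)
is C (left) or reverse-C (right), two-sided is S, below threshold is
normal.

## Statistics

Welch is the default t-test variant (the group SDs this layer is designed
for differ several-fold; Student is available by flag).  Chi-square is
uncorrected by default with an automatic fallback to Fisher's exact method
when any expected cell is below 5.  Rank-sum uses exact enumeration for
n ≤ 10 per group without ties, the normal approximation otherwise.
Percentages print as round-half-up integers.  Decisions are `p < α` with
α = 0.05 and no multiple-testing correction, matching the reporting style
the layer reproduces; the report footer says so.  Degenerate tables (a
zero margin, e.g. no positive subject in either group of a small cohort)
report p = 1 rather than failing.  Under 2000 null simulations at n = 30
per group, each test's type-I error stays within [0.03, 0.07].

## Pipeline

One global seed fans out to per-stage seeds as the low 31 bits of
SHA-256 over `"{seed}:{stage-offset}"`, so stages are independently
reproducible.  Volumes are NIfTI (uncompressed, for checksum stability),
tables CSV, k-space HDF5, config/manifest JSON; the manifest records the
config hash and per-artifact SHA-256 checksums, and a timestamp-free
variant supports bitwise reproducibility checks.

## Known limitations

* Phantoms are geometric, not anatomical; no atlas, no dipole physics, no
  multi-coil model (acquisitions are treated as coil-combined).
* The reconstruction experiment is desk-scale by design; no hyperparameter
  search, GPU training or transfer to scanner data.
* Lesion detection has no anatomical-region labelling and does not
  distinguish Virchow–Robin spaces beyond the size rule.
* Vessel centerlines are inputs (from the generator or external tools);
  segmentation from angiographic images is out of scope.
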