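# Methods

## Forward model (simulator)

The simulator produces 2-D retina-section phantoms and, per emission
channel, per-pixel TCSPC photon histograms over one laser period.

**Phantom geometry.** A straight stack of tissue bands from the image
bottom up: sclera, choroid, RPE, photoreceptor outer segments (OS), inner
segments (IS), outer nuclear layer (ONL), outer plexiform (OPL), inner
nuclear (INL), inner plexiform (IPL), ganglion cell (GCL), and retinal
nerve fiber layer (RNFL), with vitreous background above. Default band
thicknesses (40/25/8/25/20/50/12/30/40/16/10 µm) are mouse-retina scale.
One-pixel hemoglobin bands sit at the basal and apical edges of the RPE.
Three vascular plexuses are stamped as circular lumina: deep capillaries
(r ≈ 3 µm) in the OPL, superficial capillaries (r ≈ 2.5 µm) at the
INL/IPL junction, and larger vessels (r ≈ 5 µm) in the GCL, at seeded
jittered spacings (default 60 µm for the deep plexus). An optic-disc
column (default 40 µm wide, at the image center) interrupts the retinal
layers; its inner-margin center is the eccentricity origin. Pixel (0, 0)
is top-left, x rightward, y downward, distances in µm.

**Decay model.** Each emitting species is a sum of exponentials. The
noiseless decay is the fractional-intensity-weighted sum of wrapped
(periodic) exponentials circularly convolved with a wrapped Gaussian IRF,
integrated into time bins (computed on an 8× oversampled grid via FFT),
scaled to the photon budget, and Poisson-sampled. Periodic convolution
matches first-harmonic phasor theory exactly: the measured phasor is the
product of the IRF phasor and the decay phasor, which is what reference
calibration removes. Second-harmonic species emit the binned IRF pulse
itself (no decay). A noiseless mode (`poisson=False`) returns float
expectation counts and is used wherever a test needs the continuum limit.

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| repetition period | 12.5 ns | 80 MHz, standard for tunable IR multiphoton sources |
| time bins | 256 | typical TCSPC histogram depth; configurable |
| IRF | Gaussian, FWHM 0.15 ns, center 1.0 ns | typical hybrid-detector multiphoton response |
| NAD(P)H lifetimes | free 0.4 ns, bound 3.2 ns | free value is the standard anchor; the bound lifetime is not a universal constant (the analysis extrapolates it per ROI), 3.2 ns is a representative protein-bound value |
| FAD lifetimes | free 2.6 ns, bound 0.3 ns | bound flavin is the short-lived form |
| melanin | bi-exponential 0.1/1.0 ns, equal fractions | short-lifetime pigment signature, distinct phasor position |
| hemoglobin | 0.05 ns mono-exponential | very short signature distinct from melanin and from the zero-lifetime point |
| ground-truth bound % | outer 58.9, inner 60.9 | the study conditions the recovery tests target |
| FAD ground truth | free 75.3 % (outer), 65 % (inner) | representative free-FAD levels for the two regions; the outer/inner assignment is a simulator choice |
| photon budget, image size | config-level | free parameters of any acquisition; defaults chosen so the full pipeline runs in seconds–minutes on one CPU |

Channels (NAD(P)H 425–475 nm, FAD 502–577 nm, hemoglobin/melanin
600–650 nm, SHG 411–463 nm) are modelled without spectral bleed-through;
optical PSF, detector dead time and afterpulsing are out of scope.

## Phasor transform and calibration

The transform uses bin-center times and the angular frequency inferred
from the cube's time axis; zero-intensity pixels carry an invalid flag
rather than NaN. Calibration computes the complex factor mapping a
uniform reference cube's photon-weighted mean phasor onto the closed-form
position of its known lifetime, and applies it to every pixel. Finite
time bins introduce an O((ωΔt)²) deviation from the continuous closed
form (≈2×10⁻⁵ at 256 bins, first harmonic); continuum-limit checks
therefore use finely sampled decays (≥2048 bins), where the residual is
below 10⁻⁶. The spatial median filter on (g, s) is available but off by
default.

## Metabolic trajectory

The trajectory chord is found by exact line–circle intersection from the
free anchor through the ROI center of mass (photon-weighted by default;
unweighted optional). The bound fraction is the orthogonal projection of
the center of mass onto the chord, clamped to [0, 100]. It is a fraction
of *fluorescence intensity*, not of molecular concentration — phasor
linearity is in fractional intensity.

Numerical edge cases: a center of mass up to 0.02 outside the circle
(photon noise) is clamped radially with a warning; further out is an
error. A center of mass within 10⁻³ of the free anchor leaves the chord
direction undefined — the trajectory falls back to the diameter through
the anchor (the projected fraction is then ≈0, the correct answer for an
essentially pure-free population) with a warning; exact coincidence is an
error. Each ROI gets its own trajectory by default, mirroring a per-ROI
slider; a single global trajectory is available for cross-ROI
comparability and for per-pixel bound-fraction maps.

## Zoning

Eccentricity is arc length along the retina midline (midpoint of the
outer+inner layer envelope per column, interpolated across the disc);
straight-line distance is an option. Fixed zones sit at 200/400/600 µm;
mid periphery at half the disc-to-ora arc; far periphery is pulled in
from the ora by half an ROI width so the 150 µm ROI fits entirely. Fixed-
distance zones claim columns first; a zone that does not fit or would
overlap an already-claimed one is omitted with a warning — on a short
section the peripheral zones disappear rather than shrink. Outer =
{OS, IS, ONL}, inner = {OPL, INL, IPL, GCL, RNFL}; the RPE is in neither
region and never enters an ROI.

## Structural channels

Selectors are circular gates in (g, s) (Euclidean distance, default
intensity floor 5 photons). Hemoglobin and melanin share the 600–650 nm
band and are separated purely by phasor position; the melanin and
hemoglobin positions are never hard-coded as truth — they are learned
from seed ROIs (reference = seed center of mass, radius = 95th-percentile
seed distance) or configured. The second-harmonic gate sits at the
zero-lifetime point (1, 0), far from collagen autofluorescence.

## Statistics

Pairing unit is the image: per image, the mean bound % over outer ROIs vs
inner ROIs (per-eye grouping is an option). The paired t statistic is
t = mean(d)/(sd(d)/√n) on within-pair differences; the two-tailed p is
the regularized-incomplete-beta tail of Student's t with n−1 df. No
multiple-testing correction is applied (stated in the report). Degenerate
inputs: all-zero differences give t = 0, p = 1; zero-variance nonzero
differences are flagged.

Study-level simulations draw per-image (outer, inner) means with marginal
between-image SDs 3.7/2.6 and a shared per-image component (SD 2.0 by
default). The shared component models acquisition and fixation conditions
common to both regions of one section — the within-image correlation that
motivates a paired design in the first place; with it, the configured
2.0 pp effect at n = 86 pairs is detected at α = 10⁻⁴ in well over half
of replicates, and under the null the rejection rate stays at α.

## What the simulator does and does not show

Passing tests demonstrate that the analysis chain is internally
consistent and unbiased *under the forward model's assumptions*: pure
exponential mixtures, a Gaussian IRF, Poisson noise, no spectral
bleed-through, flat section geometry, and sharp layer boundaries. Real
sections add autofluorescence background, curved and folded geometry,
imperfect layer segmentation, detector artifacts, and fixation-dependent
lifetime shifts; recovery accuracy measured here is an upper bound on
what real data allow. Absolute bound percentages also depend on the
assumed free-lifetime anchor and on fixation state.

## Problem sizes used in checks

Recovery checks use 20 phantoms of 1600×300 µm at 2 µm/pixel with 128
time bins and 10⁵ photons/pixel; continuum-limit phasor checks use
single-pixel cubes at 8192 bins; statistical calibration uses 500 null
and 200 alternative replicates at the image level; determinism runs the
full pipeline twice on a two-image batch. These sizes were chosen so the
whole validation runs in about half a minute on one CPU while keeping
Monte-Carlo error well below the tolerances being checked.

## Known limitations

- No vendor FLIM file formats (.ptu/.sdt); decay cubes are TIFF+JSON.
- Layer labels come from the phantom or a user-supplied label image;
  there is no automatic layer segmentation from autofluorescence.
- Three-component unmixing and the bound-NAD(P)H/bound-FAD redox ratio
  are not implemented.
- The result bundle is bit-reproducible given a seed; the run log
  (timestamps) is excluded from that guarantee.
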