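# Methods

## Acquisition model

A multispectral acquisition visits each band of a wavelength grid (default
390–705 nm in 15 nm steps, 22 bands) twice: once without the sample
(reference) and once with it.  At each band, repeated frames (default 50)
are averaged pixel-by-pixel to suppress temporal CCD noise; with additive
noise of standard deviation σ per frame, the averaged image has noise
σ/√n.  Transmission is the pixel-wise ratio

    T(x, y, λ) = I_sample(x, y, λ) / I_reference(x, y, λ).

Two conventions deserve a note.  First, transmission is defined as
sample / reference — the ratio that lies in (0, 1] and yields non-negative
absorbance; descriptions of this kind of experiment sometimes state the
division the other way around, which would give 1/T.  Second, detector
noise can push a measured sample pixel above its reference.  T is therefore
clipped to (ε_floor, 1] with ε_floor = 10⁻⁶ (configurable): values above 1
become exactly 1 (zero absorbance), and the floor bounds the absorbance at
−ln 10⁻⁶ ≈ 13.8.  Reference pixels ≤ 0 carry no information; they are
masked invalid rather than propagated as infinities, and the mask is
honoured by every downstream statistic (means, covariances, pdfs,
fractions).

Absorbance (optical density) is A = −ln T.  Under the Beer–Lambert model
for a section of thickness L (default 5 µm), A = Σ_j ε_j(λ) C_j(x, y) L:
linear in the chromophores, additive across components, and monotone
(raising any concentration never raises transmission).  These three
properties are enforced by tests at machine precision on the forward model.

## PCA in wavelength space

Pixels are the statistical samples and bands the variables.  Each valid
pixel contributes its N-band absorbance spectrum; after removing the
per-band spatial mean ⟨A(λ)⟩, the N×N band covariance

    S[λ, λ'] = (1/M) Σ_pixels Ā(x, λ) Ā(x, λ')

is diagonalized (`numpy.linalg.eigh`), giving eigenvalues Γ_α (descending)
and orthonormal eigenvectors e_α(λ).  Population normalization (1/M) is
used; with M ∼ 10⁴–10⁵ pixels the 1/(M−1) distinction is far below every
tolerance in use.  The principal-component images
PC_α(x, y) = Σ_λ e_λα Ā(x, y, λ) are zero-mean and pairwise uncorrelated
with var(PC_α) = Γ_α, total variance is conserved
(Σ Γ_α = tr S = Σ_λ var A_λ), and the full-rank reconstruction
Ā = Σ_α e_α PC_α inverts the transform to ∼10⁻¹⁰.  Truncating to the
leading m components leaves residual variance Σ_{α>m} Γ_α exactly.

Numerical conventions, all chosen for determinism where the mathematics is
sign- or order-ambiguous:

* **Eigenvector sign**: each column is flipped so its largest-magnitude
  entry is positive.
* **Tied eigenvalues**: exactly tied pairs are ordered by the first
  differing eigenvector entry after the sign fix.
* **Averaging across individuals**: eigenvectors of different acquisitions
  may legitimately come out as e or −e, so before a group mean ± std is
  formed each individual's vector is aligned to the first individual's
  (flipped when the dot product is negative).  Without this, a group
  average can cancel to zero for purely conventional reasons.

### Choosing the number of components

Two rules are provided: the smallest m whose cumulative variance percentage
reaches a threshold (default 99 %), and a fixed m.  The default in the
pipeline is fixed m = 5.  On the published eigenvalue table this package's
analysis follows, the ≥ 99 % rule would select 4 components while the
published analysis kept 5; the pipeline therefore treats the threshold rule
as an option (`-m auto`), logs a warning when it is used, and defaults to
the fixed choice.  Note also that percentages printed in such tables are
computed against the full-spectrum total variance; normalizing only the few
listed eigenvalues yields different percentages (e.g. 88.6 % vs a printed
88.08 % for the leading control-group component) — the trailing eigenvalues
are part of the denominator.

## Endmembers and unmixing

The pixel cloud in band space has centre ⟨A(λ)⟩ and spreads by √Γ_α along
each unit eigenvector, so

    E_α(λ) = ⟨A(λ)⟩ + k·√Γ_α·e_α(λ),   k = 2 by default,

is a spectrum two standard deviations out along a principal axis — an
extreme, "pure" signature suitable as an endmember.  The scale k is exposed
because the choice of 2 is geometric rather than derived.  The construction
can produce negative entries; they are kept by default (NNLS constrains
abundances, not endmembers), with an explicit `clip_negative()` option for
physically interpretable spectra.

Unmixing solves, independently for each valid pixel,

    min ‖U x − b‖₂  subject to  x ≥ 0,

with U the N×m endmember matrix (N ≥ m required) and b the pixel's
absorbance spectrum.  The solver is `scipy.optimize.nnls` (the Lawson–
Hanson active-set method); its correctness surface is pinned by an
independent support-enumeration oracle that solves all 2^m candidate
active sets by pseudo-inverse and keeps the best feasible one — a global
optimum by exhaustion, compared against the fast solver on hundreds of
randomized instances at 10⁻⁶.  No sum-to-one closure is imposed on the
abundances.  Per-pixel problems are independent, so results cannot depend
on pixel evaluation order; identical spectra are solved once and broadcast.

When the true chromophore spectra are supplied as endmembers and the data
are noise-free, the unmixing recovers C_j·L exactly through the entire
acquisition → averaging → division → −ln → NNLS chain (tested at 10⁻⁶).
PCA-derived endmembers span the same subspace but are a shifted/rotated
frame; their abundance maps localize *spectral contrast*, and are not
expected to equal the generating concentration maps pixel-for-pixel.

## Abundance statistics

Abundance pdfs are normalized histograms over valid pixels; the default
binning is 50 uniform bins over [0, global max of the compared set], shared
across groups so the curves are directly comparable.  Group-mean pdfs are
per-bin arithmetic means (which preserves normalization).  The
high-abundance fraction is the share of valid pixels strictly above a
threshold (default 0.2), monotone non-increasing in the threshold.  Group
comparison is purely descriptive — no hypothesis testing is attached,
since the summaries are means and distributions.

## The synthetic phantom

The generator emulates the study conditions the pipeline targets, not any
particular dataset:

| parameter | default | meaning |
|---|---|---|
| grid | 390:15:705 nm | 22 bands |
| shape | 128×128 px | desk-scale stand-in for a 640×480 sensor |
| thickness L | 5 µm | section thickness |
| n_frames | 50 | repeats per band |
| levels | 256 | 8-bit quantization (None = ideal detector) |
| noise_sigma | 2.0 gray | ≈1 % of the ~200-level illumination |
| n_eyes | 9 per group | three groups: control, D2, D8 |

The scene is an idealized frontal eye section: nested elliptical shells
(cornea, choroid, retina) around a vitreous interior holding an offset
lens, the regions disjoint and tiling the eye mask.  Five components with
smooth Gaussian-band extinction spectra populate the regions; the first is
hemoglobin-like (a strong Soret-like band at 420 nm plus a weaker 550 nm
band) and lives in vessel-like blobs confined to vitreous and choroid.
The amplitudes are set so the scene's mean absorbance peaks at 420 nm in
every group.  Illumination varies smoothly across bands (the tunable-source
intensity is not flat) with a mild vignette.  Group effects are emulated by
scaling the vessel component (control 1.0, D2 0.6, D8 0.4) and roughening
the lens/retina texture component; each eye gets geometry jitter.  A single
integer seed determines everything bit-for-bit.

What the phantom does **not** model: scattering, fluorescence, optical
blur/PSF, chromatic aberration, stage drift or misregistration between
sample and reference, shot noise (the noise is additive Gaussian), and
wavelength-dependent path length.  Passing tests on the phantom therefore
validate the *computational* chain — acquisition arithmetic, PCA algebra,
NNLS optimality, bookkeeping — not the physics of any real tissue
measurement.

## Problem sizes used in the shipped checks

Desk-scale sizes keep the whole suite in seconds: exact-recovery and
variance-concentration checks run at 128×128×22 with 50 frames per band;
dataset bookkeeping (3 groups × 9 eyes × 22 bands = 594 band images) is
simulated at 64×64 with one frame per band; NNLS is cross-checked on 4×2
and 6×3 systems where the 2^m oracle is exhaustive.  The acceptance script
reports the top-five cumulative variance percentage of one full-noise
128×128×22 phantom acquisition.

## Known limitations

* Endmember count m must not exceed the band count; ill-conditioned (nearly
  collinear) endmember sets are solved but amplify noise in the abundances.
* The T > 1 clip biases absorbance slightly upward near A = 0 in noisy
  background regions; at the default noise level the effect is far below
  the structural eigenvalues.
* Sample and reference are assumed pixel-aligned (fixed-stage acquisition);
  no registration is attempted.
* On-disk cubes are float32 TIFF pages; round-trips are exact only at
  float32 precision.
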