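"""Synthetic eye-section phantoms with a simulated multispectral acquisition.

The generator emulates the study conditions of a transmission microscope
fitted with a tunable source and an 8-bit CCD: a 22-band grid from 390 to
705 nm in 15 nm steps, 640 x 480-style frames (128 x 128 by default for
desk-scale work), 50 repeated frames per band with additive Gaussian sensor
noise quantized to 256 gray levels, and a thin (5 um) section whose
transmission follows the Beer–Lambert model.

The scene is an idealized embryonic eye: nested elliptical regions
(cornea, lens, vitreous, retina, choroid) carrying five chromophore-like
components with smooth Gaussian-band extinction spectra.  The first
component mimics a hemoglobin-like double absorption band near 420/550 nm
and is placed in vessel-like blobs inside the vitreous and choroid; a
lens/retina component provides the texture-like structure.  Diet groups are
emulated by scaling the vessel component down (D2, D8) and roughening the
texture component.

Everything is driven by a single integer seed; identical seeds give
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .absorbance import (
    ChromophoreModel,
    ConcentrationMaps,
    beer_lambert_absorbance,
    beer_lambert_transmission,
    transmission_cube,
)
from .cube import FrameStack, SpectralCube, WavelengthGrid, average_frames, build_cube
from .unmixing import EndmemberSet

__all__ = [
    "DEFAULT_GRID",
    "PhantomSpec",
    "PhantomTruth",
    "EyeAcquisition",
    "component_spectra",
    "make_eye_scene",
    "eye_phantom",
    "render_transmission_cube",
    "simulate_acquisition",
    "recover_transmission",
    "generate_group",
    "GROUP_VESSEL_FACTORS",
    "REGION_NAMES",
]

#: The acquisition grid: 390–705 nm in 15 nm steps, 22 bands.
DEFAULT_GRID = WavelengthGrid.from_range(390.0, 705.0, 15.0)

REGION_NAMES = ("outside", "cornea", "lens", "vitreous", "retina", "choroid")

#: Vessel-concentration scaling per diet group (control / 2-week / 8-week
#: deficiency), emulating the reduced vascular signal of the deficient groups.
GROUP_VESSEL_FACTORS = {"control": 1.0, "D2": 0.6, "D8": 0.4}

#: Extra roughness applied to the lens/retina texture component per group.
GROUP_TEXTURE_ROUGHNESS = {"control": 0.0, "D2": 0.25, "D8": 0.45}

COMPONENT_NAMES = ("hemoglobin_like", "stroma", "lens_crystallin", "pigment", "background")


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def component_spectra(grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """Extinction spectra eps_j(lambda) of the five phantom components.

    Smooth Gaussian absorption bands, units 1/(conc * um), chosen so that
    typical optical densities fall in 0.05–1; the first component carries a
    hemoglobin-like double band (Soret-like peak at 420 nm plus a weaker
    550 nm band), which also plants the 420 nm maximum of the scene's mean
    absorbance.  Columns are linearly independent.
    """
    wl = grid.wavelengths
    cols = [
        0.130 * _gauss(wl, 420, 16) + 0.050 * _gauss(wl, 550, 28),
        0.040 * _gauss(wl, 480, 50),
        0.090 * _gauss(wl, 418, 28),
        0.032 * _gauss(wl, 525, 60),
        0.020 * _gauss(wl, 600, 90),
    ]
    return np.column_stack(cols)


def _elliptical_radius(shape: tuple[int, int], center: tuple[float, float],
                       semi_axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return np.sqrt(((rr - center[0]) / semi_axes[0]) ** 2
                   + ((cc - center[1]) / semi_axes[1]) ** 2)


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  sigma: float = 3.0) -> np.ndarray:
    """Zero-mean, unit-std smooth random field (within-region texture)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.mean()) / max(f.std(), 1e-12)


def make_eye_scene(
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    jitter: float = 0.0,
    texture_roughness: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[ConcentrationMaps, np.ndarray]:
    """Concentration maps and region labels for an idealized eye section.

    Nested elliptical shells — cornea (outer), choroid, retina, then the
    vitreous interior holding an offset lens — tile the eye mask; vessel-like
    Gaussian blobs are placed inside vitreous and choroid only.  ``jitter``
    perturbs the geometry (fractional center/axis changes, for per-individual
    variation) and ``texture_roughness`` adds extra within-region variation to
    the lens/retina component.

    Returns ``(ConcentrationMaps, labels)`` where ``labels`` indexes
    :data:`REGION_NAMES`.
    """
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError("scene shape must be at least 64 x 64")
    rng = np.random.default_rng(seed) if rng is None else rng

    center = [shape[0] / 2, shape[1] / 2]
    axes = [0.42 * shape[0], 0.45 * shape[1]]
    if jitter > 0:
        center = [c + jitter * 0.05 * s * rng.standard_normal()
                  for c, s in zip(center, shape)]
        axes = [a * (1 + jitter * 0.08 * rng.standard_normal()) for a in axes]
    rho = _elliptical_radius(shape, tuple(center), tuple(axes))

    eye = rho <= 1.0
    cornea = eye & (rho > 0.92)
    choroid = eye & (rho > 0.84) & (rho <= 0.92)
    retina = eye & (rho > 0.74) & (rho <= 0.84)
    interior = eye & (rho <= 0.74)
    lens_center = (center[0], center[1] - 0.38 * axes[1])
    lens = (_elliptical_radius(shape, lens_center,
                               (0.24 * axes[0], 0.24 * axes[1])) <= 1.0) & interior
    vitreous = interior & ~lens

    labels = np.zeros(shape, dtype=np.int8)
    for idx, region in enumerate((cornea, lens, vitreous, retina, choroid), start=1):
        labels[region] = idx

    # vessel blobs confined to vitreous + choroid
    vessel_zone = vitreous | choroid
    blob_sigma = max(1.5, 0.015 * min(shape))
    n_blobs = max(8, int(14 * (shape[0] * shape[1]) / (128 * 128)))
    zone_idx = np.argwhere(vessel_zone)
    picks = zone_idx[rng.choice(len(zone_idx), size=n_blobs, replace=False)]
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    vessels = np.zeros(shape)
    for r0, c0 in picks:
        vessels += np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * blob_sigma**2))
    vessels = np.clip(vessels, 0, 1) * vessel_zone

    base = [
        0.90 * vessels + 0.12 * choroid,                 # hemoglobin-like
        0.70 * cornea + 0.45 * retina,                   # stroma
        0.80 * lens + 0.35 * retina,                     # lens/retina texture
        0.60 * choroid + 0.25 * retina,                  # pigment
        0.30 * eye,                                      # diffuse background
    ]
    maps = []
    for j, comp in enumerate(base):
        rough = 0.15 + (texture_roughness if j == 2 else 0.0)
        texture = 1.0 + rough * _smooth_field(shape, rng)
        maps.append(np.clip(comp * texture, 0.0, None))
    return ConcentrationMaps(np.stack(maps, axis=-1)), labels


@dataclass
class PhantomSpec:
    """Full recipe for one synthetic acquisition.

    ``noise_sigma`` is the additive Gaussian sensor noise std in gray levels
    (default 2.0, about 1% of the ~200-level illumination); ``levels=None``
    disables quantization (ideal detector).  The seed fully determines the
    output.
    """

    model: ChromophoreModel
    conc: ConcentrationMaps
    labels: np.ndarray
    grid: WavelengthGrid = DEFAULT_GRID
    noise_sigma: float = 2.0
    n_frames: int = 50
    levels: int | None = 256
    illumination_peak: float = 200.0
    seed: int = 0
    component_names: tuple[str, ...] = COMPONENT_NAMES
    group: str | None = None
    individual: str | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.conc.shape


@dataclass
class PhantomTruth:
    """Ground truth accompanying a rendered phantom."""

    absorbance: np.ndarray          # (rows, cols, bands) = sum_j eps_j C_j L
    conc: ConcentrationMaps
    epsilon: np.ndarray             # (bands, comps)
    thickness_um: float
    abundances: np.ndarray          # (rows, cols, comps) = C_j * L
    labels: np.ndarray

    @property
    def endmembers(self) -> EndmemberSet:
        """The true extinction spectra as an endmember matrix.

        Unmixing the true absorbance against these recovers C_j * L exactly.
        """
        return EndmemberSet(self.epsilon, source="user-supplied")


def eye_phantom(
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    grid: WavelengthGrid = DEFAULT_GRID,
    thickness_um: float = 5.0,
    noise_sigma: float = 2.0,
    n_frames: int = 50,
    levels: int | None = 256,
    vessel_scale: float = 1.0,
    texture_roughness: float = 0.0,
    jitter: float = 0.0,
    group: str | None = None,
    individual: str | None = None,
) -> PhantomSpec:
    """Build a :class:`PhantomSpec` for one eye under the default conditions."""
    conc, labels = make_eye_scene(shape, seed=seed, jitter=jitter,
                                  texture_roughness=texture_roughness)
    maps = conc.maps.copy()
    maps[:, :, 0] *= vessel_scale
    model = ChromophoreModel(component_spectra(grid), thickness_um, grid=grid,
                             names=list(COMPONENT_NAMES))
    return PhantomSpec(model=model, conc=ConcentrationMaps(maps), labels=labels,
                       grid=grid, noise_sigma=noise_sigma, n_frames=n_frames,
                       levels=levels, seed=seed, group=group, individual=individual)


def render_transmission_cube(spec: PhantomSpec) -> tuple[SpectralCube, PhantomTruth]:
    """Noise-free Beer–Lambert transmission cube plus its ground truth."""
    T = beer_lambert_transmission(spec.model, spec.conc, grid=spec.grid)
    T.group, T.individual = spec.group, spec.individual
    truth = PhantomTruth(
        absorbance=beer_lambert_absorbance(spec.model, spec.conc),
        conc=spec.conc,
        epsilon=spec.model.epsilon,
        thickness_um=spec.model.thickness_um,
        abundances=spec.conc.maps * spec.model.thickness_um,
        labels=spec.labels,
    )
    return T, truth


def _illumination(spec: PhantomSpec, band: int) -> np.ndarray:
    """Clean reference intensity: per-band source level times a mild vignette."""
    wl = spec.grid.wavelengths
    frac = (wl[band] - wl[0]) / max(wl[-1] - wl[0], 1.0)
    level = spec.illumination_peak * (0.8 + 0.2 * np.cos(2 * np.pi * frac))
    shape = spec.shape
    rho = _elliptical_radius(shape, (shape[0] / 2, shape[1] / 2),
                             (shape[0] / 1.2, shape[1] / 1.2))
    return level * (1.0 - 0.08 * rho**2)


def _band_frames(clean: np.ndarray, spec: PhantomSpec,
                 rng: np.random.Generator) -> np.ndarray:
    frames = np.broadcast_to(clean, (spec.n_frames, *clean.shape)).copy()
    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, frames.shape)
    if spec.levels is not None:
        if np.all(clean >= spec.levels - 1):
            raise ValueError("illumination saturates the detector everywhere")
        frames = np.clip(np.round(frames), 0, spec.levels - 1)
    return frames


def simulate_acquisition(
    spec: PhantomSpec, transmission: SpectralCube
) -> tuple[list[FrameStack], list[FrameStack]]:
    """Simulate the two-pass acquisition: reference frames, then sample frames.

    Per band, ``n_frames`` reference frames (illumination plus sensor noise,
    quantized) and ``n_frames`` sample frames (illumination times the sample
    transmission, same noise model) are produced.  Fully determined by
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    refs, samples = [], []
    for b in range(len(spec.grid)):
        clean_ref = _illumination(spec, b)
        refs.append(FrameStack(_band_frames(clean_ref, spec, rng), levels=spec.levels))
        clean_sample = clean_ref * transmission.data[:, :, b]
        samples.append(FrameStack(_band_frames(clean_sample, spec, rng),
                                  levels=spec.levels))
    return refs, samples


def recover_transmission(
    refs: list[FrameStack],
    samples: list[FrameStack],
    grid: WavelengthGrid,
    group: str | None = None,
    individual: str | None = None,
) -> SpectralCube:
    """Average the repeated frames and divide sample by reference."""
    ref_cube = build_cube([average_frames(s) for s in refs], grid, "intensity",
                          group=group, individual=individual)
    sample_cube = build_cube([average_frames(s) for s in samples], grid, "intensity",
                             group=group, individual=individual)
    return transmission_cube(sample_cube, ref_cube)


def generate_group(
    base_seed: int,
    group: str,
    n_eyes: int = 9,
    shape: tuple[int, int] = (128, 128),
    grid: WavelengthGrid = DEFAULT_GRID,
    noise_sigma: float = 2.0,
    n_frames: int = 50,
    levels: int | None = 256,
    vessel_factors: dict[str, float] | None = None,
) -> list["EyeAcquisition"]:
    """Simulate all eyes of one diet group.

    The control group uses the base scene; the deficient groups scale the
    vessel component by :data:`GROUP_VESSEL_FACTORS` and roughen the
    lens/retina texture component.  Each eye gets its own geometry jitter.
    Per-eye seeds derive deterministically from ``base_seed``.
    """
    factors = vessel_factors or GROUP_VESSEL_FACTORS
    if group not in factors:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(factors)}")
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    group_offset = sorted(factors).index(group)
    out = []
    for i in range(n_eyes):
        eye_seed = (base_seed * 1_000_003 + group_offset * 10_007 + i) % (2**31 - 1)
        spec = eye_phantom(
            shape=shape, seed=eye_seed, grid=grid, noise_sigma=noise_sigma,
            n_frames=n_frames, levels=levels,
            vessel_scale=factors[group],
            texture_roughness=GROUP_TEXTURE_ROUGHNESS.get(group, 0.0),
            jitter=1.0 if n_eyes > 1 else 0.0,
            group=group, individual=f"eye{i + 1:02d}",
        )
        T, truth = render_transmission_cube(spec)
        refs, samples = simulate_acquisition(spec, T)
        ref_cube = build_cube([average_frames(s) for s in refs], grid, "intensity",
                              group=group, individual=spec.individual)
        sample_cube = build_cube([average_frames(s) for s in samples], grid,
                                 "intensity", group=group, individual=spec.individual)
        out.append(EyeAcquisition(spec=spec, transmission_true=T, truth=truth,
                                  reference=ref_cube, sample=sample_cube))
    return out


@dataclass
class EyeAcquisition:
    """One simulated eye: spec, true transmission/truth, averaged intensities."""

    spec: PhantomSpec
    transmission_true: SpectralCube
    truth: PhantomTruth
    reference: SpectralCube
    sample: SpectralCube

    def measured_transmission(self) -> SpectralCube:
        return transmission_cube(self.sample, self.reference)
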