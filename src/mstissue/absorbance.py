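"""Transmission and absorbance arithmetic under the Beer–Lambert model.

For a thin section of thickness L containing n chromophores with extinction
spectra eps_j(lambda) and concentration maps C_j(x, y), the transmitted
fraction at each pixel and band is

    T(x, y, lambda) = exp(-sum_j eps_j(lambda) * C_j(x, y) * L)

and the absorbance (optical density) is A = -ln T = sum_j eps_j C_j L,
which is linear in the chromophores.  This module converts measured
intensities to transmission (sample / reference), transmission to
absorbance, and provides the forward model used by the synthetic phantom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import SpectralCube, WavelengthGrid

__all__ = [
    "ChromophoreModel",
    "ConcentrationMaps",
    "compute_transmission",
    "transmission_cube",
    "transmission_to_absorbance",
    "beer_lambert_transmission",
    "beer_lambert_absorbance",
    "mean_absorbance",
]

#: Transmission floor applied before taking logarithms: bounds absorbance at
#: -ln(1e-6) ~ 13.8 for pixels driven to zero by noise.
DEFAULT_T_FLOOR = 1e-6


@dataclass
class ChromophoreModel:
    """Extinction spectra of the modelled tissue components.

    ``epsilon`` is (n_bands, n_components), non-negative, in units of
    1 / (concentration unit * micrometre); ``thickness_um`` is the section
    thickness L in micrometres (5 um sections in the reference protocol).
    """

    epsilon: np.ndarray
    thickness_um: float
    grid: WavelengthGrid | None = None
    names: list[str] | None = None

    def __post_init__(self) -> None:
        eps = np.atleast_2d(np.asarray(self.epsilon, dtype=float))
        if np.any(eps < 0):
            raise ValueError("extinction coefficients must be non-negative")
        if self.thickness_um <= 0:
            raise ValueError("thickness must be positive")
        if self.grid is not None and eps.shape[0] != len(self.grid):
            raise ValueError("epsilon rows must match the wavelength grid")
        self.epsilon = eps

    @property
    def n_components(self) -> int:
        return self.epsilon.shape[1]

    @property
    def n_bands(self) -> int:
        return self.epsilon.shape[0]


@dataclass
class ConcentrationMaps:
    """Per-component concentration images ``C_j(x, y)``, non-negative."""

    maps: np.ndarray  # (rows, cols, n_components)

    def __post_init__(self) -> None:
        arr = np.asarray(self.maps, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError("concentration maps must be (rows, cols, n_components)")
        if np.any(arr < 0):
            raise ValueError("concentrations must be non-negative")
        self.maps = arr

    @property
    def n_components(self) -> int:
        return self.maps.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[:2]


def compute_transmission(
    sample_img: np.ndarray,
    reference_img: np.ndarray,
    floor: float = DEFAULT_T_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise transmission T = sample / reference with a validity mask.

    Pixels whose reference intensity is <= 0 carry no information and are
    masked invalid rather than producing infinities.  T is clipped to
    ``(floor, 1]``: noise can push the measured sample above the reference
    (T > 1, i.e. negative absorbance), which is clipped to exactly 1.

    Returns ``(T, valid_mask)``; shapes follow the inputs, which may be 2-D
    images or full (rows, cols, bands) arrays.
    """
    sample = np.asarray(sample_img, dtype=float)
    reference = np.asarray(reference_img, dtype=float)
    if sample.shape != reference.shape:
        raise ValueError("sample and reference shapes differ")
    valid = reference > 0
    T = np.ones_like(sample)
    np.divide(sample, reference, out=T, where=valid)
    T = np.clip(T, floor, 1.0)
    if valid.ndim == 3:  # a pixel is valid only if every band's reference is
        valid = valid.all(axis=2)
    if not valid.any():
        raise ValueError("transmission is fully masked (no positive reference pixels)")
    return T, valid


def transmission_cube(
    sample: SpectralCube, reference: SpectralCube, floor: float = DEFAULT_T_FLOOR
) -> SpectralCube:
    """Transmission cube from matched sample/reference intensity cubes."""
    if sample.kind != "intensity" or reference.kind != "intensity":
        raise ValueError("transmission requires two intensity cubes")
    if sample.grid != reference.grid:
        raise ValueError("sample and reference wavelength grids differ")
    T, valid = compute_transmission(sample.data, reference.data, floor=floor)
    return SpectralCube(
        T, sample.grid, "transmission", group=sample.group,
        individual=sample.individual, mask=sample.mask & reference.mask & valid,
    )


def transmission_to_absorbance(T: SpectralCube) -> SpectralCube:
    """Absorbance cube A = -ln(T); the validity mask carries over."""
    if T.kind != "transmission":
        raise ValueError(f"expected a transmission cube, got kind={T.kind!r}")
    return T.with_data(-np.log(T.data), kind="absorbance")


def beer_lambert_absorbance(model: ChromophoreModel, conc: ConcentrationMaps) -> np.ndarray:
    """Ground-truth absorbance array sum_j eps_j(lambda) C_j(x,y) L."""
    if model.n_components != conc.n_components:
        raise ValueError(
            f"model has {model.n_components} components, maps have {conc.n_components}"
        )
    # (rows, cols, comps) x (bands, comps) -> (rows, cols, bands)
    return model.thickness_um * np.einsum("rcj,bj->rcb", conc.maps, model.epsilon)


def beer_lambert_transmission(
    model: ChromophoreModel,
    conc: ConcentrationMaps,
    grid: WavelengthGrid | None = None,
) -> SpectralCube:
    """Forward Beer–Lambert model: T = exp(-sum_j eps_j C_j L), in (0, 1]."""
    A = beer_lambert_absorbance(model, conc)
    grid = grid if grid is not None else model.grid
    if grid is None:
        raise ValueError("a wavelength grid is required (on the model or as argument)")
    if len(grid) != model.n_bands:
        raise ValueError("grid length must match the model's band count")
    return SpectralCube(np.exp(-A), grid, "transmission")


def mean_absorbance(A: SpectralCube) -> np.ndarray:
    """Spatial mean spectrum <A(lambda)> over valid pixels, one value per band."""
    if A.kind != "absorbance":
        raise ValueError(f"expected an absorbance cube, got kind={A.kind!r}")
    if A.n_valid == 0:
        raise ValueError("no valid pixels to average")
    return A.valid_pixels().mean(axis=0)
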