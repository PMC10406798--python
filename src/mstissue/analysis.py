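"""Statistical summaries of abundance maps and group-level absorbance.

Abundance maps are compared between sample groups descriptively: the
probability density function (pdf) of each endmember's abundance values,
group-mean pdfs on shared bins, the fraction of pixels above an abundance
threshold, and group-mean absorbance spectra with their peak wavelength.
No hypothesis testing is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .absorbance import mean_absorbance
from .cube import SpectralCube

__all__ = [
    "AbundancePdf",
    "abundance_pdf",
    "default_bin_edges",
    "group_mean_pdf",
    "high_abundance_fraction",
    "mean_absorbance_report",
]


@dataclass
class AbundancePdf:
    """Normalized histogram of one abundance map: integrates to 1."""

    bin_edges: np.ndarray
    density: np.ndarray
    endmember_id: int | None = None
    group: str | None = None
    individual: str | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        if dens.size != edges.size - 1:
            raise ValueError("density must have one entry per bin")
        if np.any(dens < 0):
            raise ValueError("density must be non-negative")
        self.bin_edges = edges
        self.density = dens

    @property
    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "density": self.density,
        })


def default_bin_edges(maps: list[np.ndarray], n_bins: int = 50) -> np.ndarray:
    """Shared uniform bins over [0, global max] so group pdfs are comparable."""
    top = max(float(np.nanmax(m)) for m in maps)
    if top <= 0:
        top = 1.0
    return np.linspace(0.0, top, n_bins + 1)


def abundance_pdf(
    abundance_map: np.ndarray,
    bin_edges: np.ndarray,
    endmember_id: int | None = None,
    group: str | None = None,
    individual: str | None = None,
) -> AbundancePdf:
    """Probability density of abundance values over valid (non-NaN) pixels."""
    values = np.asarray(abundance_map, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("abundance map has no valid pixels")
    density, edges = np.histogram(values, bins=np.asarray(bin_edges, dtype=float),
                                  density=True)
    return AbundancePdf(edges, density, endmember_id=endmember_id,
                        group=group, individual=individual)


def group_mean_pdf(pdfs: list[AbundancePdf]) -> AbundancePdf:
    """Per-bin arithmetic mean of densities; bins must be identical.

    The mean of densities that each integrate to 1 again integrates to 1.
    """
    if not pdfs:
        raise ValueError("empty pdf list")
    edges = pdfs[0].bin_edges
    for p in pdfs[1:]:
        if p.bin_edges.shape != edges.shape or not np.allclose(p.bin_edges, edges):
            raise ValueError("pdfs use different bin edges")
    mean_density = np.mean([p.density for p in pdfs], axis=0)
    return AbundancePdf(edges.copy(), mean_density,
                        endmember_id=pdfs[0].endmember_id,
                        group=pdfs[0].group)


def high_abundance_fraction(abundance_map: np.ndarray, threshold: float) -> float:
    """Fraction of valid pixels with abundance strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    values = np.asarray(abundance_map, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("abundance map has no valid pixels")
    return float(np.mean(values > threshold))


def mean_absorbance_report(cubes: list[SpectralCube]) -> pd.DataFrame:
    """Group-mean absorbance spectra and their most-absorbed wavelength.

    Each cube's spatial-mean spectrum <A(lambda)> is computed, spectra are
    averaged within each group label, and the wavelength of maximum mean
    absorbance is reported per group.  Returns a tidy frame with columns
    ``group, wavelength_nm, mean_absorbance, is_argmax``.
    """
    if not cubes:
        raise ValueError("no cubes supplied")
    grid = cubes[0].grid
    if any(c.grid != grid for c in cubes):
        raise ValueError("cubes use different wavelength grids")
    rows = []
    by_group: dict[str, list[np.ndarray]] = {}
    for c in cubes:
        by_group.setdefault(c.group or "all", []).append(mean_absorbance(c))
    for group, spectra in by_group.items():
        mean_spec = np.mean(spectra, axis=0)
        peak = int(np.argmax(mean_spec))
        for b, wl in enumerate(grid.wavelengths):
            rows.append({
                "group": group,
                "wavelength_nm": float(wl),
                "mean_absorbance": float(mean_spec[b]),
                "is_argmax": b == peak,
            })
    return pd.DataFrame(rows)
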