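"""Endmember construction and non-negative spectral unmixing.

Endmembers are idealized pure spectral signatures.  Here they are built
from the PCA structure of the absorbance data: the point cloud of pixel
spectra has mean <A(lambda)> and spreads by sqrt(Gamma_a) along each unit
eigenvector e_a, so

    E_a(lambda) = <A(lambda)> + scale * sqrt(Gamma_a) * e_a(lambda)

with the default scale of 2 places each endmember two standard deviations
out from the centre of the cloud along a principal axis — an extreme,
"pure" spectrum in that direction.

Each pixel's absorbance spectrum b is then decomposed as b ~ U x with
U = [E_1 ... E_m] and abundances x >= 0, solved independently per pixel by
non-negative least squares (NNLS).  No sum-to-one closure is imposed.
A brute-force support-enumeration solver is included as a small-problem
oracle: it examines all 2^m active sets, which is the global optimum by
exhaustion, and serves as an independent correctness check of the fast
solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.optimize

from .cube import SpectralCube
from .pca import EigenDecomposition

__all__ = [
    "EndmemberSet",
    "AbundanceMaps",
    "construct_endmembers",
    "nnls_solve",
    "nnls_bruteforce_oracle",
    "unmix_cube",
    "spectral_similarity",
]


@dataclass
class EndmemberSet:
    """Endmember spectra as columns of ``spectra`` (n_bands x m).

    ``scale`` records the multiplier on sqrt(Gamma) used in the PCA-derived
    construction; ``source`` is "pca-derived" or "user-supplied".  Endmember
    entries may be negative (the construction can overshoot zero); NNLS
    constrains abundances, not endmembers.  Use ``clip_negative`` for
    physically interpretable spectra.
    """

    spectra: np.ndarray
    scale: float | None = None
    source: str = "user-supplied"
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        U = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if U.shape[1] < 1:
            raise ValueError("at least one endmember required")
        if U.shape[0] < U.shape[1]:
            raise ValueError(
                "need at least as many bands as endmembers for a determined unmixing"
            )
        if not np.all(np.isfinite(U)):
            raise ValueError("endmember spectra must be finite")
        if np.any(np.all(U == 0, axis=0)):
            raise ValueError("endmember set contains an all-zero column")
        self.spectra = U

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_endmembers(self) -> int:
        return self.spectra.shape[1]

    def clip_negative(self) -> "EndmemberSet":
        """Copy with negative entries set to zero."""
        return EndmemberSet(np.clip(self.spectra, 0.0, None), scale=self.scale,
                            source=self.source, wavelengths=self.wavelengths)


@dataclass
class AbundanceMaps:
    """Per-endmember non-negative abundance images and per-pixel residual.

    ``maps`` is (rows, cols, m); ``residual`` is the per-pixel Euclidean norm
    ||U x - b||.  Invalid pixels are NaN in both and excluded by ``mask``.
    """

    maps: np.ndarray
    residual: np.ndarray
    mask: np.ndarray

    @property
    def n_endmembers(self) -> int:
        return self.maps.shape[2]

    def map_of(self, k: int) -> np.ndarray:
        return self.maps[:, :, k]


def construct_endmembers(
    decomp: EigenDecomposition, m: int, scale: float = 2.0
) -> EndmemberSet:
    """Endmembers E_k = <A> + scale * sqrt(Gamma_k) * e_k for k = 1..m.

    Components are taken in descending-eigenvalue order.  ``scale`` must be
    positive; 2 is the standard choice (two standard deviations out).
    """
    if not 1 <= m <= decomp.n_bands:
        raise ValueError(f"m={m} exceeds the {decomp.n_bands} available components")
    if scale <= 0:
        raise ValueError("scale must be positive")
    cols = [
        decomp.mean_spectrum + scale * np.sqrt(decomp.eigenvalues[k]) * decomp.eigenvectors[:, k]
        for k in range(m)
    ]
    return EndmemberSet(np.column_stack(cols), scale=scale, source="pca-derived",
                        wavelengths=decomp.grid.wavelengths)


def nnls_solve(U: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """min ||U x - b||_2 subject to x >= 0; returns (x, residual norm)."""
    U = np.asarray(U, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if U.ndim != 2 or U.shape[0] != b.size:
        raise ValueError(f"dimension mismatch: U is {U.shape}, b has {b.size} entries")
    if np.any(np.all(U == 0, axis=0)):
        raise ValueError("U contains an all-zero column")
    x, rnorm = scipy.optimize.nnls(U, b)
    return x, rnorm


def nnls_bruteforce_oracle(U: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Globally optimal NNLS by enumerating all 2^m support sets.

    For every subset of columns, solve the unconstrained least-squares
    problem restricted to that subset (via pseudo-inverse), keep candidates
    whose support coefficients are all non-negative, and return the feasible
    candidate with smallest residual.  Exponential in m — a test oracle for
    m <= 10, independent of the fast solver.
    """
    U = np.asarray(U, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    m = U.shape[1]
    if m > 10:
        raise ValueError("oracle limited to m <= 10 endmembers")
    best_x = np.zeros(m)
    best_r = float(np.linalg.norm(b))  # empty support
    for size in range(1, m + 1):
        for support in combinations(range(m), size):
            sub = U[:, support]
            coef = np.linalg.pinv(sub) @ b
            if np.any(coef < 0):
                continue
            r = float(np.linalg.norm(sub @ coef - b))
            if r < best_r - 1e-15:
                best_r = r
                best_x = np.zeros(m)
                best_x[list(support)] = coef
    return best_x, best_r


def unmix_cube(A: SpectralCube, endmembers: EndmemberSet) -> AbundanceMaps:
    """Per-pixel NNLS abundances of each endmember in an absorbance cube.

    One independent NNLS problem is solved per valid pixel with U = the
    endmember matrix and b = the pixel's absorbance spectrum; results do not
    depend on pixel evaluation order.  Masked pixels yield NaN abundances.
    """
    if A.kind != "absorbance":
        raise ValueError(f"expected an absorbance cube, got kind={A.kind!r}")
    U = endmembers.spectra
    if A.n_bands != U.shape[0]:
        raise ValueError(
            f"cube has {A.n_bands} bands but endmembers have {U.shape[0]}"
        )
    rows, cols, _ = A.shape
    m = endmembers.n_endmembers
    maps = np.full((rows, cols, m), np.nan)
    residual = np.full((rows, cols), np.nan)
    # Identical spectra (common in flat phantom regions) are solved once.
    spectra = A.data.reshape(-1, A.n_bands)
    valid = A.mask.ravel()
    uniq, inverse = np.unique(spectra[valid], axis=0, return_inverse=True)
    sols = np.empty((uniq.shape[0], m))
    res = np.empty(uniq.shape[0])
    for i, b in enumerate(uniq):
        sols[i], res[i] = nnls_solve(U, b)
    flat_maps = maps.reshape(-1, m)
    flat_maps[valid] = sols[inverse]
    residual.ravel()[valid] = res[inverse]
    return AbundanceMaps(maps=maps, residual=residual, mask=A.mask.copy())


def spectral_similarity(s1: np.ndarray, s2: np.ndarray) -> tuple[float, float]:
    """Spectral angle (degrees) and Pearson correlation between two spectra.

    The angle arccos(s1.s2 / |s1||s2|) is scale-invariant: 0 for parallel
    spectra, 90 for orthogonal ones.  Useful for comparing a recovered
    endmember against a reference chromophore spectrum (e.g. hemoglobin).
    """
    a = np.asarray(s1, dtype=float).ravel()
    b = np.asarray(s2, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("spectra differ in length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm spectrum")
    cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    corr = float(np.corrcoef(a, b)[0, 1])
    return angle, corr
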