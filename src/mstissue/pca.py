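"""Principal component analysis of an absorbance cube in wavelength space.

Each valid pixel contributes one N-vector (its absorbance spectrum over the
N bands).  After removing the per-band spatial mean <A(lambda)>, the N x N
band covariance

    S[l, l'] = (1/M) sum_pixels  Abar(x, l) Abar(x, l')

is diagonalized, S e_a = Gamma_a e_a.  The unit eigenvectors e_a(lambda)
carry the spectral trends; the principal-component images

    PC_a(x, y) = sum_l e[l, a] * Abar(x, y, l)

carry the spatial structure, are zero-mean and mutually uncorrelated, and
var(PC_a) = Gamma_a.  The centered cube is recovered exactly by
Abar = sum_a e[:, a] PC_a (full rank), and truncating to the leading
components gives the least-squares rank-m reconstruction.

Population (1/M) normalization is used for the covariance; at the pixel
counts involved (10^4-10^5) the 1/(M-1) distinction is negligible.

Eigenvector signs are arbitrary; a deterministic convention is applied
(the entry of largest magnitude is made positive).  When eigenvectors of
several individuals are averaged, each is first sign-aligned to the first
individual's (flipped if the dot product is negative), since two
acquisitions of the same structure may legitimately return e and -e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .absorbance import mean_absorbance
from .cube import SpectralCube, WavelengthGrid

__all__ = [
    "EigenDecomposition",
    "center_by_band_mean",
    "band_covariance",
    "eigendecompose",
    "compute_principal_components",
    "reconstruct_cube",
    "variance_percentages",
    "select_num_components",
    "decompose",
    "group_average_eigenvectors",
]


@dataclass
class EigenDecomposition:
    """Band-space PCA of one absorbance cube.

    Attributes
    ----------
    mean_spectrum : (N,) removed per-band spatial mean <A(lambda)>.
    eigenvalues : (N,) variances Gamma_a, descending, absorbance^2 units.
    eigenvectors : (N, N) unit-norm columns e[:, a].
    pcs : (rows, cols, N) principal-component images PC_a(x, y).
    variance_pct : (N,) percentage of total variance per component.
    """

    mean_spectrum: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    pcs: np.ndarray
    variance_pct: np.ndarray
    grid: WavelengthGrid
    mask: np.ndarray
    group: str | None = None
    individual: str | None = None

    @property
    def n_bands(self) -> int:
        return self.eigenvalues.size


def center_by_band_mean(A: SpectralCube) -> tuple[SpectralCube, np.ndarray]:
    """Remove the per-band spatial mean; returns (centered cube, mean spectrum).

    The centered values keep kind="absorbance" semantics (they are absorbance
    deviations); invalid pixels are zeroed so they contribute nothing to sums.
    """
    mean_spec = mean_absorbance(A)
    centered = A.data - mean_spec
    centered[~A.mask] = 0.0
    return A.with_data(centered), mean_spec


def band_covariance(centered: SpectralCube) -> np.ndarray:
    """N x N band covariance S = (1/M) Abar^T Abar over the M valid pixels."""
    M = centered.n_valid
    if M == 0:
        raise ValueError("no valid pixels")
    X = centered.valid_pixels()  # (M, N)
    return (X.T @ X) / M


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its entry of largest magnitude is positive."""
    out = vectors.copy()
    idx = np.argmax(np.abs(out), axis=0)
    flip = out[idx, np.arange(out.shape[1])] < 0
    out[:, flip] *= -1.0
    return out


def eigendecompose(S: np.ndarray, sym_tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and sign-fixed orthonormal eigenvectors of S.

    S must be symmetric positive semidefinite up to round-off; tiny negative
    eigenvalues from round-off are clamped to zero.  Ties in eigenvalue are
    ordered by the first differing eigenvector entry after the sign fix.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance matrix must be square")
    scale = max(np.abs(S).max(), 1.0)
    if np.abs(S - S.T).max() > sym_tol * scale:
        raise ValueError("covariance matrix is not symmetric within tolerance")
    evals, evecs = np.linalg.eigh((S + S.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    evecs = _fix_signs(evecs)
    # deterministic ordering among exactly tied eigenvalues
    for start in range(len(evals) - 1):
        stop = start + 1
        while stop < len(evals) and evals[stop] == evals[start]:
            stop += 1
        if stop - start > 1:
            block = evecs[:, start:stop]
            key = np.lexsort(block[::-1])
            evecs[:, start:stop] = block[:, key]
    return evals, evecs


def compute_principal_components(
    centered: SpectralCube, eigenvectors: np.ndarray
) -> np.ndarray:
    """PC images PC_a(x, y) = sum_l e[l, a] Abar(x, y, l), shape (rows, cols, N)."""
    if eigenvectors.shape[0] != centered.n_bands:
        raise ValueError("eigenvector rows must equal the cube band count")
    return np.tensordot(centered.data, eigenvectors, axes=([2], [0]))


def reconstruct_cube(
    pcs: np.ndarray,
    eigenvectors: np.ndarray,
    mean_spectrum: np.ndarray,
    n_components: int | None = None,
) -> np.ndarray:
    """Rebuild absorbance from the leading PCs: A = <A> + sum_a e[:, a] PC_a.

    With all components this inverts the decomposition exactly; with the
    leading ``n_components`` it is the least-squares rank-m approximation,
    whose residual variance is the sum of the dropped eigenvalues.
    """
    if pcs.shape[-1] != eigenvectors.shape[1]:
        raise ValueError("PC count must match eigenvector columns")
    m = eigenvectors.shape[1] if n_components is None else n_components
    if not 0 <= m <= eigenvectors.shape[1]:
        raise ValueError(f"n_components {m} out of range")
    recon = np.tensordot(pcs[..., :m], eigenvectors[:, :m], axes=([2], [1]))
    return recon + np.asarray(mean_spectrum)


def variance_percentages(eigenvalues: np.ndarray) -> np.ndarray:
    """Percent of total variance per component: 100 * Gamma_a / sum(Gamma)."""
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(ev < 0):
        raise ValueError("eigenvalues must be non-negative")
    total = ev.sum()
    if total == 0:
        raise ValueError("all eigenvalues are zero")
    return 100.0 * ev / total


def select_num_components(
    percentages: np.ndarray,
    threshold_pct: float = 99.0,
    fixed_m: int | None = None,
) -> int:
    """Number of components to keep.

    With ``fixed_m`` the choice is explicit and returned unchanged (the
    reference analysis fixed five components).  Otherwise the smallest m whose
    cumulative variance percentage reaches ``threshold_pct`` is returned.
    """
    if fixed_m is not None:
        if fixed_m < 1:
            raise ValueError("fixed_m must be >= 1")
        return int(fixed_m)
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold must be in (0, 100]")
    cum = np.cumsum(np.asarray(percentages, dtype=float))
    hit = np.nonzero(cum >= threshold_pct - 1e-12)[0]
    if hit.size == 0:
        raise ValueError(f"cumulative variance never reaches {threshold_pct}%")
    return int(hit[0]) + 1


def decompose(A: SpectralCube) -> EigenDecomposition:
    """Full band-space PCA of an absorbance cube."""
    if len(A.grid) < 2:
        raise ValueError("PCA requires at least two bands")
    centered, mean_spec = center_by_band_mean(A)
    S = band_covariance(centered)
    evals, evecs = eigendecompose(S)
    pcs = compute_principal_components(centered, evecs)
    pcs[~A.mask] = 0.0
    return EigenDecomposition(
        mean_spectrum=mean_spec,
        eigenvalues=evals,
        eigenvectors=evecs,
        pcs=pcs,
        variance_pct=variance_percentages(evals),
        grid=A.grid,
        mask=A.mask.copy(),
        group=A.group,
        individual=A.individual,
    )


def group_average_eigenvectors(
    decomps: list[EigenDecomposition], component: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and per-band std of eigenvector ``component`` across individuals.

    Eigenvector signs are acquisition-arbitrary, so each individual's vector
    is aligned to the first individual's before averaging (flipped when the
    dot product is negative).  The std gives the error bars of a
    group-representative eigenvector plot.
    """
    if not decomps:
        raise ValueError("empty decomposition list")
    grid0 = decomps[0].grid
    if any(d.grid != grid0 for d in decomps):
        raise ValueError("decompositions use different wavelength grids")
    ref = decomps[0].eigenvectors[:, component]
    aligned = []
    for d in decomps:
        v = d.eigenvectors[:, component]
        aligned.append(-v if float(v @ ref) < 0 else v)
    stack = np.stack(aligned)
    return stack.mean(axis=0), stack.std(axis=0)
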