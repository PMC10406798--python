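# mstissue

Multispectral absorbance imaging of thin tissue sections: band-space PCA,
PCA-derived endmembers, and non-negative spectral unmixing.

## The problem

Thin (micrometre-scale) paraffin-embedded tissue sections imaged in
transmission at a series of narrow wavelength bands form a multispectral
cube `T(x, y, λ)`: every pixel carries a transmission spectrum shaped by the
chromophores the light crossed.  Under the Beer–Lambert model for a section
of thickness *L*,

    T(x, y, λ) = exp(−Σ_j ε_j(λ) · C_j(x, y) · L)
    A(x, y, λ) = −ln T(x, y, λ) = Σ_j ε_j(λ) · C_j(x, y) · L

so the absorbance (optical density) *A* is **linear** in the chromophore
concentrations `C_j` with extinction spectra `ε_j`.  This package turns raw
per-band acquisitions (repeated camera frames with and without the sample)
into absorbance cubes and decomposes them:

1. **PCA in wavelength space.** After removing the per-band spatial mean
   ⟨A(λ)⟩, the N×N band covariance `S` is diagonalized, `S e_α = Γ_α e_α`.
   The unit eigenvectors `e_α(λ)` carry spectral trends; the principal-
   component images `PC_α(x, y) = Σ_λ e_λα Ā(x, y, λ)` are zero-mean,
   mutually uncorrelated, with spatial variance `Γ_α`.
2. **Endmember construction.** The pixel cloud spreads by `√Γ_α` along each
   eigenvector, so `E_α(λ) = ⟨A(λ)⟩ + 2√Γ_α e_α(λ)` is an extreme "pure"
   spectrum on the outside of the cloud — an endmember.
3. **Non-negative unmixing.** Each pixel spectrum `b` is decomposed as
   `b ≈ U x`, `x ≥ 0`, with `U = [E_1 … E_m]`, solved per pixel by NNLS.
   The abundance maps `Ab_k(x, y)` localize each spectral signature.
4. **Statistics.** Abundance pdfs, group-mean pdfs, high-abundance
   fractions, and group-mean absorbance spectra summarize differences
   between sample groups.

It is written for microscopists and image analysts working with
transmission multispectral stacks of stained-free tissue sections, and
ships a synthetic eye-section phantom generator (nested cornea / lens /
vitreous / retina / choroid regions, vessel-like blobs, five Gaussian-band
chromophores, CCD noise, 8-bit quantization, 50 frames per band) so the
entire chain is testable with known ground truth.

## Worked example

```python
import numpy as np
from mstissue import (eye_phantom, render_transmission_cube, simulate_acquisition,
                      recover_transmission, transmission_to_absorbance, decompose,
                      construct_endmembers, unmix_cube, high_abundance_fraction,
                      spectral_similarity, component_spectra)

spec = eye_phantom(shape=(128, 128), seed=1)          # 22 bands, 1% noise, 8-bit
T, truth = render_transmission_cube(spec)
refs, samples = simulate_acquisition(spec, T)          # 50 frames/band, ref + sample
A = transmission_to_absorbance(recover_transmission(refs, samples, spec.grid))

d = decompose(A)                                       # band-space PCA
print("top-5 variance %:", np.round(d.variance_pct[:5], 2),
      "cumulative:", round(d.variance_pct[:5].sum(), 2))

em = construct_endmembers(d, m=5, scale=2.0)           # <A> + 2*sqrt(G_a)*e_a
ab = unmix_cube(A, em)                                 # per-pixel NNLS
print("mean abundances:", np.round(np.nanmean(ab.maps, axis=(0, 1)), 3))
print("fraction of pixels with Ab_1 > 0.2:",
      round(high_abundance_fraction(ab.maps[:, :, 0], 0.2), 3))

angle, r = spectral_similarity(em.spectra[:, 0], component_spectra(spec.grid)[:, 0])
print(f"endmember 1 vs hemoglobin-like reference: angle {angle:.1f} deg, r = {r:.3f}")
```

prints

```
top-5 variance %: [76.79 15.93  5.94  1.02  0.15] cumulative: 99.84
mean abundances: [0.078 0.109 0.157 0.132 0.374]
fraction of pixels with Ab_1 > 0.2: 0.128
endmember 1 vs hemoglobin-like reference: angle 30.7 deg, r = 0.817
```

The five structural components of the phantom hold 99.84 % of the spectral
variance (the rest is averaged-down sensor noise); the NNLS abundances are
non-negative by construction, and about 13 % of pixels carry a strong
first-endmember (hemoglobin-like) signal — the vessel blobs and choroid.
The first endmember's spectrum is positively correlated with the
hemoglobin-like reference spectrum used to build the scene.

## Command line

The same workflow is scriptable from a shell; every stage is independently
invocable and writes a JSON run report (config echo, seed, checksums):

```bash
mstissue simulate -o data/ --seed 7            # 3 groups x 9 eyes x 22 bands
mstissue run -i data/ -o out/ -m 5             # absorb -> pca -> endmembers
                                               #   -> unmix -> report
```

Outputs are multi-page TIFFs with JSON sidecars plus CSV tables
(eigenvalues / variance percentages, eigenvectors by wavelength, endmember
spectra, abundance summaries, group pdfs).

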