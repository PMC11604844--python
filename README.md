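# xerecon

Reconstruction and analysis pipeline for dissolved-phase hyperpolarized
¹²⁹Xe gas-exchange lung MRI, exercisable end-to-end on digital lung
phantoms. Intended for MR-physics and image-reconstruction researchers who
want a tested, self-contained reference for multi-echo radial
spectroscopic imaging: k-space simulation, chemical-shift separation,
Kaiser-Bessel gridding, compressed-sensing reconstruction, gas-exchange
ratio mapping, and the fidelity/SNR evaluation machinery.

## The science in one page

Inhaled hyperpolarized ¹²⁹Xe resonates at three frequencies in the lung:
the alveolar airspace gas line, xenon dissolved in the alveolar membrane
(M, ~+197.7 ppm) and xenon in capillary red blood cells (RBC,
~+217.2 ppm). The voxelwise ratios **RBC:M**, **RBC:Gas** and **M:Gas**
are the clinical readouts of gas exchange. A four-echo 3D radial
acquisition (TE = 0.57/1.27/1.97/2.67 ms, TR 15 ms, 934 spokes, 32³
matrix, 40 cm FOV, flips 22°/0.22° on dissolved/gas) samples every k-space
point at four echo times, so each sample obeys

    s_e = Σ_c ρ_c · exp(i 2π Δf_c TE_e) · exp(−TE_e / T2*_c),

a per-sample linear system inverted (SVD pseudoinverse) to separate the
three channels in k-space. Each channel is then reconstructed either by
conventional Kaiser-Bessel gridding (oversampling 1.2, kernel width 8,
|k|² density compensation) or by compressed sensing,

    x̂ = argmin_x ‖Ax − y‖² + λ₁‖x‖₁ + λ₂‖Tx‖₁,   A = PF,

with P the spoke-subset sampling, F the non-uniform Fourier operator,
image-domain sparsity (Ψ = I — lung images have no background signal) and
anisotropic total variation T, solved by ADMM (λ₁ = 0.003, λ₂ = 0.0003
after data normalization). Retaining only the temporally first 467 of 934
spokes (AF = 2) halves the breath-hold from ~14 s to ~7 s while CS
suppresses noise; the package quantifies what that does to the ratio maps
(NMAE, CV, pixelwise regression, Bland-Altman, SNR, and the power law
NMAE = a·SNR^k).

A built-in phantom simulator generates everything needed to test this:
two-lung digital phantoms with configurable RBC:M / M:Gas targets and
focal defects, the full multi-echo radial forward model with
compartment-specific chemical shift and T2*, per-excitation reservoir
depolarization, and seeded complex Gaussian noise.

## Worked example

```python
from xerecon import pipeline
from xerecon.config import RunConfig
from xerecon.metrics import nmae, snr

cfg = RunConfig()                      # full protocol, healthy phantom, seed 0
phantom, container = pipeline.simulate_run(cfg)

grid, _ = pipeline.reconstruct(container, cfg, "gridding", af=1.0)
mask, maps_grid = pipeline.derive_maps(grid, cfg)

cs, _ = pipeline.reconstruct(container, cfg, "cs", af=2.0)
_, maps_cs = pipeline.derive_maps(cs, cfg, mask_source=grid)

print(f"gridding RBC SNR : {snr(grid.rbc, mask.mask):.1f}")
print(f"CS AF=2 RBC SNR  : {snr(cs.rbc, mask.mask):.1f}")
print(f"RBC:M  gridding  : {maps_grid.mean('rbc_m'):.3f}")
print(f"RBC:M  CS AF=2   : {maps_cs.mean('rbc_m'):.3f}")
valid = mask.mask & (maps_cs.rbc_m > 0) & (maps_grid.rbc_m > 0)
print(f"RBC:M NMAE       : {nmae(maps_cs.rbc_m, maps_grid.rbc_m, valid):.1f} %")
```

Output (seed 0):

```
gridding RBC SNR : 8.9
CS AF=2 RBC SNR  : 53.8
RBC:M  gridding  : 0.412
RBC:M  CS AF=2   : 0.410
RBC:M NMAE       : 8.5 %
```

The phantom was built with RBC:M = 0.41; both reconstructions recover it,
the accelerated reconstruction agrees with the fully sampled one to well
under 5 % in the mean, and CS raises RBC SNR several-fold by suppressing
background noise — at half the data, hence half the breath-hold.

The same stages are exposed as a CLI for file-based runs
(`xerecon simulate|recon|maps|evaluate|sweep`, each with `--config`,
`--seed`, `--out`; volumes are written as NIfTI, raw data as an HDF5
container, metrics as JSON/CSV).

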