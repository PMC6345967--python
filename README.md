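# tfmkit

Traction force microscopy (TFM) reconstruction: regularized and Bayesian
solvers for the elastic half-space inverse problem.

Adherent cells deform soft elastic substrates; TFM measures those
deformations (by tracking fiducial markers) and infers the traction stress
field the cell exerts. The inference step is a badly conditioned linear
inverse problem: the displacement samples **u** (2m values) are related to
the nodal traction **f** (2n values, Pa) through a dense operator built
from the Boussinesq surface Green's function

    G_ij(x) = (1 + ν) / (π E) [ (1 − ν) δ_ij / r + ν x_i x_j / r³ ],

so that **u** = **M f** + noise. Because cond(**M**) is very large, any
practical reconstruction penalizes the solution:

    f̂ = argmin_f ‖M f − u‖₂² + λ₁‖R₁ f‖₁ + λ₂‖R₂ f‖₂².

`tfmkit` is aimed at researchers who already have displacement fields (from
PIV/PTV tracking) and want reproducible traction maps without hand-picking
regularization parameters. It provides:

- **Forward model** — FFT-based assembly of **M** on regular traction grids
  with pyramidal shape functions, extended to arbitrarily placed
  displacement samples via the Fourier shift theorem, plus a direct
  quadrature reference.
- **Penalized solvers** — ridge (`L2Solver`), Lasso (`L1Solver`), Elastic
  Net with the (1 + λ₂) de-biasing (`ElasticNetSolver`), and proximal
  gradient / ISTA variants with orthonormal wavelet penalties
  (`ProximalGradientSolver`, the PGL and PGEN schemes).
- **Bayesian automatic regularization** — a Gaussian traction prior with
  inverse variance α and Gaussian noise with inverse variance β make the
  posterior maximizer exactly ridge regression at λ = α/β. Maximizing the
  marginal likelihood (evidence)

      log p(u|α, β) = −α E_f − β E_u − ½ log det A
                      + n log α + m log β − m log 2π,

  with A = αI + βM̃ᵀM̃ on the column-standardized problem, selects λ
  without user input. `BayesianL2Solver` (BL2) uses a separately measured β
  (e.g. from background displacement variance); `AdvancedBayesianL2Solver`
  (ABL2) infers α and β jointly.
- **Classical selection** — L-curve corner detection and generalized cross
  validation (GCV) baselines.
- **Synthetic benchmark** — scenes of circular traction spots on a
  25 μm × 25 μm, 10 kPa, ν = 0.3 substrate with semi-analytic
  displacements, random sampling and calibrated Gaussian noise.
- **Quality metrics** — DTMA, DTMB, SNR and DMA, comparing reconstructed
  and true traction inside/outside the spots.

All solvers are scikit-learn style estimators (`fit(X, y)` with X the
operator and y the stacked displacements; the fitted traction is `coef_`),
so they compose with sklearn model selection, and a `tfmkit` CLI covers the
simulate → reconstruct → evaluate loop.

## Worked example

```python
import numpy as np
from tfmkit import (TractionGrid, assemble_irregular, make_benchmark_scene,
                    sample_displacements, assign_patches, rasterize_traction,
                    evaluate)
from tfmkit.bayes import AdvancedBayesianL2Solver
from tfmkit.synthetic import NoiseSpec, add_noise, DEFAULT_PIXEL_SIZE

scene = make_benchmark_scene("fifteen_spot_0_250Pa", seed=1)
grid = TractionGrid(shape=(25, 25), mesh_constant=1.0, origin=(0.5, 0.5))
field = sample_displacements(scene, 800, seed=101)
op = assemble_irregular(field.positions, grid, scene.substrate)

# pixel units (0.1 um/pix); noise with beta = 400 pix^-2, i.e. sigma = 0.05 pix
op_pix = op.in_units("pix", DEFAULT_PIXEL_SIZE)
noisy = add_noise(field.in_units("pix", DEFAULT_PIXEL_SIZE),
                  NoiseSpec("inverse_variance", 400.0, seed=7))

est = AdvancedBayesianL2Solver().fit(op_pix, noisy.vectors)
print(f"beta_hat = {est.beta_:.0f} pix^-2, lambda_hat = {est.lambda_:.0f}")

labels = assign_patches(grid, scene)
real = rasterize_traction(scene, grid)
print(evaluate(est.coef_, real, labels))
```

Output:

```
beta_hat = 417 pix^-2, lambda_hat = 502
ErrorReport(dtma=-0.2952..., dtmb=0.1767..., snr=3.9517..., dma=-0.1062...)
```

The estimated inverse noise variance (417 pix⁻²) recovers the generating
value (400 pix⁻²) to within ~4% without being told the noise level; the
error report says the mean on-spot traction is underestimated by ~30% (the
usual L2 smoothing bias), the background is clean (|DTMB| ≪ 1) and spots
stand out at SNR ≈ 4. (One of the fifteen spots draws magnitude 0 Pa and
is excluded from the patch averages with a warning.)

The same loop from the shell:

```sh
tfmkit simulate --variant fifteen_spot_0_250Pa --m 800 --beta 400 --seed 1 --out run
tfmkit abl2 --displacements run_displacements.txt --scene run_scene.json \
            --mesh 1.0 --out traction.txt
tfmkit evaluate --traction traction.txt --scene run_scene.json
```

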