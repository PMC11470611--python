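# esomech

Planar-biaxial mechanics of esophageal soft tissue: Holzapfel-type
anisotropic hyperelastic fitting of equibiaxial stress–stretch curves, and a
small NARX recurrent network trained with Bayesian-regularized
Levenberg–Marquardt that learns to reproduce those curves.

## Who this is for

Tissue biomechanics groups running planar-biaxial tests on tubular organs
(esophagus, arteries, intestine) who want, from one set of stretch–stress
records: (i) constitutive parameters with physical meaning — ground-matrix
stiffness, fiber stiffness and stiffening exponent, fiber angle — and
(ii) a data-driven surrogate that predicts stress responses where a single
deterministic parameter set cannot follow the large specimen-to-specimen
spread typical of gross-anatomy soft tissue.

## The models

**Constitutive model.** Strain energy density (kPa ≡ kJ/m³)

$$W = \tfrac{c}{2}(I_1 - 3) + \tfrac{k_1}{k_2}\left[e^{k_2 (I_4-1)^2} - 1\right]$$

with $I_1 = \lambda_\theta^2 + \lambda_z^2 + \lambda_r^2$,
$I_4 = \lambda_\theta^2\cos^2\theta + \lambda_z^2\sin^2\theta$,
incompressibility $\lambda_r = (\lambda_\theta\lambda_z)^{-1}$, and plane
stress $\sigma_{rr}=0$ eliminating the hydrostatic pressure:

$$\sigma_{\theta\theta} = 2(\lambda_\theta^2 - \lambda_\theta^{-2}\lambda_z^{-2})\,\partial_{I_1}W + 2\lambda_\theta^2\cos^2\theta\,\partial_{I_4}W,\qquad
\sigma_{zz} = 2(\lambda_z^2 - \lambda_z^{-2}\lambda_\theta^{-2})\,\partial_{I_1}W + 2\lambda_z^2\sin^2\theta\,\partial_{I_4}W.$$

Parameters are estimated by bounded Levenberg–Marquardt least squares,
either jointly over both directions or independently per direction.  Fits
are scored by the normalized error
$\varepsilon = \sigma_{\mathrm{ref}}^{-1}\sqrt{\sum r_i^2/(n-q)}$ with
$\sigma_{\mathrm{ref}}$ the mean predicted stress, and by the Pearson
correlation.

**Surrogate network.** A 1-5-1 NARX recurrence with tapped delays {1, 2} on
the strain input and the stress feedback (31 adjustable parameters),

$$\hat y(t) = \mathbf{LW}^{out}\,\mathrm{tansig}\!\left(\mathbf{IW}\,u_{lags} + \mathbf{LW}^{fb}\,y_{lags} + \mathbf{b}^1\right) + b^2,$$

trained open-loop (teacher forcing) on the objective
$F(\mathbf w) = \beta E_D + \alpha E_w$; after each accepted LM step the
hyper-parameters follow the evidence update
$\gamma = k - 2\alpha\,\mathrm{tr}(\mathbf H^{-1})$,
$\alpha = \gamma/2E_w$, $\beta = (N-\gamma)/2E_D$, where $\gamma$ is the
effective number of parameters.  Evaluation runs closed-loop, feeding back
the network's own predictions.  Targets are normalized by the ensemble's
global maximum stress — without this the saturating hidden layer plateaus
far below the data maximum.

Because the raw laboratory data are not public, a synthetic-data module
generates ensembles with the documented statistical envelope (ramp to 50%
strain over 8.5 s at a decaying 8→4 %/s rate, toe region to ~40% strain,
axial stresses roughly twice circumferential, a near-flat "poor" specimen
class), so the entire pipeline is testable offline.

## Worked example

```sh
python examples/03_train_narx.py
```

```
architecture 1-5-1, delays (1, 2)/(1, 2), 31 adjustable parameters

final cycle: 1000 epochs, stop reason 'max_epochs'
  mse       1.48e-06
  gradient  7.94
  mu        5
  effective number of parameters gamma = 11.1 of 31
  sum of squared weights E_w = 17.28

closed-loop replay: max |error| 0.0028 on the normalized scale (target max 0.559)
```

The network was trained on the Holzapfel fit of one good-class specimen;
γ ≈ 11 of 31 means the regularizer pruned the weights the data do not
constrain, and the closed-loop replay error of 0.3% of the stress scale
shows the recurrence is stable when fed its own outputs.  The other
examples cover ensemble generation and curation (`01`), constitutive
fitting (`02`), recomputing the published evaluation statistics (`04`), and
the full pipeline (`05`).  A thin CLI mirrors these capabilities
(`esomech simulate-data | fit-holzapfel | train-narx | evaluate | anova |
run-all`).

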