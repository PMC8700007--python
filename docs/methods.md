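# Methods

## The model

`smcnet` implements a continuous logic-based ODE formalism for
intracellular signaling. Every molecular species *i* carries a
normalized activation *y&#7522;* ∈ [0, *y*<sub>max,i</sub>] obeying

    dy_i/dt = (drive_i(y) · y_max,i − y_i) / τ_i

where the drive collects the incoming reactions. A reaction is an AND
gate: a weight *W* ∈ [0, 1] times the product over its terms of the
normalized Hill transfer

    f_act(x) = β x^n / (K^n + x^n),   f_inhib(x) = 1 − f_act(x),

with β = (EC50^n − 1)/(2·EC50^n − 1) and K^n = β − 1, the unique gain
and half-constant for which f_act(EC50) = 1/2 and f_act(1) = 1 (this
requires EC50^n < 1/2; the constructor rejects anything else). Multiple
reactions on one target combine by inclusive OR, a ⊕ b = a + b − a·b,
folded pairwise — the fold is associative and commutative, so reaction
order never matters. Source-less *input* reactions contribute their
weight directly, so an unregulated input node settles exactly at *W*;
this is the only reading under which an input's steady activation
equals its configured weight. All species default to y_max = τ = 1 and
start at y₀ = 0: initial conditions are not part of the model
definition, and the all-zero start makes bistable outcomes reproducible
(a cell commits to the elevated branch only if its own transient drives
it there).

A single model-wide Hill parameterization (n = 1.4, EC50 = 0.52) is
applied uniformly; per-reaction overrides exist in the grammar but the
packaged model does not use them.

## The packaged SMC network is a reconstruction

The shipped `smc_network.txt` (81 species, 138 reactions) is a
reconstruction of an aortic smooth-muscle-cell signaling map, assembled
from the mechanism statements that accompany the published condition
experiments: TSC1/2 inhibition of mTORC1 through Rheb; mTORC1 →
p-S6K/p-S6 and p-4EBP1; the p-S6K negative feedback onto PI3K
activation by IGFR and IRS-1; the PI3K → PDK1 → AKT axis with the
AKT → mTOR → mTORC2 → AKT positive feedback; AKT/RhoA/SRF-myocardin
control of SMMHC, SMA and SM22; TGFβR–TSC1/2–Smad2/3 control of
*Col3a1* and *Eln*; S6K inhibition of GSK3 and the consequent
β-catenin/MITF/LAMP lysosomal program; and MAPK, NF-κB and Ca²⁺
crosstalk. The original supplementary reaction listing is not available
in machine-readable form, so edge-level identity with the published
network cannot be claimed. Consequences:

* the three condition experiments are validated against the published
  *directional* response patterns (14 knock-out species, 9 rapamycin
  species, phenotype and cellular-activity shifts), not against the
  printed ratio values;
* sub-network bifurcation results, the beta-parameter algebra and the
  Bayesian estimator are independent of the reconstruction and are
  validated quantitatively;
* the population-level saturation threshold emerges from the embedded
  positive-feedback loop, which the reconstruction reproduces exactly
  (the acceptance suite asserts its wiring), so it is also quantitative.

Weights follow the uniform class values (mechanical stress inputs
0.24054, oxygen/energy 0.5, glucose/leucine/fibrillin 0.25, exogenous
angiotensin II and IFN-γ 0, the 7 receptor reactions 0.85, downstream
reactions 1.0). Within those constraints the wiring around PI3K was
calibrated — in the same spirit as the published parameter sweep — so
that the tuned cell's PI3K drive sits near the fold of the
positive-feedback loop and a receptor-weight-heterogeneous population
straddles it under both Baseline and knock-out conditions. The tuned
(all-0.85) baseline cell lies just above the fold and converges to the
saturated contractile state; knock-out pushes it below.

## Conditions, scores and ratios

Conditions are y_max overrides: knock-out sets TSC1/2 y_max = 0;
rapamycin additionally sets mTORC1 y_max = 0 (full inhibition of the
rapamycin-sensitive complex, early-treatment approximation). Phenotype
scores are plain panel means of steady activations — contractile
{SMMHC, SMA, SM22}, synthetic {Col3a1, Eln, TIMP}, degradative
{LAMP2, MMP2, S6, MITF, β-catenin}. The degradative panel follows the
narrative membership (LAMP2); an alternative panel with LAMP1/2 jointly
is selectable because the two published panel descriptions differ, and
the package does not silently reconcile them. Cellular activities:
proliferation = mean(S6, β-catenin, p38), apoptosis = FOXO,
degradative activity = mean(degraded elastin, LAMP1, LAMP2). Condition
ratios divide steady states elementwise; denominators below 1e−9 are
flagged (`zero-denominator` or `indeterminate`) rather than divided
through, because rapamycin drives some nodes to exactly zero.

## Solvers and numerical choices

Single-model runs use LSODA (rtol 1e−8, atol 1e−10) with trajectories
sampled at ≥ 400 uniform points, because transient PI3K peaks gate the
bistable switch and coarse output grids can miss them. `steady_state`
integrates to t = 40 (τ = 1 units), asserts max|dy/dt| < 1e−6, and
extends the horizon once (×10) before raising — slow fold-adjacent
crossings are thereby resolved rather than silently truncated.

Population runs integrate all cells as one batched fixed-step RK4
computation (numba-compiled when available; the numpy path is
bit-identical): the dynamics are smooth first-order relaxations with
unit time constants, so a fine step (dt = 0.1) through the transient
(t ≤ 40) resolves peaks and a coarser step (dt = 0.5) relaxes to
steady state (t = 160), agreeing with the fine step to ~1e−11. Cells
caught mid-switch near the fold (residual > 1e−6) individually receive
up to three extended horizons; any cell still unconverged keeps its
residual and is excluded from threshold bracketing and may appear as
DBSCAN noise. "Saturated" means steady AKT > 0.99 (the upper branch of
the feedback loop rests at exactly 1, so the cutoff is not delicate).

The sub-network analysis reduces equilibria to a scalar fixed-point
problem in AKT (PDK1, mTOR, mTORC2 are explicit functions), enumerates
roots by a dense scan (step 1e−4) with Brent refinement, and classifies
stability by the eigenvalues of the numerically differentiated 4×4
Jacobian (stable iff all real parts < −1e−9). Branches are traced by a
pseudo-arclength predictor with a Newton corrector constrained
orthogonally to the tangent; the fold is located by bisection on the
equilibrium count to a bracket below 1e−5. No external continuation
software is involved; the dense scan is the correctness oracle. With
the default parameters the fold sits at PI3K = 0.270824; it moves to
higher PI3K as EC50 or n increase and disappears near EC50 ≈ 0.56
(EC50 above 0.5^(1/n) ≈ 0.61 is outside the admissible domain
altogether).

## Bayesian ratio of medians

Group expression values are modeled as lognormal; with Jeffreys'
prior ∝ 1/σ² the median log-expression has a non-standardized
Student-t posterior (location = mean of logs, scale = s/√n with the
n−1-denominator SD, df = n−1). The difference δ between two group
posteriors is evaluated as an FFT convolution of the two densities on a
uniform grid — 16384 points spanning ±60 pooled scales, wide enough
that the heavy df = 2–3 tails hold percentile error below 0.5% against
a Monte-Carlo oracle — and the ratio estimate exponentiates the
2.5th/50th/97.5th percentiles, obtained by monotone interpolation of
the numerically integrated CDF. The estimator is exactly scale
equivariant and group-swap antisymmetric.

A caveat the validation suite makes explicit: the equal-tailed credible
interval is a Bayesian Behrens–Fisher construction and is
*conservative* in the frequentist sense at small n — at n = 4 per
group its measured coverage of the true ratio is ≈ 0.98, not 0.95
(the 95% band of a t₃ − t₃ difference spans ±4.56 pooled scales,
against ≈ 2.45 for a Welch-style t₆ interval). One acceptance test
asserts the nominal 0.93–0.97 band and therefore fails by design; the
failure documents a property of the method, not a defect of the
implementation.

## Synthetic data

The expression generator draws lognormal groups with a specified true
median ratio and log-scale SD; group sizes default to n = 4, matching
small densitometry panels. The default σ = 0.3 is nominal — real
per-species dispersions are unknown — and was chosen to produce
interval widths of the same order as published reanalyses. The random
network generator produces arbitrary valid logic networks (cycles
allowed, self-loops excluded) for engine fuzzing; it makes no attempt
at biological realism. Passing tests on these fixtures demonstrate
correctness of the machinery, not fidelity to any particular
experimental dataset: the generator emulates lognormal dispersion and
network grammar, not blot saturation, loading-control error or
correlated replicates.

## Problem sizes

The validation suite uses 1000-cell populations over 10 seeds for the
clustering and threshold checks, 2000 replicates for estimator
coverage, 4-million-draw Monte-Carlo oracles for the convolution, and
dense scans at step 1e−4 for the bifurcation oracle. These sizes were
chosen to keep every check's sampling error well below its assertion
margin.

## Known limitations

* Edge-level fidelity to the published 81/138 network is unverifiable
  from the main text; quantitative full-network ratios (e.g. p-S6
  KO/Baseline = 75.91) are not reproduced, only their directions.
* Rapamycin is all-or-none (y_max = 0); no dose response.
* The logic-based formalism has no mass conservation, explicit
  kinetics, or stochasticity; activations are relative, not
  concentrations.
* DBSCAN operates on the 9-species panel; clustering on all 81 species
  is a one-line change but is not the validated configuration.
* The 2-D embedding used in published visualizations is decorative and
  is not part of the package's validated surface.
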