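# pymt-tme

Data-driven ODE analysis of the breast-tumor microenvironment in the
MMTV-PyMT mouse model.

The package is for systems biologists and modelers who want to fit,
simulate and interrogate a compact tumor–immune interaction network
against sparse immune-deconvolution time courses. It ships the
three-mouse study dataset (four sampling days over weeks 6–12 of tumor
progression), the full estimation/simulation/sensitivity pipeline, and a
synthetic-data layer for validating the pipeline against known ground
truth.

## The model

Fifteen coupled ODEs describe naive/helper/cytotoxic/regulatory T cells
(T_N, T_h, T_c, T_r), naive and activated dendritic cells (D_N, D),
naive and activated macrophages (M_N, M), cancer cells (C), necrotic
cells (N), cancer-associated adipocytes (A), and the cytokines HMGB1
(H), IL-12, IL-10 and IL-6. Immune compartments follow mass-action
activation/decay chains, e.g.

    dT_h/dt = (λ_ThH·H + λ_ThD·D + λ_ThIL12·IL12)·T_N
              − (δ_ThTr·T_r + δ_ThIL10·IL10 + δ_Th)·T_h,

cancer grows logistically, promoted by IL-6 and adipocytes and killed by
cytotoxic cells,

    dC/dt = (λ_C + λ_CIL6·IL6 + λ_CA·A)(1 − C/C₀)·C − (δ_CTc·T_c + δ_C)·C,

adipocytes follow an independent logistic law, and a fixed fraction
α_NC = 1.5 of the cancer death flux feeds the necrotic pool. All
variables are nondimensionalized by their maxima over all mice and
times, so every observation lies in [0, 1]; the carrying capacities are
fixed at C̄₀ = Ā₀ = 2.

Given observed states, every equation is **linear in the 57 rate
parameters θ**, so stacking one row per (mouse, time, equation) with
central/one-sided finite-difference slopes on the right-hand side gives
a linear model A·θ ≈ b. The rates are estimated by box-constrained
least squares, min ‖Aθ − b‖₂² s.t. θ ≥ θ_min = 10⁻⁵. Downstream, the
forward (direct-differential) sensitivity system dS/dt = (∂f/∂x)S +
∂f/∂θ ranks parameters by the magnitude of ∂C̄(126 d)/∂θ averaged over
a ±10% parameter box with a level-1 sparse quadrature grid (115 nodes),
and one-parameter scans record cancer load at day 42 over [0, 0.2].

## Worked example

```python
import numpy as np
import pymt_tme as pt

model = pt.TumorImmuneModel.builtin()   # the embedded 3-mouse dataset
result = model.fit()                    # bounded least squares
print(result.summary())
```

```
Tumor-microenvironment ODE model — bounded least-squares fit
==============================================================
observations (rows):    180    parameters: 57
numerical rank of A:     57    effective rank (rtol 1e-3): 56
condition number of A: 3.86e+06
theta_min: 1e-05    endpoint rows: onesided
||A theta - b||  bounded: 0.234758   unconstrained: 0.193482
parameters at the bound: 26
...
```

180 rows are 3 mice × 4 days × 15 equations. The design is full rank at
machine precision but severely ill-conditioned (one direction below the
practical rtol 10⁻³ threshold), and 26 of 57 rates sit at the 10⁻⁵
bound — with four sampling days many rates are simply not identifiable,
which the summary reports instead of hiding.

```python
traj = result.simulate(1, horizon=42)
print(traj.component("C", "dimensional")[-1])   # 74.919
```

Integrating the *fitted* rates from the mouse-1 day-0 state predicts a
day-42 cancer abundance of 74.9 against the observed 83.5 (−10%): the
logistic cancer kinetics estimated from four finite-difference slopes
track the data to first order.

```python
rep = result.sensitivity(2, "cancer", step=0.05)
print(rep.top(6))
# ('delta_C', 'lambda_C', 'lambda_IL6A', 'delta_CTc', 'lambda_CA', 'lambda_IL6M')

curve = result.bifurcation("delta_A", grid=np.linspace(0, 0.2, 5))
print(np.round(curve.values[1], 3))
# [74.962 74.367 74.132 74.018 73.954]
```

The cancer decay rate δ_C is the single most influential parameter, and
the scan shows cancer load falling monotonically as the adipocyte death
rate δ_A rises — the model's central claim that adipocyte- and
IL-6-related rates are the actionable levers on tumor burden.

The published fitted rate vector ships as a fixture
(`pt.table3_parameters()`) and can be substituted for the refit
everywhere; see `docs/methods.md` for how the two differ and why.

A command-line interface mirrors the library:

```bash
pymt-tme fit --out params.json
pymt-tme simulate --mouse 1 --out traj.csv
pymt-tme sens --mouse 1 --output cancer --out report.json
pymt-tme bifurcate --param lambda_CA --out curve.csv
pymt-tme synth --sigma 0.05 --seed 7 --out synth.csv
pymt-tme recover --data synth.csv --out recovery.json
pymt-tme all --outdir results/
```

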