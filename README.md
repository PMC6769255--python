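# cratherm

Statistical-thermodynamic modelling of gene activation by combinations of
synthetically targeted enhancers, with the supporting quantifications a
CRISPRa/CRISPRi enhancer study needs: ΔΔCt expression analysis, region-level
ChIP-seq normalization, necessity/sufficiency z-scores, and relative-importance
analysis of genomic predictors.

## The problem

Genes are often regulated by several enhancers at once — for estrogen-responsive
genes, several estrogen-receptor binding sites (ERBSs). Targeting a synthetic
activator (dCas9 fused to VP16 multimers or the p300 catalytic core) to single
sites and to combinations of sites measures each enhancer's *sufficiency*;
targeting a synthetic repressor measures its *necessity*. The question the model
answers: given relative expression for the combinatorial design (control, each
single site, each pair, all sites), what interaction energies between
activators, enhancers, and RNA polymerase II explain the pattern — and in
particular, do enhancers cooperate or act independently?

## The model

The system is `n` enhancer sites plus one promoter/RNAPII unit. A *system
state* `s` is a binary occupancy vector σ; its relative energy is

```
E_s = Σ_i σ_i q_i  +  Σ_{i<j} σ_i σ_j ω_{i,j}
```

where `q` terms are protein:DNA energies (activator:site, RNAPII:promoter) and
`ω` terms are protein:protein energies (activator:activator between sites,
activator:RNAPII between a site and the promoter). Each state gets a Boltzmann
weight `W_s = exp(−E_s / RT)` (T = 310.15 K, R in kcal·mol⁻¹·K⁻¹). An
*experimental state* `e` — the set of sites targeted by the effector — restricts
the admissible system states: untargeted sites are pinned unbound (in inhibition
mode, targeted sites are pinned instead). The probability that RNAPII occupies
the promoter is the Shea–Ackers partition ratio

```
p(RNAPII)_e = Σ_{s admissible, promoter bound} W_s / Σ_{s admissible} W_s
```

Expression is assumed proportional to `p(RNAPII)`, so parameters are fitted by
maximizing the Pearson correlation between the modelled occupancies and the
measured relative expression across all conditions. Because the correlation
surface has many local optima, fitting runs from many uniform random starts in
`[−5, 5]` per energy with **two** bound-constrained optimizers — L-BFGS-B and a
derivative-free Hooke–Jeeves pattern search — and every fit within 0.1 of the
best correlation forms the reported ensemble (mean ± 2.5/97.5 percentiles per
energy). For three sites there are 10 free energies.

## Worked example

Simulate a three-site combinatorial activation study (8 conditions, 4
replicates, 5% replicate noise) and fit it:

```python
import cratherm as ct

cfg = ct.SimulationConfig(seed=3, noise_sd=0.05)
table, truth = ct.simulate_expression(cfg)
print(table.frame.round(3).to_string(index=False))

model = ct.EnhancerActivationModel(table)
results = model.fit(n_starts=50, seed=1)
print(results.summary())
```

which prints

```
targeted       mode  mean_rel_expression   sem  n_replicates
 control activation                7.148 0.759             4
       1 activation               30.794 1.133             4
       2 activation                0.793 0.479             4
       3 activation               18.473 0.842             4
     1+2 activation               17.950 0.613             4
     1+3 activation               29.982 0.976             4
     2+3 activation                3.694 1.224             4
   1+2+3 activation               29.855 0.633             4

Enhancer activation occupancy model — multi-start fit
========================================================
conditions fitted:    8
fits (starts x alg):  100
selected (tol 0.10):  86
best Pearson r:       1.0000
--------------------------------------------------------
parameter           mean      2.5%     97.5%
q_site1           -1.544    -5.000     2.852
q_site2           -1.965    -5.000     1.118
q_site3            2.399    -4.935     5.000
q_promoter        -0.439    -4.993     1.876
omega_1,2         -0.190    -5.000     5.000
omega_1,3         -0.281    -4.874     4.286
omega_2,3         -0.257    -5.000     5.000
omega_pol1        -3.813    -5.000    -0.330
omega_pol2         2.864     0.164     5.000
omega_pol3        -1.713    -4.984     4.008
========================================================
```

Reading it: 100 fits (50 starts × 2 optimizers) reach a perfect correlation at
the top of the ensemble; 86 land within 0.1 of it. The site–RNAPII couplings
(`omega_pol*`) carry the per-site activation strengths — site 1 strongly
favourable, site 2 unfavourable — while the site–site couplings (`omega_*,*`)
centre near zero with wide intervals: the simulated enhancers act independently
and the ensemble correctly refuses to claim cooperativity. Energies are in
kcal/mol; negative is favourable.

`results.conf_int()`, `results.fittedvalues()`, and
`results.plot_param_distributions()` expose the interval table, the modelled
occupancies, and the per-parameter ensemble histograms.

## Command line

The same pipeline is scriptable end to end; every run writes a JSON manifest
(config, seed, input checksums, outputs):

```bash
cratherm simulate --noise-sd 0.05 --seed 3 --outdir run/
cratherm fit run/expression.tsv --n-starts 1000 --seed 1 --outdir run/
cratherm ddct ct.tsv --reference-gene CTCF --control-condition control
cratherm chip-norm counts.tsv libs.tsv --reference-bed controls.bed --method control_mean
cratherm importance predictors.tsv response.tsv
```

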