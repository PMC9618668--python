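# mixedstock

Many-to-many Bayesian mixed stock analysis of mitochondrial control-region
haplotypes, for population geneticists and marine-turtle biologists who need
to trace juveniles sampled at sea back to their natal rookeries.

Sea turtles nest at their natal beach, so rookeries carry characteristic
mtDNA haplotype frequencies, while juveniles disperse on ocean currents and
mix at foraging and oceanic habitats. Given per-rookery baseline haplotype
counts `X` and per-site haplotype counts `Y` of sampled juveniles,
`mixedstock` estimates the composition of every sampled mixed aggregation
over all candidate rookeries *jointly*. Each rookery `r` has a destination
vector `φ_r` over the M sampled stocks plus an "unknown" sink (so rookeries
are not forced to contribute only to sampled sites), a baseline frequency
vector `f_r ~ Dirichlet(β)`, and the stock-centric contributions are obtained
by scaling rookery output by rookery size `N_r` (nests/year):

```
φ_r ~ Dirichlet(α_r)                    θ_{m,r} = N_r φ_{r,m} / Σ_r' N_r' φ_{r',m}
X_r ~ Multinomial(f_r)                  Y_m | θ, f ~ Multinomial(Σ_r θ_{m,r} f_r)
```

Ocean-current transport probabilities `p_{r,m}` (from particle back-tracking,
consumed as input data) scale the prior: `α_r ∝ (p_{r,1} … p_{r,M}, residual)`,
and rookeries with zero transport probability to every sampled stock are
excluded. Switching the transport prior and the augmentation of the mixed
sample with previously published individuals on/off yields the four standard
model variants. The posterior is sampled by Metropolis-within-Gibbs MCMC with
latent source assignments, and convergence is checked with the Gelman–Rubin
shrink factor (threshold 1.2). See `docs/methods.md` for the full model,
priors, sampler and design rationale.

The package also provides haplotype utilities (FASTA and count-table I/O,
exact-identity haplotype assignment, truncation of long fragments to the
~500-bp window shared with legacy baselines and collapsing of haplotypes that
become indistinguishable there), registry curation (deduplication, name
disambiguation, five-bin life-stage metadata and basin/life-stage gap
reports), and a synthetic-data generator with known truth for end-to-end
validation.

## Worked example

Simulate a small six-rookery system with transport covariates, fit the
transport-scaled model variant, and summarize:

```
$ mixedstock simulate --seed 11 --rookeries 6 --stocks 2 --haplotypes 10 \
    --baseline-size 60 --mixed-sizes 80,40 --outdir sim
$ mixedstock fit --baseline sim/baseline.csv --mixed sim/mixed.csv \
    --variant 2 --iterations 20000 --burn-in 10000 --chains 4 --seed 3 \
    --orphan-policy drop --outdir fit
$ mixedstock report --rundir fit/model2
worst shrink factor: 1.0015 (phi[R04,unknown])
stock S1:
  R03: 0.633 [0.469-0.774]
  R05: 0.231 [0.119-0.377]
  R04: 0.054 [0.000-0.161]
stock S2:
  R02: 0.905 [0.809-0.972]
  R06: 0.044 [0.002-0.105]
  R01: 0.040 [0.000-0.132]
```

Each line is a rookery's posterior mean contribution to that mixed stock with
its equal-tailed 95% credibility interval; the shrink factor below 1.2 says
the four chains agree. The generating truth for this seed put 0.61 of stock
S1 from rookery R03 and 0.82 of S2 from R02 — both inside the reported
intervals. `fit/model2/` also contains `summary.csv`, `summary_phi.csv` (each
rookery's destination vector including the unknown sink), `convergence.csv`,
thinned `draws.csv` and a JSON manifest recording seeds, settings and any
excluded zero-transport rookeries.

The same analysis is scriptable from Python:

```python
import mixedstock as ms

baseline = ms.read_baseline_table("sim/baseline.csv")
mixed = ms.read_mixed_table("sim/mixed.csv")
baseline, mixed = ms.harmonize(baseline, mixed, on_orphan="drop")
spec = ms.build_model(baseline, mixed, variant=2)
result = ms.fit(spec, baseline, mixed, chains=4, iterations=20_000,
                burn_in=10_000, seed=3)
print(result.convergence.max_rhat)
print(result.summary.theta.head())
```

A full multi-variant run is driven by one YAML config via `mixedstock run
--config run.yaml` (keys mirror `mixedstock.pipeline.RunConfig`); `mixedstock
recover` runs the simulate-and-refit calibration experiment, and `mixedstock
curate` deduplicates a haplotype registry and reports basin/life-stage
sampling gaps.

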