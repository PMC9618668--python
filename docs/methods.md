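# Methods

## The estimation problem

Female sea turtles nest at their natal rookery, so mitochondrial control-region
haplotype frequencies differ among rookeries while juveniles disperse and mix
at sea. Given (i) baseline haplotype counts `X[r, h]` from R candidate
rookeries and (ii) haplotype counts `Y[m, h]` of juveniles sampled at M mixed
aggregations, mixed stock analysis estimates the composition of each
aggregation over source rookeries. `mixedstock` implements the holistic
many-to-many formulation: all rookeries and all sampled aggregations are
estimated jointly, and every rookery's output is a probability vector over the
M sampled destinations plus one "unknown" sink, so no rookery is forced to
send all of its juveniles to the places that happened to be sampled.

## Model

Rookery-centric destination vectors and baseline frequencies get Dirichlet
priors:

    phi_r ~ Dirichlet(alpha_r)   on the (M+1)-simplex (last = unknown sink)
    f_r   ~ Dirichlet(beta)      on the H-simplex
    X_r   ~ Multinomial(f_r)

The mixture-centric composition scales each rookery's output by its size
`N_r` (nests/year):

    theta[m, r] = N_r * phi[r, m] / sum_r' N_r' * phi[r', m]

Each individual sampled at aggregation m carries a latent source
`z ~ Categorical(theta[m, :])` and a haplotype drawn from `f_z`. The two
ecological covariates enter separately and are therefore independently
switchable:

* **rookery size** acts only through the deterministic theta transform;
* **ocean-current transport probability** `p[r, m]` (from particle
  back-tracking, consumed as input data) acts only through the prior:
  `alpha_r = c * normalize(max(eps, (p_r1 … p_rM, residual)))` with the
  unknown sink receiving the residual `max(0, 1 − Σ_m p_rm)`.

Four model variants arise from the covariate switches and from whether the
mixed table was augmented with additional published samples before entry
(variants 3/4; the augmentation is a data-preparation step, pooled into the
matching stock upstream of the engine and configurable there). Variants 2/4
exclude rookeries whose transport probability is zero for every sampled
stock — currents cannot deliver their hatchlings within the drift horizon.

### Hyperparameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `c` | 1 | total prior mass per rookery destination vector; weakly informative |
| `beta` | 1/H per haplotype | standard weakly informative baseline-frequency prior; configurable |
| `eps` (prior floor) | 1e-3 | a zero Dirichlet hyperparameter is ill-posed; the floor keeps every destination reachable a priori |

Mixed-stock individuals update `f` jointly (the fully Bayesian treatment); a
`freeze_f` switch fixes `f` at its baseline-only posterior for sensitivity
checks.

## Sampling

The posterior density (`log_posterior`) is the contract; the sampler is an
implementation choice verified against independent oracles. Each iteration:

1. **phi rows** — Metropolis-within-Gibbs with a Dirichlet proposal centered
   on the current row (`Dirichlet(kappa_r * phi_r + 0.05)`), evaluated against
   the *z-collapsed* conditional `p(phi | f, Y)`. Collapsing the latent
   sources out of this move leaves the joint posterior invariant (z is
   refreshed from its full conditional within the same sweep) and shortens
   autocorrelation times by roughly an order of magnitude relative to
   conditioning on the current assignments, whose strong coupling with phi
   otherwise dominates mixing.
2. **f rows** — the same collapsed Metropolis move against
   `p(f_r | phi, X, Y)`; important when baselines are small and the
   assignment-conditional update barely moves.
3. **z** — latent sources per (stock, haplotype) cell,
   `P(z = r) ∝ theta[m, r] * f[r, h]` (only cell counts matter, so this is a
   broadcasted multinomial).
4. **f** — conjugate refresh, `Dirichlet(beta + X_r + assigned counts)`.

Proposal concentrations adapt toward 25% acceptance during burn-in only
(multiplicative updates every 64 iterations, clipped to [2, 1e6]); the
post-burn-in kernel is fixed, so retained draws come from a time-homogeneous
chain. Chains start overdispersed: phi from its prior, f from the
baseline-only posterior; a non-finite density at the start triggers a bounded
number of redraws. Simplex draws are floored at 1e-12 and renormalized, which
keeps every log finite; points that would zero out an observed haplotype get
density −inf and are simply never accepted.

Determinism and label handling: all randomness flows from one
`numpy.random.SeedSequence`; per-chain streams are spawned from the master
seed. Rookery order is canonicalized (lexicographic by code) inside the
sampler and mapped back to input order on output, so permuting rookery input
order permutes every output exactly, bit for bit. Outputs preserve input
order everywhere; ties cannot arise because codes are unique.

Defaults mirror the study settings: 100,000 iterations, 50,000 burn-in, and —
since the study does not state a chain count — 4 chains, no thinning.

## Diagnostics and summaries

The classic Gelman–Rubin potential scale reduction factor is computed per
scalar theta and phi parameter: `W` = mean unbiased within-chain variance,
`B` = n·Var(chain means), `Vhat = ((n−1)/n)W + B/n`, `Rhat = sqrt(Vhat/W)`,
flagged at the conventional 1.2. Constant chains return 1 by convention; a
rank-normalized variant is available but off by default because the classic
statistic is the one mixed-stock practice reports. Summaries are posterior
means with equal-tailed 95% credibility intervals using linear-interpolation
quantiles.

## Haplotype handling

Sequence identity is literal character identity after uppercasing and gap
stripping; IUPAC ambiguity codes are ordinary characters, never wildcards —
named haplotypes are defined by exact sequence, and wildcard matching would
silently merge lineages. Long fragments are truncated to a half-open window
(default `[0, 490)`) to match the short fragments that dominate published
rookery baselines; the exact coordinates used by any given study are rarely
stated, so the default is an explicit, overridable stand-in. Haplotypes
identical on the window collapse into one class labelled by the
lexicographically smallest member. Harmonization sums same-class columns and
conserves every row total exactly. A mixed-stock haplotype class absent from
every baseline ("orphan") leaves the mixture likelihood undefined: the
default is a hard error, with an explicit drop-with-warning option because
silent dropping biases estimates low for the sources the orphans came from.

Registry curation merges identically sequenced records (canonical name:
dominant nomenclature prefix for the species, then earliest publication year,
then lexicographic — a deterministic, logged approximation of "most
consistent with others for the species"), renames colliding names of distinct
sequences by appending the author, bins life stages into five categories
(dispersal-stage juvenile; post-dispersal juvenile; mixed post-dispersal
juvenile/in-water adult; in-water adult; rookery) through a strict controlled
vocabulary — strandings are assumed to occur near foraging sites — and
reports empty (species × life stage [× basin]) cells as sampling gaps.
Indo-Pacific provenance is recorded as both Indian and Pacific unless the
source says otherwise.

## Synthetic data

`simulate_system` emulates the statistical structure the analysis assumes:
strongly differentiated rookery frequencies (Dirichlet mass 0.15 per allowed
haplotype, 20% of haplotypes private to one rookery), log-normal rookery
sizes (median ≈ 2000 nests/year, sigma 1.5 on the log scale), Beta(2,2) total
transport reach split across stocks, and true phi drawn from the same
transport-scaled prior the fit uses, with theta derived through the size
transform. The default preset matches the study's dimensions: R=17, M=2,
H=25, baselines of 50, mixed samples of 141 and 10. Because truth is drawn
from the model's own prior on phi, repeated simulate-and-fit rounds act as a
self-consistency check: posterior means should be close to unbiased and
nominal intervals close to nominal coverage.

What the generator does **not** emulate: temporal drift in haplotype
frequencies, sequencing/assignment error, spatial correlation of frequencies
among neighbouring rookeries beyond the shared/endemic split, and real
geography in the transport kernel. Passing recovery tests therefore
demonstrate statistical correctness of the estimator under its own
assumptions, not robustness to those field realities. The baseline-frequency
prior used in fitting (symmetric 1/H) is deliberately *not* matched to the
sparse generating distribution of f, so interval coverage in the recovery
experiment sits slightly below nominal (high 80s rather than 95%) — the same
mild misspecification real analyses face.

## Problem sizes used by the test suite

Oracle-equivalence checks run 20 instances at 60,000 iterations each against
an exact-marginalization + quadrature oracle; the recovery experiment runs 50
replicates of the study-scale preset at a reduced 10,000 iterations (5,000
burn-in, 2 chains), which the bias comparison at 40,000 iterations shows is
already converged for this purpose; the convergence check runs the full
4 × 100,000 / 50,000 study settings. These sizes are package choices that
keep the default suite fast while exercising the study's dimensions.

## Known limitations

* With very small mixed samples (the 10-individual stock of the preset),
  posterior means shrink toward the prior; conditioning on large true
  contributions therefore shows a negative selection bias of roughly the
  prior-to-data mass ratio. This is a property of any Bayes estimator, not of
  the implementation; the recovery report quantifies it rather than hiding it.
* Dropping orphan mixed-stock individuals slightly biases contributions away
  from the (unsampled) sources those haplotypes came from.
* The Metropolis moves operate row-wise; systems with hundreds of rookeries
  would warrant a blocked or gradient-based sampler.
* The engine operates on whatever haplotype classes harmonization produces;
  whether sub-haplotype SNP subdivisions should be collapsed before analysis
  is a data-preparation decision left to the user.
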