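"""Many-to-many Bayesian mixed stock analysis engine.

The model
---------
R candidate source rookeries contribute juveniles to M sampled mixed stocks
plus one "unknown" sink that absorbs dispersal to unsampled areas.  Each
rookery r has a destination vector ``phi_r`` on the (M+1)-simplex (rookery-
centric parameterization) and baseline haplotype frequencies ``f_r`` on the
H-simplex:

    phi_r ~ Dirichlet(alpha_r)          f_r ~ Dirichlet(beta)
    X_r   ~ Multinomial(f_r)            (rookery baseline counts)

The mixture-centric contribution of rookery r to stock m scales each rookery's
output by its size N_r (nests/year):

    theta[m, r] = N_r phi[r, m] / sum_r' N_r' phi[r', m]

and each individual sampled in stock m draws a latent source
``z ~ Categorical(theta[m, :])`` and then a haplotype from ``f_z``, giving the
mixed-stock counts Y.  The two ecological covariates enter separately: rookery
size through the deterministic theta transform, and ocean-current transport
probability through the Dirichlet prior on phi (each rookery's prior
destination mass is proportional to its transport probabilities, with the
residual assigned to the unknown sink).  Four model variants switch these on:
variants 1/3 use a uniform phi prior, variants 2/4 use the transport-scaled
prior and exclude rookeries whose transport probability is zero for every
sampled stock; variants 3/4 only differ from 1/2 in that the mixed table was
augmented with additional published samples before entry.

Sampling
--------
The posterior is explored by partially collapsed MCMC: phi rows and f rows
get Metropolis-within-Gibbs moves with Dirichlet proposals centered on the
current row, evaluated against the latent-source-collapsed conditionals
(concentrations adapted during burn-in only, so the post-burn-in kernel is
fixed), after which the latent sources z and the baseline frequencies f are
refreshed from their conjugate full conditionals.  The posterior density, not
the sampler, is the contract; ``log_posterior`` gives the unnormalized target
for independent verification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .diagnostics import (
    ContributionSummary,
    ConvergenceReport,
    convergence_report,
    summarize,
)
from .hapio import BaselineTable, MixedStockTable, ValidationError

__all__ = [
    "ModelSpec",
    "PosteriorDraws",
    "FitResult",
    "transport_alpha",
    "build_model",
    "theta_from_phi",
    "log_posterior",
    "run_chain",
    "fit",
    "fit_many_to_one",
]

logger = logging.getLogger("mixedstock")

#: Floor applied to prior destination weights before normalization; a zero
#: Dirichlet hyperparameter would put zero prior mass on a destination and is
#: ill-posed.
ALPHA_FLOOR = 1e-3

_PHI_CLIP = 1e-12


@dataclass
class ModelSpec:
    """Index sets, prior hyperparameters and variant flags for one model run."""

    variant: int
    rookery_codes: list[str]
    stock_codes: list[str]
    haplotype_names: list[str]
    alpha: np.ndarray  # (R, M+1) Dirichlet hyperparameters for phi rows
    beta: np.ndarray  # (H,) Dirichlet hyperparameters for f rows
    c: float = 1.0
    use_sizes: bool = True
    use_transport: bool = False
    freeze_f: bool = False
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.variant not in (1, 2, 3, 4):
            raise ValueError(f"variant must be 1-4, got {self.variant}")
        if self.variant in (2, 4) and not self.use_transport:
            raise ValueError(f"variant {self.variant} requires use_transport")
        if min(self.R, self.M, self.H) < 1:
            raise ValueError("R, M and H must all be >= 1")
        if self.alpha.shape != (self.R, self.M + 1):
            raise ValueError("alpha must have shape (R, M+1)")
        if np.any(self.alpha <= 0):
            raise ValueError("alpha must be strictly positive")
        if self.beta.shape != (self.H,) or np.any(self.beta <= 0):
            raise ValueError("beta must be a strictly positive length-H vector")

    @property
    def R(self) -> int:
        return len(self.rookery_codes)

    @property
    def M(self) -> int:
        return len(self.stock_codes)

    @property
    def H(self) -> int:
        return len(self.haplotype_names)

    def subset_baseline(self, baseline: BaselineTable) -> BaselineTable:
        """Restrict a baseline table to the rookeries this spec retained."""
        pos = {code: i for i, code in enumerate(baseline.rookery_codes)}
        missing = [c for c in self.rookery_codes if c not in pos]
        if missing:
            raise ValidationError(f"baseline is missing rookeries {missing}")
        return baseline.subset([pos[c] for c in self.rookery_codes])


def transport_alpha(
    p_row: np.ndarray, c: float = 1.0, epsilon: float = ALPHA_FLOOR
) -> np.ndarray:
    """Dirichlet hyperparameters for one rookery's destination vector.

    The M transport probabilities are extended with the residual
    ``max(0, 1 - sum(p))`` for the unknown sink, floored at ``epsilon``,
    renormalized to sum to 1, and scaled by the total prior mass ``c``.
    """
    p_row = np.asarray(p_row, dtype=float)
    v = np.append(p_row, max(0.0, 1.0 - p_row.sum()))
    v = np.maximum(v, epsilon)
    return c * v / v.sum()


def build_model(
    baseline: BaselineTable,
    mixed: MixedStockTable,
    variant: int = 1,
    c: float = 1.0,
    beta: float | np.ndarray | None = None,
    epsilon: float = ALPHA_FLOOR,
    freeze_f: bool = False,
    use_sizes: bool = True,
) -> ModelSpec:
    """Assemble a :class:`ModelSpec` from harmonized tables.

    Variants 2/4 require transport probabilities in the baseline and exclude
    any rookery whose transport probability is zero for every sampled stock
    (ocean currents cannot deliver its hatchlings to the sampled areas within
    the drift horizon, so it cannot contribute).  Variants 1/3 use a uniform
    prior of total mass ``c`` per rookery row.

    ``beta`` defaults to total mass 1 spread evenly, i.e. 1/H per haplotype.
    """
    if list(baseline.haplotype_names) != list(mixed.haplotype_names):
        raise ValidationError(
            "baseline and mixed tables do not share a haplotype axis; run harmonize first"
        )
    if variant not in (1, 2, 3, 4):
        raise ValueError(f"variant must be 1-4, got {variant}")
    use_transport = variant in (2, 4)
    M = mixed.M
    excluded: list[str] = []
    if use_transport:
        if baseline.p is None:
            raise ValidationError(f"variant {variant} requires transport probabilities (P_* columns)")
        if list(baseline.p_stocks) != list(mixed.stock_codes):
            raise ValidationError(
                f"transport columns {baseline.p_stocks} do not match mixed stocks {mixed.stock_codes}"
            )
        keep = np.nonzero(baseline.p.sum(axis=1) > 0)[0]
        excluded = [baseline.rookery_codes[i] for i in range(baseline.R) if i not in set(keep)]
        if len(keep) == 0:
            raise ValidationError("all rookeries have zero transport probability to every stock")
        if excluded:
            logger.info("variant %d excludes zero-transport rookeries: %s", variant, excluded)
        codes = [baseline.rookery_codes[i] for i in keep]
        alpha = np.vstack([transport_alpha(baseline.p[i], c, epsilon) for i in keep])
    else:
        codes = list(baseline.rookery_codes)
        alpha = np.full((baseline.R, M + 1), c / (M + 1))
    if beta is None:
        beta_vec = np.full(mixed.H, 1.0 / mixed.H)
    else:
        beta_vec = np.broadcast_to(np.asarray(beta, dtype=float), (mixed.H,)).copy()
    return ModelSpec(
        variant=variant,
        rookery_codes=codes,
        stock_codes=list(mixed.stock_codes),
        haplotype_names=list(mixed.haplotype_names),
        alpha=alpha,
        beta=beta_vec,
        c=c,
        use_sizes=use_sizes,
        use_transport=use_transport,
        freeze_f=freeze_f,
        excluded=excluded,
    )


def theta_from_phi(
    phi: np.ndarray, N: np.ndarray, alpha: np.ndarray | None = None
) -> np.ndarray:
    """Mixture-centric contributions from rookery-centric proportions.

    ``theta[m, r] = N_r phi[r, m] / sum_r' N_r' phi[r', m]``.  The unknown-sink
    column of ``phi`` is not returned.  A zero denominator (no rookery sends
    anything to stock m) falls back to the N-weighted prior mean of ``phi``
    (N-proportional weights when ``alpha`` is not given) with a logged warning.
    """
    phi = np.asarray(phi, dtype=float)
    N = np.asarray(N, dtype=float)
    if phi.ndim != 2 or phi.shape[0] != N.shape[0]:
        raise ValueError(f"phi shape {phi.shape} incompatible with N shape {N.shape}")
    M = phi.shape[1] - 1
    W = N[:, None] * phi[:, :M]
    D = W.sum(axis=0)
    theta = np.empty((M, phi.shape[0]))
    ok = D > 0
    theta[ok, :] = (W[:, ok] / D[ok]).T
    if not ok.all():
        logger.warning("zero total input for stocks %s; using N-weighted prior-mean fallback",
                       list(np.nonzero(~ok)[0]))
        if alpha is not None:
            mean_phi = alpha / alpha.sum(axis=1, keepdims=True)
            Wp = N[:, None] * mean_phi[:, :M]
        else:
            Wp = np.tile(N[:, None], (1, M)).astype(float)
        theta[~ok, :] = (Wp[:, ~ok] / Wp[:, ~ok].sum(axis=0)).T
    return theta


def _log_dirichlet(x: np.ndarray, a: np.ndarray) -> float:
    """Sum of log Dirichlet densities over rows; -inf on unsupported points."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lx = np.log(x)
    terms = (a - 1.0) * lx
    terms = np.where((a == 1.0) & (x == 0.0), 0.0, terms)
    if np.any(np.isnan(terms)) or np.any(terms == np.inf):
        return -math.inf
    norm = gammaln(a.sum(axis=-1)) - gammaln(a).sum(axis=-1)
    return float(norm.sum() + terms.sum())


def log_posterior(
    spec: ModelSpec,
    baseline: BaselineTable,
    mixed: MixedStockTable,
    phi: np.ndarray,
    f: np.ndarray,
) -> float:
    """Unnormalized log posterior density of (phi, f) given both tables.

    Sum of the Dirichlet priors on phi and f, the multinomial baseline term
    ``sum_rh X log f``, and the mixture term ``sum_mh Y log(sum_r theta f)``.
    Boundary points that zero out an observed haplotype return -inf rather
    than raising.
    """
    phi = np.asarray(phi, dtype=float)
    f = np.asarray(f, dtype=float)
    X = spec.subset_baseline(baseline).X
    Y = mixed.Y
    lp = _log_dirichlet(phi, spec.alpha) + _log_dirichlet(f, np.broadcast_to(spec.beta, f.shape))
    if not np.isfinite(lp):
        return -math.inf
    with np.errstate(divide="ignore"):
        lf = np.log(f)
    base_terms = np.where(X > 0, X * lf, 0.0)
    if np.any(np.isnan(base_terms)) or np.any(base_terms == -np.inf):
        return -math.inf
    N_eff = spec.subset_baseline(baseline).N if spec.use_sizes else np.ones(spec.R)
    theta = theta_from_phi(phi, N_eff, spec.alpha)
    mix_prob = theta @ f  # (M, H)
    with np.errstate(divide="ignore"):
        lmix = np.log(mix_prob)
    mix_terms = np.where(Y > 0, Y * lmix, 0.0)
    if np.any(np.isnan(mix_terms)) or np.any(mix_terms == -np.inf):
        return -math.inf
    return lp + float(base_terms.sum()) + float(mix_terms.sum())


# ---------------------------------------------------------------------------
# posterior draws container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Retained MCMC draws (one chain, or several chains pooled).

    ``phi`` has shape (n, R, M+1) with the last destination the unknown sink;
    ``theta`` has shape (n, M, R); ``f`` has shape (n, R, H); ``chain_id``
    labels each draw's chain.  ``z_counts`` optionally retains the latent
    source-assignment counts per (stock, rookery).
    """

    rookery_codes: list[str]
    stock_codes: list[str]
    haplotype_names: list[str]
    theta: np.ndarray
    phi: np.ndarray | None = None
    f: np.ndarray | None = None
    z_counts: np.ndarray | None = None
    chain_id: np.ndarray | None = None
    seeds: list[int] = field(default_factory=list)
    acceptance: np.ndarray | None = None
    kappa: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.chain_id is None:
            self.chain_id = np.zeros(self.theta.shape[0], dtype=np.int64)

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    @staticmethod
    def concat(chains: Sequence["PosteriorDraws"]) -> "PosteriorDraws":
        first = chains[0]

        def _stack(attr):
            parts = [getattr(c, attr) for c in chains]
            return None if any(p is None for p in parts) else np.concatenate(parts)

        return PosteriorDraws(
            rookery_codes=list(first.rookery_codes),
            stock_codes=list(first.stock_codes),
            haplotype_names=list(first.haplotype_names),
            theta=np.concatenate([c.theta for c in chains]),
            phi=_stack("phi"),
            f=_stack("f"),
            z_counts=_stack("z_counts"),
            chain_id=np.concatenate(
                [np.full(c.n_draws, i, dtype=np.int64) for i, c in enumerate(chains)]
            ),
            seeds=[s for c in chains for s in c.seeds],
        )

    def to_frame(self, thin: int = 1) -> "pd.DataFrame":
        """Long-format draws table (one row per draw x parameter)."""
        import pandas as pd

        rows = []
        idx = np.arange(0, self.n_draws, thin)
        dests = list(self.stock_codes) + ["unknown"]
        for m, s in enumerate(self.stock_codes):
            for r, code in enumerate(self.rookery_codes):
                rows.append(pd.DataFrame({
                    "chain": self.chain_id[idx], "draw": idx,
                    "parameter": f"theta[{s},{code}]", "value": self.theta[idx, m, r],
                }))
        if self.phi is not None:
            for r, code in enumerate(self.rookery_codes):
                for j, d in enumerate(dests):
                    rows.append(pd.DataFrame({
                        "chain": self.chain_id[idx], "draw": idx,
                        "parameter": f"phi[{code},{d}]", "value": self.phi[idx, r, j],
                    }))
        return pd.concat(rows, ignore_index=True)


def _check_orphans(X: np.ndarray, Y: np.ndarray, names: Sequence[str]) -> None:
    orphan = (X.sum(axis=0) == 0) & (Y.sum(axis=0) > 0)
    if np.any(orphan):
        bad = [names[j] for j in np.nonzero(orphan)[0]]
        raise ValidationError(
            f"orphan haplotypes reached the sampler (absent from every baseline): {bad}"
        )


def _draw_init(
    rng: np.random.Generator, alpha: np.ndarray, beta: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Overdispersed start: phi from its prior, f from the baseline-only posterior."""
    g = rng.standard_gamma(alpha)
    phi = np.clip(g, _PHI_CLIP, None)
    phi /= phi.sum(axis=1, keepdims=True)
    g = rng.standard_gamma(beta + X)
    f = np.clip(g, _PHI_CLIP, None)
    f /= f.sum(axis=1, keepdims=True)
    return phi, f


def run_chain(
    spec: ModelSpec,
    baseline: BaselineTable,
    mixed: MixedStockTable,
    iterations: int = 100_000,
    burn_in: int = 50_000,
    seed: int | np.random.SeedSequence | None = 0,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    keep_z: bool = False,
    kappa0: float = 100.0,
    adapt_target: float = 0.25,
    max_init_retries: int = 20,
) -> PosteriorDraws:
    """Run one MCMC chain targeting the posterior of :func:`log_posterior`.

    Gibbs updates for the latent sources z (categorical, probability
    proportional to ``theta[m, r] f[r, h]``) and the baseline frequencies f
    (Dirichlet with mass ``beta + X + assigned counts``); Metropolis-within-
    Gibbs for each phi row with an adaptive Dirichlet proposal centered on the
    current row (adaptation frozen at the end of burn-in).  The phi move is
    evaluated against the z-collapsed conditional ``p(phi | f, Y)`` and z is
    refreshed from its full conditional immediately afterwards, a partially
    collapsed scheme with the same stationary distribution but much shorter
    autocorrelation times than conditioning on the current assignments.
    Only post-burn-in draws are retained.
    Identical (seed, inputs) reproduce the draws bit-for-bit; rookery input
    order is canonicalized internally so permuting rookeries permutes all
    outputs exactly.
    """
    if not (iterations > burn_in >= 0):
        raise ValueError("need iterations > burn_in >= 0")
    base = spec.subset_baseline(baseline)
    if list(base.haplotype_names) != list(mixed.haplotype_names):
        raise ValidationError("baseline and mixed tables do not share a haplotype axis")
    _check_orphans(base.X, mixed.Y, base.haplotype_names)

    R, M, H = spec.R, spec.M, spec.H
    # canonical rookery order: makes the RNG stream independent of input order
    perm = np.argsort(np.asarray(base.rookery_codes, dtype=object), kind="stable")
    inv = np.argsort(perm)
    X = np.ascontiguousarray(base.X[perm])
    N = np.ascontiguousarray(base.N[perm]) if spec.use_sizes else np.ones(R)
    alpha = np.ascontiguousarray(spec.alpha[perm])
    Y = np.ascontiguousarray(mixed.Y)
    ytot = Y.sum(axis=1).astype(float)
    beta = np.asarray(spec.beta, dtype=float)

    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
        seed_label = int(seed.generate_state(1)[0] % (2**31))
    else:
        rng = np.random.default_rng(seed)
        seed_label = int(seed if seed is not None else -1)

    if init is not None:
        phi = np.asarray(init[0], dtype=float)[perm].copy()
        f = np.asarray(init[1], dtype=float)[perm].copy()
    else:
        for _ in range(max_init_retries):
            phi, f = _draw_init(rng, alpha, beta, X)
            lp = log_posterior(spec, baseline, mixed, phi[inv], f[inv])
            if np.isfinite(lp):
                break
        else:
            raise RuntimeError("could not find an initial point with finite posterior density")

    n_keep = iterations - burn_in
    out_phi = np.empty((n_keep, R, M + 1))
    out_f = np.empty((n_keep, R, H))
    out_theta = np.empty((n_keep, M, R))
    out_z = np.empty((n_keep, M, R), dtype=np.int64) if keep_z else None

    kappa = np.full(R, float(kappa0))
    kappa_f = np.full(R, float(kappa0))
    acc_win = np.zeros(R)
    accf_win = np.zeros(R)
    acc_total = np.zeros(R)
    lam = 0.05  # proposal concentration stabilizer
    adapt_every = 64
    logN = np.log(N)
    Xbeta = beta + X  # (R, H)
    alpha_m1 = alpha - 1.0
    freeze = spec.freeze_f

    ym, yh = np.nonzero(Y)
    yv = Y[ym, yh].astype(float)

    for it in range(iterations):
        # --- phi rows: Metropolis-within-Gibbs against the z-collapsed
        # conditional p(phi | f, Y); collapsing the latent sources out of this
        # move leaves the joint posterior invariant (z is refreshed from its
        # full conditional right after) and mixes far better than conditioning
        # on the current assignments.
        Wmat = N[:, None] * phi[:, :M]  # (R, M)
        D = Wmat.sum(axis=0)  # (M,)
        T = Wmat.T @ f  # (M, H): unnormalized mixture weights

        conc_fwd = kappa[:, None] * phi + lam
        g = rng.standard_gamma(conc_fwd)
        np.clip(g, _PHI_CLIP, None, out=g)
        prop = g / g.sum(axis=1, keepdims=True)
        np.clip(prop, _PHI_CLIP, None, out=prop)
        prop /= prop.sum(axis=1, keepdims=True)
        conc_rev = kappa[:, None] * prop + lam

        log_phi = np.log(phi)
        log_prop = np.log(prop)
        # own-row prior and proposal-density pieces
        lq_fwd = (gammaln(conc_fwd.sum(axis=1)) - gammaln(conc_fwd).sum(axis=1)
                  + ((conc_fwd - 1.0) * log_prop).sum(axis=1))
        lq_rev = (gammaln(conc_rev.sum(axis=1)) - gammaln(conc_rev).sum(axis=1)
                  + ((conc_rev - 1.0) * log_phi).sum(axis=1))
        delta_row = ((alpha_m1 * (log_prop - log_phi)).sum(axis=1)
                     + lq_rev - lq_fwd)
        log_u = np.log(rng.random(R))

        mix_cur = float(yv @ np.log(T[ym, yh])) - float(ytot @ np.log(D))
        for r in range(R):
            dW = N[r] * (prop[r, :M] - phi[r, :M])  # (M,)
            T_new = T + dW[:, None] * f[r][None, :]
            D_new = D + dW
            mix_new = float(yv @ np.log(T_new[ym, yh])) - float(ytot @ np.log(D_new))
            if log_u[r] < delta_row[r] + mix_new - mix_cur:
                phi[r] = prop[r]
                T = T_new
                D = D_new
                mix_cur = mix_new
                acc_win[r] += 1.0
                acc_total[r] += 1.0

        # --- f rows: same collapsed Metropolis move (the conjugate update
        # below also refreshes f; this extra sweep decorrelates f from the
        # latent assignments, which dominates the autocorrelation time when
        # baselines are weak) ---
        Wmat = N[:, None] * phi[:, :M]
        if not freeze:
            conc_fwd = kappa_f[:, None] * f + lam
            g = rng.standard_gamma(conc_fwd)
            np.clip(g, _PHI_CLIP, None, out=g)
            prop = g / g.sum(axis=1, keepdims=True)
            np.clip(prop, _PHI_CLIP, None, out=prop)
            prop /= prop.sum(axis=1, keepdims=True)
            conc_rev = kappa_f[:, None] * prop + lam
            log_f = np.log(f)
            log_prop = np.log(prop)
            lq_fwd = (gammaln(conc_fwd.sum(axis=1)) - gammaln(conc_fwd).sum(axis=1)
                      + ((conc_fwd - 1.0) * log_prop).sum(axis=1))
            lq_rev = (gammaln(conc_rev.sum(axis=1)) - gammaln(conc_rev).sum(axis=1)
                      + ((conc_rev - 1.0) * log_f).sum(axis=1))
            delta_row = (((Xbeta - 1.0) * (log_prop - log_f)).sum(axis=1)
                         + lq_rev - lq_fwd)
            log_u = np.log(rng.random(R))
            mix_cur = float(yv @ np.log(T[ym, yh]))  # D does not depend on f
            for r in range(R):
                T_new = T + Wmat[r][:, None] * (prop[r] - f[r])[None, :]
                mix_new = float(yv @ np.log(T_new[ym, yh]))
                if log_u[r] < delta_row[r] + mix_new - mix_cur:
                    f[r] = prop[r]
                    T = T_new
                    mix_cur = mix_new
                    accf_win[r] += 1.0

        # --- latent sources z: only (stock, haplotype)-cell counts matter ---
        theta = (Wmat / Wmat.sum(axis=0)).T  # (M, R)
        P = theta[:, None, :] * f.T[None, :, :]  # (M, H, R)
        P /= P.sum(axis=2, keepdims=True)
        A = rng.multinomial(Y, P)  # (M, H, R)
        n_mr = A.sum(axis=1)  # (M, R)

        # --- baseline frequencies f ---
        conc_f = Xbeta if freeze else Xbeta + A.sum(axis=0).T
        g = rng.standard_gamma(conc_f)
        np.clip(g, _PHI_CLIP, None, out=g)
        f = g / g.sum(axis=1, keepdims=True)

        if it < burn_in and (it + 1) % adapt_every == 0:
            # acceptance above target -> moves too timid -> lower concentration
            rate = acc_win / adapt_every
            kappa *= np.exp(2.0 * np.clip(adapt_target - rate, -0.5, 0.5))
            np.clip(kappa, 2.0, 1e6, out=kappa)
            acc_win[:] = 0.0
            rate_f = accf_win / adapt_every
            kappa_f *= np.exp(2.0 * np.clip(adapt_target - rate_f, -0.5, 0.5))
            np.clip(kappa_f, 2.0, 1e6, out=kappa_f)
            accf_win[:] = 0.0

        if it >= burn_in:
            k = it - burn_in
            out_phi[k] = phi
            out_f[k] = f
            Wrec = N[:, None] * phi[:, :M]
            out_theta[k] = (Wrec / Wrec.sum(axis=0)).T
            if keep_z:
                out_z[k] = n_mr

    # map canonical order back to input order
    return PosteriorDraws(
        rookery_codes=list(spec.rookery_codes),
        stock_codes=list(spec.stock_codes),
        haplotype_names=list(spec.haplotype_names),
        theta=np.ascontiguousarray(out_theta[:, :, inv]),
        phi=np.ascontiguousarray(out_phi[:, inv, :]),
        f=np.ascontiguousarray(out_f[:, inv, :]),
        z_counts=None if out_z is None else np.ascontiguousarray(out_z[:, :, inv]),
        seeds=[seed_label],
        acceptance=(acc_total / iterations)[inv],
        kappa=kappa[inv],
    )


@dataclass
class FitResult:
    """Pooled draws, convergence diagnostics and posterior summary of one fit."""

    draws: PosteriorDraws
    convergence: ConvergenceReport
    summary: ContributionSummary
    spec: ModelSpec | None = None
    manifest: dict = field(default_factory=dict)


def _per_parameter_chains(chains: list[PosteriorDraws]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    first = chains[0]
    for m, s in enumerate(first.stock_codes):
        for r, code in enumerate(first.rookery_codes):
            out[f"theta[{s},{code}]"] = np.stack([c.theta[:, m, r] for c in chains])
    if first.phi is not None:
        dests = list(first.stock_codes) + ["unknown"]
        for r, code in enumerate(first.rookery_codes):
            for j, d in enumerate(dests):
                out[f"phi[{code},{d}]"] = np.stack([c.phi[:, r, j] for c in chains])
    return out


def fit(
    spec: ModelSpec,
    baseline: BaselineTable,
    mixed: MixedStockTable,
    chains: int = 4,
    iterations: int = 100_000,
    burn_in: int = 50_000,
    seed: int = 0,
    keep_z: bool = False,
    rhat_threshold: float = 1.2,
) -> FitResult:
    """Fit the many-to-many model with several independent chains.

    Chains start from independent draws from the prior (overdispersed starts),
    with per-chain RNG streams derived from the master seed.  The convergence
    report covers every scalar theta and phi parameter; the summary gives
    posterior means and equal-tailed 95% credibility intervals.
    """
    if chains < 2:
        raise ValueError("fit requires at least 2 chains for the shrink-factor diagnostic")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(chains)
    results = [
        run_chain(spec, baseline, mixed, iterations=iterations, burn_in=burn_in,
                  seed=child, keep_z=keep_z)
        for child in children
    ]
    report = convergence_report(_per_parameter_chains(results), threshold=rhat_threshold)
    if not report.converged:
        logger.warning("convergence flag raised: max shrink factor %.3f >= %.2f",
                       report.max_rhat, rhat_threshold)
    else:
        logger.info("max shrink factor %.3f", report.max_rhat)
    pooled = PosteriorDraws.concat(results)
    summary = summarize(pooled)
    manifest = {
        "variant": spec.variant,
        "chains": chains,
        "iterations": iterations,
        "burn_in": burn_in,
        "seed": seed,
        "excluded_rookeries": list(spec.excluded),
        "max_rhat": report.max_rhat,
        "converged": report.converged,
    }
    return FitResult(draws=pooled, convergence=report, summary=summary, spec=spec,
                     manifest=manifest)


def fit_many_to_one(
    baseline: BaselineTable,
    mixed: MixedStockTable,
    prior: np.ndarray | float | None = None,
    chains: int = 4,
    iterations: int = 20_000,
    burn_in: int = 10_000,
    seed: int = 0,
) -> FitResult:
    """Classic many-to-one mixed stock fit for a single mixed aggregation.

    Fully conjugate Gibbs sampler: latent sources z, baseline frequencies f,
    and the contribution vector ``theta ~ Dirichlet(prior + assignment
    counts)`` directly.  ``prior`` defaults to a symmetric Dirichlet of total
    mass 1 (1/R per rookery).  Same summary contract as :func:`fit`.
    """
    if mixed.M != 1:
        raise ValueError("fit_many_to_one requires exactly one mixed stock")
    if list(baseline.haplotype_names) != list(mixed.haplotype_names):
        raise ValidationError("baseline and mixed tables do not share a haplotype axis")
    _check_orphans(baseline.X, mixed.Y, baseline.haplotype_names)
    if chains < 2:
        raise ValueError("fit_many_to_one requires at least 2 chains")
    if not (iterations > burn_in >= 0):
        raise ValueError("need iterations > burn_in >= 0")

    R, H = baseline.R, baseline.H
    if prior is None:
        prior_vec = np.full(R, 1.0 / R)
    else:
        prior_vec = np.broadcast_to(np.asarray(prior, dtype=float), (R,)).copy()
    if np.any(prior_vec <= 0):
        raise ValueError("prior must be strictly positive")
    beta = np.full(H, 1.0 / H)

    perm = np.argsort(np.asarray(baseline.rookery_codes, dtype=object), kind="stable")
    inv = np.argsort(perm)
    X = baseline.X[perm]
    prior_c = prior_vec[perm]
    Y = mixed.Y[0]

    n_keep = iterations - burn_in
    all_chains: list[PosteriorDraws] = []
    for child in np.random.SeedSequence(seed).spawn(chains):
        rng = np.random.default_rng(child)
        g = rng.standard_gamma(prior_c)
        theta = np.clip(g, _PHI_CLIP, None)
        theta /= theta.sum()
        g = rng.standard_gamma(beta + X)
        f = np.clip(g, _PHI_CLIP, None)
        f /= f.sum(axis=1, keepdims=True)
        out_theta = np.empty((n_keep, 1, R))
        out_f = np.empty((n_keep, R, H))
        for it in range(iterations):
            P = theta[None, :] * f.T  # (H, R)
            P /= P.sum(axis=1, keepdims=True)
            A = rng.multinomial(Y, P)  # (H, R)
            n_r = A.sum(axis=0)
            g = rng.standard_gamma(beta + X + A.T)
            np.clip(g, _PHI_CLIP, None, out=g)
            f = g / g.sum(axis=1, keepdims=True)
            g = rng.standard_gamma(prior_c + n_r)
            theta = np.clip(g, _PHI_CLIP, None)
            theta /= theta.sum()
            if it >= burn_in:
                out_theta[it - burn_in, 0] = theta
                out_f[it - burn_in] = f
        all_chains.append(PosteriorDraws(
            rookery_codes=list(baseline.rookery_codes),
            stock_codes=list(mixed.stock_codes),
            haplotype_names=list(baseline.haplotype_names),
            theta=np.ascontiguousarray(out_theta[:, :, inv]),
            phi=None,
            f=np.ascontiguousarray(out_f[:, inv, :]),
        ))
    report = convergence_report(_per_parameter_chains(all_chains))
    pooled = PosteriorDraws.concat(all_chains)
    summary = summarize(pooled)
    manifest = {"model": "many-to-one", "chains": chains, "iterations": iterations,
                "burn_in": burn_in, "seed": seed, "max_rhat": report.max_rhat}
    return FitResult(draws=pooled, convergence=report, summary=summary, manifest=manifest)
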