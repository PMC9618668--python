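"""Convergence assessment and posterior summarization.

Implements the classic Gelman-Rubin potential scale reduction factor (shrink
factor): for C chains of n retained draws each, with W the mean of the unbiased
within-chain variances and B = n * Var(chain means),

    Vhat = ((n - 1) / n) * W + B / n,      Rhat = sqrt(Vhat / W).

Values near 1 indicate the chains have forgotten their overdispersed starting
points; runs are flagged when any parameter's Rhat reaches the conventional
1.2 threshold.  A rank-normalized variant (applied to the pooled-rank normal
scores of the draws) is available but off by default, since the classic
statistic is the one most mixed-stock software reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["shrink_factor", "ConvergenceReport", "convergence_report", "summarize", "ContributionSummary"]

#: Conventional convergence threshold for the shrink factor.
RHAT_THRESHOLD = 1.2


def _rank_normalize(chains: np.ndarray) -> np.ndarray:
    flat = chains.reshape(-1)
    ranks = stats.rankdata(flat, method="average")
    z = stats.norm.ppf((ranks - 3.0 / 8.0) / (flat.size + 0.25))
    return z.reshape(chains.shape)


def shrink_factor(chains: np.ndarray, rank_normalize: bool = False) -> dict[str, float]:
    """Gelman-Rubin shrink factor for one scalar parameter.

    Parameters
    ----------
    chains
        Array of shape (C, n): C >= 2 chains of n >= 2 retained draws.
    rank_normalize
        Compute the statistic on pooled-rank normal scores instead of the raw
        draws (robust to heavy tails; off by default).

    Returns
    -------
    dict with keys ``W``, ``B``, ``Vhat``, ``Rhat``, ``n``.  Chains that are
    constant everywhere return Rhat = 1 by convention; W = 0 with B > 0 gives
    Rhat = inf.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("shrink_factor requires at least 2 chains of draws (C x n array)")
    if chains.shape[1] < 2:
        raise ValueError("shrink_factor requires at least 2 draws per chain")
    if rank_normalize:
        chains = _rank_normalize(chains)
    n = chains.shape[1]
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    B = float(n * np.var(np.mean(chains, axis=1), ddof=1))
    if W == 0.0:
        if B == 0.0:
            return {"W": 0.0, "B": 0.0, "Vhat": 0.0, "Rhat": 1.0, "n": n}
        return {"W": 0.0, "B": B, "Vhat": B / n, "Rhat": float("inf"), "n": n}
    Vhat = (n - 1) / n * W + B / n
    return {"W": W, "B": B, "Vhat": Vhat, "Rhat": float(np.sqrt(Vhat / W)), "n": n}


@dataclass
class ConvergenceReport:
    """Per-parameter shrink factors with the overall convergence flag."""

    table: pd.DataFrame
    threshold: float = RHAT_THRESHOLD

    @property
    def max_rhat(self) -> float:
        return float(self.table["Rhat"].max())

    @property
    def converged(self) -> bool:
        return bool((self.table["Rhat"] < self.threshold).all())

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def convergence_report(
    draws_by_chain: dict[str, np.ndarray],
    threshold: float = RHAT_THRESHOLD,
    rank_normalize: bool = False,
) -> ConvergenceReport:
    """Build a :class:`ConvergenceReport` from named per-parameter chain arrays.

    ``draws_by_chain`` maps parameter name -> (C, n) array.
    """
    rows = []
    for name, chains in draws_by_chain.items():
        entry = shrink_factor(chains, rank_normalize=rank_normalize)
        rows.append({"parameter": name, **entry, "converged": entry["Rhat"] < threshold})
    return ConvergenceReport(table=pd.DataFrame(rows), threshold=threshold)


@dataclass
class ContributionSummary:
    """Posterior means and equal-tailed credibility intervals.

    ``theta`` summarizes mixture-centric contributions per (stock, rookery);
    ``phi`` summarizes each rookery's destination vector including the
    "unknown" sink for unsampled areas.
    """

    theta: pd.DataFrame
    phi: pd.DataFrame | None = None
    prob: float = 0.95
    n_draws: int = 0
    extras: dict = field(default_factory=dict)

    def theta_means(self) -> pd.DataFrame:
        """Posterior mean contribution matrix, stocks x rookeries."""
        return self.theta.pivot(index="stock", columns="rookery", values="mean")


def _summary_frame(
    draws: np.ndarray, rows: list[dict], prob: float
) -> pd.DataFrame:
    lo_q, hi_q = (1 - prob) / 2, 1 - (1 - prob) / 2
    means = draws.mean(axis=0)
    lo = np.quantile(draws, lo_q, axis=0)  # linear-interpolation quantiles
    hi = np.quantile(draws, hi_q, axis=0)
    out = pd.DataFrame(rows)
    out["mean"] = means
    out["lower"] = lo
    out["upper"] = hi
    return out


def summarize(draws, prob: float = 0.95, min_draws: int = 100) -> ContributionSummary:
    """Summarize pooled posterior draws into means and credibility intervals.

    Quantiles use linear interpolation between order statistics.  Fewer than
    ``min_draws`` retained draws raise an error: the tail quantiles would be
    meaningless.
    """
    n = draws.theta.shape[0]
    if n < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws to summarize, got {n}")
    theta_rows = [
        {"stock": s, "rookery": r}
        for s in draws.stock_codes
        for r in draws.rookery_codes
    ]
    theta = _summary_frame(draws.theta.reshape(n, -1), theta_rows, prob)
    phi = None
    if draws.phi is not None:
        destinations = list(draws.stock_codes) + ["unknown"]
        phi_rows = [
            {"rookery": r, "destination": d}
            for r in draws.rookery_codes
            for d in destinations
        ]
        phi = _summary_frame(draws.phi.reshape(n, -1), phi_rows, prob)
    return ContributionSummary(theta=theta, phi=phi, prob=prob, n_draws=n)
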