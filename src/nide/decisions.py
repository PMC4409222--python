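"""Posterior decision rules: DE probabilities, Bayesian rates, ROC/AUC.

The per-gene decision statistic is the posterior probability of differential
expression, pi_i = P(not all group means equal | data), estimated as the
fraction of retained draws in which gene i's equality pattern has more than
one block.  Calls use the strict rule r_i = I(pi_i > kappa).

Bayesian rates weight each call by the posterior class probabilities:

    bFPR = sum (1-pi_i) r_i / sum (1-pi_i),   bTPR = sum pi_i r_i / sum pi_i,
    bFDR = sum (1-pi_i) r_i / sum r_i,
    bTNR = 1 - bFPR,   bFNR = 1 - bTPR.

The truth-based (frequentist) ROC/AUC against known simulation labels is
the Mann-Whitney rank statistic with half credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mcmc import PosteriorDraws
from .model import pattern_pairwise_map

__all__ = [
    "PosteriorSummary",
    "DecisionReport",
    "ROCCurve",
    "de_probability",
    "bayes_rates",
    "roc_auc",
    "truth_roc_auc",
]

DEFAULT_KAPPA_GRID = (0.5, 0.7, 0.9, 0.95)


@dataclass
class PosteriorSummary:
    """Per-gene posterior quantities pooled over chains."""

    pi: np.ndarray              # (N,) P(any pair of means unequal | data)
    pairwise_pi: np.ndarray     # (N, k, k) P(mu_is != mu_is' | data)
    mean_diff: np.ndarray       # (N, k, k) posterior mean of mu_is - mu_is'
    gene_ids: list = field(default_factory=list)
    rhat: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return self.pi.size


@dataclass
class DecisionReport:
    kappa: float
    calls: np.ndarray
    n_called: int
    bFDR: float
    bFNR: float
    bTNR: float
    bFPR: float
    bTPR: float
    no_calls: bool = False  # bFDR reported as 0 because the call set is empty


@dataclass
class ROCCurve:
    points: np.ndarray  # (m, 2) columns (bFPR, bTPR), oriented (0,0)->(1,1)
    auc: float
    degenerate: bool = False


def de_probability(draws: PosteriorDraws) -> PosteriorSummary:
    """Posterior DE and pairwise-difference probabilities from the z traces."""
    if draws.n_keep == 0:
        raise ValueError("no retained draws")
    n_chains, keep, N = draws.z.shape
    P = len(draws.patterns)
    k = draws.patterns[0].n_groups
    total = n_chains * keep

    zflat = draws.z.reshape(total, N)
    counts = np.zeros((N, P), dtype=np.int64)
    for p in range(P):
        counts[:, p] = (zflat == p).sum(axis=0)

    sep = np.stack([pattern_pairwise_map(pat) for pat in draws.patterns])
    freq = counts / total                        # (N, P)
    pairwise = np.einsum("np,pij->nij", freq, sep.astype(float))
    pi = 1.0 - freq[:, 0]                        # pattern 0 is all-equal

    mu = draws.mu.astype(float).reshape(total, N, k)
    mu_bar = mu.mean(axis=0)
    mean_diff = mu_bar[:, :, None] - mu_bar[:, None, :]
    return PosteriorSummary(pi=pi, pairwise_pi=pairwise, mean_diff=mean_diff,
                            gene_ids=list(draws.gene_ids), rhat=dict(draws.rhat))


def bayes_rates(summary: PosteriorSummary | np.ndarray,
                kappa: float) -> DecisionReport:
    """Bayesian error rates of the threshold rule I(pi > kappa).

    Accepts either a :class:`PosteriorSummary` or a bare pi vector.  With an
    empty call set bFDR is reported as 0 and flagged.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    pi = summary.pi if isinstance(summary, PosteriorSummary) else \
        np.asarray(summary, dtype=float)
    r = pi > kappa
    n_called = int(r.sum())
    s1, s0 = pi.sum(), (1.0 - pi).sum()
    bFPR = float((1.0 - pi)[r].sum() / s0) if s0 > 0 else 0.0
    bTPR = float(pi[r].sum() / s1) if s1 > 0 else 0.0
    no_calls = n_called == 0
    bFDR = 0.0 if no_calls else float((1.0 - pi)[r].sum() / n_called)
    return DecisionReport(kappa=float(kappa), calls=r, n_called=n_called,
                          bFDR=bFDR, bFNR=1.0 - bTPR, bTNR=1.0 - bFPR,
                          bFPR=bFPR, bTPR=bTPR, no_calls=no_calls)


def roc_auc(summary: PosteriorSummary | np.ndarray) -> ROCCurve:
    """Posterior-weighted ROC over the kappa grid {0} U {distinct pi} U {1}."""
    pi = summary.pi if isinstance(summary, PosteriorSummary) else \
        np.asarray(summary, dtype=float)
    if pi.size < 2:
        raise ValueError("need at least 2 genes")
    grid = np.unique(np.concatenate([[0.0], np.unique(pi), [1.0]]))
    pts = np.array([[bayes_rates(pi, k).bFPR, bayes_rates(pi, k).bTPR]
                    for k in grid])
    pts = np.vstack([[0.0, 0.0], pts[np.argsort(pts[:, 0], kind="stable")],
                     [1.0, 1.0]])
    degenerate = np.unique(pi).size == 1
    auc = 0.5 if degenerate else float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCCurve(points=pts, auc=auc, degenerate=degenerate)


def truth_roc_auc(pi, truth) -> float:
    """Frequentist AUC of the pi ranking against known 0/1 labels.

    Equals the Mann-Whitney statistic; ties get half credit.
    """
    pi = np.asarray(pi, dtype=float)
    truth = np.asarray(truth)
    n1 = int(truth.sum())
    n0 = truth.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("truth labels must contain both classes")
    ranks = stats.rankdata(pi)
    return float((ranks[truth == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
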