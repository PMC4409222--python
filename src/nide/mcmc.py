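"""Metropolis-within-Gibbs sampler and convergence diagnostics.

The sweep order is: equality patterns and group means (block means
integrated out of the pattern draw) -> latent scale factors -> error and
mean-prior precisions -> family shape parameters -> pattern mixing
probabilities.  The compiled kernels live in :mod:`nide._kernels`; this
module owns initialisation, chain orchestration, storage and the
Gelman-Rubin diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .families import NIFamilySpec
from .model import (ExpressionDataset, HyperPriorConfig, pattern_arrays,
                    prior_predictive_draw)

__all__ = [
    "MCMCConfig",
    "ChainState",
    "PosteriorDraws",
    "init_state",
    "run_chains",
    "gelman_rubin",
    "geweke_traces",
]

log = logging.getLogger(__name__)

#: shape-parameter starting values per family
_NU_DEFAULTS = {"normal": (0.0, 0.0), "t": (5.0, 0.0), "slash": (2.0, 0.0),
                "contaminated_normal": (0.5, 0.5), "laplace": (1.0, 0.0)}

#: precision cap used when a gene has (near) zero within-group variance
TAU_INIT_CAP = 1e6


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.  Defaults follow the two-chain real-data protocol
    (20,000 iterations, 15,000 burn-in); simulation batches use the shorter
    schedule via :func:`simulation_defaults`."""

    n_iter: int = 20000
    n_burnin: int = 15000
    n_chains: int = 2
    seed: int = 0
    family: NIFamilySpec = field(default_factory=NIFamilySpec.normal)
    thin: int = 1
    mh_step: float = 0.5  # t-df random-walk step on log(v)

    def __post_init__(self):
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be >= 1")

    @property
    def n_keep(self) -> int:
        return -((self.n_iter - self.n_burnin) // -self.thin)

    def to_dict(self) -> dict:
        return {"n_iter": self.n_iter, "n_burnin": self.n_burnin,
                "n_chains": self.n_chains, "seed": self.seed,
                "family": [self.family.family, list(self.family.shape)],
                "thin": self.thin, "mh_step": self.mh_step}

    @classmethod
    def from_dict(cls, d: dict) -> "MCMCConfig":
        d = dict(d)
        fam = d.pop("family", ["normal", []])
        return cls(family=NIFamilySpec(fam[0], tuple(fam[1])), **d)


def simulation_defaults(family: NIFamilySpec, seed: int = 0,
                        n_iter: int = 15000, n_burnin: int = 10000) -> MCMCConfig:
    """Single-chain schedule used inside the simulation studies."""
    return MCMCConfig(n_iter=n_iter, n_burnin=n_burnin, n_chains=1,
                      seed=seed, family=family)


@dataclass
class ChainState:
    """One MCMC state (all arrays are mutated in place by the kernels)."""

    mu: np.ndarray        # (N, k) group means, equal within a z-block
    z: np.ndarray         # (N,) pattern index
    u: np.ndarray         # (N, n) latent scale factors
    b: np.ndarray         # (N, n) contamination indicators (CN only)
    tau_eps: np.ndarray   # (N,) error precisions
    nu: np.ndarray        # (N, 2) family shapes
    p: np.ndarray         # (P,) pattern probabilities
    tau_mu: np.ndarray    # (k+1,) mean-prior precisions


def _chain_seed(seed: int, chain: int) -> int:
    return int(np.random.SeedSequence([seed, chain]).generate_state(1)[0]
               % (2 ** 31 - 1))


def init_state(data: ExpressionDataset, config: MCMCConfig,
               chain: int = 0) -> ChainState:
    """Deterministic per-chain initialisation.

    Group means start at the sample means (jittered per chain), scale
    factors at 1, precisions at the inverse pooled within-group variance
    (capped for degenerate genes), the pattern at all-equal, p uniform and
    the shapes at family defaults.
    """
    rng = np.random.default_rng([config.seed, 7919, chain])
    N, k = data.n_genes, data.n_groups
    n = data.values.shape[1]
    patterns, assign, nblocks, comp = pattern_arrays(k)
    P = len(patterns)

    mu = np.column_stack([data.group_values(s).mean(axis=1) for s in range(k)])
    mu = mu + rng.normal(0.0, 0.05 * (1 + chain), size=mu.shape)
    sse = np.zeros(N)
    for s in range(k):
        g = data.group_values(s)
        sse += ((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    var = sse / max(n - k, 1)
    tau_eps = np.minimum(1.0 / np.maximum(var, 1.0 / TAU_INIT_CAP), TAU_INIT_CAP)

    nu = np.tile(np.asarray(_NU_DEFAULTS[config.family.family]), (N, 1))
    tau_mu = np.full(k + 1, 1.0 / (np.mean(mu ** 2) + 1e-3))
    return ChainState(
        mu=np.ascontiguousarray(mu), z=np.zeros(N, dtype=np.int64),
        u=np.ones((N, n)), b=np.zeros((N, n), dtype=np.uint8),
        tau_eps=tau_eps, nu=np.ascontiguousarray(nu, dtype=float),
        p=np.full(P, 1.0 / P), tau_mu=tau_mu)


@dataclass
class PosteriorDraws:
    """Retained post-burn-in draws, one leading axis per chain."""

    z: np.ndarray         # (chains, keep, N) int16 pattern indices
    p: np.ndarray         # (chains, keep, P)
    tau_mu: np.ndarray    # (chains, keep, k+1)
    tau_eps: np.ndarray   # (chains, keep, N) float32
    mu: np.ndarray        # (chains, keep, N, k) float32
    nu: np.ndarray        # (chains, keep, N, 2) float32
    patterns: list
    config: MCMCConfig
    gene_ids: list
    rhat: dict = field(default_factory=dict)
    t_accept_rate: float = float("nan")

    @property
    def n_keep(self) -> int:
        return self.z.shape[1]

    def scalar_table(self):
        """Chain-level scalar traces as a tidy table (one row per retained
        iteration per chain): p components and tau_mu components."""
        import pandas as pd

        n_chains, keep, P = self.p.shape
        rows = {"chain": np.repeat(np.arange(n_chains), keep),
                "iteration": np.tile(np.arange(keep), n_chains)}
        for j in range(P):
            rows[f"p{j}"] = self.p[:, :, j].ravel()
        for c in range(self.tau_mu.shape[2]):
            rows[f"tau_mu{c}"] = self.tau_mu[:, :, c].ravel()
        return pd.DataFrame(rows)

    def save_scalars(self, path) -> None:
        """Write the scalar traces to (gzip-compressed, if *.gz) TSV."""
        self.scalar_table().to_csv(path, sep="\t", index=False)


def run_chains(data: ExpressionDataset, config: MCMCConfig) -> PosteriorDraws:
    """Run ``config.n_chains`` chains and collect retained draws.

    Fully reproducible from ``config.seed``.  Raises if a non-finite state
    component is detected mid-run.
    """
    patterns, assign, nblocks, comp = pattern_arrays(data.n_groups)
    N, k = data.n_genes, data.n_groups
    P, keep = len(patterns), config.n_keep
    fam = config.family

    z_tr = np.empty((config.n_chains, keep, N), dtype=np.int16)
    p_tr = np.empty((config.n_chains, keep, P))
    tmu_tr = np.empty((config.n_chains, keep, k + 1))
    te_tr = np.empty((config.n_chains, keep, N), dtype=np.float32)
    mu_tr = np.empty((config.n_chains, keep, N, k), dtype=np.float32)
    nu_tr = np.empty((config.n_chains, keep, N, 2), dtype=np.float32)

    y = np.ascontiguousarray(data.values)
    n_acc_tot = 0
    for c in range(config.n_chains):
        st = init_state(data, config, chain=c)
        log.info("chain %d/%d: %d iterations (family=%s, N=%d)",
                 c + 1, config.n_chains, config.n_iter, fam.family, N)
        status, n_acc = _kernels.run_chain(
            y, data.group_of, assign, nblocks, comp, fam.code,
            st.mu, st.z, st.u, st.b, st.tau_eps, st.nu, st.p, st.tau_mu,
            config.n_iter, config.n_burnin, config.thin,
            _chain_seed(config.seed, c), config.mh_step,
            z_tr[c], p_tr[c], tmu_tr[c], te_tr[c], mu_tr[c], nu_tr[c])
        if status >= 0:
            raise RuntimeError(
                f"non-finite state in chain {c} near iteration {status}")
        n_acc_tot += n_acc

    acc_rate = float("nan")
    if fam.family == "t":
        acc_rate = n_acc_tot / (config.n_chains * config.n_iter * N)
        if not 0.05 <= acc_rate <= 0.95:
            log.warning("t-df MH acceptance rate %.3f outside (0.05, 0.95); "
                        "consider retuning mh_step", acc_rate)

    draws = PosteriorDraws(z_tr, p_tr, tmu_tr, te_tr, mu_tr, nu_tr,
                           patterns, config, list(data.gene_ids),
                           t_accept_rate=acc_rate)
    if config.n_chains >= 2 and keep >= 2:
        draws.rhat = _convergence_summary(draws)
        worst = max(v for v in draws.rhat.values() if np.isfinite(v))
        if worst > 1.1:
            log.warning("Gelman-Rubin R-hat up to %.3f > 1.1: chains may not "
                        "have converged", worst)
    return draws


def _convergence_summary(draws: PosteriorDraws) -> dict:
    """R-hat for p, a 1% subsample of tau_eps, and the mean log-precision."""
    out = {}
    for j in range(draws.p.shape[2]):
        out[f"p[{j}]"] = gelman_rubin(draws.p[:, :, j])
    N = draws.tau_eps.shape[2]
    rng = np.random.default_rng(draws.config.seed)
    idx = rng.choice(N, size=max(1, N // 100), replace=False)
    for i in idx:
        out[f"tau_eps[{i}]"] = gelman_rubin(
            np.log(draws.tau_eps[:, :, i].astype(float)))
    out["mean_log_tau_eps"] = gelman_rubin(
        np.log(draws.tau_eps.astype(float)).mean(axis=2))
    return out


def gelman_rubin(traces) -> float:
    """Potential scale reduction factor over equal-length chains.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B = n * variance of the chain means.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2 or traces.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    n = traces.shape[1]
    W = traces.var(axis=1, ddof=1).mean()
    if W <= 0.0:
        raise ValueError("zero within-chain variance: R-hat undefined")
    B = n * traces.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


# ---------------------------------------------------------------------------
# pure-python full-conditional algebra (shared by docs and oracle tests)
# ---------------------------------------------------------------------------

def tau_eps_conditional(y, mu_per_sample, u,
                        prior_shape: float = _kernels.GAMMA_PRIOR_SHAPE,
                        prior_rate: float = _kernels.GAMMA_PRIOR_RATE):
    """(shape, rate) of the gamma full conditional of one gene's precision."""
    y, m, u = map(np.asarray, (y, mu_per_sample, u))
    return (prior_shape + 0.5 * y.size,
            prior_rate + 0.5 * float((u * (y - m) ** 2).sum()))


def mixing_conditional(pattern_counts, concentration: float = 1.0):
    """Dirichlet parameter of the full conditional of p."""
    return concentration + np.asarray(pattern_counts, dtype=float)


def cn_contamination_probability(residual, tau, lam, gam):
    """P(u = gamma | residual) for the contaminated-normal scale factor."""
    e2t = tau * residual ** 2
    w1 = lam * np.sqrt(gam) * np.exp(-0.5 * gam * e2t)
    w0 = (1.0 - lam) * np.exp(-0.5 * e2t)
    return w1 / (w0 + w1)


def slash_shape_conditional(u, prior_shape=1.0, prior_rate=0.005):
    u = np.asarray(u)
    return prior_shape + u.size, prior_rate - float(np.log(u).sum())


def laplace_shape_conditional(u, prior_shape=1.0, prior_rate=0.005):
    u = np.asarray(u)
    return prior_shape + u.size, prior_rate + float((1.0 / u).sum())


def pattern_log_weights(su, sy, tau_e, tau_mu, p, k):
    """Python mirror of the collapsed pattern-update weights (for oracles)."""
    _, assign, nblocks, comp = pattern_arrays(k)
    su, sy = np.asarray(su, dtype=float), np.asarray(sy, dtype=float)
    lw = np.log(np.asarray(p, dtype=float))
    for pp in range(assign.shape[0]):
        for b in range(nblocks[pp]):
            sel = assign[pp] == b
            tb = tau_mu[comp[pp, b]]
            A = tau_e * su[sel].sum()
            C = tau_e * sy[sel].sum()
            lw[pp] += 0.5 * (np.log(tb) - np.log(tb + A)) + 0.5 * C * C / (tb + A)
    return lw


# ---------------------------------------------------------------------------
# joint-distribution (Geweke-style) self test
# ---------------------------------------------------------------------------

def geweke_traces(family: str, n_genes: int = 20, group_sizes=(3, 2),
                  n_sweeps: int = 4000, thin: int = 5, burn: int = 200,
                  seed: int = 0, config: HyperPriorConfig | None = None):
    """Successive-conditional simulator for the sampler's stationarity.

    Starts from an exact prior-predictive draw, then alternates one Gibbs
    sweep on the parameters with a redraw of the data given the parameters.
    If every full conditional is correct, the parameter marginals stay at
    the prior; returns thinned traces of tau_eps[0], the first gene's error
    precision, and p[1], the first non-null pattern probability.
    """
    config = config or HyperPriorConfig()
    rng = np.random.default_rng([seed, 424243])
    data, z0, params = prior_predictive_draw(config, family, n_genes,
                                             group_sizes, rng)
    k = data.n_groups
    _, assign, nblocks, comp = pattern_arrays(k)
    fam_code = NIFamilySpec(family, params["shapes"][0]).code \
        if family != "normal" else 0

    y = np.ascontiguousarray(data.values)
    group_of = data.group_of
    mu = np.ascontiguousarray(params["mu"])
    z = z0.astype(np.int64)
    u = np.ascontiguousarray(params["u"])
    b = (u != 1.0).astype(np.uint8)
    tau_eps = params["tau_eps"].copy()
    nu = np.zeros((n_genes, 2))
    for i, shp in enumerate(params["shapes"]):
        for j, s in enumerate(shp):
            nu[i, j] = s
    p = params["p"].copy()
    tau_mu = params["tau_mu"].copy()

    _kernels.seed_rng(_chain_seed(seed, 999))
    mu_cols = np.empty_like(y)
    tau_tr, p_tr = [], []
    for it in range(n_sweeps):
        _kernels.sweep(y, group_of, mu, z, u, b, tau_eps, nu, p, tau_mu,
                       assign, nblocks, comp, fam_code, 0.5)
        mu_cols[:] = mu[:, group_of]
        y[:] = mu_cols + rng.standard_normal(y.shape) / np.sqrt(
            u * tau_eps[:, None])
        if it >= burn and (it - burn) % thin == 0:
            tau_tr.append(tau_eps[0])
            p_tr.append(p[1])
    return {"tau_eps": np.array(tau_tr), "p": np.array(p_tr)}
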