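"""Hierarchical mixture model over group-mean equality patterns.

Per gene i, group s, replicate r the observed log-expression is

    Y_isr = mu_is + eps_isr / sqrt(U_isr),
    eps_isr | tau_eps_i ~ N(0, 1/tau_eps_i),   U_isr ~ g(u; nu_i),

with a mixture prior over the vector of group means mu_i = (mu_i1..mu_ik):
a set partition z_i of the groups assigns groups in one block a common mean.
For two groups this is the spike mixture

    mu_i ~ (1-p) N(mu_i1; 0, 1/tau_mu12) I[mu_i1 = mu_i2]
         +   p   N(mu_i1; 0, 1/tau_mu1) N(mu_i2; 0, 1/tau_mu2),

and for k groups every set partition of {1..k} is a mixture component.  A
multi-group block's mean gets the shared precision tau_mu12; a singleton
block of group s gets tau_mus.  All precisions carry Gamma(1, 0.005)
(shape-rate) priors and the pattern probabilities a symmetric Dirichlet(1).

A gene is differentially expressed iff its pattern has more than one block
(union-intersection over all pairwise equalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .families import NIFamilySpec, sample_nid, LocationScale

__all__ = [
    "ExpressionDataset",
    "PartitionPattern",
    "HyperPriorConfig",
    "enumerate_partitions",
    "pattern_pairwise_map",
    "pattern_arrays",
    "prior_predictive_draw",
]

MAX_GROUPS = 5


@dataclass
class ExpressionDataset:
    """Gene x sample matrix with a group label per sample column.

    ``values[i, j]`` is the (already log-transformed) expression of gene i in
    sample j; ``group_of[j]`` indexes into ``group_names``.  Columns need not
    be sorted by group.
    """

    values: np.ndarray
    gene_ids: list
    group_names: list
    group_of: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.group_of = np.asarray(self.group_of, dtype=np.int64)
        n_genes, n_samples = self.values.shape
        if n_genes < 1:
            raise ValueError("need at least one gene")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix")
        if self.group_of.shape != (n_samples,):
            raise ValueError("group_of length does not match matrix columns")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")
        k = len(self.group_names)
        if k < 2:
            raise ValueError("need at least two groups")
        sizes = np.bincount(self.group_of, minlength=k)
        if (sizes < 2).any():
            bad = self.group_names[int(np.argmin(sizes))]
            raise ValueError(f"group {bad!r} has fewer than 2 replicates")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group_of, minlength=self.n_groups)

    def group_values(self, s: int) -> np.ndarray:
        """(n_genes, n_s) slice of the matrix for group index s."""
        return self.values[:, self.group_of == s]


@dataclass(frozen=True)
class PartitionPattern:
    """A set partition of group indices; groups in one block share a mean."""

    blocks: tuple  # tuple of tuples of 0-based group indices

    def __post_init__(self):
        flat = sorted(g for b in self.blocks for g in b)
        if flat != list(range(len(flat))) or not all(self.blocks):
            raise ValueError("blocks must be disjoint, non-empty and cover the groups")

    @property
    def n_groups(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def is_null(self) -> bool:
        return len(self.blocks) == 1

    @property
    def assignment(self) -> np.ndarray:
        """Block index of each group (restricted-growth form)."""
        out = np.empty(self.n_groups, dtype=np.int64)
        for b, members in enumerate(self.blocks):
            for g in members:
                out[g] = b
        return out


def enumerate_partitions(k: int) -> list[PartitionPattern]:
    """All set partitions of {1..k} in restricted-growth lexicographic order.

    The all-equal partition comes first; for k=3 the order is the canonical
    five-pattern list (all equal; 1=2; 1=3; 2=3; all distinct).
    """
    if not 2 <= k <= MAX_GROUPS:
        raise ValueError(f"group count must be in [2, {MAX_GROUPS}], got {k}")

    def _grow(prefix, nmax):
        if len(prefix) == k:
            yield list(prefix)
            return
        for b in range(nmax + 1):
            yield from _grow(prefix + [b], max(nmax, b + 1))

    patterns = []
    for assign in _grow([0], 1):
        nb = max(assign) + 1
        blocks = tuple(tuple(g for g in range(k) if assign[g] == b)
                       for b in range(nb))
        patterns.append(PartitionPattern(blocks))
    return patterns


def pattern_pairwise_map(pattern: PartitionPattern) -> np.ndarray:
    """Boolean (k, k) matrix: True where the two groups have unequal means."""
    a = pattern.assignment
    return a[:, None] != a[None, :]


def pattern_arrays(k: int):
    """Dense arrays describing the partitions, as consumed by the kernels.

    Returns (patterns, assign, nblocks, comp): assign[p, g] is the block of
    group g under pattern p; comp[p, b] indexes the prior-precision component
    of block b (0 = shared tau_mu12 for blocks of 2+ groups, s+1 = tau_mus
    for a singleton of group s).
    """
    patterns = enumerate_partitions(k)
    P = len(patterns)
    assign = np.zeros((P, k), dtype=np.int64)
    nblocks = np.zeros(P, dtype=np.int64)
    comp = np.zeros((P, k), dtype=np.int64)
    for p, pat in enumerate(patterns):
        assign[p] = pat.assignment
        nblocks[p] = len(pat.blocks)
        for b, members in enumerate(pat.blocks):
            comp[p, b] = 0 if len(members) > 1 else members[0] + 1
    return patterns, assign, nblocks, comp


@dataclass(frozen=True)
class HyperPriorConfig:
    """Hyperprior settings; defaults are the low-informative choices.

    All Gamma priors are shape-rate.  ``pattern_concentration`` is the
    symmetric Dirichlet concentration over equality patterns.
    """

    tau_shape: float = 1.0
    tau_rate: float = 0.005
    pattern_concentration: float = 1.0
    t_df_max: float = 100.0

    def __post_init__(self):
        if min(self.tau_shape, self.tau_rate, self.pattern_concentration,
               self.t_df_max) <= 0:
            raise ValueError("hyperprior parameters must be positive")


def _draw_shape_prior(family: str, rng: np.random.Generator,
                      config: HyperPriorConfig) -> tuple:
    if family == "normal":
        return ()
    if family == "t":
        return (rng.uniform(1e-6, config.t_df_max),)
    if family == "contaminated_normal":
        return (rng.uniform(1e-6, 1 - 1e-6), rng.uniform(1e-6, 1 - 1e-6))
    # slash and laplace rate parameters share the Gamma(1, 0.005) prior
    return (max(rng.gamma(config.tau_shape, 1.0 / config.tau_rate), 1e-6),)


def prior_predictive_draw(config: HyperPriorConfig, family: str, n_genes: int,
                          group_sizes, rng: np.random.Generator):
    """Sample (dataset, patterns z, params) from the full prior predictive.

    Used by the sampler joint-distribution (Geweke-style) tests: hyper-
    parameters from their priors, per-gene patterns from p, block means from
    the pattern-specific normal priors, then data through the N/I errors.
    """
    group_sizes = np.asarray(group_sizes, dtype=int)
    k = len(group_sizes)
    patterns, assign, nblocks, comp = pattern_arrays(k)
    P = len(patterns)
    tau_mu = rng.gamma(config.tau_shape, 1.0 / config.tau_rate, size=k + 1)
    p = rng.dirichlet(np.full(P, config.pattern_concentration))
    tau_eps = rng.gamma(config.tau_shape, 1.0 / config.tau_rate, size=n_genes)
    z = rng.choice(P, size=n_genes, p=p)
    group_of = np.repeat(np.arange(k), group_sizes)

    mu = np.zeros((n_genes, k))
    shapes = []
    values = np.zeros((n_genes, group_of.size))
    u_vals = np.ones_like(values)
    for i in range(n_genes):
        pat = patterns[z[i]]
        for b, members in enumerate(pat.blocks):
            c = comp[z[i], b]
            m = rng.normal(0.0, 1.0 / np.sqrt(tau_mu[c]))
            for g in members:
                mu[i, g] = m
        shp = _draw_shape_prior(family, rng, config)
        shapes.append(shp)
        spec = NIFamilySpec(family, shp)
        for s in range(k):
            cols = np.flatnonzero(group_of == s)
            values[i, cols], u_vals[i, cols] = sample_nid(
                LocationScale(mu[i, s], 1.0 / tau_eps[i]), spec,
                len(cols), rng, return_u=True)

    data = ExpressionDataset(values, [f"g{i}" for i in range(n_genes)],
                             [f"grp{s + 1}" for s in range(k)], group_of)
    params = {"tau_mu": tau_mu, "p": p, "tau_eps": tau_eps, "mu": mu,
              "shapes": shapes, "u": u_vals}
    return data, z, params
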