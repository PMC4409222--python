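"""Synthetic two-group expression data and the simulation protocol.

Each replication generates N genes with a common baseline location (default
14, a typical log2 intensity) and unit error variance; a fixed fraction p of
genes (default 5%) has its *group-1* location shifted by delta.  Errors are
drawn from a configurable N/I family — contaminated normal with
(lambda=0.1, gamma in {0.10, 0.25}) or Student t with 2 df emulate heavy
outlier regimes.  Group sizes default to (27, 11), an unbalanced design of
the size found in two-class leukaemia panels.

Per replication k and fitted family, the model is fit by MCMC, genes are
called at posterior threshold 0.5, and the rates

    TPR_k = sum I_real I_called / (N p),
    FPR_k = sum (1-I_real) I_called / (N (1-p)),
    TDR_k = sum I_real I_called / sum I_called,

plus the truth-based AUC_k are recorded and averaged over replications.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decisions import de_probability, truth_roc_auc
from .families import NIFamilySpec, sample_nid, LocationScale
from .mcmc import MCMCConfig, run_chains, simulation_defaults
from .model import ExpressionDataset

__all__ = [
    "SimulationConfig",
    "SimulationMetrics",
    "generate_dataset",
    "replication_metrics",
    "run_study",
]

log = logging.getLogger(__name__)

METRIC_COLUMNS = ("TPR", "FPR", "TDR", "AUC")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design; defaults are the standard heavy-tail benchmark."""

    n_genes: int = 1000
    n_reps: int = 100
    group_sizes: tuple = (27, 11)
    base_mu: float = 14.0
    sigma: float = 1.0
    error_family: NIFamilySpec = field(
        default_factory=lambda: NIFamilySpec.contaminated_normal(0.1, 0.1))
    delta: float = 3.0
    de_fraction: float = 0.05
    fit_families: tuple = ("contaminated_normal",)
    kappa: float = 0.5
    n_iter: int = 15000
    n_burnin: int = 10000
    n_chains: int = 1
    seed: int = 0
    redraw_de_genes: bool = True  # redraw the DE subset each replication

    def __post_init__(self):
        if not 0.0 < self.de_fraction < 1.0:
            raise ValueError("de_fraction must be in (0, 1)")
        if round(self.n_genes * self.de_fraction) < 1:
            raise ValueError("no DE genes at this size and fraction")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")

    @property
    def n_de(self) -> int:
        return int(round(self.n_genes * self.de_fraction))

    def mcmc_for(self, family: str, rep: int) -> MCMCConfig:
        from .families import FAMILY_CODES
        seed = int(np.random.SeedSequence(
            [self.seed, rep, FAMILY_CODES[family]]).generate_state(1)[0]
            % (2 ** 31 - 1))
        return simulation_defaults(NIFamilySpec(family, _default_fit_shape(family)),
                                   seed=seed, n_iter=self.n_iter,
                                   n_burnin=self.n_burnin)


def _default_fit_shape(family: str) -> tuple:
    """Shape starting values for fitting; sampled in the chain thereafter."""
    return {"normal": (), "t": (5.0,), "slash": (2.0,),
            "contaminated_normal": (0.5, 0.5), "laplace": (1.0,)}[family]


@dataclass
class SimulationMetrics:
    """Per-replication rates and their Monte-Carlo averages for one family."""

    family: str
    per_rep: pd.DataFrame  # columns TPR, FPR, TDR, AUC indexed by replication
    n_undefined_tdr: int = 0

    @property
    def means(self) -> pd.Series:
        return self.per_rep.mean()

    @property
    def mc_se(self) -> pd.Series:
        m = len(self.per_rep)
        return self.per_rep.std(ddof=1) / np.sqrt(m) if m > 1 else \
            self.per_rep.iloc[0] * np.nan

    def summary_row(self) -> dict:
        row = {"family": self.family}
        for c in METRIC_COLUMNS:
            row[c] = self.means[c]
            row[f"{c}_se"] = self.mc_se[c]
        row["n_undefined_tdr"] = self.n_undefined_tdr
        return row


def generate_dataset(config: SimulationConfig, rep: int):
    """One replication: (dataset, truth labels).

    Exactly round(N * de_fraction) genes are shifted by delta in group 1;
    errors come from ``config.error_family`` with variance ``sigma``.  The
    stream is seeded by (config.seed, rep) so replications are independent
    and reproducible.
    """
    if not 1 <= rep <= max(config.n_reps, rep):
        raise ValueError("replication index must be >= 1")
    rng = np.random.default_rng([config.seed, rep])
    N = config.n_genes
    k = len(config.group_sizes)
    group_of = np.repeat(np.arange(k), config.group_sizes)
    n = group_of.size

    de_rng = rng if config.redraw_de_genes else \
        np.random.default_rng([config.seed, 0])
    de_idx = de_rng.choice(N, size=config.n_de, replace=False)
    truth = np.zeros(N, dtype=np.int8)
    truth[de_idx] = 1

    errors = sample_nid(LocationScale(0.0, config.sigma), config.error_family,
                        N * n, rng).reshape(N, n)
    means = np.full((N, n), config.base_mu)
    means[np.ix_(de_idx, np.flatnonzero(group_of == 0))] += config.delta
    values = means + errors
    data = ExpressionDataset(values, [f"g{i}" for i in range(N)],
                             [f"grp{s + 1}" for s in range(k)], group_of)
    return data, truth


def replication_metrics(truth, calls, pi, config: SimulationConfig):
    """(TPR_k, FPR_k, TDR_k, AUC_k) for one replication.

    TDR is NaN when no gene is called (empty denominator); such
    replications are excluded from the TDR average with a count.
    """
    truth = np.asarray(truth, dtype=float)
    calls = np.asarray(calls, dtype=float)
    if truth.size != calls.size or truth.size != np.asarray(pi).size:
        raise ValueError("truth, calls and pi lengths differ")
    N = truth.size
    p = config.de_fraction
    tp = float((truth * calls).sum())
    fp = float(((1.0 - truth) * calls).sum())
    tpr = tp / (N * p)
    fpr = fp / (N * (1.0 - p))
    n_called = tp + fp
    tdr = tp / n_called if n_called > 0 else float("nan")
    auc = truth_roc_auc(pi, truth)
    return tpr, fpr, tdr, auc


def run_study(config: SimulationConfig, out_dir: str | Path | None = None,
              progress: bool = False) -> dict[str, SimulationMetrics]:
    """Full protocol: generate -> fit each family -> rates -> averages.

    With ``out_dir`` set, per-replication metrics are checkpointed to TSV
    and finished replications are skipped on re-run.  Replications whose
    MCMC fails are logged and excluded with a visible count.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows: dict[str, list] = {f: [] for f in config.fit_families}
    n_failed = 0
    for rep in range(1, config.n_reps + 1):
        ck = out_dir / f"rep_{rep:04d}.tsv" if out_dir is not None else None
        if ck is not None and ck.exists():
            prev = pd.read_csv(ck, sep="\t")
            for f in config.fit_families:
                rows[f].append(prev[prev.family == f].iloc[0])
            continue
        data, truth = generate_dataset(config, rep)
        rep_rows = []
        for fam in config.fit_families:
            try:
                draws = run_chains(data, config.mcmc_for(fam, rep))
            except RuntimeError as err:  # pragma: no cover - defensive
                log.error("replication %d, family %s failed: %s", rep, fam, err)
                n_failed += 1
                continue
            summary = de_probability(draws)
            calls = summary.pi > config.kappa
            tpr, fpr, tdr, auc = replication_metrics(truth, calls,
                                                     summary.pi, config)
            rep_rows.append(pd.Series(
                {"rep": rep, "family": fam, "TPR": tpr, "FPR": fpr,
                 "TDR": tdr, "AUC": auc}))
            rows[fam].append(rep_rows[-1])
        if ck is not None and rep_rows:
            pd.DataFrame(rep_rows).to_csv(ck, sep="\t", index=False)
        if progress:
            log.info("replication %d/%d done", rep, config.n_reps)

    out = {}
    for fam in config.fit_families:
        df = pd.DataFrame(rows[fam])
        if df.empty:
            continue
        df = df.set_index("rep")[list(METRIC_COLUMNS)].astype(float)
        out[fam] = SimulationMetrics(
            family=fam, per_rep=df,
            n_undefined_tdr=int(df["TDR"].isna().sum()))
        # NaN TDR replications are excluded from the mean by pandas
    if n_failed:
        log.warning("%d replication fits failed and were excluded", n_failed)
    if out_dir is not None:
        summary = pd.DataFrame([m.summary_row() for m in out.values()])
        summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        manifest = {"seed": config.seed, "n_genes": config.n_genes,
                    "n_reps": config.n_reps, "delta": config.delta,
                    "error_family": [config.error_family.family,
                                     list(config.error_family.shape)],
                    "n_failed": n_failed}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def study_table(metrics: dict[str, SimulationMetrics]) -> pd.DataFrame:
    """Aggregated table (one row per fitted family) with MC standard errors."""
    return pd.DataFrame([m.summary_row() for m in metrics.values()])
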