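"""Synthetic benchmark generator with planted expression-dependent occupancy.

Emulates the statistical structure the scoring pipeline assumes: each gene
carries a Poisson number of binding sites, each site a negative binding free
energy, and each miRNA a read-count-like log-normal abundance (floored at 50,
mirroring the usual minimum-read filter).  Ground truth is the FD occupancy
computed from the true energies and abundances; positive labels are the
top-occupancy genes, balanced against the remainder.

Four per-tool observation tables are derived from the truth: two tools emit
noisy energies (FD combination path), two emit noisy positive scores (WSUM
path); a configurable detection-dropout rate creates the partial inter-tool
overlap seen among real predictors.

Abundance units are arbitrary in the FD model (mu shifts additively under
rescaling), so the generator converts read counts to concentrations with a
global scale placing the median chemical potential at the mean binding
energy — the responsive regime where expression can modulate occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .thermo import GeneScoreTable, RT_DEFAULT, fd_gene_scores, naive_gene_scores
from .wsum import wsum_gene_scores

#: Which simulated predictor emits energies vs positive scores.
TOOL_KINDS = {
    "energy_a": "energy",
    "energy_b": "energy",
    "score_a": "score",
    "score_b": "score",
}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults define the standard study conditions."""

    n_genes: int = 2000
    n_mirnas: int = 25
    mean_sites_per_gene: float = 4.0
    energy_mean: float = -8.0       # kcal/mol
    energy_sd: float = 1.0          # kcal/mol, truncated at <= 0
    expression_meanlog: float = math.log(5000.0)  # read-count-like
    expression_sdlog: float = 6.0   # miRNA pools are dominated by a few species
    expression_floor: float = 50.0  # minimum-read filter
    rt: float = RT_DEFAULT
    pos_fraction: float = 0.5       # balanced positive/negative design
    primary_mirna_prob: float = 0.7  # chance a site belongs to the gene's primary miRNA
    tool_noise_sd: float = 0.5      # kcal/mol additive per-tool observation noise
    tool_rel_noise_sd: float = 0.2  # multiplicative per-tool energy disagreement
    #: Per-tool score-scale curvature (energy_a, energy_b, score_a, score_b):
    #: each tool reports magnitudes on its own convex/concave scale, the way
    #: real predictors' scoring models stretch or compress strong sites.
    tool_curvature: tuple = (1.0, 1.6, 0.7, 1.3)
    #: Maximum per-tool detection dropout, reached for the weakest sites.
    #: Detection is strength-dependent: strong (very negative) sites are
    #: consensus calls every predictor reports, marginal sites are called
    #: idiosyncratically.  The per-site dropout probability is
    #: ``dropout * expit((E - (energy_mean + 2)) / 1.5)``.
    dropout: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_mirnas < 1:
            raise ValueError("need at least 2 genes and 1 miRNA")
        for name in ("mean_sites_per_gene", "energy_sd", "expression_sdlog",
                     "tool_noise_sd", "tool_rel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.dropout <= 1):
            raise ValueError("dropout must be in [0, 1]")
        if not (0 <= self.primary_mirna_prob <= 1):
            raise ValueError("primary_mirna_prob must be in [0, 1]")
        if not (0 < self.pos_fraction < 1):
            raise ValueError("pos_fraction must be in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def expression_scale(self) -> float:
        """Read-count -> concentration factor centering mu on the energy mean."""
        return math.exp(self.energy_mean / self.rt - self.expression_meanlog)


@dataclass
class SimulatedDataset:
    """Ground-truth site table plus expression, labels and true occupancy."""

    sites: pd.DataFrame          # true energies, tool = "truth"
    expression: pd.Series        # mirna_id -> read-count-like level
    labels: pd.Series            # gene_id -> 0/1
    occupancy: pd.Series         # gene_id -> true FD score
    config: SimConfig = field(repr=False, default=None)


def _truncated_energies(rng, n, mean, sd):
    if sd == 0:
        return np.full(n, min(mean, 0.0))
    b = (0.0 - mean) / sd  # upper bound at 0 kcal/mol
    return truncnorm.rvs(-np.inf, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Draw a dataset; reproducible from ``cfg.seed``.

    Labels: the top ``pos_fraction`` of genes by true FD occupancy are
    positives, the rest negatives (ties broken by gene id), emulating a
    balanced IP-derived positive set against highly expressed non-targets.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    mirnas = [f"mir{j:03d}" for j in range(cfg.n_mirnas)]

    levels = np.exp(rng.normal(cfg.expression_meanlog, cfg.expression_sdlog,
                               cfg.n_mirnas))
    levels = np.maximum(levels, cfg.expression_floor)
    expression = pd.Series(levels, index=mirnas, name="level")

    counts = rng.poisson(cfg.mean_sites_per_gene, cfg.n_genes)
    gene_col = np.repeat(genes, counts)
    n_sites = int(counts.sum())
    # Sites cluster on a per-gene primary miRNA (real 3'UTRs often carry
    # repeated sites of one regulator); the rest hit uniform miRNAs.
    primary = rng.integers(0, cfg.n_mirnas, cfg.n_genes)
    mirna_col = np.where(
        rng.random(n_sites) < cfg.primary_mirna_prob,
        np.repeat(primary, counts),
        rng.integers(0, cfg.n_mirnas, n_sites),
    )
    energies = _truncated_energies(rng, n_sites, cfg.energy_mean, cfg.energy_sd)
    within = np.concatenate([np.arange(c) for c in counts]) if n_sites else np.array([], int)
    sites = pd.DataFrame({
        "gene_id": gene_col,
        "mirna_id": [mirnas[j] for j in mirna_col],
        "start": within * 8,
        "end": within * 8 + 7,
        "tool": "truth",
        "score": energies,
    })

    occupancy = fd_gene_scores(
        sites, expression, rt=cfg.rt,
        expression_scale=cfg.expression_scale, genes=genes,
    ).scores.rename("occupancy")

    n_pos = round(cfg.pos_fraction * cfg.n_genes)
    if n_pos == 0 or n_pos == cfg.n_genes:
        raise ValueError(
            f"infeasible class balance: {n_pos} positives of {cfg.n_genes} genes"
        )
    ranked = occupancy.sort_values(ascending=False, kind="stable")
    positives = set(ranked.index[:n_pos])
    labels = pd.Series(
        [1 if g in positives else 0 for g in genes], index=genes, name="label"
    )
    return SimulatedDataset(sites, expression, labels, occupancy, cfg)


def simulate_tool_scores(dataset: SimulatedDataset, cfg: SimConfig | None = None) -> dict[str, pd.DataFrame]:
    """Derive the four per-tool site tables from the true site table.

    Each tool reports site strengths on its own scale: the true magnitude
    ``|E|`` is raised to a tool-specific curvature exponent (anchored so the
    mean-strength site keeps its value), then perturbed by multiplicative and
    additive noise — emulating real predictors, whose scoring models agree on
    which sites are strong but stretch or compress the strong tail very
    differently.  Score tools report the negated observation clipped at 0
    (oriented larger = stronger).  Each tool independently drops sites at the
    configured rate, creating partial inter-tool overlap.  Reproducible: each
    tool uses a child seed of ``cfg.seed``.
    """
    cfg = cfg if cfg is not None else dataset.config
    truth = dataset.sites
    anchor = -cfg.energy_mean  # curvature pivots around the mean site strength
    tables: dict[str, pd.DataFrame] = {}
    e_true = truth["score"].to_numpy()
    p_drop = cfg.dropout * expit((e_true - (cfg.energy_mean + 2.0)) / 1.5)
    for t, (tool, kind) in enumerate(sorted(TOOL_KINDS.items())):
        rng = np.random.default_rng((cfg.seed, 1 + t))
        keep = rng.random(len(truth)) >= p_drop
        obs = truth.loc[keep].copy()
        gamma = cfg.tool_curvature[t]
        mag = np.abs(obs["score"].to_numpy())
        bent = anchor * (mag / anchor) ** gamma
        observed = (
            -bent * (1.0 + rng.normal(0.0, cfg.tool_rel_noise_sd, len(obs)))
            + rng.normal(0.0, cfg.tool_noise_sd, len(obs))
        )
        if kind == "energy":
            obs["score"] = observed
        else:
            obs["score"] = np.maximum(-observed, 0.0)
        obs["tool"] = tool
        tables[tool] = obs.reset_index(drop=True)
    return tables


def combine_tool_tables(
    tool_tables: dict[str, pd.DataFrame],
    expression: pd.Series,
    cfg: SimConfig,
    scheme: str = "comir",
    genes=None,
) -> list[GeneScoreTable]:
    """Per-tool combined gene scores under the expression-aware or naive scheme.

    ``comir``: FD combination for energy tools, WSUM for score tools.
    ``naive``: expression-blind sums (energies negated so larger = stronger).
    """
    if scheme not in ("comir", "naive"):
        raise ValueError(f"unknown combination scheme {scheme!r}")
    tables = []
    for tool in sorted(tool_tables):
        df = tool_tables[tool]
        kind = TOOL_KINDS.get(tool)
        if kind is None:
            raise ValueError(f"unknown simulated tool {tool!r}")
        if scheme == "comir":
            if kind == "energy":
                tables.append(fd_gene_scores(
                    df, expression, rt=cfg.rt,
                    expression_scale=cfg.expression_scale,
                    genes=genes, tool=tool,
                ))
            else:
                tables.append(wsum_gene_scores(df, expression, genes=genes, tool=tool))
        else:
            tables.append(naive_gene_scores(
                df, negate=(kind == "energy"), genes=genes, tool=tool,
            ))
    return tables


def simulate_transfection_fc(
    n_genes: int,
    a: float,
    b: float,
    c: float,
    noise_sd: float,
    seed: int,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Planted co-transfection fold changes for the additivity regression.

    ``FC_lm = intercept + a*FC_l + b*FC_m + c*FC_l*FC_m + N(0, noise_sd)``
    with standard-normal single-transfection fold changes.
    """
    rng = np.random.default_rng(seed)
    fc_l = rng.normal(0.0, 1.0, n_genes)
    fc_m = rng.normal(0.0, 1.0, n_genes)
    eps = rng.normal(0.0, noise_sd, n_genes) if noise_sd > 0 else 0.0
    fc_lm = intercept + a * fc_l + b * fc_m + c * fc_l * fc_m + eps
    return pd.DataFrame({"fc_l": fc_l, "fc_m": fc_m, "fc_lm": fc_lm})
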