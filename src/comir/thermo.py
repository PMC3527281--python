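"""Fermi-Dirac occupancy scoring of miRNA binding sites.

Energy-emitting target predictors report a binding free energy ``E`` (kcal/mol,
typically negative) for each predicted site.  Treating every site as an
independent two-state system in contact with a reservoir of its miRNA at
chemical potential ``mu = RT * ln([miR])``, the probability that the site is
occupied is the Fermi-Dirac form

    p = 1 / (1 + exp((E - mu) / RT))

A gene's combined (FD) score is the sum of occupancy probabilities over all
sites of all considered miRNAs, so it lies between 0 and the gene's total site
count and increases with both binding strength and miRNA abundance.  The naive
baseline ignores expression and simply adds oriented site scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

logger = logging.getLogger(__name__)

#: Thermal energy RT in kcal/mol (R = 1.987e-3 kcal/mol/K, T = 310.15 K).
RT_DEFAULT = 0.6163

#: Canonical column order of a binding-site table.
SITE_COLUMNS = ("gene_id", "mirna_id", "start", "end", "tool", "score")


@dataclass(frozen=True)
class BindingSite:
    """One predicted miRNA binding site on a gene's 3'UTR.

    ``score`` is tool-specific: a free energy in kcal/mol for energy-based
    predictors (typically <= 0), or a positive "larger = stronger" score for
    score-based predictors.  Coordinates are 0-based half-open on the UTR.
    """

    gene_id: str
    mirna_id: str
    start: int
    end: int
    tool: str
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid site interval [{self.start}, {self.end}) for "
                f"{self.gene_id}/{self.mirna_id}: need end > start >= 0"
            )
        if not math.isfinite(self.score):
            raise ValueError(
                f"non-finite site score for {self.gene_id}/{self.mirna_id}"
            )


def sites_to_frame(sites: Iterable[BindingSite]) -> pd.DataFrame:
    """Convert ``BindingSite`` records to the canonical site table."""
    rows = [
        (s.gene_id, s.mirna_id, s.start, s.end, s.tool, s.score) for s in sites
    ]
    return pd.DataFrame(rows, columns=list(SITE_COLUMNS))


def as_site_frame(sites) -> pd.DataFrame:
    """Accept a site DataFrame or an iterable of BindingSite records."""
    if isinstance(sites, pd.DataFrame):
        missing = set(SITE_COLUMNS) - set(sites.columns)
        if missing:
            raise ValueError(f"site table missing columns: {sorted(missing)}")
        return sites
    return sites_to_frame(sites)


@dataclass
class GeneScoreTable:
    """Per-gene combined scores for one predictor under one combination rule."""

    scores: pd.Series  # index: gene_id -> combined score
    tool: str
    method: str  # "fd" | "wsum" | "naive"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scores.isna().any():
            raise ValueError(f"NaN combined score for tool {self.tool!r}")
        self.scores = self.scores.astype(float)


def _as_expression(expression) -> pd.Series:
    expr = pd.Series(expression, dtype=float)
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate miRNA ids in expression table: {dups}")
    return expr


def chemical_potential(level, rt: float = RT_DEFAULT):
    """Chemical potential ``mu = RT * ln(level)`` of a miRNA species.

    ``level`` is the miRNA abundance in the (arbitrary) concentration units
    the caller works in; rescaling units shifts mu additively.
    """
    if rt <= 0:
        raise ValueError(f"RT must be positive, got {rt}")
    level_arr = np.asarray(level, dtype=float)
    if np.any(level_arr <= 0):
        raise ValueError(
            f"miRNA abundance must be > 0 to define a chemical potential, got {level}"
        )
    out = rt * np.log(level_arr)
    return float(out) if np.isscalar(level) or level_arr.ndim == 0 else out


def fd_site_probability(energy, mu, rt: float = RT_DEFAULT):
    """Fermi-Dirac occupancy ``1 / (1 + exp((E - mu) / RT))``.

    Evaluated through a numerically stable logistic, so arbitrarily large
    ``|E - mu| / RT`` (and the E -> +/-inf limits) neither overflow nor lose
    the 0/1 limits.  Strictly decreasing in E, strictly increasing in mu.
    """
    if rt <= 0:
        raise ValueError(f"RT must be positive, got {rt}")
    e = np.asarray(energy, dtype=float)
    m = np.asarray(mu, dtype=float)
    with np.errstate(invalid="ignore"):
        arg = (m - e) / rt
        # E and mu both infinite is ill-posed; anything else is a clean limit.
        if np.any(np.isnan(arg) & ~(np.isnan(e) | np.isnan(m))):
            raise ValueError("fd_site_probability: E and mu are both infinite")
    p = expit(arg)
    if np.isscalar(energy) and np.isscalar(mu):
        return float(p)
    return p


def drop_unexpressed_sites(sites: pd.DataFrame, expression: pd.Series) -> pd.DataFrame:
    """Drop sites of miRNAs absent from ``expression`` or with level <= 0.

    Only expressed miRNAs take part in combinatorial scoring; dropped site
    counts are logged so input filtering stays auditable.
    """
    expressed = set(expression.index[expression > 0])
    keep = sites["mirna_id"].isin(expressed)
    n_drop = int((~keep).sum())
    if n_drop:
        dropped = sorted(sites.loc[~keep, "mirna_id"].unique())
        logger.warning(
            "dropping %d site(s) of %d unexpressed/absent miRNA(s): %s",
            n_drop, len(dropped), ", ".join(dropped[:10]),
        )
    return sites.loc[keep]


def fd_gene_scores(
    sites,
    expression,
    *,
    rt: float = RT_DEFAULT,
    expression_scale: float = 1.0,
    genes: Iterable[str] | None = None,
    tool: str | None = None,
) -> GeneScoreTable:
    """Combine energy-based sites into per-gene FD scores.

    Parameters
    ----------
    sites
        Site table (or BindingSite iterable) whose ``score`` column holds
        binding free energies in kcal/mol.
    expression
        Mapping/Series miRNA id -> abundance level (> 0 to contribute).
    expression_scale
        Global factor converting abundance units to the concentration entering
        mu; shifts every mu additively by ``RT * ln(scale)``.
    genes
        Optional gene universe; genes without sites score 0.
    """
    if expression_scale <= 0:
        raise ValueError("expression_scale must be positive")
    frame = as_site_frame(sites)
    expr = _as_expression(expression)
    frame = drop_unexpressed_sites(frame, expr)
    if len(frame):
        mu = chemical_potential(
            (expr * expression_scale).loc[frame["mirna_id"]].to_numpy(), rt
        )
        p = fd_site_probability(frame["score"].to_numpy(), mu, rt)
        per_gene = pd.Series(p, index=frame["gene_id"].to_numpy()).groupby(level=0).sum()
    else:
        per_gene = pd.Series(dtype=float)
    if genes is not None:
        per_gene = per_gene.reindex(sorted(genes), fill_value=0.0)
    per_gene = per_gene.sort_index()
    label = tool if tool is not None else _single_tool_label(frame)
    return GeneScoreTable(
        per_gene, tool=label, method="fd",
        meta={"rt": rt, "expression_scale": expression_scale,
              "n_mirnas": int(expr.gt(0).sum())},
    )


def fd_gene_score(
    sites,
    expression,
    *,
    rt: float = RT_DEFAULT,
    expression_scale: float = 1.0,
) -> float:
    """FD score of a single gene: sum of site occupancies over its sites."""
    frame = as_site_frame(sites)
    if frame.empty:
        return 0.0
    table = fd_gene_scores(
        frame, expression, rt=rt, expression_scale=expression_scale
    )
    return float(table.scores.sum())


def naive_gene_scores(
    sites,
    *,
    negate: bool = False,
    genes: Iterable[str] | None = None,
    tool: str | None = None,
) -> GeneScoreTable:
    """Expression-blind baseline: per-gene sum of oriented site scores.

    For energy-emitting predictors pass ``negate=True`` so that stronger
    (more negative) energies yield larger scores.
    """
    frame = as_site_frame(sites)
    oriented = -frame["score"] if negate else frame["score"]
    per_gene = oriented.groupby(frame["gene_id"].to_numpy()).sum()
    if genes is not None:
        per_gene = per_gene.reindex(sorted(genes), fill_value=0.0)
    per_gene = per_gene.sort_index()
    label = tool if tool is not None else _single_tool_label(frame)
    return GeneScoreTable(per_gene, tool=label, method="naive",
                          meta={"negated_energies": negate})


def naive_gene_score(sites, *, negate: bool = False) -> float:
    """Naive score of a single gene (sum of oriented site scores)."""
    frame = as_site_frame(sites)
    if frame.empty:
        return 0.0
    oriented = -frame["score"] if negate else frame["score"]
    return float(oriented.sum())


def top_fraction_targets(table: GeneScoreTable, q: float) -> set[str]:
    """Genes in the top fraction ``q`` of combined scores.

    The cut is the linear-interpolation ``(1 - q)`` quantile; every gene tied
    with the boundary score is included, so the returned set can exceed
    ``q * n`` under ties.
    """
    if not (0 < q <= 1):
        raise ValueError(f"fraction q must be in (0, 1], got {q}")
    if table.scores.empty:
        raise ValueError("cannot take top fraction of an empty score table")
    threshold = float(np.quantile(table.scores.to_numpy(), 1.0 - q))
    return set(table.scores.index[table.scores >= threshold])


def _single_tool_label(frame: pd.DataFrame) -> str:
    tools = frame["tool"].unique() if len(frame) else []
    return str(tools[0]) if len(tools) == 1 else "combined"
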