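"""Expression-weighted sum (WSUM) combination for score-based predictors.

Predictors that do not report binding energies (n-mer matchers, regression
scores) still benefit from miRNA abundance: each miRNA's summed site scores
on a gene are weighted by the miRNA's relative expression within the analyzed
set, so highly expressed miRNAs dominate the combined score.  Scaling all
abundances by a common factor leaves the weights, hence the scores, unchanged.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .thermo import GeneScoreTable, _as_expression, as_site_frame, _single_tool_label

logger = logging.getLogger(__name__)


def relative_weights(expression) -> pd.Series:
    """Per-miRNA weights ``level_i / sum_j level_j`` over the supplied set.

    miRNAs with level 0 get weight 0; negative levels are rejected.  The
    denominator runs over all supplied miRNAs (set-level normalization),
    whether or not they have sites on any particular gene.
    """
    expr = _as_expression(expression)
    if (expr < 0).any():
        bad = expr.index[expr < 0].tolist()
        raise ValueError(f"negative expression level(s) for {bad}")
    total = float(expr.sum())
    if total <= 0:
        raise ValueError("all expression levels are <= 0; weights undefined")
    return expr / total


def wsum_gene_scores(
    sites,
    expression,
    *,
    genes: Iterable[str] | None = None,
    tool: str | None = None,
) -> GeneScoreTable:
    """Combine score-based sites into per-gene WSUM scores.

    ``score = sum_i w_i * (sum_j S_ij)`` where ``w`` are :func:`relative_weights`
    of the supplied miRNA set.  Sites of miRNAs missing from the expression
    table are dropped with a warning; genes with no sites score 0.
    """
    frame = as_site_frame(sites)
    weights = relative_weights(expression)
    known = frame["mirna_id"].isin(weights.index)
    n_drop = int((~known).sum())
    if n_drop:
        dropped = sorted(frame.loc[~known, "mirna_id"].unique())
        logger.warning(
            "dropping %d site(s) of %d miRNA(s) missing from the expression set: %s",
            n_drop, len(dropped), ", ".join(dropped[:10]),
        )
    frame = frame.loc[known]
    if len(frame):
        w = weights.loc[frame["mirna_id"]].to_numpy()
        contrib = frame["score"].to_numpy() * w
        per_gene = pd.Series(contrib, index=frame["gene_id"].to_numpy()).groupby(level=0).sum()
    else:
        per_gene = pd.Series(dtype=float)
    if genes is not None:
        per_gene = per_gene.reindex(sorted(genes), fill_value=0.0)
    per_gene = per_gene.sort_index()
    label = tool if tool is not None else _single_tool_label(frame)
    return GeneScoreTable(per_gene, tool=label, method="wsum")


def wsum_gene_score(sites, weights: pd.Series) -> float:
    """WSUM score of a single gene given precomputed relative weights."""
    frame = as_site_frame(sites)
    if frame.empty:
        return 0.0
    known = frame["mirna_id"].isin(weights.index)
    if (~known).any():
        dropped = sorted(frame.loc[~known, "mirna_id"].unique())
        logger.warning("dropping sites of miRNA(s) without weights: %s", dropped)
        frame = frame.loc[known]
    if frame.empty:
        return 0.0
    w = weights.loc[frame["mirna_id"]].to_numpy()
    return float((frame["score"].to_numpy() * w).sum())
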