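"""Ranking SNPs by their disruption of combinatorial miRNA targeting.

For each SNP:miRNA pair the full scoring pipeline is run on the reference
3'UTR and on the SNP-bearing 3'UTR, yielding targeting probabilities P_ref
and P_alt.  Two ranking scores are provided:

    plain     delta = P_ref - P_alt
    weighted  delta = P_ref * (P_ref - P_alt)   (default)

The weighted form up-weights pairs where the reference allele is a
high-confidence target, focusing the ranking on sites that are both strong
and strongly disrupted.  Pairs with delta above a threshold (default 0.01)
are reported in descending order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .ensemble import EnsembleModel, FeatureMatrix, predict_probability
from .sites import SeedMatchSpec, UtrSequence, find_seed_sites, normalize_rna
from .thermo import RT_DEFAULT, fd_gene_scores, sites_to_frame

logger = logging.getLogger(__name__)

SNP_MODES = ("weighted", "plain")


@dataclass(frozen=True)
class SnpRecord:
    """A single-nucleotide substitution at a 0-based offset within a 3'UTR."""

    snp_id: str
    gene_id: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for name in ("ref", "alt"):
            base = getattr(self, name)
            if len(base) != 1:
                raise ValueError(
                    f"{self.snp_id}: {name} allele must be a single nucleotide, got {base!r}"
                )
            object.__setattr__(self, name, normalize_rna(base, context=f"{self.snp_id} {name}"))
        if self.ref == self.alt:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")
        if self.pos < 0:
            raise ValueError(f"{self.snp_id}: negative UTR offset {self.pos}")


@dataclass
class SnpRankRecord:
    """Scored SNP:miRNA pair with reference/alternate probabilities."""

    snp_id: str
    mirna_id: str
    p_ref: float
    p_alt: float
    delta: float
    mode: str
    rank: int | None = None


def apply_snp(utr: UtrSequence, snp: SnpRecord) -> UtrSequence:
    """Return a copy of the UTR with the SNP's alternate allele substituted.

    The observed reference base is checked against the record, which guards
    against off-by-one coordinate conventions.
    """
    if snp.gene_id != utr.gene_id:
        raise ValueError(
            f"{snp.snp_id} annotated on {snp.gene_id}, got UTR of {utr.gene_id}"
        )
    if snp.pos >= len(utr):
        raise ValueError(
            f"{snp.snp_id}: offset {snp.pos} outside 3'UTR of length {len(utr)}"
        )
    observed = utr.sequence[snp.pos]
    if observed != snp.ref:
        raise ValueError(
            f"{snp.snp_id}: reference allele {snp.ref} does not match observed "
            f"base {observed} at offset {snp.pos} (0-based, within-UTR)"
        )
    seq = utr.sequence[: snp.pos] + snp.alt + utr.sequence[snp.pos + 1:]
    return UtrSequence(utr.gene_id, seq)


class SeedScanPipeline:
    """Self-contained per-(gene, miRNA) probability scorer for SNP screens.

    Scans the UTR for seed matches of one miRNA, combines the surrogate
    site energies with the FD model, and scores the resulting single-gene
    feature matrix through a trained ensemble (each model tool receives the
    scan-derived combined score; the typical use is a single-tool model).

    When no expression table is available — the common situation in SNP
    screens — uniform abundance is assumed and logged; the chemical potential
    is then identical for all miRNAs.
    """

    def __init__(
        self,
        model: EnsembleModel,
        mirna_seqs: Mapping[str, str],
        expression: Mapping[str, float] | pd.Series | None = None,
        *,
        spec: SeedMatchSpec | None = None,
        rt: float = RT_DEFAULT,
        expression_scale: float = 1.0,
    ) -> None:
        self.model = model
        self.mirna_seqs = dict(mirna_seqs)
        self.spec = spec if spec is not None else SeedMatchSpec()
        self.rt = rt
        self.expression_scale = expression_scale
        if expression is None:
            logger.warning(
                "no miRNA expression supplied to the SNP pipeline; "
                "assuming uniform abundance for all %d miRNA(s)", len(self.mirna_seqs)
            )
            expression = {m: 1.0 for m in self.mirna_seqs}
        self.expression = pd.Series(expression, dtype=float)

    def probability(self, utr: UtrSequence, mirna_id: str) -> float:
        """Targeting probability of one miRNA on one UTR."""
        found = find_seed_sites(
            utr, mirna_id, self.mirna_seqs[mirna_id], self.spec
        )
        frame = sites_to_frame(found)
        table = fd_gene_scores(
            frame,
            self.expression.loc[[mirna_id]],
            rt=self.rt,
            expression_scale=self.expression_scale,
            genes=[utr.gene_id],
        )
        score = float(table.scores.loc[utr.gene_id])
        X = FeatureMatrix(
            [utr.gene_id], list(self.model.tools),
            [[score] * len(self.model.tools)],
        )
        return float(predict_probability(self.model, X).iloc[0])


def snp_delta_score(
    pipeline: "SeedScanPipeline | Callable[[UtrSequence, str], float]",
    ref_utr: UtrSequence,
    snp: SnpRecord,
    mirna_id: str,
    *,
    mode: str = "weighted",
) -> SnpRankRecord:
    """Score one SNP:miRNA pair through the full ref/alt pipeline."""
    if mode not in SNP_MODES:
        raise ValueError(f"unknown ranking mode {mode!r}")
    score = pipeline.probability if isinstance(pipeline, SeedScanPipeline) else pipeline
    alt_utr = apply_snp(ref_utr, snp)
    p_ref = float(score(ref_utr, mirna_id))
    p_alt = float(score(alt_utr, mirna_id))
    diff = p_ref - p_alt
    delta = p_ref * diff if mode == "weighted" else diff
    return SnpRankRecord(snp.snp_id, mirna_id, p_ref, p_alt, delta, mode)


def screen_snps(
    pipeline: SeedScanPipeline,
    utrs: Mapping[str, UtrSequence],
    snps: Iterable[SnpRecord],
    mirna_ids: Sequence[str] | None = None,
    *,
    mode: str = "weighted",
) -> list[SnpRankRecord]:
    """Score every SNP:miRNA pair (deterministic order)."""
    ids = sorted(mirna_ids) if mirna_ids is not None else sorted(pipeline.mirna_seqs)
    records = []
    for snp in sorted(snps, key=lambda s: s.snp_id):
        utr = utrs[snp.gene_id]
        for mirna_id in ids:
            records.append(snp_delta_score(pipeline, utr, snp, mirna_id, mode=mode))
    return records


def rank_snp_mirna_pairs(
    records: Sequence[SnpRankRecord],
    threshold: float = 0.01,
) -> list[SnpRankRecord]:
    """Rank pairs with delta above ``threshold``, descending.

    Ties are broken lexicographically by (snp_id, mirna_id); records at or
    below the threshold are excluded.  All records must share one mode.
    """
    modes = {r.mode for r in records}
    if len(modes) > 1:
        raise ValueError(f"records scored in mixed modes: {sorted(modes)}")
    kept = [r for r in records if r.delta > threshold]
    kept.sort(key=lambda r: (-r.delta, r.snp_id, r.mirna_id))
    return [replace(r, rank=i + 1) for i, r in enumerate(kept)]
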