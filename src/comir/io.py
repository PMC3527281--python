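"""Readers, writers and input filters.

All tabular formats are TSV with a header row, preceded by '#'-prefixed
metadata lines (version, config hash, seed) so every emitted file records how
it was produced; readers skip such lines.  Sequences travel as FASTA.
Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .sites import UtrSequence
from .snp import SnpRecord, SnpRankRecord
from .thermo import GeneScoreTable, SITE_COLUMNS

logger = logging.getLogger(__name__)

#: Default minimum 3'UTR length retained at load.
MIN_UTR_LENGTH = 50
#: Default minimum miRNA abundance retained at load.
MIN_EXPRESSION_LEVEL = 50.0


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def metadata_lines(meta: dict | None) -> str:
    meta = dict(meta or {})
    meta.setdefault("version", __version__)
    return "".join(f"# {k}: {meta[k]}\n" for k in sorted(meta))


def write_tsv(frame: pd.DataFrame, path, meta: dict | None = None, *, index: bool = False) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(metadata_lines(meta))
        frame.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# --------------------------------------------------------------------------
# 3'UTR FASTA
# --------------------------------------------------------------------------

def load_utrs(path, min_length: int = MIN_UTR_LENGTH) -> dict[str, UtrSequence]:
    """Load 3'UTRs from FASTA: one record per gene, longest isoform kept.

    The gene id is the first whitespace-separated token of the header.
    Records shorter than ``min_length`` (default 50 nt) are dropped; on
    equal-length duplicates the first record in file order wins.  Filter
    counts are logged.
    """
    best: dict[str, UtrSequence] = {}
    n_total = n_short = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_total += 1
        seq = str(rec.seq)
        if len(seq) < min_length:
            n_short += 1
            continue
        gene = rec.id
        if gene in best and len(best[gene].sequence) >= len(seq):
            if len(best[gene].sequence) == len(seq):
                logger.info("duplicate equal-length 3'UTR for %s; keeping first", gene)
            continue
        best[gene] = UtrSequence(gene, seq)
    logger.info(
        "loaded %d/%d 3'UTR records (%d shorter than %d nt dropped; %d genes)",
        n_total - n_short, n_total, n_short, min_length, len(best),
    )
    return best


def write_utrs(utrs, path) -> None:
    records = [
        SeqRecord(Seq(u.sequence), id=u.gene_id, description="")
        for u in (utrs.values() if isinstance(utrs, dict) else utrs)
    ]
    SeqIO.write(records, str(path), "fasta")


def load_mirna_fasta(path) -> dict[str, str]:
    """miRNA id -> mature sequence (5'->3')."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --------------------------------------------------------------------------
# Expression TSV
# --------------------------------------------------------------------------

def load_expression(path, min_level: float = MIN_EXPRESSION_LEVEL) -> pd.Series:
    """Load a miRNA expression table (columns: mirna_id, level).

    Rows with level below ``min_level`` (default 50, boundary inclusive) are
    excluded and logged; duplicate ids and non-numeric levels are errors
    (the latter reported with the file line number).
    """
    entries: dict[str, float] = {}
    n_filtered = 0
    with open(path, encoding="utf-8") as fh:
        header = None
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:2] != ["mirna_id", "level"]:
                    raise ValueError(
                        f"{path}: expected header 'mirna_id\\tlevel', got {header!r}"
                    )
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            mirna, raw_level = fields[0], fields[1]
            try:
                level = float(raw_level)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric level {raw_level!r}"
                ) from None
            if mirna in entries:
                raise ValueError(f"{path}: line {lineno}: duplicate miRNA id {mirna!r}")
            if level < min_level:
                n_filtered += 1
                continue
            entries[mirna] = level
    logger.info(
        "loaded %d miRNA(s); %d below minimum level %g dropped",
        len(entries), n_filtered, min_level,
    )
    return pd.Series(entries, name="level", dtype=float)


def write_expression(expression: pd.Series, path, meta: dict | None = None) -> None:
    frame = expression.rename_axis("mirna_id").rename("level").reset_index()
    write_tsv(frame, path, meta)


# --------------------------------------------------------------------------
# Site / score / label / SNP tables
# --------------------------------------------------------------------------

def load_sites(path) -> pd.DataFrame:
    frame = _read_tsv(path)
    missing = set(SITE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: site table missing columns {sorted(missing)}")
    frame = frame[list(SITE_COLUMNS)]
    key = ["gene_id", "mirna_id", "start", "end", "tool"]
    if frame.duplicated(key).any():
        n = int(frame.duplicated(key).sum())
        raise ValueError(f"{path}: {n} duplicate site record(s)")
    return frame


def write_sites(frame: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_tsv(frame[list(SITE_COLUMNS)], path, meta)


def write_scores(table: GeneScoreTable, path, meta: dict | None = None) -> None:
    meta = dict(meta or {})
    meta.setdefault("tool", table.tool)
    meta.setdefault("method", table.method)
    frame = table.scores.rename_axis("gene_id").rename("score").reset_index()
    write_tsv(frame, path, meta)


def load_scores(path) -> GeneScoreTable:
    tool = method = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition(": ")
            if k == "tool":
                tool = v
            elif k == "method":
                method = v
    frame = _read_tsv(path)
    series = frame.set_index("gene_id")["score"].astype(float)
    return GeneScoreTable(series, tool=tool or Path(path).stem, method=method or "unknown")


def load_labels(path) -> pd.Series:
    frame = _read_tsv(path)
    if frame["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids in label table")
    labels = frame.set_index("gene_id")["label"].astype(int)
    if not set(labels.unique()) <= {0, 1}:
        raise ValueError(f"{path}: labels must be 0/1")
    return labels


def write_labels(labels: pd.Series, path, meta: dict | None = None) -> None:
    frame = labels.rename_axis("gene_id").rename("label").reset_index()
    write_tsv(frame, path, meta)


def load_snps(path, min_maf: float | None = None) -> list[SnpRecord]:
    """Load a SNP table (snp_id, gene_id, pos, ref, alt[, maf]).

    Positions are 0-based offsets within the supplied 3'UTR.  If ``min_maf``
    is given and a ``maf`` column exists, rows at or below the cutoff are
    dropped (an input-column filter; allele frequencies are never computed).
    """
    frame = _read_tsv(path)
    required = {"snp_id", "gene_id", "pos", "ref", "alt"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: SNP table missing columns {sorted(missing)}")
    if min_maf is not None:
        if "maf" not in frame.columns:
            raise ValueError(f"{path}: MAF filter requested but no 'maf' column")
        before = len(frame)
        frame = frame[frame["maf"] > min_maf]
        logger.info("MAF filter > %g kept %d/%d SNP rows", min_maf, len(frame), before)
    return [
        SnpRecord(str(r.snp_id), str(r.gene_id), int(r.pos), str(r.ref), str(r.alt))
        for r in frame.itertuples(index=False)
    ]


def write_ranking(records: list[SnpRankRecord], path, meta: dict | None = None) -> None:
    meta = dict(meta or {})
    if records:
        meta.setdefault("mode", records[0].mode)
    frame = pd.DataFrame(
        [
            {
                "rank": r.rank, "snp_id": r.snp_id, "mirna_id": r.mirna_id,
                "p_ref": f"{r.p_ref:.10g}", "p_alt": f"{r.p_alt:.10g}",
                "delta": f"{r.delta:.10g}", "mode": r.mode,
            }
            for r in records
        ],
        columns=["rank", "snp_id", "mirna_id", "p_ref", "p_alt", "delta", "mode"],
    )
    write_tsv(frame, path, meta)
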