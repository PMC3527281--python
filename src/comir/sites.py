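"""Canonical seed-match scanning of 3'UTR sequences.

A transparent stand-in for external site predictors so the SNP workflow is
self-contained: it reports strict Watson-Crick matches (no G:U wobble) to the
miRNA seed on the sense strand of the 3'UTR.  Site classes follow the standard
definitions — with miRNA positions numbered 1-based from the 5' end, the
target site (read 5'->3') is

    6mer     reverse complement of positions 2-7
    7mer-m8  reverse complement of positions 2-8
    7mer-A1  reverse complement of positions 2-7, followed by an A
    8mer     reverse complement of positions 2-8, followed by an A

where the A sits opposite miRNA position 1 regardless of that position's
identity.  A window matching several classes is reported once at the
highest-priority class (8mer > 7mer-m8 > 7mer-A1 > 6mer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .thermo import BindingSite

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

SEED_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

#: Default surrogate site scores, on an energy-like scale (stronger classes
#: more negative) so scanned sites plug directly into the FD combiner.
DEFAULT_CLASS_SCORES = {
    "8mer": -1.0,
    "7mer-m8": -0.75,
    "7mer-A1": -0.75,
    "6mer": -0.5,
}


def normalize_rna(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase, map T->U, and validate the alphabet (error names the offset)."""
    seq = sequence.upper().replace("T", "U")
    for offset, base in enumerate(seq):
        if base not in RNA_ALPHABET:
            raise ValueError(
                f"invalid character {base!r} at offset {offset} in {context}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class UtrSequence:
    """A gene's 3'UTR as RNA (T accepted on input, stored as U)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence",
            normalize_rna(self.sequence, context=f"3'UTR of {self.gene_id}"),
        )
        if len(self.sequence) == 0:
            raise ValueError(f"empty 3'UTR for {self.gene_id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SeedMatchSpec:
    """Which seed classes to scan for and the surrogate score of each."""

    classes: tuple[str, ...] = SEED_CLASSES
    scores: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_SCORES))

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(SEED_CLASSES)
        if unknown:
            raise ValueError(f"unknown seed class(es): {sorted(unknown)}")
        if not self.classes:
            raise ValueError("at least one seed class must be enabled")
        for cls in self.classes:
            if cls not in self.scores:
                raise ValueError(f"no surrogate score for enabled class {cls!r}")


@dataclass(frozen=True)
class SeedSite(BindingSite):
    """A seed-match site annotated with its class."""

    site_class: str = "6mer"


def find_seed_sites(
    utr: UtrSequence,
    mirna_id: str,
    mirna_seq: str,
    spec: SeedMatchSpec | None = None,
    *,
    tool: str = "seedscan",
) -> list[SeedSite]:
    """Scan a 3'UTR for seed matches of one miRNA (5'->3' sequence).

    Every 6mer-core occurrence is classified by whether the m8 extension
    (target base pairing miRNA position 8, 5' of the core) and/or the A1
    anchor (A immediately 3' of the core) are present, and reported once at
    the highest-priority enabled class it satisfies.  Coordinates are 0-based
    half-open on the UTR and span the full matched window.
    """
    spec = spec if spec is not None else SeedMatchSpec()
    m = normalize_rna(mirna_seq, context=f"miRNA {mirna_id}")
    if len(m) < 8:
        raise ValueError(f"miRNA {mirna_id} shorter than 8 nt ({len(m)} nt)")
    core = reverse_complement(m[1:7])     # pairs miRNA positions 2-7
    m8_base = _COMPLEMENT[m[7]]           # pairs miRNA position 8
    seq = utr.sequence
    enabled = set(spec.classes)

    sites: list[SeedSite] = []
    i = seq.find(core)
    while i != -1:
        m8_ok = i > 0 and seq[i - 1] == m8_base
        a1_ok = i + 6 < len(seq) and seq[i + 6] == "A"
        for cls in SEED_CLASSES:  # priority order
            if cls not in enabled:
                continue
            if cls == "8mer" and m8_ok and a1_ok:
                start, end = i - 1, i + 7
            elif cls == "7mer-m8" and m8_ok:
                start, end = i - 1, i + 6
            elif cls == "7mer-A1" and a1_ok:
                start, end = i, i + 7
            elif cls == "6mer":
                start, end = i, i + 6
            else:
                continue
            sites.append(
                SeedSite(
                    gene_id=utr.gene_id,
                    mirna_id=mirna_id,
                    start=start,
                    end=end,
                    tool=tool,
                    score=float(spec.scores[cls]),
                    site_class=cls,
                )
            )
            break
        i = seq.find(core, i + 1)
    return sites
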