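"""Disordered-region definitions of the human IRE1α ER-lumenal domain (LD).

The LD (residues 24–443) carries several segments that are unresolved in the
crystal structure of the core lumenal domain and behave as intrinsically
disordered regions: DR1 (131–152), DR2 (307–358), DR3 (369–389) and the
linker to the transmembrane helix (390–443).  The three peptides that are
simulated as isolated chains — DR1, DR2 and the 369–443 "linker region"
(DR3 + linker) — are shipped here with their sequences; the folded cores
(cLD 24–389, LD 24–443) are boundary-only entries whose sequences can be
supplied from FASTA when needed.

All numbering is 1-based and inclusive, in LD coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_DR1_SEQ = "LTGEKQQTLSSAFADSLSPSTS"
_DR2_SEQ = "VPRGSTLPLLEGPQTDGVTIGDKGESVITPSTDVKFDPGLKSKNKLNYLRNY"
_LINKER_SEQ = (
    "LSASTKMLERFPNNLPKHRENVIPADSEKKSFEEVINLVDQTSENAPTTVSRDVEEKPAHAPARPEAPVDSMLKD"
)


@dataclass(frozen=True)
class Region:
    """A named LD segment with 1-based inclusive boundaries.

    ``sequence`` may be ``None`` for boundary-only entries (cLD, LD) whose
    full sequence is not carried by the package.
    """

    name: str
    start: int
    end: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"region {self.name}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"region {self.name}: end < start")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"region {self.name}: sequence length {len(self.sequence)} "
                    f"!= end - start + 1 = {self.length}"
                )
            bad = set(self.sequence) - AMINO_ACIDS
            if bad:
                raise ValueError(
                    f"region {self.name}: non-canonical residues {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def slice(self, start: int, end: int, name: str | None = None) -> "Region":
        """Sub-region in LD coordinates (inclusive)."""
        if start < self.start or end > self.end:
            raise ValueError(
                f"slice {start}-{end} outside {self.name} ({self.start}-{self.end})"
            )
        seq = None
        if self.sequence is not None:
            seq = self.sequence[start - self.start : end - self.start + 1]
        return Region(name or f"{self.name}[{start}-{end}]", start, end, seq)


def builtin_regions() -> dict[str, Region]:
    """The LD segments used throughout: DR1, DR2, DR3, linker, cLD, LD.

    DR1, DR2 and the linker-region peptide (369–443, the chain simulated in
    the multi-copy systems) carry their sequences; DR3 is the 369–389 slice
    of that peptide; cLD and LD are boundary-only.
    """
    linker = Region("linker", 369, 443, _LINKER_SEQ)
    return {
        "DR1": Region("DR1", 131, 152, _DR1_SEQ),
        "DR2": Region("DR2", 307, 358, _DR2_SEQ),
        "DR3": linker.slice(369, 389, name="DR3"),
        "linker": linker,
        "cLD": Region("cLD", 24, 389),
        "LD": Region("LD", 24, 443),
    }


def map_position(region: Region, ld_residue: int) -> tuple[int, str]:
    """LD residue number -> (1-based chain-internal index, one-letter code)."""
    if not region.start <= ld_residue <= region.end:
        raise ValueError(
            f"LD residue {ld_residue} outside {region.name} "
            f"({region.start}-{region.end})"
        )
    if region.sequence is None:
        raise ValueError(f"region {region.name} carries no sequence")
    idx = ld_residue - region.start + 1
    return idx, region.sequence[idx - 1]


def ld_position(region: Region, chain_index: int) -> int:
    """Inverse of :func:`map_position`: chain-internal index -> LD residue."""
    if not 1 <= chain_index <= region.length:
        raise ValueError(
            f"chain index {chain_index} outside 1-{region.length} of {region.name}"
        )
    return region.start + chain_index - 1


# ---------------------------------------------------------------------------
# Residue classes

@dataclass(frozen=True)
class ResidueClassScheme:
    """Partition of the 20 canonical residues into chemical classes."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = AMINO_ACIDS - set(self.mapping)
        if missing:
            raise ValueError(f"unclassified residues: {sorted(missing)}")

    def class_of(self, residue: str) -> str:
        return self.mapping[residue]

    @property
    def classes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.mapping.values():
            if c not in seen:
                seen.append(c)
        return tuple(seen)


def _default_mapping() -> dict[str, str]:
    groups = {
        "negative": "DE",
        "positive": "KR",
        "aromatic": "FYW",
        "hydrophobic": "AILMV",
        "polar": "CHNQST",
        "other": "GP",
    }
    return {aa: cls for cls, aas in groups.items() for aa in aas}


#: Charged (D/E vs K/R) and aromatic (F/Y/W) residues are the contact-driving
#: "sticker" classes of the disordered segments; the rest are spacers.
DEFAULT_SCHEME = ResidueClassScheme(_default_mapping())


@dataclass(frozen=True)
class Composition:
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def composition(region: Region, scheme: ResidueClassScheme = DEFAULT_SCHEME) -> Composition:
    """Per-class residue counts and fractions of a region's sequence.

    An empty sequence yields zero counts and ``fractions=None`` (undefined).
    """
    if region.sequence is None:
        raise ValueError(f"region {region.name} carries no sequence")
    counts = {cls: 0 for cls in scheme.classes}
    for aa in region.sequence:
        counts[scheme.class_of(aa)] += 1
    n = sum(counts.values())
    fractions = {c: k / n for c, k in counts.items()} if n else None
    return Composition(counts=counts, fractions=fractions)


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(regions: Iterable[Region], path: str | Path) -> None:
    records = []
    for r in regions:
        if r.sequence is None:
            raise ValueError(f"region {r.name} has no sequence to export")
        records.append(
            SeqRecord(Seq(r.sequence), id=r.name, description=f"LD {r.start}-{r.end}")
        )
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, Region]:
    """Read peptides; LD boundaries are parsed from a ``LD a-b`` description
    when present, otherwise the region spans 1..len."""
    out: dict[str, Region] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        start, end = 1, len(seq)
        parts = rec.description.split()
        for i, tok in enumerate(parts):
            if tok == "LD" and i + 1 < len(parts) and "-" in parts[i + 1]:
                a, b = parts[i + 1].split("-")
                start, end = int(a), int(b)
                break
        out[rec.id] = Region(rec.id, start, end, seq)
    return out
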