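"""Coarse-grained chain topologies for the sticker–spacer model.

Each residue maps to one bead (backbone) or two beads (backbone +
sidechain).  Beads belonging to charged residues carry ±1 charge and beads
of the sticker classes (charged negative/positive, aromatic) participate in
the attractive wells; everything else is an inert spacer.  With two beads
per residue the charge and sticker role sit on the sidechain bead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import DEFAULT_SCHEME, AMINO_ACIDS, Region, ResidueClassScheme

#: Integer codes for the interaction classes; 0 is the inert spacer.
STICKER_CODES = {"none": 0, "negative": 1, "positive": 2, "aromatic": 3}
DEFAULT_STICKER_CLASSES = ("negative", "positive", "aromatic")

_CHARGE = {"negative": -1, "positive": +1}


@dataclass
class ChainTopology:
    """Bead-level description of one chain species."""

    species: str
    sequence: str
    beads_per_residue: int = 1
    bead_residue: np.ndarray = field(default=None, repr=False)  # residue idx per bead (0-based)
    bead_type: list[str] = field(default=None, repr=False)      # "BB" or "SC-<class>"
    bead_charge: np.ndarray = field(default=None, repr=False)
    bead_sticker: np.ndarray = field(default=None, repr=False)  # sticker code per bead
    bonds: np.ndarray = field(default=None, repr=False)         # (n_bonds, 2) bead indices

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return self.n_residues * self.beads_per_residue

    @classmethod
    def from_sequence(
        cls,
        species: str,
        sequence: str,
        beads_per_residue: int = 1,
        scheme: ResidueClassScheme = DEFAULT_SCHEME,
        sticker_classes: tuple[str, ...] = DEFAULT_STICKER_CLASSES,
    ) -> "ChainTopology":
        if beads_per_residue not in (1, 2):
            raise ValueError("beads_per_residue must be 1 or 2")
        bad = set(sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-canonical residues {sorted(bad)}")
        n = len(sequence)
        bpr = beads_per_residue
        residue = np.repeat(np.arange(n), bpr)
        charge = np.zeros(n * bpr, dtype=np.int64)
        sticker = np.zeros(n * bpr, dtype=np.int64)
        types: list[str] = []
        for i, aa in enumerate(sequence):
            cls_label = scheme.class_of(aa)
            q = _CHARGE.get(cls_label, 0)
            code = (
                STICKER_CODES.get(cls_label, 0)
                if cls_label in sticker_classes
                else 0
            )
            if bpr == 1:
                types.append("BB")
                charge[i] = q
                sticker[i] = code
            else:
                types.extend(["BB", f"SC-{cls_label}"])
                charge[2 * i + 1] = q
                sticker[2 * i + 1] = code
        bonds = []
        if bpr == 1:
            bonds = [(i, i + 1) for i in range(n - 1)]
        else:
            for i in range(n):
                bonds.append((2 * i, 2 * i + 1))        # backbone-sidechain
                if i < n - 1:
                    bonds.append((2 * i, 2 * (i + 1)))  # backbone-backbone
        return cls(
            species=species,
            sequence=sequence,
            beads_per_residue=bpr,
            bead_residue=residue,
            bead_type=types,
            bead_charge=charge,
            bead_sticker=sticker,
            bonds=np.asarray(bonds, dtype=np.int64),
        )

    @classmethod
    def from_region(cls, region: Region, **kwargs) -> "ChainTopology":
        if region.sequence is None:
            raise ValueError(f"region {region.name} has no sequence")
        return cls.from_sequence(region.name, region.sequence, **kwargs)

    @property
    def net_charge(self) -> int:
        return int(self.bead_charge.sum())

    def validate(self) -> None:
        assert self.n_beads == len(self.bead_residue)
        assert self.bonds.max(initial=-1) < self.n_beads
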