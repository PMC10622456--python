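"""Built-in C-terminal membrane-anchor (PIDR) sequences.

Each entry is the mature prenylated intrinsically disordered region of a
small GTPase: the C-terminal stretch ending at the prenylated cysteine
(the CAAX ``-AAX`` residues are already removed and the cysteine is
carboxymethylated after prenylation).  Residue numbering follows the
full-length protein (author numbering), so e.g. RhoA's anchor spans
Arg182...Cys190.

Sequences follow the canonical human UniProt C-termini of these proteins.
The Rheb entry is a partial reconstruction: its C-terminal ``...GKSSC``
motif and overall composition (a single lysine, serine-rich, no acidic
cluster) are fixed, but the identity of residues 170-175 is approximate;
no descriptor in this package depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple


@dataclass(frozen=True)
class PIDRSequence:
    """A prenylated-anchor sequence with its lipidation annotations."""

    name: str
    sequence: str  # one-letter residues, N -> C, ending at the prenyl-Cys
    start_residue: int  # author numbering of the first residue
    prenyl: str  # "farnesyl" (C15) or "geranylgeranyl" (C20)
    carboxymethylated: bool = True
    palmitoyl_positions: Tuple[int, ...] = ()  # author numbering

    def __post_init__(self) -> None:
        if self.prenyl not in ("farnesyl", "geranylgeranyl"):
            raise ValueError(f"unknown prenyl type {self.prenyl!r}")
        if self.sequence[-1] != "C":
            raise ValueError(
                f"{self.name}: a prenylated anchor must end in Cys"
            )
        for pos in self.palmitoyl_positions:
            if self.residue_at(pos) != "C":
                raise ValueError(
                    f"{self.name}: palmitoyl position {pos} is not a Cys"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def prenyl_cys_position(self) -> int:
        """Author-numbering position of the prenylated cysteine."""
        return self.start_residue + len(self.sequence) - 1

    def residue_at(self, position: int) -> str:
        return self.sequence[position - self.start_residue]

    def numbering(self) -> Tuple[int, ...]:
        return tuple(range(self.start_residue, self.start_residue + self.length))


#: The six anchors studied: Rheb, Rap1A, Rap1B (Ras family) and RhoA, Rac1,
#: Cdc42b (Rho family).  Rheb is farnesylated; the others geranylgeranylated;
#: Rac1 additionally palmitoylated at Cys178.
BUILTIN_ANCHORS: Dict[str, PIDRSequence] = {
    "Rheb": PIDRSequence(
        name="Rheb",
        sequence="SAHSEMQGKSSC",  # residues 170-175 approximate; see module docstring
        start_residue=170,
        prenyl="farnesyl",
    ),
    "RhoA": PIDRSequence(
        name="RhoA",
        sequence="ARRGKKKSGC",
        start_residue=181,
        prenyl="geranylgeranyl",
    ),
    "Rap1A": PIDRSequence(
        name="Rap1A",
        sequence="RQINRKTPVEKKKPKKKSC",
        start_residue=163,
        prenyl="geranylgeranyl",
    ),
    "Rap1B": PIDRSequence(
        name="Rap1B",
        sequence="RQINRKTPVPGKARKKSSC",
        start_residue=163,
        prenyl="geranylgeranyl",
    ),
    "Rac1": PIDRSequence(
        name="Rac1",
        sequence="EAIRAVLCPPPVKKRKRKC",
        start_residue=171,
        prenyl="geranylgeranyl",
        palmitoyl_positions=(178,),
    ),
    "Cdc42b": PIDRSequence(
        name="Cdc42b",
        sequence="DEAILAALEPPEPKKSRRC",
        start_residue=170,
        prenyl="geranylgeranyl",
    ),
}
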