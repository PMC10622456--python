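"""Polybasic-domain (PBD) identification and anchor sequence descriptors.

A PBD is a run of at least four lysine/arginine residues that are
contiguous or *semicontiguous* -- consecutive basic residues separated by
no more than two non-basic residues.  The descriptor scheme summarises an
anchor sequence by:

==========  ==============================================================
``SL``      sequence length (residues)
``Np``      number of basic residues inside the PBD
``K:R``     lysine:arginine counts inside the PBD
``Nh``      fraction of hydrophobic residues N-terminal to the PBD
``B:A``     basic:acidic counts N-terminal to the PBD
``S``       residues strictly between the last PBD residue and the
            prenylated cysteine
==========  ==============================================================

All PBD-relative fields are ``None`` when the sequence has no PBD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Tuple

import pandas as pd

from .groups import ACIDIC_RESIDUES, BASIC_RESIDUES, NONPOLAR_RESIDUES
from .membrane import PidrError
from .sequences import BUILTIN_ANCHORS, PIDRSequence

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: PBD rule parameters.
MIN_BASIC = 4
MAX_GAP = 2


@dataclass(frozen=True)
class PBDSpan:
    """0-based [start, end] span of a polybasic domain within a sequence."""

    start: int
    end: int
    basic_positions: Tuple[int, ...]

    @property
    def n_basic(self) -> int:
        return len(self.basic_positions)


@dataclass(frozen=True)
class DescriptorSet:
    name: str
    SL: int
    pbd: Optional[PBDSpan]
    Np: Optional[int]
    K: Optional[int]
    R: Optional[int]
    Nh: Optional[float]
    B: Optional[int]
    A: Optional[int]
    S: Optional[int]

    def as_row(self) -> Dict[str, object]:
        return {
            "name": self.name,
            "SL": self.SL,
            "Np": self.Np,
            "K:R": None if self.Np is None else f"{self.K}:{self.R}",
            "Nh": self.Nh,
            "B:A": None if self.Np is None else f"{self.B}:{self.A}",
            "S": self.S,
            "pbd_start": None if self.pbd is None else self.pbd.start,
            "pbd_end": None if self.pbd is None else self.pbd.end,
        }


def _validate(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residue letters: {sorted(bad)}")
    return seq


def basic_runs(sequence: str) -> List[PBDSpan]:
    """All maximal semicontiguous K/R runs with at least MIN_BASIC residues.

    A run is grown greedily N->C while consecutive basic residues are
    separated by at most MAX_GAP non-basic residues, and is trimmed so that
    it starts and ends on a basic residue.
    """
    seq = _validate(sequence)
    positions = [i for i, aa in enumerate(seq) if aa in BASIC_RESIDUES]
    runs: List[List[int]] = []
    for pos in positions:
        if runs and pos - runs[-1][-1] - 1 <= MAX_GAP:
            runs[-1].append(pos)
        else:
            runs.append([pos])
    return [
        PBDSpan(start=r[0], end=r[-1], basic_positions=tuple(r))
        for r in runs
        if len(r) >= MIN_BASIC
    ]


def identify_pbd(sequence: str) -> Optional[PBDSpan]:
    """The C-terminal-most qualifying polybasic run, or None.

    PBDs function adjacent to the prenylation site, so when several runs
    qualify the one closest to the C terminus is returned.
    """
    runs = basic_runs(sequence)
    return runs[-1] if runs else None


def compute_descriptors(
    anchor: PIDRSequence,
    hydrophobic: FrozenSet[str] = NONPOLAR_RESIDUES,
) -> DescriptorSet:
    """Descriptor set for an anchor sequence.

    ``Nh`` and ``B:A`` are computed over residues strictly N-terminal to the
    PBD; ``S`` counts residues strictly between the last PBD residue and the
    prenylated cysteine.  The hydrophobic set defaults to the standard
    nonpolar residue class {G,A,V,L,I,P,F,M,W,C}.
    """
    seq = _validate(anchor.sequence)
    span = identify_pbd(seq)
    if span is None:
        return DescriptorSet(
            name=anchor.name, SL=len(seq), pbd=None,
            Np=None, K=None, R=None, Nh=None, B=None, A=None, S=None,
        )
    inside = [seq[i] for i in span.basic_positions]
    k = sum(1 for aa in inside if aa == "K")
    r = sum(1 for aa in inside if aa == "R")
    nterm = seq[: span.start]
    nh = (
        round(sum(1 for aa in nterm if aa in hydrophobic) / len(nterm), 2)
        if nterm
        else None
    )
    b = sum(1 for aa in nterm if aa in BASIC_RESIDUES) if nterm else None
    a = sum(1 for aa in nterm if aa in ACIDIC_RESIDUES) if nterm else None
    # prenylated Cys is the last residue of the anchor sequence
    if seq[-1] != "C":
        raise PidrError(
            f"{anchor.name}: S requires a C-terminal prenylated Cys annotation"
        )
    s = (len(seq) - 1) - span.end - 1
    return DescriptorSet(
        name=anchor.name, SL=len(seq), pbd=span,
        Np=span.n_basic, K=k, R=r, Nh=nh, B=b, A=a, S=s,
    )


def descriptors_for_builtin(name: str) -> DescriptorSet:
    return compute_descriptors(BUILTIN_ANCHORS[name])


def scan_fasta(path, window: int = 19) -> pd.DataFrame:
    """Descriptor table for every record of a FASTA file.

    Descriptors are computed on the C-terminal ``window`` residues of each
    record (anchors live at the very C terminus); records shorter than the
    window are used whole, with a warning.  Each windowed sequence must end
    in the (to-be-)prenylated cysteine.
    """
    from Bio import SeqIO

    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    rows = []
    for rec in records:
        seq = str(rec.seq).upper()
        if len(seq) < window:
            warnings.warn(
                f"{rec.id}: sequence shorter than window ({len(seq)} < "
                f"{window}); using the full sequence"
            )
        win = seq[-window:]
        anchor = PIDRSequence(
            name=rec.id,
            sequence=win,
            start_residue=len(seq) - len(win) + 1,
            prenyl="geranylgeranyl",
        )
        rows.append(compute_descriptors(anchor).as_row())
    return pd.DataFrame(rows)


def builtin_descriptor_table() -> pd.DataFrame:
    """Descriptor table for the six built-in anchors."""
    return pd.DataFrame(
        [compute_descriptors(a).as_row() for a in BUILTIN_ANCHORS.values()]
    )
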