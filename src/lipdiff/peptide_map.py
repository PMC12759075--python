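"""Peptide provenance for limited-proteolysis (LiP) experiments.

LiP-MS couples a brief proteinase K (PK) pulse on a native lysate with a
complete tryptic digest.  Fully tryptic peptides can arise from trypsin
alone, whereas a half-tryptic peptide carries one PK-generated terminus
that localizes a proteolytic cut-site on the protein.  This module holds
the in-silico trypsin digestion, the classification of observed peptide
spans by terminal provenance, and the mapping from each peptide to the
cut-site evidence it carries.

Coordinate convention
---------------------
Residue coordinates are 1-based and inclusive.  A cut-site index ``i``
denotes cleavage of the backbone between residues ``i`` and ``i + 1``.

Trypsin specificity is cleavage C-terminal to K or R, suppressed when the
next residue is proline.  A span starting at residue 2 of a protein whose
first residue is methionine is treated as tryptic-consistent (N-terminal
methionine excision, not a PK cut).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinSeq",
    "PeptideSpan",
    "Trypticity",
    "TrypticityCall",
    "CutSiteKey",
    "digest_tryptic",
    "classify_trypticity",
    "assign_cutsite",
    "map_ions_to_sites",
    "read_fasta",
]

CLEAVAGE_RESIDUES = frozenset("KR")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class InvalidSequenceError(ValueError):
    """Raised for empty or non-amino-acid protein sequences."""


@dataclass(frozen=True)
class ProteinSeq:
    """A protein record: unique identifier and uppercase amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidSequenceError("protein id must be non-empty")
        if not self.sequence:
            raise InvalidSequenceError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise InvalidSequenceError(
                f"{self.id}: non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class PeptideSpan:
    """A peptide located on its parent protein, 1-based inclusive."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid span ({self.start}, {self.end}) on {self.protein_id}"
            )

    def sequence_in(self, protein: ProteinSeq) -> str:
        if self.end > len(protein):
            raise ValueError(
                f"span ({self.start}, {self.end}) exceeds {protein.id} "
                f"length {len(protein)}"
            )
        return protein.sequence[self.start - 1 : self.end]


class Trypticity(str, Enum):
    """Peptide terminal provenance.

    The ``half_tryptic_N`` / ``half_tryptic_C`` suffix names the terminus
    generated by PK: an N-half-tryptic peptide has a PK-derived N-terminus
    (and a tryptic C-terminus), and vice versa.
    """

    FULL = "full_tryptic"
    HALF_N = "half_tryptic_N"
    HALF_C = "half_tryptic_C"
    NON = "non_tryptic"


@dataclass(frozen=True)
class TrypticityCall:
    n_tryptic: bool
    c_tryptic: bool

    @property
    def trypticity(self) -> Trypticity:
        if self.n_tryptic and self.c_tryptic:
            return Trypticity.FULL
        if self.c_tryptic:
            return Trypticity.HALF_N
        if self.n_tryptic:
            return Trypticity.HALF_C
        return Trypticity.NON


@dataclass(frozen=True)
class CutSiteKey:
    """Identifier of the proteolytic evidence a peptide reports on.

    ``PK_inferred`` keys carry a single residue ``position`` (cleavage
    between ``position`` and ``position + 1``).  Fully tryptic peptides are
    retained as evidence keyed by their span (``tryptic_span`` origin with
    ``start``/``end``): their abundance change still reports on internal PK
    cleavage, so downstream statistics treat span keys and site keys
    uniformly as "cut-sites".
    """

    protein_id: str
    origin: str  # "PK_inferred" | "tryptic_span"
    position: int | None = None
    start: int | None = None
    end: int | None = None

    @property
    def label(self) -> str:
        if self.origin == "PK_inferred":
            return f"PK@{self.position}"
        return f"T:{self.start}-{self.end}"


def digest_tryptic(protein: ProteinSeq) -> list[PeptideSpan]:
    """Fully digest a protein with trypsin (cleave after K/R, not before P).

    The returned spans partition the sequence in order; concatenating their
    substrings reproduces the input sequence exactly.
    """
    seq = protein.sequence
    spans: list[PeptideSpan] = []
    start = 1
    for i in range(1, len(seq)):
        if seq[i - 1] in CLEAVAGE_RESIDUES and seq[i] != "P":
            spans.append(PeptideSpan(protein.id, start, i))
            start = i + 1
    spans.append(PeptideSpan(protein.id, start, len(seq)))
    return spans


def _tryptic_nterm(seq: str, start: int) -> bool:
    if start == 1:
        return True
    if start == 2 and seq[0] == "M":
        # N-terminal Met excision: protein processing, not a PK cut.
        return True
    return seq[start - 2] in CLEAVAGE_RESIDUES and seq[start - 1] != "P"


def _tryptic_cterm(seq: str, end: int) -> bool:
    if end == len(seq):
        return True
    return seq[end - 1] in CLEAVAGE_RESIDUES and seq[end] != "P"


def classify_trypticity(span: PeptideSpan, protein: ProteinSeq) -> TrypticityCall:
    """Decide, for each terminus of a peptide, whether trypsin can explain it."""
    if span.end > len(protein):
        raise ValueError(
            f"span ({span.start}, {span.end}) out of bounds for {protein.id}"
        )
    seq = protein.sequence
    return TrypticityCall(
        n_tryptic=_tryptic_nterm(seq, span.start),
        c_tryptic=_tryptic_cterm(seq, span.end),
    )


def assign_cutsite(span: PeptideSpan, call: TrypticityCall) -> tuple[CutSiteKey, ...]:
    """Map a classified peptide to the cut-site key(s) it is evidence for.

    Half-tryptic peptides yield one PK-inferred site at their PK-generated
    terminus; non-tryptic peptides yield two (both termini); fully tryptic
    peptides keep their span as the key.
    """
    pid = span.protein_id
    trypticity = call.trypticity
    if trypticity is Trypticity.FULL:
        return (
            CutSiteKey(pid, "tryptic_span", start=span.start, end=span.end),
        )
    if trypticity is Trypticity.HALF_N:
        if span.start == 1:
            raise ValueError(
                f"{pid}: protein N-terminus cannot be a PK cut (span start 1)"
            )
        return (CutSiteKey(pid, "PK_inferred", position=span.start - 1),)
    if trypticity is Trypticity.HALF_C:
        return (CutSiteKey(pid, "PK_inferred", position=span.end),)
    # non-tryptic: both termini are PK-derived
    if span.start == 1:
        raise ValueError(
            f"{pid}: protein N-terminus cannot be a PK cut (span start 1)"
        )
    return (
        CutSiteKey(pid, "PK_inferred", position=span.start - 1),
        CutSiteKey(pid, "PK_inferred", position=span.end),
    )


def map_ions_to_sites(
    ions: pd.DataFrame, proteome: Mapping[str, ProteinSeq] | Iterable[ProteinSeq]
) -> pd.DataFrame:
    """Annotate an ion table with trypticity and cut-site keys.

    ``ions`` must carry ``protein_id``, ``start`` and ``end`` columns.  The
    output repeats non-tryptic ions once per site (both PK termini) and adds
    ``trypticity``, ``site_id``, ``site_origin`` and ``site_position``
    columns.  ``site_position`` is NA for span-keyed (fully tryptic) ions.
    """
    seqs = _as_mapping(proteome)
    rows: list[int] = []
    trypt: list[str] = []
    site_id: list[str] = []
    origin: list[str] = []
    position: list[float] = []
    prot = ions["protein_id"].to_numpy()
    start = ions["start"].to_numpy()
    end = ions["end"].to_numpy()
    for i in range(len(ions)):
        protein = seqs.get(prot[i])
        if protein is None:
            raise KeyError(f"ion references unknown protein {prot[i]!r}")
        span = PeptideSpan(prot[i], int(start[i]), int(end[i]))
        call = classify_trypticity(span, protein)
        for key in assign_cutsite(span, call):
            rows.append(i)
            trypt.append(call.trypticity.value)
            site_id.append(key.label)
            origin.append(key.origin)
            position.append(float(key.position) if key.position is not None else float("nan"))
    out = ions.iloc[rows].reset_index(drop=True)
    out["trypticity"] = trypt
    out["site_id"] = site_id
    out["site_origin"] = origin
    out["site_position"] = position
    return out


def _as_mapping(
    proteome: Mapping[str, ProteinSeq] | Iterable[ProteinSeq],
) -> Mapping[str, ProteinSeq]:
    if isinstance(proteome, Mapping):
        return proteome
    return {p.id: p for p in proteome}


def read_fasta(path) -> list[ProteinSeq]:
    """Read a proteome FASTA; the description token before the first
    whitespace is the protein id.  Ids must be unique."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id in FASTA: {rec.id}")
        seen.add(rec.id)
        records.append(ProteinSeq(rec.id, str(rec.seq).upper()))
    return records
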