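"""Protein N-terminus model: mature-N-terminus rules, semi-specific digestion,
dipeptidyl cleavage arithmetic and P-position annotation.

Coordinates are 1-based inclusive throughout; the initiator Met is residue 1.

The mature N-terminus of a protein is where an exopeptidase can first act:

* a signal peptide, when annotated, is removed co-translationally, so the
  mature N-terminus is the residue after its end;
* otherwise the initiator Met is excised by Met aminopeptidases when residue 2
  is small (Gly, Ala, Ser, Thr, Cys, Pro or Val), making residue 2 the mature
  N-terminus;
* otherwise the N-terminus is residue 1.

A dipeptidyl peptidase then removes dipeptides sequentially from that mature
N-terminus, so observed peptide starts at ``mature_start + 2k`` are candidate
products of ``k`` cleavage cycles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "IMET_EXCISION_RESIDUES",
    "ProteinRecord",
    "NtermRule",
    "MatureNterm",
    "PeptideSpan",
    "DigestParams",
    "OriginClass",
    "mature_nterm",
    "digest_semi",
    "dipeptidyl_cleave",
    "classify_origin",
    "p_positions",
]

#: Residues at position 2 that trigger initiator-Met excision.
IMET_EXCISION_RESIDUES = frozenset("GASTCPV")

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """A proteome entry; the coordinate frame for every peptide observation.

    Parameters
    ----------
    protein_id : str
        Unique identifier (FASTA record id).
    sequence : str
        Uppercase amino-acid sequence over the 20-letter alphabet plus X.
    description : str
        Free-text description.
    signal_peptide_end : int or None
        1-based inclusive index of the last signal-peptide residue, when a
        signal peptide is annotated.
    """

    protein_id: str
    sequence: str
    description: str = ""
    signal_peptide_end: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.protein_id}: invalid residues {sorted(bad)}")
        if self.signal_peptide_end is not None:
            if not 1 <= self.signal_peptide_end < len(self.sequence):
                raise ValueError(
                    f"{self.protein_id}: signal_peptide_end={self.signal_peptide_end} "
                    f"outside [1, {len(self.sequence) - 1}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(f"{self.protein_id}: position {pos} outside protein")
        return self.sequence[pos - 1]


class NtermRule(str, enum.Enum):
    """Which maturation rule determined the expected N-terminus."""

    NONE = "none"
    IMET_EXCISION = "imet_excision"
    SIGNAL_PEPTIDE = "signal_peptide"


@dataclass(frozen=True)
class MatureNterm:
    """Expected mature N-terminus of a protein: start residue and the rule that fired."""

    protein_id: str
    start: int
    rule: NtermRule


@dataclass(frozen=True)
class PeptideSpan:
    """A peptide located on its protein: 1-based inclusive [start, end] plus sequence."""

    protein_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match span "
                f"{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_protein(cls, protein: ProteinRecord, start: int, end: int) -> "PeptideSpan":
        if not 1 <= start <= end <= len(protein):
            raise ValueError(
                f"{protein.protein_id}: span {start}-{end} outside protein of "
                f"length {len(protein)}"
            )
        return cls(protein.protein_id, start, end, protein.sequence[start - 1 : end])


@dataclass(frozen=True)
class DigestParams:
    """Parameters of the in-silico Arg-C (semi) digestion.

    ``cleave_after`` is the residue set C-terminal to which the protease cuts
    (Arg-C: {R}); ``proline_block`` suppresses cleavage before Pro when set.
    Semi-specific mode additionally enumerates peptides with exactly one
    enzymatic terminus, which is how neo-N-termini enter the search space.
    """

    cleave_after: frozenset[str] = frozenset("R")
    max_missed_cleavages: int = 1
    min_length: int = 7
    max_length: int = 40
    semi_specific: bool = True
    proline_block: bool = False

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_length < self.min_length:
            raise ValueError("max_length < min_length")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        object.__setattr__(self, "cleave_after", frozenset(self.cleave_after))


class OriginClass:
    """Origin of a peptide relative to the expected mature N-terminus.

    ``kind`` is one of ``"nterm_substrate"`` (starts exactly at the mature
    N-terminus), ``"nterm_product"`` (starts an even number of residues
    downstream, i.e. ``cycles`` dipeptidyl cleavages in) or ``"internal"``.
    """

    __slots__ = ("kind", "cycles")

    NTERM_SUBSTRATE = "nterm_substrate"
    NTERM_PRODUCT = "nterm_product"
    INTERNAL = "internal"

    def __init__(self, kind: str, cycles: int = 0):
        if kind not in (self.NTERM_SUBSTRATE, self.NTERM_PRODUCT, self.INTERNAL):
            raise ValueError(f"unknown origin kind {kind!r}")
        if kind == self.NTERM_PRODUCT and cycles < 1:
            raise ValueError("nterm_product requires cycles >= 1")
        self.kind = kind
        self.cycles = cycles if kind == self.NTERM_PRODUCT else 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OriginClass):
            return NotImplemented
        return self.kind == other.kind and self.cycles == other.cycles

    def __hash__(self) -> int:
        return hash((self.kind, self.cycles))

    def __repr__(self) -> str:
        if self.kind == self.NTERM_PRODUCT:
            return f"OriginClass(nterm_product, cycles={self.cycles})"
        return f"OriginClass({self.kind})"


def mature_nterm(protein: ProteinRecord) -> MatureNterm:
    """Annotate the expected mature N-terminus of a protein.

    Signal-peptide removal takes precedence over initiator-Met excision.
    iMet excision fires only when residue 1 is Met and residue 2 is one of
    G, A, S, T, C, P, V (an ``X`` at position 2 never fires).

    Examples
    --------
    >>> mature_nterm(ProteinRecord("p", "MVTAQ"))
    MatureNterm(protein_id='p', start=2, rule=<NtermRule.IMET_EXCISION: 'imet_excision'>)
    """
    if protein.signal_peptide_end is not None:
        return MatureNterm(protein.protein_id, protein.signal_peptide_end + 1,
                           NtermRule.SIGNAL_PEPTIDE)
    if (len(protein) >= 2 and protein.sequence[0] == "M"
            and protein.sequence[1] in IMET_EXCISION_RESIDUES):
        return MatureNterm(protein.protein_id, 2, NtermRule.IMET_EXCISION)
    return MatureNterm(protein.protein_id, 1, NtermRule.NONE)


def _cleavage_boundaries(sequence: str, params: DigestParams) -> list[int]:
    """0-based boundary offsets where the protease can cut (between i-1 and i),
    including the protein termini 0 and len(sequence)."""
    n = len(sequence)
    sites = [0]
    for i in range(1, n):
        if sequence[i - 1] in params.cleave_after:
            if params.proline_block and sequence[i] == "P":
                continue
            sites.append(i)
    sites.append(n)
    return sites


def digest_semi(protein: ProteinRecord, params: DigestParams | None = None) -> list[PeptideSpan]:
    """Enumerate Arg-C (semi) peptides of a protein.

    Returns all fully specific peptides (both termini enzymatic or protein
    termini, at most ``max_missed_cleavages`` internal sites) plus, when
    ``semi_specific``, all peptides with exactly one specific terminus, within
    the length window. Spans are deduplicated and sorted by (start, end).
    """
    if params is None:
        params = DigestParams()
    seq = protein.sequence
    n = len(seq)
    boundaries = _cleavage_boundaries(seq, params)
    bset = set(boundaries)
    spans: set[tuple[int, int]] = set()

    def n_internal(b_start: int, b_end: int) -> int:
        # number of cleavable boundaries strictly inside (b_start, b_end)
        return sum(1 for b in boundaries if b_start < b < b_end)

    # fully specific: consecutive boundary pairs with <= max_missed internal sites
    for i, b0 in enumerate(boundaries[:-1]):
        for b1 in boundaries[i + 1 : i + 2 + params.max_missed_cleavages]:
            if params.min_length <= b1 - b0 <= params.max_length:
                spans.add((b0, b1))

    if params.semi_specific:
        # one specific terminus: anchor at each boundary, free other end
        for b0 in boundaries[:-1]:
            for b1 in range(b0 + params.min_length, min(b0 + params.max_length, n) + 1):
                if b1 in bset:
                    continue
                if n_internal(b0, b1) <= params.max_missed_cleavages:
                    spans.add((b0, b1))
        for b1 in boundaries[1:]:
            for b0 in range(max(b1 - params.max_length, 0), b1 - params.min_length + 1):
                if b0 in bset:
                    continue
                if n_internal(b0, b1) <= params.max_missed_cleavages:
                    spans.add((b0, b1))

    return [
        PeptideSpan(protein.protein_id, b0 + 1, b1, seq[b0:b1])
        for b0, b1 in sorted(spans)
    ]


def dipeptidyl_cleave(span: PeptideSpan, cycles: int = 1) -> PeptideSpan:
    """Remove ``cycles`` dipeptides from the N-terminus of a peptide span.

    The product keeps the C-terminus and starts ``2 * cycles`` residues later;
    each cycle shortens the peptide by exactly 2 residues.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if len(span) < 2 * cycles + 1:
        raise ValueError(
            f"span of length {len(span)} too short for {cycles} dipeptidyl cycles"
        )
    shift = 2 * cycles
    return PeptideSpan(span.protein_id, span.start + shift, span.end,
                       span.sequence[shift:])


def classify_origin(span: PeptideSpan, mature: MatureNterm,
                    max_cycles: int = 15) -> OriginClass:
    """Classify a peptide as N-terminal substrate, dipeptidyl product, or internal.

    A start exactly at the mature N-terminus is a potential substrate; a start
    ``2k`` residues downstream (1 <= k <= max_cycles) is a potential product of
    ``k`` sequential dipeptidyl cleavages; anything else — upstream starts, odd
    offsets, offsets beyond ``2 * max_cycles`` — is internal.
    """
    if span.protein_id != mature.protein_id:
        raise ValueError(
            f"span protein {span.protein_id!r} != mature protein {mature.protein_id!r}"
        )
    offset = span.start - mature.start
    if offset == 0:
        return OriginClass(OriginClass.NTERM_SUBSTRATE)
    if offset > 0 and offset % 2 == 0 and offset // 2 <= max_cycles:
        return OriginClass(OriginClass.NTERM_PRODUCT, cycles=offset // 2)
    return OriginClass(OriginClass.INTERNAL)


def p_positions(span: PeptideSpan, protein: ProteinRecord) -> tuple[str, str, str]:
    """P2/P1/P1' residues for a substrate span of a dipeptidyl peptidase.

    By exopeptidase convention the substrate's N-terminal residue is P2, the
    second residue is P1 (cleavage occurs C-terminal to P1) and the third —
    the first residue of the product — is P1'.
    """
    if span.protein_id != protein.protein_id:
        raise ValueError("span does not belong to this protein")
    if len(span) < 3:
        raise ValueError("span must have length >= 3 to define P2/P1/P1'")
    return (protein.residue(span.start),
            protein.residue(span.start + 1),
            protein.residue(span.start + 2))
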