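"""Substrate/product calling from TAILS fold changes.

A dipeptidyl-peptidase substrate screen compares peptide abundances between
protease-deficient mutants and wild-type. An N-terminal peptide that starts at
the expected mature N-terminus and accumulates in both mutants (the protein is
no longer consumed) is a substrate candidate; a peptide two residues shorter
that is depleted in both mutants (it is no longer produced) is a product
candidate. The strongest evidence is a matching substrate/product pair from
the same protein: starts differing by one dipeptide step and fold changes far
apart (Manhattan distance in the two-comparison log2FC plane).

Fold-change orientation throughout is mutant vs wild-type: substrates move up,
products move down.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from tailskit.nterm import (
    MatureNterm,
    OriginClass,
    PeptideSpan,
    ProteinRecord,
    classify_origin,
    mature_nterm,
)
from tailskit.quant import ComparisonFC

__all__ = [
    "PairingParams",
    "CandidateLabel",
    "LabeledPeptide",
    "SubstrateProductPair",
    "CleavageCandidate",
    "quadrant_classify",
    "pair_candidates",
    "build_candidate_table",
    "call_substrates",
]


@dataclass(frozen=True)
class PairingParams:
    """Thresholds of the quadrant/pairing analysis.

    fc_threshold : float
        Absolute log2 fold change a candidate must exceed in both mutant
        comparisons (default 2).
    max_start : int
        Peptides starting beyond this residue are too deep inside the protein
        to be N-terminal evidence and are filtered (default 50).
    manhattan_min : float
        Minimum |dfc_del| + |dfc_cat| separation between pair members
        (default 4); set ``manhattan_max`` instead for the upper-bound reading.
    allowed_offsets : frozenset of int
        Permitted product-minus-substrate start differences; multiples of 2
        (default {2}, one dipeptidyl cycle).
    require_opposite_sign : bool
        Demand substrate up / product down in both comparisons (default True).
    require_both_comparisons : bool
        Apply fc_threshold to both mutant comparisons (default) rather than
        either one.
    """

    fc_threshold: float = 2.0
    max_start: int = 50
    manhattan_min: float = 4.0
    manhattan_max: float | None = None
    allowed_offsets: frozenset[int] = frozenset({2})
    require_opposite_sign: bool = True
    require_both_comparisons: bool = True

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be > 0")
        if self.manhattan_min < 0:
            raise ValueError("manhattan_min must be >= 0")
        offs = frozenset(int(o) for o in self.allowed_offsets)
        if any(o <= 0 or o % 2 for o in offs):
            raise ValueError("allowed_offsets must be positive even integers")
        object.__setattr__(self, "allowed_offsets", offs)


class CandidateLabel(str, enum.Enum):
    SUBSTRATE_CANDIDATE = "substrate_candidate"
    PRODUCT_CANDIDATE = "product_candidate"
    UNCHANGED = "unchanged"
    DISCORDANT = "discordant"
    POSITION_FILTERED = "position_filtered"


@dataclass(frozen=True)
class LabeledPeptide:
    """A peptide ion with its origin class, fold changes and quadrant label."""

    key: str
    span: PeptideSpan
    origin: OriginClass
    fc_del: float
    fc_cat: float
    label: CandidateLabel


@dataclass(frozen=True)
class SubstrateProductPair:
    """A matched substrate/product peptide pair from one protein."""

    protein_id: str
    substrate_key: str
    product_key: str
    start_offset: int
    manhattan_d: float


@dataclass(frozen=True)
class CleavageCandidate:
    """A called cleavage event: pair or singleton, with P-position annotation.

    For a singleton product the substrate start is inferred one dipeptide step
    upstream of the product start. ``flagged`` marks candidates whose P
    positions could not be read off the protein.
    """

    protein_id: str
    substrate_span: PeptideSpan | None
    product_span: PeptideSpan | None
    P2: str | None
    P1: str | None
    P1prime: str | None
    fc_del_sub: float | None
    fc_cat_sub: float | None
    fc_del_prod: float | None
    fc_cat_prod: float | None
    evidence_score: float
    paired: bool
    manhattan_d: float | None = None
    flagged: bool = False


def quadrant_classify(fc: ComparisonFC, origin: OriginClass, start: int,
                      params: PairingParams | None = None) -> CandidateLabel:
    """Quadrant label of one peptide from its two mutant-vs-wild-type fold changes.

    Position filtering (start beyond ``max_start``) takes precedence. A
    substrate candidate must rise above the threshold in both comparisons and
    start at the mature N-terminus; a product candidate must fall below the
    negative threshold in both comparisons and sit an even dipeptide offset
    downstream. Above-threshold changes with disagreeing signs are discordant;
    everything else (including concordant changes at an incompatible origin)
    is unchanged.
    """
    if params is None:
        params = PairingParams()
    t = params.fc_threshold
    if start > params.max_start:
        return CandidateLabel.POSITION_FILTERED
    up = fc.fc_del > t and fc.fc_cat > t
    down = fc.fc_del < -t and fc.fc_cat < -t
    if up and origin.kind == OriginClass.NTERM_SUBSTRATE:
        return CandidateLabel.SUBSTRATE_CANDIDATE
    if down and origin.kind == OriginClass.NTERM_PRODUCT:
        return CandidateLabel.PRODUCT_CANDIDATE
    if (abs(fc.fc_del) > t and abs(fc.fc_cat) > t
            and (fc.fc_del > 0) != (fc.fc_cat > 0)):
        return CandidateLabel.DISCORDANT
    return CandidateLabel.UNCHANGED


def _exceeds(p: LabeledPeptide, params: PairingParams) -> bool:
    if params.require_both_comparisons:
        return abs(p.fc_del) > params.fc_threshold and abs(p.fc_cat) > params.fc_threshold
    return abs(p.fc_del) > params.fc_threshold or abs(p.fc_cat) > params.fc_threshold


def pair_candidates(peptides: list[LabeledPeptide],
                    params: PairingParams | None = None) -> list[SubstrateProductPair]:
    """Match substrate and product peptides within each protein.

    A candidate pair (s, p) satisfies: same protein; p.start - s.start in
    ``allowed_offsets``; at least one member above the fold-change threshold;
    Manhattan distance |dfc_del| + |dfc_cat| within the configured bound; and,
    when ``require_opposite_sign``, s up and p down in both comparisons.
    Matching is greedy one-to-one by largest distance (ties: smaller offset,
    then lexicographic keys), so each peptide joins at most one pair and the
    result is independent of input order.
    """
    if params is None:
        params = PairingParams()
    eligible = [p for p in peptides
                if p.label != CandidateLabel.POSITION_FILTERED]
    by_protein: dict[str, list[LabeledPeptide]] = {}
    for p in eligible:
        by_protein.setdefault(p.span.protein_id, []).append(p)

    candidates: list[tuple[float, int, str, str, SubstrateProductPair]] = []
    for protein_id, peps in by_protein.items():
        for s in peps:
            for p in peps:
                offset = p.span.start - s.span.start
                if offset not in params.allowed_offsets:
                    continue
                if not (_exceeds(s, params) or _exceeds(p, params)):
                    continue
                if params.require_opposite_sign:
                    if not (s.fc_del > 0 and s.fc_cat > 0
                            and p.fc_del < 0 and p.fc_cat < 0):
                        continue
                d = abs(s.fc_del - p.fc_del) + abs(s.fc_cat - p.fc_cat)
                if d < params.manhattan_min:
                    continue
                if params.manhattan_max is not None and d > params.manhattan_max:
                    continue
                candidates.append((
                    -d, offset, s.key, p.key,
                    SubstrateProductPair(protein_id, s.key, p.key, offset, d),
                ))

    candidates.sort()
    used: set[str] = set()
    pairs: list[SubstrateProductPair] = []
    for _, _, skey, pkey, pair in candidates:
        if skey in used or pkey in used:
            continue
        used.update((skey, pkey))
        pairs.append(pair)
    return pairs


def _score(p: LabeledPeptide) -> float:
    return min(abs(p.fc_del), abs(p.fc_cat))


def build_candidate_table(pairs: list[SubstrateProductPair],
                          peptides: list[LabeledPeptide],
                          proteome: dict[str, ProteinRecord]) -> list[CleavageCandidate]:
    """Assemble the final cleavage-candidate table.

    One record per matched pair, plus one per unpaired substrate or product
    candidate. P2/P1/P1' are read from the protein at the substrate start
    (inferred as product start - 2 for a lone product). The evidence score is
    the larger, over the members, of min(|fc_del|, |fc_cat|); output is sorted
    paired-first, then by descending score.
    """
    by_key = {p.key: p for p in peptides}
    paired_keys = {k for pr in pairs for k in (pr.substrate_key, pr.product_key)}
    records: list[CleavageCandidate] = []

    def p_pos_at(protein_id: str, sub_start: int) -> tuple[str | None, str | None, str | None, bool]:
        protein = proteome.get(protein_id)
        if protein is None or not 1 <= sub_start or sub_start + 2 > len(protein):
            return None, None, None, True
        return (protein.residue(sub_start), protein.residue(sub_start + 1),
                protein.residue(sub_start + 2), False)

    for pr in pairs:
        s = by_key[pr.substrate_key]
        p = by_key[pr.product_key]
        P2, P1, P1p, flagged = p_pos_at(pr.protein_id, s.span.start)
        records.append(CleavageCandidate(
            protein_id=pr.protein_id,
            substrate_span=s.span, product_span=p.span,
            P2=P2, P1=P1, P1prime=P1p,
            fc_del_sub=s.fc_del, fc_cat_sub=s.fc_cat,
            fc_del_prod=p.fc_del, fc_cat_prod=p.fc_cat,
            evidence_score=max(_score(s), _score(p)),
            paired=True, manhattan_d=pr.manhattan_d, flagged=flagged,
        ))

    for p in peptides:
        if p.key in paired_keys:
            continue
        if p.label == CandidateLabel.SUBSTRATE_CANDIDATE:
            P2, P1, P1p, flagged = p_pos_at(p.span.protein_id, p.span.start)
            records.append(CleavageCandidate(
                protein_id=p.span.protein_id,
                substrate_span=p.span, product_span=None,
                P2=P2, P1=P1, P1prime=P1p,
                fc_del_sub=p.fc_del, fc_cat_sub=p.fc_cat,
                fc_del_prod=None, fc_cat_prod=None,
                evidence_score=_score(p), paired=False, flagged=flagged,
            ))
        elif p.label == CandidateLabel.PRODUCT_CANDIDATE:
            inferred_start = p.span.start - 2
            P2, P1, P1p, flagged = p_pos_at(p.span.protein_id, inferred_start)
            records.append(CleavageCandidate(
                protein_id=p.span.protein_id,
                substrate_span=None, product_span=p.span,
                P2=P2, P1=P1, P1prime=P1p,
                fc_del_sub=None, fc_cat_sub=None,
                fc_del_prod=p.fc_del, fc_cat_prod=p.fc_cat,
                evidence_score=_score(p), paired=False, flagged=flagged,
            ))

    records.sort(key=lambda r: (not r.paired, -r.evidence_score, r.protein_id))
    return records


def call_substrates(proteome: dict[str, ProteinRecord],
                    fcs: list[ComparisonFC],
                    spans: dict[str, PeptideSpan],
                    params: PairingParams | None = None,
                    max_cycles: int = 15) -> tuple[list[CleavageCandidate],
                                                   list[SubstrateProductPair],
                                                   list[LabeledPeptide]]:
    """End-to-end candidate calling from fold changes and peptide locations.

    ``spans`` maps each fold-change key to its peptide span. Returns the
    candidate table together with the pair list and the per-peptide labels.
    """
    if params is None:
        params = PairingParams()
    matures = {pid: mature_nterm(rec) for pid, rec in proteome.items()}
    labeled: list[LabeledPeptide] = []
    for fc in fcs:
        span = spans[fc.key]
        mature = matures[span.protein_id]
        origin = classify_origin(span, mature, max_cycles)
        label = quadrant_classify(fc, origin, span.start, params)
        labeled.append(LabeledPeptide(fc.key, span, origin, fc.fc_del, fc.fc_cat, label))
    pairs = pair_candidates(labeled, params)
    table = build_candidate_table(pairs, labeled, proteome)
    return table, pairs, labeled
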