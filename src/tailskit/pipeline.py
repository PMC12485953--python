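"""End-to-end TAILS analysis: quant rows in, cleavage candidates out.

Composes the stages in the published order — log2 transform, median centering,
MinProb imputation, mutant-vs-wild-type fold changes, quadrant classification,
substrate/product pairing — and provides truth-based scoring for simulated
screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from tailskit.nterm import PeptideSpan, ProteinRecord
from tailskit.quant import (
    ChannelDesign,
    ImputeParams,
    PeptideQuantRow,
    comparison_fc,
    log2_transform,
    median_center,
    minprob_impute,
    peptide_key,
    rows_to_matrix,
)
from tailskit.simulate import SynthTruth
from tailskit.substrates import (
    CleavageCandidate,
    LabeledPeptide,
    PairingParams,
    SubstrateProductPair,
    call_substrates,
)

__all__ = ["TailsResult", "run_tails_pipeline", "score_against_truth", "RecoveryScore"]


@dataclass
class TailsResult:
    """Everything the TAILS stage produces, intermediates included."""

    candidates: list[CleavageCandidate]
    pairs: list[SubstrateProductPair]
    labeled: list[LabeledPeptide]
    fold_changes: pd.DataFrame
    matrix: pd.DataFrame


def run_tails_pipeline(proteome: dict[str, ProteinRecord],
                       rows: list[PeptideQuantRow],
                       design: ChannelDesign | None = None,
                       impute_params: ImputeParams | None = None,
                       pairing_params: PairingParams | None = None,
                       max_cycles: int = 15,
                       restrict_observed: bool = False,
                       exclude_mod_labels: frozenset[str] = frozenset()) -> TailsResult:
    """Run the full substrate-discovery analysis on a peptide-quant table.

    With ``restrict_observed`` fold changes use observed channels only
    (imputation skipped); complete absence in one genotype then counts as an
    infinite fold change. ``exclude_mod_labels`` drops peptide ions whose
    modification label is listed (e.g. N-terminal acetylation) before
    analysis; the default keeps everything.
    """
    if design is None:
        design = ChannelDesign.default_6plex()
    if exclude_mod_labels:
        rows = [r for r in rows if r.mod_label not in exclude_mod_labels]
    mat = rows_to_matrix(rows, channels=list(design.channels))
    mat = median_center(log2_transform(mat))
    if not restrict_observed:
        mat = minprob_impute(mat, impute_params)
    fcs = comparison_fc(mat, design, restrict_observed=restrict_observed)
    spans = {peptide_key(r): r.span for r in rows}
    candidates, pairs, labeled = call_substrates(
        proteome, fcs, spans, pairing_params, max_cycles=max_cycles)
    fc_frame = pd.DataFrame(
        [(f.key, f.fc_del, f.fc_cat, f.mean_abundance) for f in fcs],
        columns=["key", "fc_del", "fc_cat", "mean_abundance"],
    ).set_index("key")
    return TailsResult(candidates, pairs, labeled, fc_frame, mat)


@dataclass(frozen=True)
class RecoveryScore:
    """Truth-based recovery metrics of a simulated screen.

    sensitivity
        Fraction of true substrates present in the candidate table with the
        correct inferred cleavage start (paired or singleton).
    false_pair_fraction
        Fraction of emitted pairs that do not match a true substrate/product
        pair (0.0 when no pairs were emitted).
    """

    sensitivity: float
    false_pair_fraction: float
    n_true: int
    n_recovered: int
    n_pairs: int
    n_false_pairs: int
    recovered_ids: frozenset[str] = field(default=frozenset())


def score_against_truth(result: TailsResult, truth: SynthTruth) -> RecoveryScore:
    """Score candidate calls against the generator's ground truth."""
    true_subs = truth.substrates
    recovered: set[str] = set()
    for cand in result.candidates:
        t = true_subs.get(cand.protein_id)
        if t is None:
            continue
        sub_start = (cand.substrate_span.start if cand.substrate_span is not None
                     else cand.product_span.start - 2)
        if sub_start == t["substrate_start"]:
            recovered.add(cand.protein_id)

    n_false = 0
    by_key = {p.key: p for p in result.labeled}
    for pair in result.pairs:
        t = true_subs.get(pair.protein_id)
        s = by_key[pair.substrate_key]
        p = by_key[pair.product_key]
        ok = (t is not None
              and s.span.start == t["substrate_start"]
              and p.span.start == t["product_start"])
        if not ok:
            n_false += 1

    n_true = len(true_subs)
    n_pairs = len(result.pairs)
    return RecoveryScore(
        sensitivity=len(recovered) / n_true if n_true else float("nan"),
        false_pair_fraction=n_false / n_pairs if n_pairs else 0.0,
        n_true=n_true,
        n_recovered=len(recovered),
        n_pairs=n_pairs,
        n_false_pairs=n_false,
        recovered_ids=frozenset(recovered),
    )
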