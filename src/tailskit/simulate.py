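"""Synthetic proteomes, TAILS quant experiments and IP-MS tables with known truth.

The generator emulates the statistical structure of a three-genotype TAILS
substrate screen so every pipeline stage can be exercised and scored without
real data:

* a random proteome in which designated substrate proteins carry a mature
  N-terminus (initiator-Met excision or signal peptide) and a P1 residue
  drawn from the protease's specificity preferences;
* per-genotype substrate conversion — in wild-type most substrate molecules
  are cleaved into the dipeptidyl product, in the protease-deficient mutants
  almost none — which fixes the expected fold-change geometry of
  substrate/product pairs;
* log-normal protein abundances, multiplicative reporter noise, and
  intensity-dependent (MNAR) dropout via a logistic curve anchored at a low
  quantile of the intensity distribution;
* an IP-MS label-free table with a planted enriched set and QC-flagged rows.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from tailskit.nterm import (
    IMET_EXCISION_RESIDUES,
    PeptideSpan,
    ProteinRecord,
    mature_nterm,
)
from tailskit.quant import ChannelDesign, PeptideQuantRow
from tailskit.enrich import LFQTable

__all__ = ["SimConfig", "SynthTruth", "generate_proteome", "simulate_tails",
           "simulate_ipms"]

_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_ALPHABET_NO_R = np.array([a for a in _ALPHABET if a != "R"])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic screen.

    The defaults encode the simulated biology: high substrate conversion in
    wild-type (0.9) against near-zero conversion in the two loss-of-function
    mutants (0.02 each), P1 specificity dominated by Pro and Ala with minor
    tolerance of Ser/Thr/Gly, log2 reporter noise of sd 0.3, and logistic
    MNAR dropout anchored at the 10th intensity percentile.
    """

    n_proteins: int = 1000
    length_min: int = 80
    length_max: int = 400
    signal_peptide_fraction: float = 0.15
    n_substrates: int = 50
    p1_weights: Mapping[str, float] = field(default_factory=lambda: {
        "P": 1.0, "A": 0.8, "S": 0.3, "T": 0.3, "G": 0.2,
    })
    conversion: Mapping[str, float] = field(default_factory=lambda: {
        "wildtype": 0.9, "dpf3_del": 0.02, "dpf3_S784A": 0.02,
    })
    abundance_log2_mean: float = 20.0
    abundance_log2_sd: float = 2.5
    noise_log2_sd: float = 0.3
    mnar_enabled: bool = True
    mnar_midpoint_quantile: float = 0.10
    mnar_slope: float = 1.0
    reporter_floor_quantile: float = 0.01
    n_background_peptides: int = 2
    # IP-MS experiment
    ipms_n_proteins: int = 500
    ipms_n_enriched: int = 5
    ipms_effect_log2: float = 5.0
    ipms_within_sd: float = 0.3
    ipms_baseline_mean: float = 25.0
    ipms_baseline_sd: float = 2.0
    ipms_flagged_fraction: float = 0.04
    ipms_missing_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("signal_peptide_fraction", "ipms_flagged_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(w < 0 for w in self.p1_weights.values()):
            raise ValueError("p1_weights must be >= 0")
        if any(not 0 <= c <= 1 for c in self.conversion.values()):
            raise ValueError("conversion fractions must be in [0, 1]")
        if self.n_substrates > self.n_proteins:
            raise ValueError("n_substrates > n_proteins")
        if self.length_min < 60:
            raise ValueError("length_min must be >= 60 to host signal peptides "
                             "and the engineered N-terminal peptide")


@dataclass
class SynthTruth:
    """Ground truth of one simulated screen.

    ``substrates`` maps protein id to a record with the substrate start
    (mature N-terminus), product start, the N-terminal peptide end, and the
    P2/P1/P1' residues. ``ipms_enriched`` maps enriched protein ids to their
    planted log2 effect.
    """

    substrates: dict[str, dict] = field(default_factory=dict)
    conversion: dict[str, float] = field(default_factory=dict)
    ipms_enriched: dict[str, float] = field(default_factory=dict)


def _nterm_peptide_end(sequence: str, mature_start: int) -> int:
    """1-based end of the N-terminal Arg-C peptide: first R at >= mature_start+8."""
    for pos in range(mature_start + 8, len(sequence)):
        if sequence[pos - 1] == "R":
            return pos
    raise ValueError("no Arg downstream of the mature N-terminus")


def generate_proteome(config: SimConfig) -> tuple[dict[str, ProteinRecord], SynthTruth]:
    """Generate a random proteome with designated, fully annotated substrates.

    Every protein starts with Met; a configured fraction carries a signal
    peptide ending uniformly at residue 15-25. Substrate proteins are given a
    well-defined mature N-terminus (residue 2 from the Met-excision set when
    no signal peptide is present) and a P1 residue drawn from the specificity
    weights; every protein is guaranteed an Arg-C N-terminal peptide of
    tractable length (first Arg placed 8-14 residues into the mature chain's
    window when none occurs naturally).
    """
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_proteins
    substrate_idx = set(rng.choice(n, size=config.n_substrates, replace=False).tolist())
    p1_residues = list(config.p1_weights)
    p1_w = np.array([config.p1_weights[r] for r in p1_residues], dtype=float)
    if p1_w.sum() == 0:
        raise ValueError("p1_weights sum to zero")
    p1_w = p1_w / p1_w.sum()

    proteome: dict[str, ProteinRecord] = {}
    truth = SynthTruth(conversion=dict(config.conversion))

    for i in range(n):
        pid = f"SYN{i + 1:05d}"
        length = int(rng.integers(config.length_min, config.length_max + 1))
        seq = rng.choice(_ALPHABET, size=length)
        seq[0] = "M"
        sp_end: int | None = None
        if rng.random() < config.signal_peptide_fraction:
            sp_end = int(rng.integers(15, 26))

        is_substrate = i in substrate_idx
        if is_substrate and sp_end is None:
            # force initiator-Met excision so the mature N-terminus is residue 2
            seq[1] = rng.choice(sorted(IMET_EXCISION_RESIDUES))
        mstart = (sp_end + 1) if sp_end is not None else (
            2 if seq[1] in IMET_EXCISION_RESIDUES else 1
        )
        if is_substrate:
            if seq[mstart - 1] == "R":  # P2 must not truncate the peptide
                seq[mstart - 1] = rng.choice(_ALPHABET_NO_R)
            seq[mstart] = rng.choice(p1_residues, p=p1_w)

        # guarantee an N-terminal Arg-C peptide: no Arg in the first 8 mature
        # residues, and an Arg within the detectable window after them
        for pos in range(mstart, min(mstart + 8, length)):
            if seq[pos - 1] == "R":
                seq[pos - 1] = "L"
        window = range(mstart + 8, min(mstart + 35, length))
        if not any(seq[p - 1] == "R" for p in window):
            seq[mstart + 13] = "R"

        record = ProteinRecord(pid, "".join(seq), description="synthetic protein",
                               signal_peptide_end=sp_end)
        proteome[pid] = record
        if is_substrate:
            m = mature_nterm(record)
            assert m.start == mstart
            end = _nterm_peptide_end(record.sequence, mstart)
            truth.substrates[pid] = {
                "substrate_start": mstart,
                "product_start": mstart + 2,
                "peptide_end": end,
                "P2": record.residue(mstart),
                "P1": record.residue(mstart + 1),
                "P1prime": record.residue(mstart + 2),
            }
    return proteome, truth


def _background_spans(record: ProteinRecord, after: int, n_wanted: int,
                      rng: np.random.Generator) -> list[PeptideSpan]:
    """Fully tryptic internal peptides (length 7-40) starting after ``after``."""
    seq = record.sequence
    bounds = [i for i in range(1, len(seq)) if seq[i - 1] == "R" and i >= after]
    bounds.append(len(seq))
    spans = []
    for b0, b1 in zip(bounds, bounds[1:]):
        if 7 <= b1 - b0 <= 40:
            spans.append(PeptideSpan.from_protein(record, b0 + 1, b1))
    if len(spans) > n_wanted:
        idx = rng.choice(len(spans), size=n_wanted, replace=False)
        spans = [spans[i] for i in sorted(idx)]
    return spans


def simulate_tails(proteome: dict[str, ProteinRecord], truth: SynthTruth,
                   config: SimConfig,
                   design: ChannelDesign | None = None) -> list[PeptideQuantRow]:
    """Simulate the 6-channel TAILS peptide-quant table.

    Each protein contributes its N-terminal peptide (for substrates, split
    between the substrate and its dipeptidyl product according to the
    genotype's conversion fraction) plus background internal tryptic peptides.
    Linear intensities are protein abundance x molecule split x per-peptide
    ionization efficiency x per-channel log-normal reporter noise; cells then
    drop out by the logistic MNAR curve, and zero-intensity cells are recorded
    as missing. Rows missing in every channel are not reported.
    """
    if design is None:
        design = ChannelDesign.default_6plex()
    rng = np.random.default_rng([config.seed, 202])
    channels = list(design.channels)
    genotypes = [design.channels[c][0] for c in channels]
    conv = {g: truth.conversion.get(g, config.conversion[g]) for g in set(genotypes)}

    entries: list[tuple[PeptideSpan, np.ndarray]] = []
    for pid, record in proteome.items():
        abundance = 2.0 ** rng.normal(config.abundance_log2_mean,
                                      config.abundance_log2_sd)
        m = mature_nterm(record)
        sub = truth.substrates.get(pid)
        if sub is not None:
            end = sub["peptide_end"]
            s_span = PeptideSpan.from_protein(record, sub["substrate_start"], end)
            p_span = PeptideSpan.from_protein(record, sub["product_start"], end)
            s_base = np.array([abundance * (1 - conv[g]) for g in genotypes])
            p_base = np.array([abundance * conv[g] for g in genotypes])
            entries.append((s_span, s_base))
            entries.append((p_span, p_base))
            bg_after = end
        else:
            end = _nterm_peptide_end(record.sequence, m.start)
            span = PeptideSpan.from_protein(record, m.start, end)
            entries.append((span, np.full(len(channels), abundance)))
            bg_after = end
        for span in _background_spans(record, bg_after, config.n_background_peptides, rng):
            eff = 2.0 ** rng.normal(0.0, 0.5)
            entries.append((span, np.full(len(channels), abundance * eff)))

    # reporter noise
    intensities = np.zeros((len(entries), len(channels)))
    for i, (_, base) in enumerate(entries):
        noise = (2.0 ** rng.normal(0.0, config.noise_log2_sd, size=len(channels))
                 if config.noise_log2_sd > 0 else 1.0)
        intensities[i] = base * noise

    # Intensity-dependent missingness, mirroring isobaric quantification:
    # identification is one event per peptide row (all channels are measured
    # from the same pooled precursor), so whole rows drop out by a logistic
    # MNAR curve on the pooled intensity; within identified rows, individual
    # reporter channels are censored by the same logistic anchored at the
    # reporter detection floor.
    missing = intensities <= 0
    if config.mnar_enabled:
        with np.errstate(divide="ignore"):
            log2i = np.where(intensities > 0,
                             np.log2(np.maximum(intensities, 1e-300)), -np.inf)
        pooled = np.log2(np.maximum(intensities.mean(axis=1), 1e-300))
        row_mid = np.quantile(pooled, config.mnar_midpoint_quantile)
        p_row = 1.0 / (1.0 + np.exp(config.mnar_slope * (pooled - row_mid)))
        missing |= (rng.random(len(entries)) < p_row)[:, None]
        cells = log2i[np.isfinite(log2i)]
        floor = np.quantile(cells, config.reporter_floor_quantile)
        p_cell = 1.0 / (1.0 + np.exp(config.mnar_slope * (log2i - floor)))
        missing |= rng.random(intensities.shape) < p_cell

    rows: list[PeptideQuantRow] = []
    for i, (span, _) in enumerate(entries):
        if missing[i].all():
            continue
        vals = {
            ch: (None if missing[i, j] else float(intensities[i, j]))
            for j, ch in enumerate(channels)
        }
        rows.append(PeptideQuantRow(span=span, mod_label="", charge=2,
                                    intensities=vals))
    return rows


def simulate_ipms(config: SimConfig) -> tuple[LFQTable, SynthTruth]:
    """Simulate an IP-MS protein-group LFQ table (3 bait vs 3 control).

    Protein baselines are Normal(baseline_mean, baseline_sd) on the log2
    scale with within-group noise ``ipms_within_sd``; the planted enriched set
    receives ``ipms_effect_log2`` in the bait samples. A configured fraction
    of rows carries QC flags to exercise filtering, and optional MNAR dropout
    removes low-intensity cells.
    """
    rng = np.random.default_rng([config.seed, 303])
    n = config.ipms_n_proteins
    samples = ["bait_1", "bait_2", "bait_3", "control_1", "control_2", "control_3"]
    groups = {s: ("bait" if s.startswith("bait") else "control") for s in samples}
    ids = [f"IP{i + 1:05d}" for i in range(n)]

    baseline = rng.normal(config.ipms_baseline_mean, config.ipms_baseline_sd, size=n)
    X = baseline[:, None] + rng.normal(0.0, config.ipms_within_sd, size=(n, 6))

    enriched_idx = rng.choice(n, size=config.ipms_n_enriched, replace=False)
    for i in enriched_idx:
        X[i, :3] += config.ipms_effect_log2

    n_flagged = int(round(config.ipms_flagged_fraction * n))
    # flag only non-enriched rows so the planted truth survives filtering
    flaggable = np.array([i for i in range(n) if i not in set(enriched_idx.tolist())])
    flagged_idx = rng.choice(flaggable, size=n_flagged, replace=False)
    flag_kinds = ["reverse", "contaminant", "only_by_site"]
    flags = {ids[i]: {flag_kinds[k % 3]} for k, i in enumerate(sorted(flagged_idx))}

    if config.ipms_missing_enabled:
        midpoint = np.quantile(X, 0.05)
        p_miss = 1.0 / (1.0 + np.exp(1.0 * (X - midpoint)))
        X = np.where(rng.random(X.shape) < p_miss, np.nan, X)

    table = LFQTable(
        intensities=pd.DataFrame(X, index=ids, columns=samples),
        flags=flags,
        groups=groups,
    )
    truth = SynthTruth(
        conversion=dict(config.conversion),
        ipms_enriched={ids[i]: config.ipms_effect_log2 for i in sorted(enriched_idx.tolist())},
    )
    return table, truth
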