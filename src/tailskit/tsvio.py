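"""Readers and writers for the pipeline's file formats.

All tabular files are tab-delimited UTF-8 with a header row; empty fields are
missing values; lines starting with '#' are comments. Every writer emits a
comment line declaring the coordinate convention (1-based inclusive residue
indices, initiator Met = 1). FASTA goes through Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tailskit.enrich import LFQ_FLAGS, LFQTable, VolcanoRow
from tailskit.kinetics import TimeCourse
from tailskit.nterm import PeptideSpan, ProteinRecord
from tailskit.quant import PeptideQuantRow
from tailskit.simulate import SynthTruth
from tailskit.substrates import CleavageCandidate

__all__ = [
    "read_fasta", "write_fasta",
    "read_signal_peptides", "write_signal_peptides",
    "read_peptide_table", "write_peptide_table",
    "write_spans",
    "read_lfq_table", "write_lfq_table", "read_maxquant_protein_groups",
    "read_timecourses", "write_timecourses",
    "write_candidate_table", "write_volcano",
    "read_truth", "write_truth",
]

_COORD_COMMENT = "# coordinates: 1-based inclusive residue indices; initiator Met = 1\n"


class SchemaError(ValueError):
    """A table is missing a required column or has an unparseable field."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------- proteomes

def read_fasta(path: str | Path,
               signal_peptides: dict[str, int] | None = None) -> dict[str, ProteinRecord]:
    """Read a proteome FASTA, optionally attaching signal-peptide annotations."""
    signal_peptides = signal_peptides or {}
    proteome: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        proteome[rec.id] = ProteinRecord(
            protein_id=rec.id,
            sequence=str(rec.seq).upper(),
            description=rec.description,
            signal_peptide_end=signal_peptides.get(rec.id),
        )
    return proteome


def write_fasta(proteome: dict[str, ProteinRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description=p.description)
        for p in proteome.values()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_signal_peptides(path: str | Path) -> dict[str, int]:
    """Sidecar TSV with columns protein_id, signal_peptide_end."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["protein_id", "signal_peptide_end"], Path(path))
    return {str(r.protein_id): int(r.signal_peptide_end) for r in df.itertuples()}


def write_signal_peptides(ends: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fh.write("protein_id\tsignal_peptide_end\n")
        for pid, end in ends.items():
            fh.write(f"{pid}\t{end}\n")


# ----------------------------------------------------------- peptide quant

def read_peptide_table(path: str | Path) -> list[PeptideQuantRow]:
    """Peptide-quant TSV: protein_id, start, end, sequence, mod_label, charge,
    then one column per channel (empty = missing)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"mod_label": str})
    meta = ["protein_id", "start", "end", "sequence", "mod_label", "charge"]
    _require_columns(df, meta, path)
    channels = [c for c in df.columns if c not in meta]
    if not channels:
        raise SchemaError(f"{path}: no intensity channels found")
    rows: list[PeptideQuantRow] = []
    for i, (_, r) in enumerate(df.iterrows(), start=2):  # 1-based incl. header
        intensities: dict[str, float | None] = {}
        for ch in channels:
            v = r[ch]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                intensities[ch] = None
            else:
                try:
                    intensities[ch] = float(v)
                except (TypeError, ValueError) as exc:
                    raise SchemaError(
                        f"{path}:{i}: non-numeric intensity {v!r} in channel {ch}"
                    ) from exc
        mod = r["mod_label"]
        mod = "" if (mod is None or (isinstance(mod, float) and np.isnan(mod))) else str(mod)
        span = PeptideSpan(str(r["protein_id"]), int(r["start"]), int(r["end"]),
                           str(r["sequence"]))
        rows.append(PeptideQuantRow(span=span, mod_label=mod,
                                    charge=int(r["charge"]), intensities=intensities))
    return rows


def write_peptide_table(rows: list[PeptideQuantRow], path: str | Path) -> None:
    channels: dict[str, None] = {}
    for r in rows:
        for c in r.intensities:
            channels.setdefault(c)
    chans = list(channels)
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fh.write("protein_id\tstart\tend\tsequence\tmod_label\tcharge\t"
                 + "\t".join(chans) + "\n")
        for r in rows:
            s = r.span
            vals = "\t".join(
                "" if (v := r.intensities.get(c)) is None else repr(float(v))
                for c in chans
            )
            fh.write(f"{s.protein_id}\t{s.start}\t{s.end}\t{s.sequence}\t"
                     f"{r.mod_label}\t{r.charge}\t{vals}\n")


def write_spans(spans: list[PeptideSpan], path: str | Path) -> None:
    """Peptide span TSV: protein_id, start, end, sequence."""
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fh.write("protein_id\tstart\tend\tsequence\n")
        for s in spans:
            fh.write(f"{s.protein_id}\t{s.start}\t{s.end}\t{s.sequence}\n")


# ------------------------------------------------------------------- LFQ

def write_lfq_table(table: LFQTable, path: str | Path) -> None:
    """Internal LFQ dialect: protein_id, flags (semicolon list), group:<sample>
    intensity columns on the log2 scale."""
    cols = list(table.intensities.columns)
    with open(path, "w") as fh:
        fh.write("# log2 LFQ intensities; empty = missing\n")
        header = ["protein_id", "flags"] + [
            f"{table.groups.get(c, 'unassigned')}:{c}" for c in cols
        ]
        fh.write("\t".join(header) + "\n")
        for pid, row in table.intensities.iterrows():
            flags = ";".join(sorted(table.flags.get(str(pid), set())))
            vals = "\t".join("" if np.isnan(v) else repr(float(v)) for v in row)
            fh.write(f"{pid}\t{flags}\t{vals}\n")


def read_lfq_table(path: str | Path) -> LFQTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"flags": str})
    _require_columns(df, ["protein_id", "flags"], path)
    sample_cols = [c for c in df.columns if c not in ("protein_id", "flags")]
    groups: dict[str, str] = {}
    renames: dict[str, str] = {}
    for c in sample_cols:
        if ":" not in c:
            raise SchemaError(f"{path}: intensity column {c!r} lacks 'group:sample'")
        group, sample = c.split(":", 1)
        groups[sample] = group
        renames[c] = sample
    intensities = df.set_index("protein_id")[sample_cols].rename(columns=renames)
    intensities = intensities.astype(float)
    flags = {}
    for pid, f in zip(df["protein_id"], df["flags"]):
        fs = set() if (not isinstance(f, str) or not f) else set(f.split(";"))
        if fs:
            flags[str(pid)] = fs
    return LFQTable(intensities=intensities, flags=flags, groups=groups)


_MQ_FLAG_COLUMNS = {
    "Reverse": "reverse",
    "Potential contaminant": "contaminant",
    "Only identified by site": "only_by_site",
}


def read_maxquant_protein_groups(path: str | Path, groups: dict[str, str],
                                 id_column: str = "Protein IDs") -> LFQTable:
    """Adapter for the MaxQuant proteinGroups dialect.

    Flag columns are marked with '+'; intensities come from 'LFQ intensity
    <sample>' columns (linear scale; zeros become missing and values are
    log2-transformed). ``groups`` maps sample name to bait/control.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, [id_column], path)
    lfq_cols = {c: c[len("LFQ intensity "):] for c in df.columns
                if c.startswith("LFQ intensity ")}
    if not lfq_cols:
        raise SchemaError(f"{path}: no 'LFQ intensity <sample>' columns")
    ids = df[id_column].astype(str)
    intens = df[list(lfq_cols)].rename(columns=lfq_cols).astype(float)
    intens[intens <= 0] = np.nan
    intens = np.log2(intens)
    intens.index = ids
    flags: dict[str, set[str]] = {}
    for mq_col, flag in _MQ_FLAG_COLUMNS.items():
        if mq_col not in df.columns:
            continue
        marked = df[mq_col].astype(str).str.strip() == "+"
        for pid in ids[marked.to_numpy()]:
            flags.setdefault(pid, set()).add(flag)
    return LFQTable(intensities=intens, flags=flags, groups=dict(groups))


# ------------------------------------------------------------ time courses

def read_timecourses(path: str | Path) -> list[TimeCourse]:
    """Time-course TSV: peptide_id, enzyme_label, time_min, replicate, intensity."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["peptide_id", "enzyme_label", "time_min", "replicate",
                          "intensity"], path)
    out: list[TimeCourse] = []
    for (pid, enzyme), grp in df.groupby(["peptide_id", "enzyme_label"], sort=False):
        reps: dict[float, list[float]] = {}
        for t, sub in grp.groupby("time_min", sort=True):
            reps[float(t)] = [float(v) for v in sub["intensity"]]
        out.append(TimeCourse(str(pid), str(enzyme), reps))
    return out


def write_timecourses(tcs: list[TimeCourse], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide_id\tenzyme_label\ttime_min\treplicate\tintensity\n")
        for tc in tcs:
            for t, vals in tc.replicates.items():
                for i, v in enumerate(vals, start=1):
                    fh.write(f"{tc.peptide_id}\t{tc.enzyme_label}\t{t}\t{i}\t{v}\n")


# ------------------------------------------------------------------ outputs

def write_candidate_table(candidates: list[CleavageCandidate], path: str | Path) -> None:
    cols = ["protein_id", "paired", "substrate_start", "substrate_end",
            "product_start", "product_end", "P2", "P1", "P1prime",
            "fc_del_sub", "fc_cat_sub", "fc_del_prod", "fc_cat_prod",
            "manhattan_d", "evidence_score", "flagged"]

    def f(v) -> str:
        return "" if v is None else str(v)

    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            ss, ps = c.substrate_span, c.product_span
            fh.write("\t".join([
                c.protein_id, str(c.paired),
                f(ss.start if ss else None), f(ss.end if ss else None),
                f(ps.start if ps else None), f(ps.end if ps else None),
                f(c.P2), f(c.P1), f(c.P1prime),
                f(c.fc_del_sub), f(c.fc_cat_sub), f(c.fc_del_prod), f(c.fc_cat_prod),
                f(c.manhattan_d), str(c.evidence_score), str(c.flagged),
            ]) + "\n")


def write_volcano(rows: list[VolcanoRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tdiff\td_stat\tp_value\tsignificant\tside\n")
        for r in rows:
            fh.write(f"{r.protein_id}\t{r.diff}\t{r.d_stat}\t{r.p_value}\t"
                     f"{r.significant}\t{r.side}\n")


# -------------------------------------------------------------------- truth

def write_truth(truth: SynthTruth, path: str | Path) -> None:
    payload = {
        "substrates": truth.substrates,
        "conversion": truth.conversion,
        "ipms_enriched": truth.ipms_enriched,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SynthTruth:
    payload = json.loads(Path(path).read_text())
    return SynthTruth(
        substrates=payload.get("substrates", {}),
        conversion=payload.get("conversion", {}),
        ipms_enriched=payload.get("ipms_enriched", {}),
    )
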