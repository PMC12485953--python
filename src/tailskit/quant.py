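"""Reporter-intensity matrix processing for TAILS peptide quantification.

The unit of analysis is a peptide ion (span + modification label + charge)
quantified across 6 TMT-style reporter channels covering three genotypes in
duplicate. Processing follows the usual isobaric workflow: log2 transform
(zeros treated as non-detections), per-channel median centering, MinProb
imputation of missing values from the low tail of each channel's observed
distribution, then per-peptide log2 fold changes of each mutant genotype
against wild-type.

Matrices are pandas DataFrames with peptide keys as the index, channel ids as
columns and NaN marking missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from tailskit.nterm import PeptideSpan

__all__ = [
    "GENOTYPES",
    "PeptideQuantRow",
    "ChannelDesign",
    "ComparisonFC",
    "ImputeParams",
    "peptide_key",
    "rows_to_matrix",
    "log2_transform",
    "median_center",
    "minprob_impute",
    "comparison_fc",
]

#: Genotype labels of the three-strain comparison: wild-type, a protease
#: deletion allele, and a catalytically dead point mutant.
GENOTYPES = ("wildtype", "dpf3_del", "dpf3_S784A")


@dataclass(frozen=True)
class PeptideQuantRow:
    """One observed peptide ion with per-channel reporter intensities.

    ``intensities`` maps channel id to a non-negative linear-scale intensity;
    missing channels may be absent or None.
    """

    span: PeptideSpan
    mod_label: str = ""
    charge: int = 2
    intensities: Mapping[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.intensities:
            raise ValueError("at least one channel must be defined")
        for ch, v in self.intensities.items():
            if v is not None and not np.isnan(v) and v < 0:
                raise ValueError(f"negative intensity {v} in channel {ch}")


def peptide_key(row: PeptideQuantRow) -> str:
    """Stable identifier of a peptide ion: span plus charge/modification status.

    Charge and modification are part of the key because the same peptide
    sequence can be observed as several ions that quantify independently.
    """
    s = row.span
    mod = row.mod_label or "-"
    return f"{s.protein_id}|{s.start}-{s.end}|{mod}|z{row.charge}"


@dataclass(frozen=True)
class ChannelDesign:
    """Map from channel id to (genotype, replicate index)."""

    channels: Mapping[str, tuple[str, int]]

    def __post_init__(self) -> None:
        genos = {g for g, _ in self.channels.values()}
        missing = set(GENOTYPES) - genos
        if missing:
            raise ValueError(f"design lacks channels for genotypes: {sorted(missing)}")

    def channels_for(self, genotype: str) -> list[str]:
        chans = [c for c, (g, _) in self.channels.items() if g == genotype]
        if not chans:
            raise ValueError(f"no channels for genotype {genotype!r}")
        return chans

    @classmethod
    def default_6plex(cls) -> "ChannelDesign":
        """Three genotypes in duplicate across six reporter channels."""
        return cls({
            "ch1": ("wildtype", 1), "ch2": ("wildtype", 2),
            "ch3": ("dpf3_del", 1), "ch4": ("dpf3_del", 2),
            "ch5": ("dpf3_S784A", 1), "ch6": ("dpf3_S784A", 2),
        })


@dataclass(frozen=True)
class ComparisonFC:
    """Per-peptide log2 fold changes of the two mutants against wild-type."""

    key: str
    fc_del: float
    fc_cat: float
    mean_abundance: float


@dataclass(frozen=True)
class ImputeParams:
    """MinProb imputation parameters.

    Missing cells are drawn from a Gaussian centred at the ``q``-quantile of
    each channel's observed log2 intensities with sd ``sd_scale`` times the
    observed sd — a model of detection-limited (left-censored) missingness.
    """

    q: float = 0.01
    sd_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q < 0.5:
            raise ValueError("q must be in (0, 0.5)")
        if self.sd_scale <= 0:
            raise ValueError("sd_scale must be > 0")


def rows_to_matrix(rows: Iterable[PeptideQuantRow],
                   channels: Iterable[str] | None = None) -> pd.DataFrame:
    """Assemble quant rows into a peptide x channel intensity matrix (linear scale)."""
    rows = list(rows)
    if channels is None:
        seen: dict[str, None] = {}
        for r in rows:
            for c in r.intensities:
                seen.setdefault(c)
        channels = list(seen)
    data = {}
    for r in rows:
        key = peptide_key(r)
        if key in data:
            raise ValueError(f"duplicate peptide key {key!r}")
        data[key] = [
            np.nan if (v := r.intensities.get(c)) is None else float(v)
            for c in channels
        ]
    return pd.DataFrame.from_dict(data, orient="index", columns=list(channels))


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2-transform a linear-scale intensity matrix.

    Zeros are non-detections and become missing; negative values are invalid.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValueError("negative intensities are not valid reporter values")
    with np.errstate(divide="ignore"):
        out = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each channel's observed median so column medians are exactly 0.

    Missing entries are untouched. Raises if a channel has no observed value.
    """
    empty = matrix.columns[matrix.notna().sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"channel(s) with no observed values: {list(empty)}")
    return matrix - matrix.median(axis=0, skipna=True)


def minprob_impute(matrix: pd.DataFrame, params: ImputeParams | None = None) -> pd.DataFrame:
    """Fill missing log2 intensities with MinProb draws.

    Per channel c: missing cells <- Normal(q-quantile of observed, sd_scale x
    observed sd). Observed cells are unchanged; a fixed seed gives identical
    output.
    """
    if params is None:
        params = ImputeParams()
    rng = np.random.default_rng(params.seed)
    out = matrix.copy()
    for col in out.columns:
        obs = out[col].dropna()
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        if len(obs) < 3:
            raise ValueError(
                f"channel {col!r} has only {len(obs)} observed values; "
                "cannot estimate MinProb distribution"
            )
        center = float(obs.quantile(params.q))
        sd = params.sd_scale * float(obs.std(ddof=1))
        draws = rng.normal(center, sd, size=n_missing)
        out.loc[out[col].isna(), col] = draws
    return out


def comparison_fc(matrix: pd.DataFrame, design: ChannelDesign,
                  stat: str = "mean", restrict_observed: bool = False) -> list[ComparisonFC]:
    """Per-peptide log2 fold changes: each mutant genotype vs wild-type.

    The default expects a complete (imputed) log2 matrix and returns finite
    fold changes. With ``restrict_observed`` the means use only observed
    channels: a peptide detected in one genotype but in no channel of the
    other gets an infinite fold change of the appropriate sign
    (presence/absence evidence), and NaN when neither side was observed.
    ``stat`` chooses the replicate summary (mean or median) within genotypes.
    """
    if not restrict_observed and matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    agg = (lambda df: df.mean(axis=1)) if stat == "mean" else (lambda df: df.median(axis=1))
    wt = agg(matrix[design.channels_for("wildtype")])
    dele = agg(matrix[design.channels_for("dpf3_del")])
    cat = agg(matrix[design.channels_for("dpf3_S784A")])
    grand = matrix.mean(axis=1)

    def fc(mut: float, ref: float) -> float:
        if np.isnan(mut) and np.isnan(ref):
            return float("nan")
        if np.isnan(ref):
            return float("inf")
        if np.isnan(mut):
            return float("-inf")
        return float(mut - ref)

    return [
        ComparisonFC(key=str(k),
                     fc_del=fc(dele[k], wt[k]),
                     fc_cat=fc(cat[k], wt[k]),
                     mean_abundance=float(grand[k]))
        for k in matrix.index
    ]
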