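"""IP-MS differential enrichment: flag filtering, Gaussian-downshift imputation,
S0-moderated two-sample statistic and permutation-based FDR.

This reproduces the standard Perseus-style analysis of a label-free
affinity-purification experiment. Protein groups flagged as decoys,
contaminants or site-only identifications are removed; log2 LFQ intensities
are completed by drawing missing values from a down-shifted Gaussian
(simulating signals of low-abundance proteins); each protein is tested with a
SAM-type statistic d = (mean_bait - mean_control) / (se + S0), where se is the
two-sample t standard error and S0 damps small-variance, small-effect
proteins; significance is calibrated by permuting the sample-group labels.

With few samples per group (e.g. 3 vs 3) only a handful of distinct
relabelings exist; the FDR estimate uses an add-one-smoothed exceedance ratio
so that it is never optimistic about thresholds no permutation ever reached.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LFQ_FLAGS",
    "LFQTable",
    "PermTestParams",
    "VolcanoRow",
    "PRESET_STRICT",
    "PRESET_PERMISSIVE",
    "filter_protein_groups",
    "impute_gaussian_downshift",
    "s0_statistic",
    "permutation_fdr",
    "volcano",
]

LFQ_FLAGS = ("reverse", "contaminant", "only_by_site")


@dataclass
class LFQTable:
    """Protein-group LFQ table: log2 intensities plus QC flags and group design.

    ``intensities`` is proteins x samples (NaN = missing); ``flags`` maps
    protein_id to a subset of {reverse, contaminant, only_by_site}; ``groups``
    maps sample id to "bait" or "control".
    """

    intensities: pd.DataFrame
    flags: dict[str, set[str]] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = {f for fs in self.flags.values() for f in fs} - set(LFQ_FLAGS)
        if unknown:
            raise ValueError(f"unknown flags: {sorted(unknown)}")
        extra = set(self.groups) - set(self.intensities.columns)
        if extra:
            raise ValueError(f"group map names unknown samples: {sorted(extra)}")

    def samples_for(self, group: str) -> list[str]:
        return [s for s in self.intensities.columns if self.groups.get(s) == group]


@dataclass(frozen=True)
class PermTestParams:
    """Parameters of the S0/permutation significance procedure."""

    s0: float = 2.0
    fdr_target: float = 0.05
    n_permutations: int = 250
    seed: int = 0
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    estimator: str = "mean"  # or "median": permutation-exceedance summary

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must be in (0, 1)")
        if self.n_permutations < 25:
            raise ValueError("n_permutations must be >= 25")
        if self.estimator not in ("mean", "median"):
            raise ValueError("estimator must be 'mean' or 'median'")


#: The two parameter presets used for stringent vs permissive volcano calls.
PRESET_STRICT = PermTestParams(s0=2.0, fdr_target=0.05)
PRESET_PERMISSIVE = PermTestParams(s0=1.22, fdr_target=0.1)


@dataclass(frozen=True)
class VolcanoRow:
    """Per-protein differential-enrichment result."""

    protein_id: str
    diff: float
    d_stat: float
    p_value: float
    significant: bool
    side: str  # bait | control | none


def filter_protein_groups(table: LFQTable) -> LFQTable:
    """Drop protein groups flagged reverse, contaminant or only-by-site."""
    keep = [pid for pid in table.intensities.index
            if not table.flags.get(str(pid), set())]
    return LFQTable(
        intensities=table.intensities.loc[keep],
        flags={pid: set() for pid in map(str, keep) if pid in table.flags},
        groups=dict(table.groups),
    )


def impute_gaussian_downshift(table: LFQTable,
                              params: PermTestParams | None = None) -> LFQTable:
    """Complete the table by per-sample down-shifted Gaussian imputation.

    Missing values in sample s are drawn from Normal(mean_s - downshift * sd_s,
    width * sd_s) where mean_s and sd_s summarize the observed log2 intensities
    of that sample. Observed values are untouched; seeded and reproducible.
    """
    if params is None:
        params = PermTestParams()
    rng = np.random.default_rng(params.seed)
    out = table.intensities.copy()
    for col in out.columns:
        obs = out[col].dropna()
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        if len(obs) < 3:
            raise ValueError(f"sample {col!r} has fewer than 3 observed values")
        mu = float(obs.mean())
        sd = float(obs.std(ddof=1))
        draws = rng.normal(mu - params.impute_downshift * sd,
                           params.impute_width * sd, size=n_missing)
        out.loc[out[col].isna(), col] = draws
    return LFQTable(out, dict(table.flags), dict(table.groups))


def s0_statistic(group_a: np.ndarray, group_b: np.ndarray, s0: float = 0.0) -> float:
    """SAM/Perseus variance-offset statistic d = (mean_a - mean_b) / (se + s0).

    ``se`` is the pooled-variance two-sample t standard error, so s0 = 0
    recovers the classical Student t statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    if se + s0 == 0:
        raise ValueError("zero variance in both groups with s0 = 0: d undefined")
    return float((a.mean() - b.mean()) / (se + s0))


def _d_stats(X: np.ndarray, mask_a: np.ndarray, s0: float) -> np.ndarray:
    """Vectorized d statistic per row of X for boolean group-A mask."""
    A = X[:, mask_a]
    B = X[:, ~mask_a]
    na, nb = A.shape[1], B.shape[1]
    sp2 = ((na - 1) * A.var(axis=1, ddof=1) + (nb - 1) * B.var(axis=1, ddof=1)) / (na + nb - 2)
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    return (A.mean(axis=1) - B.mean(axis=1)) / (se + s0)


def _distinct_relabelings(n: int, na: int, observed: tuple[int, ...],
                          n_wanted: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Distinct group relabelings as boolean masks, excluding the observed one.

    Because |d| is invariant under swapping the two groups, relabelings are
    canonicalised to unordered partitions (sample 0 always in group A when
    group sizes are equal).
    """
    combos = []
    obs = frozenset(observed)
    comp = frozenset(range(n)) - obs
    seen = set()
    for c in itertools.combinations(range(n), na):
        key = frozenset(c)
        canon = frozenset({key, frozenset(range(n)) - key} if na * 2 == n else {key})
        canon_key = min(tuple(sorted(k)) for k in canon)
        if canon_key in seen:
            continue
        seen.add(canon_key)
        if key == obs or (na * 2 == n and key == comp):
            continue
        combos.append(key)
    if len(combos) > n_wanted:
        idx = rng.choice(len(combos), size=n_wanted, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    masks = []
    for key in combos:
        m = np.zeros(n, dtype=bool)
        m[list(key)] = True
        masks.append(m)
    return masks


def permutation_fdr(table: LFQTable, params: PermTestParams | None = None
                    ) -> tuple[float, pd.DataFrame]:
    """Permutation-calibrated significance of the S0 statistic.

    Computes observed |d| per protein, recomputes |d*| under random
    relabelings of the sample-group assignment, and for every candidate
    threshold t among the observed |d| estimates

        FDR(t) = smoothed exceedances of permuted |d*| >= t  /  #{observed |d| >= t}

    where the permutation exceedance count is summarized by the mean (add-one
    smoothed: (1 + total) / (B + 1)) or the median across the B relabelings.
    The cutoff is the smallest t with FDR(t) <= fdr_target (infinity when no
    threshold qualifies). Returns (cutoff, per-protein frame with columns
    diff, d_stat, significant).
    """
    if params is None:
        params = PermTestParams()
    X = table.intensities.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("table contains missing values; impute first")
    bait = table.samples_for("bait")
    ctrl = table.samples_for("control")
    if len(bait) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 samples per group")
    cols = list(table.intensities.columns)
    obs_idx = tuple(cols.index(s) for s in bait)
    n = len(cols)
    mask_obs = np.zeros(n, dtype=bool)
    mask_obs[list(obs_idx)] = True

    d_obs = _d_stats(X, mask_obs, params.s0)
    abs_obs = np.abs(d_obs)

    rng = np.random.default_rng(params.seed)
    masks = _distinct_relabelings(n, len(bait), obs_idx, params.n_permutations, rng)
    if len(masks) < params.n_permutations:
        warnings.warn(
            f"only {len(masks)} distinct relabelings exist; using all of them",
            stacklevel=2,
        )
    if not masks:
        raise ValueError("no non-trivial relabelings possible")
    perm_abs = np.stack([np.abs(_d_stats(X, m, params.s0)) for m in masks])
    B = len(masks)

    thresholds = np.unique(abs_obs)
    # exceedance counts per permutation at each threshold, via sorted search
    sorted_obs = np.sort(abs_obs)
    n_obs = len(sorted_obs) - np.searchsorted(sorted_obs, thresholds, side="left")
    counts = np.empty((B, len(thresholds)))
    n_prot = perm_abs.shape[1]
    for b in range(B):
        counts[b] = n_prot - np.searchsorted(np.sort(perm_abs[b]), thresholds,
                                             side="left")
    if params.estimator == "mean":
        exceed = (1.0 + counts.sum(axis=0)) / (B + 1)
    else:
        exceed = np.median(counts, axis=0)
    fdr = exceed / np.maximum(1, n_obs)
    passing = np.nonzero(fdr <= params.fdr_target)[0]
    cutoff = float(thresholds[passing[0]]) if len(passing) else math.inf

    significant = abs_obs >= cutoff if math.isfinite(cutoff) else np.zeros(len(abs_obs), bool)
    diff = X[:, mask_obs].mean(axis=1) - X[:, ~mask_obs].mean(axis=1)
    frame = pd.DataFrame(
        {"diff": diff, "d_stat": d_obs, "significant": significant},
        index=table.intensities.index,
    )
    return cutoff, frame


def volcano(table: LFQTable, params: PermTestParams | None = None) -> list[VolcanoRow]:
    """Volcano-plot rows: fold enrichment, S0 statistic, classical Student p,
    and the permutation significance call.

    The p-value on the y-axis is the ordinary two-tailed two-sample t test
    (no S0), reported alongside — not instead of — the S0/permutation call.
    """
    if params is None:
        params = PermTestParams()
    cutoff, frame = permutation_fdr(table, params)
    bait = table.samples_for("bait")
    ctrl = table.samples_for("control")
    A = table.intensities[bait].to_numpy(dtype=float)
    B = table.intensities[ctrl].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = stats.ttest_ind(A, B, axis=1, equal_var=True).pvalue
    rows = []
    for i, pid in enumerate(table.intensities.index):
        sig = bool(frame["significant"].iloc[i])
        d = float(frame["diff"].iloc[i])
        side = "none" if not sig else ("bait" if d > 0 else "control")
        rows.append(VolcanoRow(
            protein_id=str(pid), diff=d,
            d_stat=float(frame["d_stat"].iloc[i]),
            p_value=float(pvals[i]), significant=sig, side=side,
        ))
    return rows
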