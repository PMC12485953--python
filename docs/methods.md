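# Methods

This note describes the models implemented in `tailskit`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Coordinates are 1-based inclusive;
the initiator Met is residue 1.

## Mature N-termini and cleavage arithmetic

A dipeptidyl peptidase acts on free N-termini, so the analysis anchors every
peptide to the protein's *expected mature* N-terminus:

1. an annotated signal peptide is removed co-translationally — mature start =
   signal-peptide end + 1; this rule takes precedence;
2. otherwise, when residue 1 is Met and residue 2 is small
   (G, A, S, T, C, P, V), Met aminopeptidases excise the initiator Met —
   mature start = 2. An `X` at position 2 never fires the rule;
3. otherwise the mature start is residue 1. Sequences not beginning with Met
   (fragments) are tolerated; only rule 2 requires Met1.

Each cleavage cycle removes one dipeptide, so a peptide starting at
`mature_start + 2k` (k ≥ 1) is classified as a *k*-cycle product; a start at
the mature N-terminus is a potential substrate; anything else — upstream
starts, odd offsets, offsets beyond `max_cycles` (default 15, covering deep
sequential processing) — is internal. Odd-offset downstream peptides are
deliberately *not* rounded into the product frame: sequential dipeptidyl
processing cannot produce them from the annotated mature start, so they are
left internal rather than guessing an unannotated alternative N-terminus.

P-position convention (exopeptidase nomenclature): substrate residue 1 = P2,
residue 2 = P1 with the scissile bond C-terminal to it, residue 3 = P1′.

In-silico digestion is Arg-C with semi-specific termini: all fully specific
peptides (both ends at cleavage boundaries or protein termini, at most
`max_missed_cleavages` = 1 internal sites) plus all peptides with exactly one
specific terminus. Proline blocking of cleavage is off by default (plain
Arg-C) but available. The length window is 7–40; the lower bound is the usual
identifiability limit and the upper bound a detectability convention. The
enumeration is validated against an exhaustive O(n²) substring oracle.

## Reporter-matrix processing

Zero reporter intensities are treated as non-detections (missing), not as
−∞. After log2 transform, each channel is median-centered (median of observed
values exactly 0). MinProb imputation fills missing cells per channel from
Normal(q-quantile of observed, sd_scale × observed sd) with q = 0.01 and
sd_scale = 0.3 — the standard left-censored model for detection-limited
missingness. Imputation is seeded and touches only missing cells; channels
with fewer than 3 observed values are an error.

Fold changes are means over replicate channels (median selectable), computed
after imputation by default. A `restrict_observed` mode instead uses only
observed channels and maps complete absence in one genotype to an infinite
fold change of the appropriate sign. This presence/absence reading is the
faithful one for structurally missing signals: when a substrate is fully
converted in wild-type, its peptide has *no* wild-type signal, and any finite
imputed fold change would merely measure where the random imputation floor
landed relative to that protein's abundance. The noiseless complete-conversion
verification therefore runs in this mode; noisy analyses use the imputed
route. Peptide identity includes charge and modification label, since one
sequence can quantify as several independent ions.

## Quadrant classification and pairing

With fold changes oriented mutant vs wild-type, substrates move up in both
comparisons and products move down. Defaults: |log2FC| > 2 in *both*
comparisons (the both-comparison reading matches the candidate-coloring rule;
an either-comparison flag exists); start position ≤ 50 for candidate labeling
(deeper peptides are internal-reference material, still usable as pair
context but never labeled); allowed pair offsets {2} (one dipeptidyl step);
Manhattan distance |Δfc_del| + |Δfc_cat| ≥ 4, read as a *minimum* separation
— substrate and product move in opposite directions, so genuine pairs are far
apart in fold-change space; a maximum-distance comparator is available for
the alternative reading. Pairs must be opposite-signed in all four
coordinates by default.

Matching is greedy one-to-one by largest Manhattan distance (ties: smaller
offset, then lexicographic peptide keys), which is deterministic and
order-invariant; an exhaustive bipartite option was considered unnecessary
since ties at equal distance are vanishingly rare in continuous data.
Unpaired substrate- or product-candidates are kept as singletons (detection
bias routinely hides one member); a lone product infers its substrate start
one dipeptide step upstream. The evidence score of a record is
max over members of min(|fc_del|, |fc_cat|); the table is sorted paired-first,
then by descending score. Candidates whose P positions fall outside the
protein are flagged, not dropped.

## IP-MS enrichment statistics

Protein groups flagged reverse / contaminant / only-by-site are removed.
Missing log2 LFQ values are imputed per sample from
Normal(mean − 1.8 × sd, 0.3 × sd) (down-shifted Gaussian, simulating
low-abundance signals). Each protein is scored with
d = (mean_bait − mean_control) / (se + S0), where se is the pooled two-sample
t standard error; S0 = 0 recovers the classical t statistic, larger S0
de-emphasizes small-variance, small-effect proteins.

Significance is calibrated by permutation: relabelings of the sample-group
assignment are drawn uniformly without replacement from the distinct
*unordered* partitions (|d| is invariant under swapping groups), excluding
the observed one — a 3 vs 3 design has 9 such relabelings, so requests for
more use all of them with a warning. For each candidate threshold t among
the observed |d|,

    FDR(t) = [(1 + Σ_b #{|d*_b| ≥ t}) / (B + 1)] / #{observed |d| ≥ t}

and the cutoff is the smallest t with FDR(t) ≤ target. The add-one smoothing
(the permutation analogue of never reporting p = 0) matters precisely in the
small-B regime: with 9 relabelings an unsmoothed mean estimator returns
FDR = 0 whenever the observed maximum happens to exceed every permuted value,
which under a global null occurs with probability ≈ 1/(B+1) per dataset and
would produce spurious calls in ~10% of null experiments. With smoothing, a
single protein can never be called at FDR 0.05 from 9 relabelings alone —
a deliberate conservatism. A median-of-exceedances estimator is selectable.
No π₀ correction is applied.

Volcano rows report the fold enrichment (diff), the S0 statistic, the
*classical* two-tailed Student t p-value (S0-free, for the y-axis), and the
permutation significance call — both are reported to keep the moderated and
classical views distinct. Presets: strict (FDR 0.05, S0 = 2) and permissive
(FDR 0.1, S0 = 1.22).

## Time-course summaries

Product-peptide MS1 traces are summarized as the arithmetic mean over
technical replicates per timepoint. Product formation is called when the
final mean is ≥ 5-fold over the t0 baseline and the trace is non-decreasing
in at least half the steps. The baseline is floored at a configurable
fraction (0.002) of the trace maximum rather than a fixed pseudo-intensity,
so a zero start does not divide away and the call is invariant to rescaling
all intensities — a property a fixed absolute floor would break.

## The synthetic-data generator

`SimConfig` encodes the simulated study: 1000 proteins (length 80–400,
uniform residue background), 15% with signal peptides ending uniformly at
residue 15–25, 50 designated substrates. Substrates get a well-defined mature
N-terminus (residue 2 drawn from the Met-excision set when no signal peptide)
and a P1 residue drawn from the specificity weights
P:1.0, A:0.8, S:0.3, T:0.3, G:0.2 — a proline-dominated profile with minor
tolerance of small residues, as expected for this protease family. Every
protein is guaranteed an Arg-C N-terminal peptide of tractable length (an
Arg is placed 9–14 residues into the mature sequence when none occurs within
the detectable window; Arg within the first 8 mature residues is replaced).

Quantification: protein abundance is log-normal with log2 mean 20 and sd 2.5
(~3 orders of magnitude for the central 95%, typical of deep isobaric
peptide data). Substrate molecules split between substrate and product
peptides by the genotype's conversion fraction — wild-type 0.9, both
loss-of-function mutants 0.02 with independent noise (they share conversion
because both abolish catalysis, which is what puts concordant peptides on
the diagonal of the two-comparison plane). Each peptide gets a log-normal
ionization-efficiency factor (log2 sd 0.5, constant across channels, so it
cancels from fold changes) and each channel multiplicative reporter noise of
log2 sd 0.3. In the noiseless limit the substrate fold change is exactly
log2((1 − c_mut)/(1 − c_wt)) — the closed form the tests pin.

Missingness mirrors isobaric quantification, where all six channels derive
from a single identification event: whole peptide rows drop out by a logistic
MNAR curve on the pooled (channel-mean) intensity, anchored at the 10th
percentile with slope 1.0 per log2 unit, and within identified rows
individual channels are censored by the same logistic anchored at the
reporter detection floor (the 0.01 cell-intensity quantile, mirroring the
MinProb q convention). Structural zeros (conversion exactly 0 or 1) are
always missing. Rows missing in every channel are not reported. Under these
defaults, identification loss concentrates in the dimmest ~10–20% of
proteins; substrates in that abundance range are unrecoverable by any
analysis, which is the realistic price of MNAR detection. Recovery
benchmarks that isolate the *analysis* (noise-only conditions,
`mnar_enabled=False`) achieve sensitivity 1.0 with no false pairs; with
dropout enabled, protein-level sensitivity is ~0.75–0.90 depending on seed.

The IP-MS simulator plants `ipms_n_enriched` = 5 proteins with a +5 log2
bait shift on Normal(25, 2) baselines with within-group sd 0.3, flags 4% of
non-planted rows to exercise filtering, and optionally applies MNAR dropout.
With dropout enabled, occasional extra significant calls appear next to the
planted set; these are genuine differential-detection events (groupwise
dropout followed by down-shifted imputation), not false positives of the
statistic, and the calibration checks therefore run without dropout.

What the generator does **not** emulate: spectra and search-engine behavior,
isotopic impurity and co-isolation effects, retention time and fractionation,
peptide-specific digestion efficiency, correlated (batch) noise, and real
proteome sequence composition. Passing recovery tests therefore demonstrates
correctness of the analysis logic under the stated statistical structure, not
performance on real instruments' quirks.

## Numerical conventions and degenerate inputs

- All randomness flows through `numpy.random.default_rng` seeded from the
  config; identical seeds give bit-identical outputs, including FASTA bytes.
- Median centering errors on an all-missing channel, naming it; imputation
  errors on channels/samples with < 3 observed values.
- `s0_statistic` with zero variance in both groups and S0 = 0 is an error
  (undefined), not a silent infinity.
- Infinite fold changes (observed-only mode) propagate through
  classification and pairing naturally: ±∞ exceeds any threshold and an
  ∞ Manhattan distance satisfies the minimum; NaN (absent on both sides of a
  comparison) classifies as unchanged.
- Pair tie-breaks and table sort orders are fully specified (see above) so
  outputs are reproducible across runs and row orders.

## Problem sizes

The shipped tests and examples use 1000-protein screens (≈3000 peptide ions)
for recovery benchmarks, 500-protein IP-MS tables with 100 seeded replicate
runs for null calibration, and 100-protein batches for the digestion oracle;
these sizes give stable pass/fail behavior for the statistical checks while
keeping the whole suite in the seconds-to-minutes range.

## Known limitations

- MinProb and the Perseus imputation/FDR internals are under-specified in
  common usage; the concrete definitions here (quantile centers, add-one
  smoothed exceedance ratio, no π₀) are documented choices, and alternatives
  (median estimator, either-comparison thresholding, ≤-distance pairing) are
  exposed as options rather than silently decided.
- Greedy pairing is one-to-one; a peptide supported by two plausible partners
  keeps only the stronger pair.
- N-terminally modified (e.g. acetylated) peptides are not excluded from
  substrate candidacy; a config flag can restrict by modification label.
- The kinetics module makes a qualitative formed/not-formed call; it does not
  fit rate constants.
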