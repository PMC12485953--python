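"""Synthetic-data generator: determinism, ground-truth structure, noise model."""

import numpy as np
import pytest
from scipy import stats

from tailskit.nterm import mature_nterm
from tailskit.pipeline import run_tails_pipeline, score_against_truth
from tailskit.quant import ChannelDesign, peptide_key
from tailskit.simulate import (
    SimConfig,
    generate_proteome,
    simulate_ipms,
    simulate_tails,
)

SMALL = dict(n_proteins=120, n_substrates=12)


class TestGenerateProteome:
    def test_same_seed_identical_output(self):
        a, ta = generate_proteome(SimConfig(seed=3, **SMALL))
        b, tb = generate_proteome(SimConfig(seed=3, **SMALL))
        assert {k: v.sequence for k, v in a.items()} == \
            {k: v.sequence for k, v in b.items()}
        assert ta.substrates == tb.substrates

    def test_truth_lists_exactly_n_substrates(self):
        prot, truth = generate_proteome(SimConfig(seed=1, n_proteins=300,
                                                  n_substrates=50))
        assert len(truth.substrates) == 50
        assert set(truth.substrates) <= set(prot)

    def test_substrate_annotation_consistent_with_nterm_rules(self):
        prot, truth = generate_proteome(SimConfig(seed=2, **SMALL))
        for pid, t in truth.substrates.items():
            rec = prot[pid]
            m = mature_nterm(rec)
            assert m.start == t["substrate_start"]
            assert t["product_start"] == t["substrate_start"] + 2
            assert rec.residue(t["substrate_start"] + 1) == t["P1"]

    def test_signal_peptide_ends_in_annotated_window(self):
        prot, _ = generate_proteome(SimConfig(seed=4, n_proteins=400,
                                              n_substrates=10,
                                              signal_peptide_fraction=0.5))
        ends = [p.signal_peptide_end for p in prot.values()
                if p.signal_peptide_end is not None]
        assert ends and all(15 <= e <= 25 for e in ends)
        assert 100 < len(ends) < 300  # ~50% of 400

    def test_p1_composition_follows_specificity_weights(self):
        cfg = SimConfig(seed=6, n_proteins=4000, n_substrates=4000)
        _, truth = generate_proteome(cfg)
        counts = {}
        for t in truth.substrates.values():
            counts[t["P1"]] = counts.get(t["P1"], 0) + 1
        residues = list(cfg.p1_weights)
        w = np.array([cfg.p1_weights[r] for r in residues], float)
        expected = w / w.sum() * len(truth.substrates)
        observed = np.array([counts.get(r, 0) for r in residues], float)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        # df = 4; 0.999 quantile ~ 18.5
        assert chi2 < stats.chi2.ppf(0.999, df=len(residues) - 1)
        assert set(counts) <= set(residues)


class TestSimulateTails:
    def test_seeded_determinism(self):
        cfg = SimConfig(seed=9, **SMALL)
        prot, truth = generate_proteome(cfg)
        r1 = simulate_tails(prot, truth, cfg)
        r2 = simulate_tails(prot, truth, cfg)
        assert [(peptide_key(a), a.intensities) for a in r1] == \
            [(peptide_key(b), b.intensities) for b in r2]

    def test_full_conversion_limit_zero_product_in_mutants(self):
        cfg = SimConfig(seed=5, noise_log2_sd=0.0, mnar_enabled=False,
                        conversion={"wildtype": 1.0, "dpf3_del": 0.0,
                                    "dpf3_S784A": 0.0}, **SMALL)
        prot, truth = generate_proteome(cfg)
        rows = simulate_tails(prot, truth, cfg)
        design = ChannelDesign.default_6plex()
        mut_ch = design.channels_for("dpf3_del") + design.channels_for("dpf3_S784A")
        wt_ch = design.channels_for("wildtype")
        for r in rows:
            t = truth.substrates.get(r.span.protein_id)
            if t and r.span.start == t["product_start"]:
                assert all(r.intensities[c] is None for c in mut_ch)
                assert all(r.intensities[c] > 0 for c in wt_ch)

    def test_noiseless_fold_change_matches_closed_form(self):
        # log2 FC of a substrate peptide (mutant vs wild-type) in the
        # noiseless limit is log2((1 - c_mut) / (1 - c_wt))
        cfg = SimConfig(seed=7, noise_log2_sd=0.0, mnar_enabled=False,
                        conversion={"wildtype": 0.9, "dpf3_del": 0.0,
                                    "dpf3_S784A": 0.0}, **SMALL)
        prot, truth = generate_proteome(cfg)
        rows = simulate_tails(prot, truth, cfg)
        expected = np.log2(1.0 / (1.0 - 0.9))
        design = ChannelDesign.default_6plex()
        checked = 0
        for r in rows:
            t = truth.substrates.get(r.span.protein_id)
            if t and r.span.start == t["substrate_start"]:
                wt = np.mean([np.log2(r.intensities[c])
                              for c in design.channels_for("wildtype")])
                mut = np.mean([np.log2(r.intensities[c])
                               for c in design.channels_for("dpf3_del")])
                assert mut - wt == pytest.approx(expected, abs=1e-9)
                checked += 1
        assert checked == len(truth.substrates)

    def test_missingness_increases_toward_low_intensity(self):
        cfg = SimConfig(seed=11, n_proteins=800, n_substrates=20)
        prot, truth = generate_proteome(cfg)
        rows = simulate_tails(prot, truth, cfg)
        obs_mean, miss_frac = [], []
        for r in rows:
            vals = [v for v in r.intensities.values() if v is not None]
            obs_mean.append(np.log2(np.mean(vals)))
            miss_frac.append(np.mean([v is None for v in r.intensities.values()]))
        q = np.quantile(obs_mean, [0.25, 0.75])
        low = np.mean([m for o, m in zip(obs_mean, miss_frac) if o <= q[0]])
        high = np.mean([m for o, m in zip(obs_mean, miss_frac) if o >= q[1]])
        assert low > high  # more dropout at lower intensity (MNAR)

    def test_noiseless_full_pipeline_recovers_truth_exactly(self):
        cfg = SimConfig(seed=13, noise_log2_sd=0.0, mnar_enabled=False,
                        conversion={"wildtype": 1.0, "dpf3_del": 0.0,
                                    "dpf3_S784A": 0.0}, **SMALL)
        prot, truth = generate_proteome(cfg)
        rows = simulate_tails(prot, truth, cfg)
        result = run_tails_pipeline(prot, rows, restrict_observed=True)
        score = score_against_truth(result, truth)
        assert score.sensitivity == 1.0
        assert score.n_false_pairs == 0
        assert {c.protein_id for c in result.candidates} == set(truth.substrates)


class TestSimulateIpms:
    def test_flagged_row_count_matches_fraction(self):
        cfg = SimConfig(seed=1, ipms_n_proteins=400, ipms_flagged_fraction=0.05)
        table, _ = simulate_ipms(cfg)
        assert sum(1 for f in table.flags.values() if f) == 20

    def test_seeded_determinism(self):
        a, _ = simulate_ipms(SimConfig(seed=21))
        b, _ = simulate_ipms(SimConfig(seed=21))
        assert a.intensities.equals(b.intensities)

    def test_enriched_truth_size_and_shift(self):
        cfg = SimConfig(seed=2, ipms_missing_enabled=False)
        table, truth = simulate_ipms(cfg)
        assert len(truth.ipms_enriched) == cfg.ipms_n_enriched
        X = table.intensities
        for pid in truth.ipms_enriched:
            bait = [c for c in X.columns if c.startswith("bait")]
            ctrl = [c for c in X.columns if c.startswith("control")]
            diff = X.loc[pid, bait].mean() - X.loc[pid, ctrl].mean()
            assert diff == pytest.approx(5.0, abs=1.0)
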