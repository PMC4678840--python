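"""Gating: singlet rule, DNA peaks, thresholds, quadrants."""

import numpy as np
import pandas as pd
import pytest

from mcmflow import (AnalysisError, DnaPeaks, InputError, OpticsConfig, auto_gate,
                     classify_quadrants, define_gates, derive_mcm_threshold,
                     derive_rb1_threshold, derive_threshold_from_control,
                     find_dna_peaks, fraction_s_phase, gate_singlets, get_scenario,
                     apply_measurement_model, inject_doublets, simulate_cells)
from mcmflow.simulate import TRUTH_COLUMNS

from conftest import make_events


def events_frame(**cols):
    n = max((len(np.atleast_1d(v)) for v in cols.values()), default=1)
    base = {"dna_area": 200.0, "dna_width": 100.0, "mcm_signal": 10.0, "rb1_signal": 10.0}
    base.update(cols)
    return pd.DataFrame({k: np.broadcast_to(np.asarray(v, dtype=float), n).copy()
                         for k, v in base.items()})


class TestSingletGate:
    def test_mad_cut_excludes_wide_event(self):
        widths = np.array([100.0] * 25 + [102.0] * 26 + [160.0] * 9)
        ev = events_frame(dna_width=widths)
        kept, (center, cut) = gate_singlets(ev, k_mad=4.0)
        assert center == 102.0
        assert cut < 160.0
        assert set(kept["dna_width"]) == {100.0, 102.0}

    def test_degenerate_width_falls_back_with_warning(self):
        ev = events_frame(dna_width=np.array([100.0] * 59 + [160.0]))
        with pytest.warns(UserWarning, match="degenerate"):
            kept, (center, cut) = gate_singlets(ev)
        assert cut == pytest.approx(130.0)
        assert 160.0 not in set(kept["dna_width"])

    def test_doublet_removal_and_singlet_retention(self):
        optics = OpticsConfig(doublet_rate=0.0476)  # ~500 doublets on 10,000 singlets
        ev = make_events(n_cells=10_000, seed=21, optics=optics)
        ev = inject_doublets(ev, optics, seed=22)
        kept, _ = gate_singlets(ev)
        n_dbl = ev["is_doublet"].sum()
        assert n_dbl >= 490
        assert 1 - kept["is_doublet"].sum() / n_dbl >= 0.95
        assert len(kept[~kept["is_doublet"]]) / (~ev["is_doublet"]).sum() >= 0.98

    def test_requires_minimum_events(self):
        with pytest.raises(InputError):
            gate_singlets(events_frame(dna_width=np.full(10, 100.0)))


class TestDnaPeaks:
    def test_pure_g1_population_infers_g2(self):
        rng = np.random.default_rng(1)
        ev = events_frame(dna_area=200 * rng.lognormal(0, 0.03, 5000))
        p = find_dna_peaks(ev)
        assert p.g1_peak == pytest.approx(200, rel=0.02)
        assert p.g2_peak == pytest.approx(2 * p.g1_peak)
        assert p.g2_inferred

    def test_g1_g2_mixture_recovered_within_2pct(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([200 * rng.lognormal(0, 0.03, 12_000),
                            400 * rng.lognormal(0, 0.03, 6_000),
                            rng.uniform(210, 390, 2_000)])
        p = find_dna_peaks(events_frame(dna_area=x))
        assert p.g1_peak == pytest.approx(200, rel=0.02)
        assert p.g2_peak == pytest.approx(400, rel=0.02)
        assert not p.g2_inferred and not p.g1_ambiguous

    def test_all_g2m_sample_flagged_ambiguous(self):
        # a mitotic-arrest sample at t=0: single 4N mode, G1 cannot be inferred
        sc = get_scenario("u2os_nocodazole_release", n_cells=5000, seed=3)
        ev = apply_measurement_model(simulate_cells(sc, 0.0), OpticsConfig(), seed=3)
        p = find_dna_peaks(ev)
        assert p.g1_peak == pytest.approx(400, rel=0.03)
        assert p.g1_ambiguous and p.g2_inferred

    def test_too_few_events(self):
        with pytest.raises(InputError):
            find_dna_peaks(events_frame(dna_area=np.full(50, 200.0)))


class TestDefineGates:
    def test_interval_arithmetic(self):
        gates = define_gates(events_frame(), DnaPeaks(200.0, 400.0))
        assert gates.g1_gate == (pytest.approx(180.0), pytest.approx(200.0))
        assert gates.sg2_border == (pytest.approx(360.0), pytest.approx(392.0))
        assert gates.s_interval == (pytest.approx(220.0), pytest.approx(360.0))

    def test_right_side_of_g1_peak_excluded(self):
        gates = define_gates(events_frame(), DnaPeaks(200.0, 400.0))
        gates.mcm_threshold, gates.rb1_threshold = 1.0, 1.0
        ev = events_frame(dna_area=np.array([185.0, 200.0, 205.0]))
        qr = classify_quadrants(ev, gates)
        assert qr.n_total == 2  # 205 is right of the peak


class TestThresholds:
    def test_constant_border_signal(self):
        ev = events_frame(dna_area=np.full(100, 370.0), mcm_signal=np.full(100, 7.5))
        gates = define_gates(ev, DnaPeaks(200.0, 400.0))
        for q in (0.5, 0.9, 0.99):
            assert derive_mcm_threshold(ev, gates, q=q) == pytest.approx(7.5)

    def test_lognormal_quantile_closed_form(self):
        rng = np.random.default_rng(3)
        ev = events_frame(dna_area=np.full(20_000, 370.0),
                          mcm_signal=50 * rng.lognormal(0, 0.2, 20_000))
        gates = define_gates(ev, DnaPeaks(200.0, 400.0))
        expect = 50 * np.exp(0.2 * 2.3263)  # ~79.6
        assert derive_mcm_threshold(ev, gates, q=0.99) == pytest.approx(expect, rel=0.05)

    def test_threshold_monotone_in_q(self, async_events):
        _, gates = auto_gate(async_events)
        thrs = [derive_mcm_threshold(async_events, gates, q=q)
                for q in (0.95, 0.99, 0.999)]
        assert thrs == sorted(thrs)

    def test_rb1_geometric_midpoint(self):
        rng = np.random.default_rng(4)
        n = 4000
        g1_rb1 = np.where(rng.random(n) < 0.5,
                          10 * rng.lognormal(0, 0.1, n), 1000 * rng.lognormal(0, 0.1, n))
        ev = pd.DataFrame({
            "dna_area": np.concatenate([rng.normal(200, 6, n), rng.normal(290, 30, n)]),
            "dna_width": 100.0,
            "mcm_signal": 10.0,
            "rb1_signal": np.concatenate([g1_rb1, 10 * rng.lognormal(0, 0.1, n)]),
        })
        gates = define_gates(ev, DnaPeaks(200.0, 400.0))
        thr, fallback = derive_rb1_threshold(ev, gates)
        assert not fallback
        assert thr == pytest.approx(np.sqrt(10 * 1000), rel=0.2)

    def test_rb1_s_phase_classified_negative(self, async_events):
        singlets, gates = auto_gate(async_events)
        s = singlets[(singlets["dna_area"] >= gates.s_interval[0])
                     & (singlets["dna_area"] < gates.s_interval[1])]
        assert (s["rb1_signal"] <= gates.rb1_threshold).mean() >= 0.99

    def test_control_threshold(self):
        rng = np.random.default_rng(5)
        const = events_frame(mcm_signal=np.full(200, 4.2))
        assert derive_threshold_from_control(const, "mcm_signal", q=0.9) == pytest.approx(4.2)
        ctrl = events_frame(mcm_signal=10 * rng.lognormal(0, 0.3, 50_000))
        expect = 10 * np.exp(0.3 * 2.5758)  # ~21.7
        assert derive_threshold_from_control(ctrl, "mcm_signal", q=0.995) == \
            pytest.approx(expect, rel=0.05)

    def test_control_and_population_thresholds_agree(self, async_events):
        # mirrors the observation that population-derived regions coincide
        # with secondary-antibody-control regions
        _, gates = auto_gate(async_events)
        rng = np.random.default_rng(6)
        optics = OpticsConfig()
        ctrl = events_frame(
            mcm_signal=optics.background_mcm * rng.lognormal(0, np.sqrt(np.log1p(optics.cv_mcm ** 2)), 20_000))
        ctrl_thr = derive_threshold_from_control(ctrl, "mcm_signal", q=0.99)
        assert 1 / 1.5 < gates.mcm_threshold / ctrl_thr < 1.5

    def test_sparse_border_raises_analysis_error(self):
        ev = events_frame(dna_area=np.full(1000, 200.0))
        gates = define_gates(ev, DnaPeaks(200.0, 400.0))
        with pytest.raises(AnalysisError, match="control"):
            derive_mcm_threshold(ev, gates)


class TestQuadrants:
    def make_gates(self):
        gates = define_gates(events_frame(), DnaPeaks(200.0, 400.0))
        gates.mcm_threshold, gates.rb1_threshold = 80.0, 100.0
        return gates

    def test_quadrant_definitions_and_conservation(self):
        gates = self.make_gates()
        ev = events_frame(dna_area=np.full(4, 190.0),
                          mcm_signal=np.array([200.0, 200.0, 10.0, 10.0]),
                          rb1_signal=np.array([30.0, 300.0, 300.0, 30.0]))
        qr = classify_quadrants(ev, gates)
        assert (qr.n_q1, qr.n_q2, qr.n_q3, qr.n_q4) == (1, 1, 1, 1)
        assert qr.n_total == 4
        assert qr.frac_q1 + qr.frac_q2 + qr.frac_q3 + qr.frac_q4 == pytest.approx(1.0, abs=1e-9)
        for frac, ci in ((qr.frac_q1, qr.ci_q1), (qr.frac_q2, qr.ci_q2),
                         (qr.frac_q3, qr.ci_q3), (qr.frac_q4, qr.ci_q4)):
            assert 0 <= ci[0] <= frac <= ci[1] <= 1

    def test_tie_at_threshold_is_negative(self):
        gates = self.make_gates()
        ev = events_frame(dna_area=190.0, mcm_signal=np.array([80.0]),
                          rb1_signal=np.array([100.0]))
        qr = classify_quadrants(ev, gates)
        assert qr.n_q4 == 1

    def test_zero_g1_events_raises(self):
        gates = self.make_gates()
        with pytest.raises(AnalysisError):
            classify_quadrants(events_frame(dna_area=np.full(10, 300.0)), gates)

    def test_quadrant_fractions_track_ground_truth(self):
        ev = make_events(n_cells=30_000, seed=31)
        singlets, gates = auto_gate(ev)
        qr = classify_quadrants(singlets, gates)
        lo, hi = gates.g1_gate
        g1 = singlets[(singlets["dna_area"] >= lo) & (singlets["dna_area"] <= hi)]
        mcm = g1["mcm_loaded_fraction"] > 0
        rb1 = g1["rb1_state"] == "hypo_phosphorylated"
        truth = {"q1": (mcm & ~rb1).mean(), "q2": (mcm & rb1).mean(),
                 "q3": (~mcm & rb1).mean(), "q4": (~mcm & ~rb1).mean()}
        for name, t in truth.items():
            assert abs(getattr(qr, f"frac_{name}") - t) < 0.03, (name, t)

    def test_ground_truth_blindness(self, async_events):
        stripped = async_events.drop(columns=[c for c in TRUTH_COLUMNS
                                              if c in async_events.columns])
        s1, g1 = auto_gate(async_events)
        s2, g2 = auto_gate(stripped)
        assert len(s1) == len(s2)
        assert g1.mcm_threshold == g2.mcm_threshold
        assert g1.rb1_threshold == g2.rb1_threshold
        q1 = classify_quadrants(s1, g1)
        q2 = classify_quadrants(s2, g2)
        assert (q1.n_q1, q1.n_q2, q1.n_q3, q1.n_q4) == (q2.n_q1, q2.n_q2, q2.n_q3, q2.n_q4)

    def test_gate_stability_across_seeds(self):
        thrs = []
        for seed in (41, 42):
            ev = make_events(n_cells=50_000, seed=seed)
            _, g = auto_gate(ev)
            thrs.append((g.mcm_threshold, g.rb1_threshold))
        for a, b in zip(*thrs):
            assert abs(a - b) / a < 0.05


class TestSPhaseFraction:
    def test_pure_g1_near_zero(self):
        rng = np.random.default_rng(7)
        ev = events_frame(dna_area=200 * rng.lognormal(0, 0.03, 5000))
        gates = define_gates(ev, DnaPeaks(200.0, 400.0))
        assert fraction_s_phase(ev, gates).fraction <= 0.02

    def test_g0_release_before_and_after_s_entry(self):
        timepoints = (0.0, 6.0, 18.0)
        for tp, bound, cmp in ((6.0, 0.02, "le"), (18.0, 0.10, "gt")):
            ev = make_events("bj_g0_release", timepoint=tp, n_cells=10_000, seed=51,
                             timepoints=timepoints)
            gates = define_gates(ev, DnaPeaks(200.0, 400.0))
            frac = fraction_s_phase(ev, gates).fraction
            assert (frac <= bound) if cmp == "le" else (frac > bound), (tp, frac)

    def test_balanced_mixture_recovered(self):
        rng = np.random.default_rng(8)
        n = 10_000
        s_dna = 2 * (1 + rng.uniform(0.2, 0.7, n)) * 100  # mid-S cells, inside the band
        ev = events_frame(dna_area=np.concatenate([200 * rng.lognormal(0, 0.03, n), s_dna]))
        gates = define_gates(ev, DnaPeaks(200.0, 400.0))
        res = fraction_s_phase(ev, gates)
        tol = 3 * np.sqrt(0.25 / (2 * n))
        assert abs(res.fraction - 0.5) < tol
        assert res.ci[0] < res.fraction < res.ci[1]
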