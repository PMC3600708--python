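"""Synthetic-data generator: genotypes, stutter model, trace rendering."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import msatpipe as mp
from msatpipe.simulate import MONO_MODAL_TRUTH, stutter_series, truth_lattice


class TestSampleGenotype:
    def test_degenerate_frequency_gives_homozygote(self, panel):
        freqs = mp.default_frequencies(panel)
        freqs["D2S123"] = {211.0: 1.0}
        g = mp.sample_genotype(panel, freqs, rng=0)
        assert g.alleles["D2S123"] == (211.0, 211.0)

    def test_seed_determinism(self, panel):
        a = mp.sample_genotype(panel, rng=42)
        b = mp.sample_genotype(panel, rng=42)
        assert a.alleles == b.alleles

    def test_heterozygosity_matches_binomial_oracle(self, panel):
        # two alleles at p = 0.5 each: P(het) = 2 * 0.5 * 0.5 = 0.5
        panel = mp.PanelConfig(name="one", markers=[panel.marker("D2S123")],
                               params=panel.params, ladder=panel.ladder)
        freqs = {"D2S123": {211.0: 0.5, 215.0: 0.5}}
        rng = np.random.default_rng(1)
        n = 10_000
        het = 0
        for _ in range(n):
            a, b = mp.sample_genotype(panel, freqs, rng).alleles["D2S123"]
            het += a != b
        assert abs(het / n - 0.5) < 0.02

    def test_mono_markers_quasimonomorphic(self, panel):
        rng = np.random.default_rng(2)
        modal = 0
        n = 500
        for _ in range(n):
            g = mp.sample_genotype(panel, rng=rng)
            modal += g.alleles["BAT26"] == (121.0, 121.0)
        assert modal / n > 0.9  # modal allele probability 0.98 per chromosome

    def test_alleles_lie_on_marker_lattice(self, panel):
        g = mp.sample_genotype(panel, rng=3)
        for m in panel.markers:
            lattice = truth_lattice(m)
            for a in g.alleles[m.name]:
                assert a in lattice

    def test_empty_frequency_table_errors(self, panel):
        with pytest.raises(ValueError, match="no allele frequencies"):
            mp.sample_genotype(panel, {m.name: {} for m in panel.markers}, rng=0)


class TestFamily:
    def test_homozygous_parents_give_obligate_heterozygotes(self, panel):
        freqs = mp.default_frequencies(panel)
        p1 = mp.sample_genotype(panel, {k: {min(v): 1.0} for k, v in
                                        {m: list(f) for m, f in freqs.items()}.items()},
                                rng=0, subject="P1")
        p2 = mp.sample_genotype(panel, {k: {max(v): 1.0} for k, v in
                                        {m: list(f) for m, f in freqs.items()}.items()},
                                rng=0, subject="P2")
        kids = mp.make_family(p1, p2, n_children=3, rng=1)
        for child in kids:
            for m in panel.marker_names:
                a, b = sorted((p1.alleles[m][0], p2.alleles[m][0]))
                assert child.alleles[m] == (a, b)

    def test_children_draw_from_parental_alleles(self, panel):
        rng = np.random.default_rng(5)
        p1 = mp.sample_genotype(panel, rng=rng, subject="P1")
        p2 = mp.sample_genotype(panel, rng=rng, subject="P2")
        for child in mp.make_family(p1, p2, n_children=5, rng=rng):
            for m in panel.marker_names:
                pool = set(p1.alleles[m]) | set(p2.alleles[m])
                assert set(child.alleles[m]) <= pool

    def test_twins_identical_at_all_markers(self, panel):
        rng = np.random.default_rng(6)
        p1 = mp.sample_genotype(panel, rng=rng, subject="P1")
        p2 = mp.sample_genotype(panel, rng=rng, subject="P2")
        kids = mp.make_family(p1, p2, n_children=2, twins=True, rng=rng)
        assert kids[0].alleles == kids[1].alleles
        assert kids[0].subject != kids[1].subject


class TestApplyMsi:
    def test_zero_shift_identity(self, panel):
        g = mp.control_genotype(panel)
        shifted = mp.apply_msi(g, panel, "BAT26", 0)
        assert shifted.alleles == g.alleles

    def test_bat26_contraction(self, panel):
        g = mp.control_genotype(panel)
        g.alleles["BAT26"] = (122.0, 122.0)
        shifted = mp.apply_msi(g, panel, "BAT26", -5)
        assert shifted.alleles["BAT26"] == (117.0, 122.0)
        assert g.alleles["BAT26"] == (122.0, 122.0)  # input untouched

    def test_out_of_window_shift_flagged_but_applied(self, panel):
        g = mp.control_genotype(panel)
        shifted = mp.apply_msi(g, panel, "BAT26", -30)
        assert any("msi-out-of-window" in f for f in shifted.flags)
        assert min(shifted.alleles["BAT26"]) == 91.0


class TestStutterSeries:
    def test_geometric_ladder_oracle(self):
        series = stutter_series(150.0, 1000.0, unit=2, adjacent_ratio=0.5,
                                adenylation_fraction=0.0)
        sizes = {s: h for s, h, _ in series}
        assert sizes[150.0] == 1000.0
        assert sizes[148.0] == 500.0
        assert sizes[146.0] == 250.0
        assert sizes[144.0] == 125.0
        assert min(sizes.values()) >= 0.01 * 1000.0  # truncated below 1%

    def test_full_adenylation_shifts_plus_one(self):
        series = stutter_series(150.0, 1000.0, unit=2, adjacent_ratio=0.5,
                                adenylation_fraction=1.0)
        assert all(s % 2 == 1 for s, _, _ in series)  # 151, 149, ...
        assert dict((s, h) for s, h, _ in series)[151.0] == 1000.0

    def test_half_adenylation_splits_equally(self):
        series = stutter_series(150.0, 1000.0, unit=2, adjacent_ratio=0.0001,
                                adenylation_fraction=0.5)
        main = {s: h for s, h, kind in series if kind == "allele"}
        assert main == {151.0: 500.0, 150.0: 500.0}

    def test_amplicon_peaks_respect_marker_dyes(self, panel):
        g = mp.control_genotype(panel)
        peaks = mp.amplicon_peaks(g, panel, rng=0, group=1)
        dyes = {panel.marker(p.marker).dye for p in peaks}
        assert dyes <= {"FAM", "HEX", "NED"}
        assert all(p.marker in {m.name for m in panel.group_markers(1)}
                   for p in peaks)


class TestMobility:
    @given(st.floats(min_value=35, max_value=499))
    def test_strictly_increasing(self, L):
        mob = mp.MobilityModel()
        assert mob.scan(L + 1.0) > mob.scan(L)

    @given(st.floats(min_value=35, max_value=500))
    def test_invertible(self, L):
        mob = mp.MobilityModel()
        assert mob.size(mob.scan(L)) == pytest.approx(L, abs=1e-9)

    def test_decreasing_parameterization_rejected(self):
        with pytest.raises(ValueError):
            mp.MobilityModel(c=1.0e6)


class TestRenderTrace:
    def test_seed_determinism(self, panel, nominal_conditions):
        g = mp.control_genotype(panel)
        t1, d1 = mp.simulate_run(g, panel, 1, run=nominal_conditions, rng=11)
        t2, d2 = mp.simulate_run(g, panel, 1, run=nominal_conditions, rng=11)
        for ch in t1.channels:
            assert np.array_equal(t1.channels[ch], t2.channels[ch])
        assert d1.equals(d2)

    def test_no_bleed_keeps_fam_pure(self, panel, clean_conditions):
        g = mp.control_genotype(panel)
        peaks = [p for p in mp.amplicon_peaks(g, panel, rng=0, group=1)
                 if p.dye == "HEX"]
        trace, _ = mp.render_trace(peaks, mp.MobilityModel(), clean_conditions,
                                   panel.ladder, rng=0)
        assert trace.channels["FAM"].max() < 1.0
        assert trace.channels["HEX"].max() > 500.0

    def test_bleed_coefficient_scales_artifact(self, panel, clean_conditions):
        from dataclasses import replace

        run = replace(clean_conditions, bleed=0.1)
        peaks = [mp.simulate.IdealPeak("HEX", "BAT26", 121.0, 2000.0, "allele")]
        trace, truth = mp.render_trace(peaks, mp.MobilityModel(), run,
                                       panel.ladder, rng=0)
        apex = int(round(truth[truth.kind == "allele"].apex_scan.iloc[0]))
        assert trace.channels["FAM"][apex] == pytest.approx(200.0, rel=0.01)
        bleed_rows = truth[truth.kind == "bleed"]
        assert len(bleed_rows) == 1
        assert bleed_rows.height.iloc[0] == pytest.approx(200.0)

    def test_ladder_only_render_has_exact_fragment_count(self, panel,
                                                          clean_conditions):
        trace, truth = mp.render_trace([], mp.MobilityModel(), clean_conditions,
                                       panel.ladder, rng=0)
        det = mp.detect_peaks(trace, panel.params, 1)
        assert len(det["ROX"]) == len(panel.ladder.sizes)
        assert len(truth[truth.kind == "ladder"]) == len(panel.ladder.sizes)
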