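"""Allele calling: binning, range filters, stutter and mono cut-off rules."""

import numpy as np
import pytest
from hypothesis import assume, given, strategies as st

import msatpipe as mp
from msatpipe.calling import (
    BinSet,
    assign_bin,
    call_dinucleotide,
    call_mono,
    bins_from_observations,
    range_filter,
)
from msatpipe.sizing import SizedPeak


def sized(channel, size, height):
    return SizedPeak(channel, 0.0, height, 5.0, 100.0, size, "local_southern", True)


@pytest.fixture()
def di_marker(panel):
    return panel.marker("D18S61")  # window 145-180, repeat 2


@pytest.fixture()
def di_bins():
    return BinSet("D18S61", tuple(range(146, 179, 2)))


class TestAssignBin:
    def test_within_offset(self):
        bins = BinSet("X", tuple(range(118, 131)), max_offset=0.5)
        assert assign_bin(122.4, bins) == 122

    def test_outside_offset_none(self):
        bins = BinSet("X", (122,), max_offset=0.5)
        assert assign_bin(122.6, bins) is None
        assert assign_bin(121.3, bins) is None

    def test_exact_tie_breaks_low(self):
        bins = BinSet("X", tuple(range(118, 131)), max_offset=0.5)
        assert assign_bin(122.5, bins) == 122

    @given(
        st.integers(min_value=60, max_value=120),
        st.floats(min_value=-0.49, max_value=0.49),
    )
    def test_stable_under_small_perturbation(self, center_idx, offset):
        bins = BinSet("X", tuple(range(100, 241, 2)), max_offset=0.5)
        center = bins.centers[min(center_idx - 50, len(bins.centers) - 1)]
        size = center + offset
        label = assign_bin(size, bins)
        assert label == center
        # any perturbation staying within the remaining slack keeps the label
        slack = 0.5 - abs(size - center)
        eps = slack * 0.9
        assert assign_bin(size + eps, bins) == label
        assert assign_bin(size - eps, bins) == label


class TestRangeFilter:
    def test_excludes_peaks_inside_filter_interval(self, panel):
        # group 1 FAM exclusion band is 146-194, between Bat25 and D3S3623
        peaks = [sized("FAM", 170.0, 900.0), sized("FAM", 130.0, 800.0),
                 sized("FAM", 210.0, 700.0)]
        kept = range_filter(peaks, panel.params, 1)
        assert [p.size_bp for p in kept] == [130.0, 210.0]

    def test_boundaries_closed(self, panel):
        peaks = [sized("FAM", 146.0, 500.0), sized("FAM", 194.0, 500.0),
                 sized("FAM", 145.9, 500.0), sized("FAM", 194.1, 500.0)]
        kept = range_filter(peaks, panel.params, 1)
        assert [p.size_bp for p in kept] == [145.9, 194.1]

    def test_other_dyes_unaffected(self, panel):
        # 180 bp is inside the FAM band (146-194) but outside NED's (116-174)
        peaks = [sized("NED", 180.0, 500.0)]
        kept = range_filter(peaks, panel.params, 1)
        assert len(kept) == 1

    def test_empty_input(self, panel):
        assert range_filter([], panel.params, 1) == []

    def test_unsized_peaks_pass_through(self, panel):
        p = SizedPeak("FAM", 5000.0, 400.0, 5.0, 90.0, None, "local_southern",
                      False)
        assert range_filter([p], panel.params, 1) == [p]


class TestCallDinucleotide:
    def test_stutter_ladder_called_homozygous(self, di_marker, di_bins):
        peaks = [sized("FAM", 150.0, 1000.0), sized("FAM", 148.0, 500.0),
                 sized("FAM", 146.0, 250.0)]
        calls, _ = call_dinucleotide(peaks, di_marker, di_bins)
        assert [c.bin for c in calls] == [150]
        assert calls[0].ratio == 1.0

    def test_close_heterozygote_retained(self, di_marker, di_bins):
        peaks = [sized("FAM", 150.0, 1000.0), sized("FAM", 148.0, 900.0)]
        calls, _ = call_dinucleotide(peaks, di_marker, di_bins)
        assert sorted(c.bin for c in calls) == [148, 150]

    def test_never_more_than_two_alleles(self, di_marker, di_bins):
        peaks = [sized("FAM", s, h) for s, h in
                 [(150.0, 1000.0), (154.0, 950.0), (158.0, 900.0),
                  (162.0, 850.0)]]
        calls, flags = call_dinucleotide(peaks, di_marker, di_bins)
        assert len(calls) == 2
        assert "nonspecific-interference" in flags

    def test_no_peaks_is_no_call(self, di_marker, di_bins):
        calls, flags = call_dinucleotide([], di_marker, di_bins)
        assert calls == [] and "no-call" in flags

    def test_unbinned_survivors_dropped(self, di_marker, di_bins):
        calls, flags = call_dinucleotide([sized("FAM", 151.0, 800.0)],
                                         di_marker, di_bins)
        assert calls == [] and "no-call" in flags


class TestCallMono:
    def setup_method(self):
        self.bins = BinSet("BAT26", tuple(range(105, 136)))

    def marker(self, panel):
        return panel.marker("BAT26")

    def test_stutter_below_cutoff_single_allele(self, panel):
        peaks = [sized("HEX", 122.0, 1000.0), sized("HEX", 121.0, 800.0),
                 sized("HEX", 120.0, 300.0)]
        calls, _ = call_mono(peaks, self.marker(panel), self.bins, 0.95)
        assert [c.bin for c in calls] == [122]

    def test_above_cutoff_two_alleles(self, panel):
        peaks = [sized("HEX", 122.0, 1000.0), sized("HEX", 121.0, 980.0)]
        calls, _ = call_mono(peaks, self.marker(panel), self.bins, 0.95)
        assert [c.bin for c in calls] == [122, 121]
        assert calls[0].ratio == 1.0

    def test_boundary_ratio_not_called(self, panel):
        """Exactly 95% of the maximum is not an additional allele (strict >)."""
        peaks = [sized("HEX", 122.0, 1000.0), sized("HEX", 121.0, 950.0)]
        calls, _ = call_mono(peaks, self.marker(panel), self.bins, 0.95)
        assert [c.bin for c in calls] == [122]

    def test_height_tie_breaks_to_smaller_size(self, panel):
        peaks = [sized("HEX", 122.0, 1000.0), sized("HEX", 121.0, 1000.0)]
        calls, _ = call_mono(peaks, self.marker(panel), self.bins, 0.95)
        assert calls[0].bin == 121 and calls[0].ratio == 1.0

    def test_any_in_window_peak_yields_a_call(self, panel):
        calls, _ = call_mono([sized("HEX", 117.3, 60.0)], self.marker(panel),
                             self.bins, 0.95)
        assert len(calls) == 1 and calls[0].ratio == 1.0


class TestBinsFromObservations:
    def test_seeded_bins_match_default_lattice(self, panel):
        """Bins seeded from clean reference observations reproduce the
        adenylation-shifted default lattice."""
        g = mp.control_genotype(panel)
        obs = {
            m: [a + 1 + e for a in pair for e in (-0.05, 0.0, 0.08)]
            for m, pair in g.alleles.items()
        }
        seeded = bins_from_observations(obs, panel)
        for m in panel.markers:
            assert set(seeded[m.name].centers) >= set(panel.bins[m.name].centers)
            # identical parity / spacing
            assert (seeded[m.name].centers[0] - panel.bins[m.name].centers[0]) \
                % m.repeat_unit == 0


class TestGenotypeRun:
    def test_flat_trace_gives_run_level_no_call(self, panel):
        n = 3000
        trace = mp.Trace(
            scans=np.arange(n),
            channels={c: np.zeros(n) for c in ("FAM", "HEX", "NED", "ROX")},
        )
        prof = mp.genotype_run(trace, panel, 1)
        assert all(calls == [] for calls in prof.calls.values())
        assert all("ladder-failure" in f for f in prof.flags.values())

    def test_clean_sample_profile_equals_truth(self, panel, clean_conditions):
        rng = np.random.default_rng(9)
        g = mp.sample_genotype(panel, rng=rng, subject="S0")
        for group in (1, 2):
            trace, _ = mp.simulate_run(g, panel, group, run=clean_conditions,
                                       rng=rng)
            prof = mp.genotype_run(trace, panel, group)
            exp = g.expected_bins()
            for m in panel.group_markers(group):
                if m.repeat_unit == 2:
                    assert prof.genotype_bins(m.name) == exp[m.name]
                else:
                    allele1 = prof.calls[m.name][0].bin  # rank 1 = tallest
                    assert any(allele1 - e in (0, 1) for e in exp[m.name])

    def test_bleed_replicas_excluded_from_fam_calls(self, panel):
        """HEX bleed-through inside the FAM exclusion band never reaches
        FAM marker calls (the D6S262-into-FAM scenario)."""
        from dataclasses import replace

        rng = np.random.default_rng(10)
        g = mp.control_genotype(panel)
        run = replace(mp.RunConditions(), bleed=0.15, spike_rate=0.0,
                      nonspecific_rate=0.0)
        trace, truth = mp.simulate_run(g, panel, 1, run=run, rng=rng)
        prof = mp.genotype_run(trace, panel, 1, run_id="bleed")
        exp = g.expected_bins()
        assert prof.genotype_bins("D3S3623") == exp["D3S3623"]
        assert prof.genotype_bins("BAT25")[0] in (127, 128)
        # the bleed artifacts really are present in the FAM channel region
        bleed = truth[(truth.kind == "bleed") & (truth.marker == "D6S262")]
        assert len(bleed) > 0
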