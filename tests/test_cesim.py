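"""Simulator: migration map, lane construction, mixing, cohorts."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msipcr.cesim import (
    CaseTruth,
    GelModel,
    IHCErrorModel,
    LaneDistortion,
    migration_to_size,
    simulate_case,
    simulate_cohort,
    simulate_dilution_series,
    simulate_lane,
    size_to_migration,
)
from msipcr.panel import MarkerSpec, validate_panel


class TestMigrationMap:
    def test_anchor_self_consistency(self):
        # the 15 and 1000 bp anchors sit at the canonical anchor positions
        assert size_to_migration(15.0) == pytest.approx(100.0)
        assert size_to_migration(1000.0) == pytest.approx(900.0)

    def test_log_linear_midpoint(self):
        # geometric mean of the anchors maps to the arithmetic midpoint
        mid = math.sqrt(15.0 * 1000.0)
        assert size_to_migration(mid) == pytest.approx(500.0, abs=1e-9)

    @given(
        size=st.floats(1.0, 1200.0),
        scale=st.floats(0.9, 1.1),
        offset=st.floats(-20.0, 20.0),
    )
    def test_round_trip_and_monotone(self, size, scale, offset):
        d = LaneDistortion(scale, offset)
        m = size_to_migration(size, d)
        assert migration_to_size(m, d) == pytest.approx(size, rel=1e-12)
        if size * 1.01 <= 1200.0:
            assert size_to_migration(size * 1.01, d) > m

    @pytest.mark.parametrize("bad", [0.0, -3.0, 0.5, 1300.0])
    def test_out_of_range_size_rejected(self, bad):
        with pytest.raises(ValueError):
            size_to_migration(bad)


class TestSimulateLane:
    def test_clean_lane_has_exactly_seven_maxima(self, panel, germline_alleles):
        gel = GelModel("screening", 6.0, 0.0, stutter_steps=0)
        tr = simulate_lane(panel, germline_alleles, gel, seed=0, lane_id="a")
        s = tr.signal
        interior = (s[1:-1] > s[:-2]) & (s[1:-1] > s[2:])
        assert int(interior.sum()) == 7  # 5 markers + 2 anchors

    def test_deterministic_given_seed(self, panel, germline_alleles, gel_screening):
        a = simulate_lane(panel, germline_alleles, gel_screening, seed=5, lane_id="x")
        b = simulate_lane(panel, germline_alleles, gel_screening, seed=5, lane_id="x")
        assert np.array_equal(a.signal, b.signal)
        c = simulate_lane(panel, germline_alleles, gel_screening, seed=6, lane_id="x")
        assert not np.array_equal(a.signal, c.signal)

    def test_separated_tumor_alleles_are_bimodal(self, panel):
        # two equal-weight Gaussians are bimodal iff separated by > 2 sigma:
        # a 13 bp deletion clears 2 sigma on the screening gel (sigma 6)
        gel = GelModel("screening", 6.0, 0.0, stutter_steps=0)
        spec = panel[1]  # NR-21, germline 120
        alleles = {
            spec.name: [
                (float(spec.germline_size), 0.5),
                (float(spec.germline_size - 13), 0.5),
            ]
        }
        tr = simulate_lane([spec], alleles, gel, seed=0, lane_id="b")
        lo = size_to_migration(spec.window[0])
        hi = size_to_migration(spec.window[1])
        sel = (tr.migration > lo) & (tr.migration < hi)
        s = tr.signal[sel]
        maxima = int(((s[1:-1] > s[:-2]) & (s[1:-1] > s[2:])).sum())
        assert maxima == 2

    def test_allele_outside_window_rejected(self, panel, gel_screening):
        with pytest.raises(ValueError, match="outside window"):
            simulate_lane(panel, {"NR-21": [(150.0, 1.0)]}, gel_screening, seed=0)

    def test_amounts_must_sum_to_one(self, panel, gel_screening):
        with pytest.raises(ValueError, match="sum"):
            simulate_lane(panel, {"NR-21": [(120.0, 0.7)]}, gel_screening, seed=0)

    def test_mixture_conservation_in_tumor_fraction(self, panel):
        # total band-family area of a marker (in bp domain) does not depend
        # on how the material splits between germline and deleted alleles
        gel = GelModel("highres", 0.75, 0.0)  # stutter on, no noise
        spec = panel[1]
        areas = []
        for f in (0.0, 0.25, 0.5, 0.9, 1.0):
            alleles = {spec.name: []}
            if f < 1:
                alleles[spec.name].append((120.0, 1.0 - f))
            if f > 0:
                alleles[spec.name].append((108.0, f))
            tr = simulate_lane([spec], alleles, gel, seed=0, lane_id=f"f{f}")
            size = np.asarray(migration_to_size(tr.migration))
            sel = (size >= spec.window[0]) & (size < spec.window[1])
            areas.append(np.trapezoid(tr.signal[sel], size[sel]))
        assert np.ptp(areas) / np.mean(areas) < 1e-3


class TestSimulateCase:
    def test_mss_case_has_identical_expected_peaks(self, panel):
        gel = GelModel("screening", 6.0, 0.0)
        truth = CaseTruth("c", frozenset(), {}, 0.7)
        normal, tumor = simulate_case(truth, gel, seed=0, specs=panel, distort=False)
        assert np.allclose(normal.signal, tumor.signal)

    def test_unstable_marker_mixes_at_tumor_fraction(self, panel):
        gel = GelModel("highres", 0.75, 0.0, stutter_steps=0)
        truth = CaseTruth("c", frozenset({"NR-21"}), {"NR-21": 12}, 0.3)
        normal, tumor = simulate_case(truth, gel, seed=0, specs=panel, distort=False)
        m_del = size_to_migration(108.0)
        m_germ = size_to_migration(120.0)
        i_del = int(np.argmin(np.abs(tumor.migration - m_del)))
        i_germ = int(np.argmin(np.abs(tumor.migration - m_germ)))
        assert tumor.signal[i_del] == pytest.approx(300.0, rel=0.05)
        assert tumor.signal[i_germ] == pytest.approx(700.0, rel=0.05)
        assert normal.signal[i_del] < 1.0


class TestDilutionSeries:
    def test_default_layout(self, gel_screening):
        normal, lanes = simulate_dilution_series({"NR-21": 12}, gel=gel_screening, seed=0)
        assert normal.role == "normal"
        assert len(lanes) == 7
        assert [f for f, _ in lanes] == [1.0, 0.5, 0.2, 0.1, 0.075, 0.05, 0.025]

    def test_empty_fractions_rejected(self, gel_screening):
        with pytest.raises(ValueError):
            simulate_dilution_series({"NR-21": 12}, (), gel_screening, seed=0)

    def test_single_fraction_matches_pure_case(self, panel):
        gel = GelModel("screening", 6.0, 0.0)
        _, lanes = simulate_dilution_series(
            {"NR-21": 12}, (1.0,), gel, seed=0, distort=False
        )
        truth = CaseTruth("x", frozenset({"NR-21"}), {"NR-21": 12}, 1.0)
        _, tumor = simulate_case(truth, gel, seed=0, specs=panel, distort=False)
        assert np.allclose(lanes[0][1].signal, tumor.signal)


class TestCohort:
    def test_deterministic(self):
        a = simulate_cohort(10, seed=4)
        b = simulate_cohort(10, seed=4)
        for ca, cb in zip(a, b):
            assert ca.truth == cb.truth
            assert np.array_equal(ca.tumor.signal, cb.tumor.signal)
            assert ca.ihc == cb.ihc

    def test_zero_prevalence_yields_no_msih(self):
        cases = simulate_cohort(40, msi_h_prevalence=0.0, seed=1)
        assert all(c.truth.true_status in ("MSS", "MSI-L") for c in cases)

    def test_ihc_matches_truth_without_error(self):
        cases = simulate_cohort(60, seed=2)
        for c in cases:
            any_loss = "loss" in c.ihc.values()
            assert any_loss == (c.truth.true_status == "MSI-H")

    def test_exact_count_error_model(self):
        em = IHCErrorModel(false_loss_count=4, false_preserved_count=1)
        cases = simulate_cohort(100, seed=3, ihc_error_model=em)
        discordant = sum(
            ("loss" in c.ihc.values()) != (c.truth.true_status == "MSI-H")
            for c in cases
        )
        assert discordant == 5
        # the injected false-loss mode is an isolated MSH6 loss
        false_loss = [
            c
            for c in cases
            if c.truth.true_status != "MSI-H" and "loss" in c.ihc.values()
        ]
        assert all(c.ihc["msh6"] == "loss" and c.ihc["mlh1"] == "preserved"
                   for c in false_loss)


class TestTruthAndPanel:
    @pytest.mark.parametrize(
        "markers,expected",
        [(set(), "MSS"), ({"NR-21"}, "MSI-L"), ({"NR-21", "BAT-26"}, "MSI-H"),
         ({"NR-21", "BAT-26", "BAT-25", "NR-24", "NR-27"}, "MSI-H")],
    )
    def test_truth_status_is_bethesda_of_count(self, markers, expected):
        truth = CaseTruth("c", frozenset(markers), {m: 12 for m in markers}, 0.5)
        assert truth.true_status == expected

    def test_panel_invariants(self, panel):
        validate_panel(panel)  # disjoint windows
        for s in panel:
            assert s.window[0] < s.germline_size < s.window[1]
            assert 15.0 < s.window[0] and s.window[1] < 1000.0

    def test_germline_outside_window_rejected(self):
        with pytest.raises(ValueError):
            MarkerSpec("X", 90, (100.0, 120.0))

    def test_screening_gel_is_coarser(self, gel_screening, gel_highres):
        assert gel_screening.peak_sigma_bp > gel_highres.peak_sigma_bp
        # resolvability (2 sigma) in the instrument classes
        assert 10 <= 2 * gel_screening.peak_sigma_bp <= 15
        assert 1 <= 2 * gel_highres.peak_sigma_bp <= 3
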