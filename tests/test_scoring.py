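"""Aquaculture vector score, weighted protection score, Likert rescaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coastnis import (
    CoverageError,
    FarmRecord,
    ProtectionSegment,
    ValidationError,
    aquaculture_vector,
    likert_rescale,
    local_protection_status,
    weighted_protection,
)


class TestAquacultureVector:
    def test_no_farms_scores_zero(self):
        assert aquaculture_vector([]) == 0.0

    def test_status_weights(self):
        native = [FarmRecord("oyster", 1, n_farms=1, distance_to_site_km=2)]
        invader = [FarmRecord("mussel", 3, n_farms=1, distance_to_site_km=2)]
        assert aquaculture_vector(native) == 1.0
        assert aquaculture_vector(invader) == 3.0

    def test_radius_excludes_distant_farms(self):
        farms = [
            FarmRecord("a", 2, n_farms=3, distance_to_site_km=9.9),
            FarmRecord("b", 3, n_farms=5, distance_to_site_km=10.1),
        ]
        assert aquaculture_vector(farms, radius_km=10) == 6.0

    def test_native_vs_exotic_ratio_matches_survey_cells(self, table1):
        """One native farm vs one exotic farm score 1:2 — exactly the ratio
        of the two nonzero Moorea aquaculture cells in the packaged survey
        (a pearl-oyster exhibition farm vs an imported-shrimp farm)."""
        raw_native = aquaculture_vector([FarmRecord("pearl oyster", 1)])
        raw_exotic = aquaculture_vector([FarmRecord("shrimp", 2)])
        tiki = table1["M-Ti"].aquaculture
        opunohu = table1["M-Op"].aquaculture
        assert raw_exotic / raw_native == pytest.approx(opunohu / tiki)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValidationError):
            FarmRecord("x", 4)

    @given(
        st.lists(
            st.tuples(st.integers(1, 3), st.integers(1, 5), st.floats(0, 9)),
            max_size=10,
        ),
        st.lists(
            st.tuples(st.integers(1, 3), st.integers(1, 5), st.floats(0, 9)),
            max_size=10,
        ),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_additive_over_disjoint_farm_sets(self, spec_a, spec_b):
        mk = lambda spec, tag: [
            FarmRecord(f"{tag}{i}", w, n, d) for i, (w, n, d) in enumerate(spec)
        ]
        a, b = mk(spec_a, "a"), mk(spec_b, "b")
        assert aquaculture_vector(a + b) == pytest.approx(
            aquaculture_vector(a) + aquaculture_vector(b)
        )

    def test_monotone_in_farm_count(self):
        low = [FarmRecord("m", 2, n_farms=2)]
        high = [FarmRecord("m", 2, n_farms=3)]
        assert aquaculture_vector(high) > aquaculture_vector(low)


class TestLocalProtectionStatus:
    @pytest.mark.parametrize(
        "tier, level",
        [
            ("MPA", 5),
            ("national park", 5),
            ("ecological reserve", 3),
            ("regional park", 2),
            ("none", 1),
        ],
    )
    def test_tier_mapping(self, tier, level):
        assert local_protection_status(tier) == level

    def test_unknown_tier_rejected(self):
        with pytest.raises(ValidationError):
            local_protection_status("picnic area")


class TestWeightedProtection:
    def test_worked_ten_km_example(self):
        segs = [
            ProtectionSegment(5, 1.0),
            ProtectionSegment(3, 3.0),
            ProtectionSegment(2, 2.0),
            ProtectionSegment(1, 4.0),
        ]
        assert weighted_protection(segs, 10.0) == pytest.approx(2.2)

    def test_unprotected_baseline_is_one(self):
        assert weighted_protection([ProtectionSegment(1, 10.0)], 10.0) == 1.0

    def test_duration_weighting(self):
        segs = [
            ProtectionSegment(5, 1.0, duration=3.0),
            ProtectionSegment(1, 1.0, duration=0.0),
        ]
        assert weighted_protection(segs, 2.0, include_duration=True) == pytest.approx(7.5)

    def test_coverage_mismatch_rejected(self):
        with pytest.raises(CoverageError):
            weighted_protection([ProtectionSegment(5, 3.0)], 10.0)

    def test_negative_length_rejected(self):
        with pytest.raises(ValidationError):
            ProtectionSegment(5, -1.0)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([1, 2, 3, 5]),
                st.floats(0.1, 5.0),
                st.floats(0, 4),
            ),
            min_size=1,
            max_size=8,
        ),
        st.integers(0, 7),
        st.floats(0.2, 0.8),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_invariant_to_segment_splitting(self, spec, idx, frac):
        segs = [ProtectionSegment(l, km, t) for l, km, t in spec]
        window = sum(s.length_km for s in segs)
        idx %= len(segs)
        s = segs[idx]
        split = (
            segs[:idx]
            + [
                ProtectionSegment(s.level, s.length_km * frac, s.duration),
                ProtectionSegment(s.level, s.length_km * (1 - frac), s.duration),
            ]
            + segs[idx + 1:]
        )
        for dur in (False, True):
            assert weighted_protection(split, window, dur) == pytest.approx(
                weighted_protection(segs, window, dur)
            )

    @given(
        st.lists(
            st.tuples(st.sampled_from([1, 2, 3, 5]), st.floats(0.1, 5.0)),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_bounded_and_monotone_in_level(self, spec):
        segs = [ProtectionSegment(l, km) for l, km in spec]
        window = sum(s.length_km for s in segs)
        score = weighted_protection(segs, window)
        assert 1.0 <= score <= 5.0 + 1e-12
        raised = [ProtectionSegment(5, s.length_km) for s in segs]
        assert weighted_protection(raised, window) >= score - 1e-12


class TestLikertRescale:
    def test_linear_map(self):
        out = likert_rescale([0, 31.5, 63], 0, 5, anchor_zero=True)
        np.testing.assert_allclose(out, [0, 2.5, 5])

    def test_all_zero_vector_maps_to_zero(self):
        np.testing.assert_array_equal(
            likert_rescale([0, 0, 0], anchor_zero=True), [0, 0, 0]
        )

    def test_max_anchored_map_reproduces_survey_aquaculture_cell(self, table1):
        """A single native farm (raw score 1) against a dataset maximum of 63
        lands exactly on the smallest nonzero aquaculture value in the
        packaged survey: 5 x 1/63 = 0.079365079."""
        scaled = likert_rescale([0.0, 1.0, 2.0, 63.0], 0, 5, anchor_zero=True)
        assert scaled[1] == pytest.approx(table1["M-Ti"].aquaculture, abs=1e-9)
        assert scaled[2] == pytest.approx(table1["M-Op"].aquaculture, abs=1e-9)

    def test_minmax_map_hits_both_ends(self):
        out = likert_rescale([2, 4, 10], 1, 5, anchor_zero=False)
        np.testing.assert_allclose(out, [1, 2, 5])

    def test_constant_nonzero_without_anchor_rejected(self):
        with pytest.raises(ValidationError):
            likert_rescale([3, 3, 3], 1, 5, anchor_zero=False)

    @given(
        st.lists(st.floats(0, 1e6), min_size=2, max_size=30).filter(
            lambda v: max(v) > min(v)
        )
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_monotone_in_raw_values(self, raw):
        # non-strict: distinct raw values separated by less than the float
        # resolution of the stretched scale may legitimately collapse
        order = np.argsort(np.asarray(raw), kind="stable")
        for anchor in (True, False):
            out = likert_rescale(raw, 0 if anchor else 1, 5, anchor_zero=anchor)
            assert np.all(np.diff(out[order]) >= -1e-12)
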