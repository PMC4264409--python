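"""Unit and property tests for the cue-redintegration core."""

import io
import math
from itertools import zip_longest

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuemem.features import (
    FeatureVector,
    RetrievalScenario,
    SweepSpec,
    build_sweep_scenario,
    competitor_sweep,
    count_mismatches,
    distance,
    distinctiveness_sweep,
    load_reference_scenarios,
    printed_table,
    read_scenarios,
    sampling_probabilities,
    similarity,
)

FV = FeatureVector.from_string


def oracle_mismatches(probe, candidate):
    """Independent brute force: positional comparison over probe slots."""
    n = 0
    for p_tok, c_tok in zip_longest(
        probe.features, candidate.features[: len(probe)]
    ):
        if p_tok is None:
            break
        if c_tok is None or c_tok != p_tok:
            n += 1
    return n


class TestDistances:
    @pytest.mark.parametrize(
        "probe, cand, mm, d",
        [
            ("C C 2 3 1", "C C 1 2 3", 3, 0.6),
            ("C C 2 3 1", "C C 2 3 1", 0, 0.0),
            # probe slots without a counterpart count as mismatches; the
            # denominator is the probe's length
            ("C C 2 3 1 Q R N", "C C 1 2 3", 6, 0.75),
            ("C C 2 3 1", "C C 3 1 2", 3, 0.6),
        ],
    )
    def test_mismatches_and_distance(self, probe, cand, mm, d):
        assert count_mismatches(FV(probe), FV(cand)) == mm
        assert distance(FV(probe), FV(cand)) == pytest.approx(d)

    def test_candidate_surplus_is_ignored(self):
        """A competitor with extra features beyond the probe's length is no
        less similar: the probe fixes what can mismatch."""
        probe = FV("C X 1 2 3")
        assert distance(probe, FV("C X 4 5 6")) == distance(
            probe, FV("C X 4 5 6 L M")
        )

    @pytest.mark.parametrize(
        "probe, cand, sim2dp",
        [("C C 2 3 1", "C C 1 2 3", 0.55), ("C C 2 3 1 Q R N", "C C 1 2 3", 0.47)],
    )
    def test_similarity_worked_values(self, probe, cand, sim2dp):
        assert round(similarity(FV(probe), FV(cand)), 2) == sim2dp

    def test_identity_similarity_is_one(self):
        assert similarity(FV("C C 2 3 1"), FV("C C 2 3 1")) == 1.0

    @given(
        st.lists(st.sampled_from("abc"), min_size=1, max_size=6),
        st.lists(st.sampled_from("abc"), min_size=1, max_size=6),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_distance_matches_brute_force(self, ptoks, ctoks):
        probe, cand = FeatureVector(ptoks), FeatureVector(ctoks)
        mm = oracle_mismatches(probe, cand)
        assert count_mismatches(probe, cand) == mm
        d = distance(probe, cand)
        assert d == pytest.approx(mm / len(probe))
        assert 0.0 <= d <= 1.0
        assert math.exp(-1) <= similarity(probe, cand) <= 1.0


class TestWildcard:
    def test_mismatch_policy_counts_blurry_slot(self):
        probe, cand = FV("C X ? 2 3"), FV("C X 1 2 3")
        assert count_mismatches(probe, cand) == 1
        assert distance(probe, cand) == pytest.approx(1 / 5)

    def test_exclude_policy_shrinks_denominator(self):
        probe, cand = FV("C X ? 2 3"), FV("C X 1 2 3")
        assert count_mismatches(probe, cand, "exclude") == 0
        assert distance(probe, cand, "exclude") == 0.0
        assert distance(FV("C ? ? ?"), FV("D X Y Z"), "exclude") == 1.0

    def test_all_wildcard_probe_has_no_compared_features(self):
        with pytest.raises(ValueError, match="no compared features"):
            distance(FV("? ?"), FV("a b"), "exclude")

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="wildcard policy"):
            distance(FV("a"), FV("a"), "fuzzy")


class TestValidation:
    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector([])

    def test_empty_token_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(["a", ""])

    def test_wildcard_trace_rejected(self):
        with pytest.raises(ValueError, match="wildcard"):
            RetrievalScenario(FV("a b"), [FV("a ?")], 0)

    def test_bad_target_index(self):
        with pytest.raises(ValueError, match="target_index"):
            RetrievalScenario(FV("a"), [FV("a")], 1)


class TestSampling:
    def test_reference_scenarios_printed_cells(self):
        intact, elaborated = load_reference_scenarios()
        tab = printed_table(intact)
        assert tab["similarity"].tolist() == [0.55, 1.0, 0.55]
        assert tab["probability"].tolist() == [0.26, 0.48, 0.26]
        tab = printed_table(elaborated)
        assert tab["similarity"].tolist() == [0.47, 1.0, 0.47]
        assert tab["probability"].tolist() == [0.24, 0.52, 0.24]

    def test_exact_probabilities_intact_probe(self):
        intact, _ = load_reference_scenarios()
        res = sampling_probabilities(intact)
        assert [round(p, 2) for p in res.probabilities] == [0.26, 0.48, 0.26]
        assert res.target_probability == max(res.probabilities)

    def test_single_trace_normalizes_to_one(self):
        res = sampling_probabilities(RetrievalScenario(FV("a b"), [FV("a c")], 0))
        assert res.probabilities == (1.0,)

    @given(
        st.lists(
            st.lists(st.sampled_from("abcd"), min_size=1, max_size=5),
            min_size=1,
            max_size=6,
        ),
        st.lists(st.sampled_from("abcd"), min_size=1, max_size=5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_probabilities_normalize(self, trace_toks, probe_toks):
        scen = RetrievalScenario(
            FeatureVector(probe_toks),
            [FeatureVector(t) for t in trace_toks],
            0,
        )
        res = sampling_probabilities(scen)
        assert sum(res.probabilities) == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= p <= 1.0 for p in res.probabilities)


class TestSweeps:
    def test_build_sweep_scenario_similarities(self):
        scen = build_sweep_scenario(m=2, u=3, n_competitors=2)
        assert len(scen.probe) == 5
        sims = sampling_probabilities(scen).similarities
        assert sims[0] == 1.0
        for s in sims[1:]:
            assert s == pytest.approx(math.exp(-3 / 5))

    def test_no_unique_features_all_identical(self):
        scen = build_sweep_scenario(m=2, u=0, n_competitors=2)
        assert sampling_probabilities(scen).similarities == (1.0, 1.0, 1.0)
        assert build_sweep_scenario(5, 0, 1).probe  # valid
        assert sampling_probabilities(
            build_sweep_scenario(5, 0, 1)
        ).target_probability == pytest.approx(0.5)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            build_sweep_scenario(0, 0, 2)
        with pytest.raises(ValueError):
            build_sweep_scenario(2, 1, 0)

    def test_equal_similarity_closed_form(self):
        tab = competitor_sweep(m=2, u_values=[0], n_values=range(1, 11))
        for _, row in tab.iterrows():
            assert row.target_probability == pytest.approx(
                1.0 / (row.n_competitors + 1)
            )

    def test_more_competitors_always_hurts(self):
        tab = competitor_sweep(m=2, u_values=range(0, 6), n_values=range(1, 11))
        for _, grp in tab.groupby("u"):
            p = grp.sort_values("n_competitors").target_probability.to_numpy()
            assert (np.diff(p) < 0).all()

    def test_unique_features_monotone_with_diminishing_returns(self):
        spec = SweepSpec(
            m_values=tuple(range(0, 11)),
            u_values=tuple(range(1, 21)),
            n_values=(2, 5),
        )
        tab = distinctiveness_sweep(spec)
        for _, grp in tab.groupby(["m", "n_competitors"]):
            p = grp.sort_values("u").target_probability.to_numpy()
            d1 = np.diff(p)
            assert (d1 >= -1e-12).all()  # adding a unique feature never hurts
            assert (np.diff(d1) <= 1e-12).all()  # and helps less and less

    def test_large_u_two_competitor_asymptote(self):
        scen = build_sweep_scenario(m=2, u=2000, n_competitors=2)
        p = sampling_probabilities(scen).target_probability
        assert p == pytest.approx(1.0 / (1.0 + 2.0 * math.exp(-1)), abs=1e-3)


class TestScenarioIO:
    def test_round_trip(self, tmp_path):
        text = "probe: a b c\ntrace: * a b c\ntrace: a b d\n"
        path = tmp_path / "scen.txt"
        path.write_text(text)
        (scen,) = read_scenarios(path)
        assert scen.probe == FV("a b c")
        assert scen.target_index == 0
        assert len(scen.traces) == 2

    def test_missing_target_marker(self):
        with pytest.raises(ValueError, match="no target"):
            read_scenarios(io.StringIO("probe: a b\ntrace: a b\n"))

    def test_unknown_key_names_line(self):
        with pytest.raises(ValueError, match="line 2"):
            read_scenarios(io.StringIO("probe: a\nitem: a\ntrace: * a\n"))
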