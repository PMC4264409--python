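"""Tests for the synthetic self-paced-reading generator."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cuemem.generate import (
    DATASET_COLUMNS,
    GeneratorParams,
    generate_exp1,
    generate_exp2,
    read_dataset,
    write_dataset,
)

SMALL = dict(n_participants=8, n_items=8, n_fillers=10)


class TestStructure:
    def test_critical_trial_count(self, exp1_default):
        crit = exp1_default[~exp1_default.is_filler]
        assert crit.groupby(["participant", "item"]).ngroups == 52 * 28

    def test_each_participant_sees_each_item_once(self, exp1_default):
        crit = exp1_default[~exp1_default.is_filler]
        per = crit.groupby(["participant", "item"]).condition.nunique()
        assert (per == 1).all()

    def test_latin_square_balance(self, exp1_default):
        crit = exp1_default[~exp1_default.is_filler]
        counts = (
            crit.groupby(["item", "condition"]).participant.nunique().unstack()
        )
        assert counts.shape[1] == 4
        assert ((counts - 52 / 4).abs() <= 1).all().all()

    def test_critical_regions_once_per_trial(self, exp1_default):
        crit = exp1_default[~exp1_default.is_filler]
        for region in ("NP2_head", "NP3_head", "NP3_head+1", "RC_verb", "RC_verb+1"):
            per_trial = (
                crit[crit.region == region]
                .groupby(["participant", "item"])
                .size()
            )
            assert (per_trial == 1).all()
            assert len(per_trial) == 52 * 28

    def test_seed_determinism_byte_identical(self):
        p = GeneratorParams(**SMALL, seed=4)
        a = generate_exp1(p).to_csv(index=False)
        b = generate_exp1(p).to_csv(index=False)
        assert a == b
        c = generate_exp1(GeneratorParams(**SMALL, seed=5)).to_csv(index=False)
        assert a != c

    def test_param_validation(self):
        with pytest.raises(ValueError):
            GeneratorParams(n_participants=0)
        with pytest.raises(ValueError):
            GeneratorParams(sd_residual=-1)
        with pytest.raises(ValueError):
            GeneratorParams(carryover=1.5)


class TestEffects:
    def test_encoding_cost_slows_complex_np2_head(self, exp1_default):
        crit = exp1_default[exp1_default.region == "NP2_head"]
        np2_level = crit.condition.str.split("-").str[1]
        assert (
            crit[np2_level == "complex"].rt_ms.mean()
            > crit[np2_level == "simple"].rt_ms.mean()
        )

    def test_retrieval_benefit_speeds_complex_np2_at_verb(self, exp1_default):
        for region in ("RC_verb", "RC_verb+1"):
            crit = exp1_default[exp1_default.region == region]
            np2_level = crit.condition.str.split("-").str[1]
            assert (
                crit[np2_level == "complex"].rt_ms.mean()
                < crit[np2_level == "simple"].rt_ms.mean()
            )

    def test_null_effects_leave_verb_conditions_equal(self):
        params = GeneratorParams(
            n_participants=24,
            n_items=16,
            n_fillers=10,
            kappa=0.0,
            encoding_cost=0.0,
            contamination_rate=0.0,
            seed=9,
        )
        df = generate_exp1(params)
        verb = df[df.region == "RC_verb"].copy()
        verb["log_rt"] = np.log(verb.rt_ms)
        np2 = verb.condition.str.split("-").str[1]
        t = stats.ttest_ind(
            verb.log_rt[np2 == "complex"], verb.log_rt[np2 == "simple"]
        )
        assert t.pvalue > 0.01

    def test_residual_noise_is_lognormal(self):
        """With every systematic and random effect switched off, log RTs
        are exactly Gaussian around the deterministic structure."""
        params = GeneratorParams(
            n_participants=10,
            n_items=8,
            n_fillers=8,
            kappa=0.0,
            encoding_cost=0.0,
            contamination_rate=0.0,
            sd_participant_intercept=0.0,
            sd_participant_slope=0.0,
            sd_item_intercept=0.0,
            sd_item_slope=0.0,
            overwrite_probability=0.0,
            seed=13,
        )
        df = generate_exp1(params)
        mu = (
            params.mu_log_rt
            + params.beta_length * df.word_length
            + params.beta_logpos * np.log(df.list_position)
        )
        z = (np.log(df.rt_ms) - mu) / params.sd_residual
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_accuracy_rate(self, exp1_default):
        rate = exp1_default.groupby(["participant", "list_position"]).question_correct.first().mean()
        n = exp1_default.groupby(["participant", "list_position"]).ngroups
        assert rate == pytest.approx(0.84, abs=4 * np.sqrt(0.84 * 0.16 / n))


@pytest.fixture(scope="module")
def exp2():
    return generate_exp2(GeneratorParams.exp2(seed=17))


class TestExp2:
    def test_defaults(self, exp2):
        crit = exp2[~exp2.is_filler]
        assert crit.participant.nunique() == 44
        assert crit.item.nunique() == 32
        assert set(crit.condition) == {
            "white-white",
            "white-green",
            "green-white",
            "green-green",
        }

    def test_green_noun_slows_encoding(self, exp2):
        head = exp2[exp2.region == "NP2_head"]
        noun = head.condition.str.split("-").str[0]
        assert (
            head[noun == "green"].rt_ms.mean() > head[noun == "white"].rt_ms.mean()
        )

    def test_green_verb_slows_retrieval_region(self, exp2):
        verb = exp2[exp2.region == "RC_verb"]
        color = verb.condition.str.split("-").str[1]
        assert (
            verb[color == "green"].rt_ms.mean()
            > verb[color == "white"].rt_ms.mean()
        )

    def test_noun_color_inert_at_verb_without_reinstatement(self, exp2):
        verb = exp2[exp2.region == "RC_verb"].copy()
        verb["log_rt"] = np.log(verb.rt_ms)
        noun = verb.condition.str.split("-").str[0]
        t = stats.ttest_ind(
            verb.log_rt[noun == "green"], verb.log_rt[noun == "white"]
        )
        assert t.pvalue > 0.01


class TestRoundTrip:
    def test_write_read_identical(self, tmp_path):
        df = generate_exp1(GeneratorParams(**SMALL, seed=21))
        path = tmp_path / "data.csv"
        write_dataset(df, path)
        back = read_dataset(path)
        pd.testing.assert_frame_equal(df[DATASET_COLUMNS], back)

    def test_missing_column_rejected(self, tmp_path):
        df = generate_exp1(GeneratorParams(**SMALL, seed=21)).drop(columns=["rt_ms"])
        with pytest.raises(ValueError, match="rt_ms"):
            write_dataset(df, tmp_path / "x.csv")
        (tmp_path / "y.csv").write_text("participant,item\n1,2\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_dataset(tmp_path / "y.csv")

    def test_malformed_row_names_line(self):
        good = ",".join(DATASET_COLUMNS)
        bad = io.StringIO(good + "\n" + "1,2,simple-simple,False,1,1,the,3,other,200.0,True,EXTRA,EXTRA\n")
        with pytest.raises(ValueError, match="malformed"):
            read_dataset(bad)
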