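"""Registered statistical plan: summaries, paired tests, RM-ANOVA, power."""

import numpy as np
import pandas as pd
import pytest

from motionmlp.group import (
    PowerSpec,
    belief_report_percent,
    cohens_d,
    hemifield_summary,
    ipsi_contra_diff,
    paired_t_one_tailed,
    power_paired_one_tailed,
    required_n,
    rm_anova_condition,
)
from motionmlp.synthetic import CohortEffects, generate_cohort


def vector_with_moments(mean: float, sem: float, n: int, seed: int = 0) -> np.ndarray:
    """A sample with exactly the requested mean and standard error."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sem * np.sqrt(n) * x


@pytest.fixture()
def cohort():
    return generate_cohort(CohortEffects(seed=17))


class TestSummaries:
    def test_constant_table_has_zero_sem(self):
        table = generate_cohort(CohortEffects(n_participants=6, subject_sd=0, residual_sd=0))
        s = hemifield_summary(table)
        assert (s["sem"] == 0).all()
        assert (s["n"] == 6).all()

    def test_agrees_with_two_pass_oracle(self, cohort):
        s = hemifield_summary(cohort).set_index(["condition", "hemifield"])
        for (cond, hemi), row in s.iterrows():
            vals = cohort.query("condition == @cond and hemifield == @hemi")["threshold"].to_numpy()
            mean = sum(vals) / len(vals)
            sd = np.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
            assert row["mean"] == pytest.approx(mean, abs=1e-12)
            assert row["sem"] == pytest.approx(sd / np.sqrt(len(vals)), abs=1e-12)

    def test_missing_cells_reported(self, cohort):
        broken = cohort[~((cohort.condition == "hMT_sham") & (cohort.hemifield == "ipsilateral"))]
        with pytest.raises(ValueError, match="hMT_sham"):
            hemifield_summary(broken)


class TestDifferences:
    def test_equal_hemifields_give_zero_vector(self):
        table = generate_cohort(CohortEffects(n_participants=6, subject_sd=5, residual_sd=0))
        d = ipsi_contra_diff(table, "hMT_active")
        assert np.allclose(d, 0.0)

    def test_mean_difference_linearity(self, cohort):
        d = ipsi_contra_diff(cohort, "hMT_active")
        s = hemifield_summary(cohort).set_index(["condition", "hemifield"])["mean"]
        assert d.mean() == pytest.approx(
            s[("hMT_active", "ipsilateral")] - s[("hMT_active", "contralateral")], abs=1e-10
        )

    def test_unmatched_participants_rejected(self, cohort):
        broken = cohort.drop(
            cohort[
                (cohort.participant == "P001")
                & (cohort.condition == "hMT_active")
                & (cohort.hemifield == "contralateral")
            ].index
        )
        with pytest.raises(ValueError, match="P001"):
            ipsi_contra_diff(broken, "hMT_active")


class TestPairedT:
    def test_reproduces_reported_statistic(self):
        # mean -1.17, SEM 1.91, n 42 -> t = -0.61, one-tailed p = 0.73
        d = vector_with_moments(-1.17, 1.91, 42)
        res = paired_t_one_tailed(d, "greater")
        assert res.statistic == pytest.approx(-0.61, abs=0.005)
        assert res.df == (41,)
        assert res.p == pytest.approx(0.72, abs=0.01)

    def test_direction_flip_complements_p(self):
        d = vector_with_moments(2.0, 0.8, 20, seed=3)
        pg = paired_t_one_tailed(d, "greater").p
        pl = paired_t_one_tailed(d, "less").p
        assert pg + pl == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            paired_t_one_tailed(np.zeros(10))
        with pytest.raises(ValueError):
            paired_t_one_tailed([1.0])


class TestRMAnova:
    def test_identical_condition_means_give_zero_f(self):
        table = generate_cohort(CohortEffects(n_participants=6, subject_sd=5, residual_sd=0))
        res = rm_anova_condition(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-18)
        assert res.df == (2, 10)

    def test_agrees_with_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        for seed in (1, 2, 3):
            table = generate_cohort(CohortEffects(n_participants=12, seed=seed))
            res = rm_anova_condition(table)
            cell = (
                table.groupby(["participant", "condition"], observed=True)["threshold"]
                .mean()
                .reset_index()
            )
            ref = pingouin.rm_anova(
                data=cell, dv="threshold", within="condition", subject="participant"
            )
            assert res.statistic == pytest.approx(float(ref["F"][0]), abs=1e-8)
            assert res.p == pytest.approx(float(ref["p_unc"][0]), abs=1e-8)

    def test_incomplete_design_rejected(self):
        table = generate_cohort(CohortEffects(n_participants=6, seed=1))
        with pytest.raises(ValueError):
            rm_anova_condition(table[table.condition != "hMT_sham"])


class TestEffectSizeAndPower:
    def test_sampling_plan_effect_size(self):
        assert cohens_d(10.51, 2.59, 14.8) == pytest.approx(0.54, abs=0.005)
        assert cohens_d(5.0, 5.0, 3.0) == 0.0
        assert cohens_d(2.0, 5.0, 3.0) == -cohens_d(5.0, 2.0, 3.0)
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0, 0.0)

    def test_required_n_reproduces_sampling_plan(self):
        d = (10.51 - 2.59) / 14.8
        assert required_n(PowerSpec(d=d, power=0.9, alpha=0.02)) == 42

    def test_power_matches_statsmodels_oracle(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        tt = smp.TTestPower()
        for d, n in [(0.54, 42), (0.3, 80), (1.0, 12)]:
            ref = tt.power(effect_size=d, nobs=n, alpha=0.02, alternative="larger")
            assert power_paired_one_tailed(d, n, alpha=0.02) == pytest.approx(ref, abs=1e-8)

    def test_power_monotone_and_large_effects_need_few_subjects(self):
        d = 0.5351
        powers = [power_paired_one_tailed(d, n, 0.02) for n in range(5, 120)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))
        assert required_n(PowerSpec(d=3.0)) <= 4
        with pytest.raises(ValueError):
            required_n(PowerSpec(d=-0.2))


def test_belief_report_percentages():
    assert belief_report_percent(5, 9) == 36
    assert belief_report_percent(6, 7) == 46
    assert belief_report_percent(0, 13) == 0
    with pytest.raises(ValueError):
        belief_report_percent(0, 0)
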