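"""The synthetic registry generator and its ground-truth oracles."""

import json

import numpy as np
import pandas as pd
import pytest

from mhconsult import (
    PANDEMIC_SPEC,
    PRE_PANDEMIC_SPEC,
    DiagnosisParams,
    EffectWindow,
    SyntheticConfig,
    build_dataset,
    deterministic_mode,
    expected_deviation,
    generate,
    simulate,
    slice_years,
    weekly_counts,
)
from mhconsult.registry_io import read_consultations_frame, read_population_frame
from mhconsult.synthetic import GroundTruth, theoretical_correlation
from mhconsult.weekly import align_weeks

SMALL = dict(n_patients=1500, years=(2017, 2018, 2019), seed=5)


def _single_diag(lambda0=0.2, amplitude=0.0, shape=1.0, persistence=1.0, **kw):
    return SyntheticConfig(
        diagnoses={"P76": DiagnosisParams(lambda0, amplitude, 2.0)},
        holiday_dip_weeks=(),
        frailty_shape=shape,
        persistence=persistence,
        **kw,
    )


def _between_year_r(config, diagnosis="P76", years=(2017, 2018)):
    pop, cons, _ = simulate(config)
    ds = build_dataset(cons, pop, PRE_PANDEMIC_SPEC, "pre_pandemic")
    series = weekly_counts(ds, diagnosis)
    x, y = align_weeks(slice_years(series, years[0]), slice_years(series, years[1]))
    return np.corrcoef(x, y)[0, 1]


class TestGenerate:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        config = SyntheticConfig(n_patients=300, years=(2019, 2020), seed=8)
        p1, c1, _ = generate(config, tmp_path / "a")
        p2, c2, _ = generate(config, tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()
        assert c1.read_bytes() == c2.read_bytes()

    def test_generated_files_pass_registry_validation(self, tmp_path):
        config = SyntheticConfig(n_patients=300, years=(2019, 2020), seed=8)
        pop_path, cons_path, _ = generate(config, tmp_path)
        cons = read_consultations_frame(cons_path)
        pop = read_population_frame(cons_path.parent / "population.csv")
        assert len(pop) == 300
        assert cons["date"].dt.year.isin([2019, 2020]).all()
        assert (tmp_path / "ground_truth.json").exists()
        json.loads((tmp_path / "ground_truth.json").read_text())

    def test_gender_fraction_within_three_binomial_sd(self):
        config = SyntheticConfig(n_patients=10_000, years=(2019,), gender_split=0.62, seed=1)
        pop, _, _ = simulate(config)
        frac = (pop["gender"] == "female").mean()
        assert abs(frac - 0.62) < 3 * np.sqrt(0.62 * 0.38 / 10_000)

    def test_age_groups_span_their_bands(self):
        config = SyntheticConfig(n_patients=5000, years=(2017,), seed=2)
        pop, _, _ = simulate(config)
        age = 2017 - pop["birth_year"]
        assert age.between(18, 65).all()

    def test_no_seasonality_no_heterogeneity_gives_near_zero_correlation(self):
        r = _between_year_r(_single_diag(shape=1e9, amplitude=0.0, **SMALL))
        assert abs(r) < 0.3

    def test_stronger_heterogeneity_raises_between_year_correlation(self):
        rs = []
        for shape in (0.2, 1.0, 5.0):
            vals = [
                _between_year_r(
                    _single_diag(shape=shape, n_patients=1500,
                                 years=(2017, 2018, 2019), seed=seed)
                )
                for seed in range(4)
            ]
            rs.append(np.mean(vals))
        assert rs[0] > rs[1] > rs[2]

    def test_empirical_correlation_matches_theory(self):
        config = _single_diag(
            lambda0=0.1, amplitude=0.3, shape=0.5, persistence=0.9,
            n_patients=4000, years=(2017, 2018, 2019), seed=4,
        )
        theory = theoretical_correlation(config, "P76", 1)
        vals = [
            _between_year_r(
                _single_diag(lambda0=0.1, amplitude=0.3, shape=0.5, persistence=0.9,
                             n_patients=4000, years=(2017, 2018, 2019), seed=seed)
            )
            for seed in range(5)
        ]
        assert abs(np.mean(vals) - theory) < 0.1

    def test_injected_effect_scales_expected_weekly_counts(self):
        effect = EffectWindow("P76", (2020, 11), (2020, 20), 2.0)
        config = SyntheticConfig(
            n_patients=100, years=(2019, 2020), effect_schedule=(effect,), seed=0
        )
        _, _, truth = simulate(config)
        base = SyntheticConfig(n_patients=100, years=(2019, 2020), seed=0)
        _, _, truth0 = simulate(base)
        assert truth.expected_weekly["P76"][(2020, 15)] == pytest.approx(
            2.0 * truth0.expected_weekly["P76"][(2020, 15)]
        )
        assert truth.expected_weekly["P76"][(2020, 25)] == pytest.approx(
            truth0.expected_weekly["P76"][(2020, 25)]
        )

    def test_registration_loss_thins_final_december(self):
        base = SyntheticConfig(n_patients=2000, years=(2020, 2021), seed=6)
        lossy = SyntheticConfig(
            n_patients=2000, years=(2020, 2021), seed=6, registration_loss=0.5
        )
        _, cons_a, _ = simulate(base)
        _, cons_b, _ = simulate(lossy)
        dec = lambda c: int(((c["date"].dt.year == 2021) & (c["date"].dt.month == 12)).sum())
        assert dec(cons_b) < dec(cons_a)
        other = lambda c: int((c["date"].dt.year == 2020).sum())
        assert other(cons_b) == other(cons_a)

    def test_infeasible_config_is_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SyntheticConfig(
                n_patients=10_000_000,
                diagnoses={"P76": DiagnosisParams(100.0)},
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(gender_split=1.2),
            dict(age_group_weights=(0.5, 0.5, 0.5)),
            dict(frailty_shape=0.0),
            dict(persistence=1.5),
            dict(dip_factor=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(n_patients=10, **kwargs)


class TestDeterministicMode:
    def test_identity_ratios_reproduce_the_inclusion_year(self):
        pop, cons, _ = deterministic_mode({})
        ds = build_dataset(cons, pop, PANDEMIC_SPEC, "pandemic")
        series = weekly_counts(ds, "P79")
        y19, y21 = align_weeks(
            slice_years(series, 2019), slice_years(series, 2021)
        )
        np.testing.assert_array_equal(y19, y21)

    @pytest.mark.parametrize("ratio", [0.8, 1.2, 1.5])
    def test_ratio_scales_weekly_counts_exactly(self, ratio):
        pop, cons, _ = deterministic_mode({2020: ratio})
        ds = build_dataset(cons, pop, PANDEMIC_SPEC, "pandemic")
        series = weekly_counts(ds, "P74")
        y19, y20 = align_weeks(
            slice_years(series, 2019), slice_years(series, 2020)
        )
        np.testing.assert_array_equal(y20, ratio * y19)

    def test_non_integer_ratio_products_are_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            deterministic_mode({2020: 1.23})

    def test_every_patient_is_a_member_of_both_cohorts(self):
        pop, cons, _ = deterministic_mode({})
        pre = build_dataset(cons, pop, PRE_PANDEMIC_SPEC, "pre")
        pan = build_dataset(cons, pop, PANDEMIC_SPEC, "pan")
        assert len(pre.cohort_ids) == len(pan.cohort_ids) == len(pop)


class TestExpectedDeviation:
    def test_multiplier_equal_to_r_gives_zero(self):
        assert expected_deviation(0.9, 0.9) == 0.0

    def test_arithmetic_cases(self):
        assert expected_deviation(1.5, 1.0) == pytest.approx(50.0)
        assert expected_deviation(0.8, 1.0) == pytest.approx(20.0)
        # no effect still deviates when r < 1 — structural model property
        assert expected_deviation(1.0, 0.9) == pytest.approx(11.1111, abs=1e-3)

    def test_nonpositive_r_is_an_error(self):
        with pytest.raises(ValueError):
            expected_deviation(1.0, 0.0)

    def test_ground_truth_multiplier_extraction(self):
        effect = EffectWindow("P76", (2020, 11), (2021, 52), 1.5)
        config = SyntheticConfig(n_patients=50, years=(2019, 2020, 2021),
                                 effect_schedule=(effect,), seed=0)
        _, _, truth = simulate(config)
        window = [(2020, w) for w in range(11, 53)] + [(2021, w) for w in range(1, 53)]
        assert truth.constant_multiplier("P76", window) == 1.5
        assert expected_deviation(truth, 1.0, "P76", window) == pytest.approx(50.0)
        mixed = [(2020, 5)] + window
        with pytest.raises(ValueError, match="constant"):
            truth.constant_multiplier("P76", mixed)
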