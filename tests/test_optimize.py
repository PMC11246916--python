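"""Montage evaluation, ranking, per-model optima and sensitivity scenarios."""

import numpy as np
import pandas as pd
import pytest

from tdcsphere.montage import MontageSpec
from tdcsphere.optimize import (
    MontageEvaluation,
    SensitivityScenario,
    SolverSettings,
    default_scenarios,
    evaluate_montage,
    per_model_optima,
    rank_montages,
    sensitivity_analysis,
)
from tdcsphere.phantom import PopulationSpec, conductivity_table, default_head_spec, sample_population

MONTAGES = [MontageSpec("FCz", "POz"), MontageSpec("Cz", "Extracephalic")]
SETTINGS = SolverSettings(n_surface_points=4000)


@pytest.fixture(scope="module")
def pop3():
    """Three identical phantoms (zero-variance population) at h=4."""
    pop = PopulationSpec(default_head_spec(), n=3, thickness_cv=0.0, size_cv=0.0, seed=11)
    return sample_population(pop, 4.0)


@pytest.fixture(scope="module")
def cache():
    return {}


@pytest.fixture(scope="module")
def evals3(pop3, cache):
    return [evaluate_montage(pop3, m, settings=SETTINGS, cache=cache) for m in MONTAGES]


def _fake_eval(name, averages):
    per = pd.DataFrame(
        {
            "M1_left": averages,
            "M1_right": averages,
            "SMA_left": averages,
            "SMA_right": averages,
            "average": averages,
        },
        index=[f"m{i}" for i in range(len(averages))],
    )
    return MontageEvaluation(MontageSpec(*name.split("-")), per)


def test_zero_variance_population_has_zero_sd(evals3):
    for ev in evals3:
        assert np.allclose(ev.population_sd.to_numpy(), 0.0, atol=1e-12)
        assert not ev.incomplete


def test_population_mean_of_average_consistent(evals3):
    ev = evals3[0]
    roi_means = ev.population_mean[["M1_left", "M1_right", "SMA_left", "SMA_right"]]
    assert ev.population_mean["average"] == pytest.approx(roi_means.mean())


def test_polarity_swap_gives_identical_evaluation(pop3, cache):
    fwd = evaluate_montage(pop3[:1], MontageSpec("FCz", "POz"), settings=SETTINGS, cache=cache)
    rev = evaluate_montage(pop3[:1], MontageSpec("POz", "FCz"), settings=SETTINGS)
    np.testing.assert_allclose(
        fwd.per_model.to_numpy(), rev.per_model.to_numpy(), rtol=1e-6
    )


def test_current_scales_roi_means(pop3, cache):
    base = evaluate_montage(pop3[:1], MontageSpec("FCz", "POz", 2.0), settings=SETTINGS, cache=cache)
    double = evaluate_montage(pop3[:1], MontageSpec("FCz", "POz", 4.0), settings=SETTINGS)
    np.testing.assert_allclose(
        double.per_model.to_numpy(), 2.0 * base.per_model.to_numpy(), rtol=1e-6
    )


def test_rank_montages_orders_and_flags():
    evals = [_fake_eval("Fz-Pz", [0.64]), _fake_eval("FCz-POz", [0.65]), _fake_eval("Cz-Pz", [0.36])]
    ranked = rank_montages(evals)
    assert list(ranked["montage"]) == ["FCz-POz", "Fz-Pz", "Cz-Pz"]
    assert list(ranked["rank"]) == [1, 2, 3]
    assert not ranked["tied"].any()

    tied = rank_montages([_fake_eval("Fz-Pz", [0.5]), _fake_eval("FCz-POz", [0.5])])
    assert list(tied["montage"]) == ["Fz-Pz", "FCz-POz"]  # candidate order kept
    assert tied["tied"].all()


def test_rank_rejects_mixed_populations():
    a = _fake_eval("Fz-Pz", [0.5, 0.6])
    b = _fake_eval("FCz-POz", [0.5])
    with pytest.raises(ValueError, match="population"):
        rank_montages([a, b])


def test_single_montage_ranks_first(evals3):
    ranked = rank_montages(evals3[:1])
    assert len(ranked) == 1 and ranked.loc[0, "rank"] == 1


def test_per_model_optima_partition():
    evals = [
        _fake_eval("FCz-POz", [0.65, 0.60, 0.70, 0.55]),
        _fake_eval("Fz-Pz", [0.64, 0.62, 0.69, 0.58]),
    ]
    counts = per_model_optima(evals)
    assert counts.sum() == 4
    assert counts["FCz-POz"] == 2 and counts["Fz-Pz"] == 2


def test_per_model_optima_zero_variance(evals3, pop3):
    counts = per_model_optima(evals3)
    assert counts.sum() == len(pop3)
    assert (counts > 0).sum() == 1  # identical models agree on one optimum


def test_tie_goes_to_candidate_order():
    evals = [_fake_eval("Fz-Pz", [0.5]), _fake_eval("FCz-POz", [0.5])]
    counts = per_model_optima(evals)
    assert counts["Fz-Pz"] == 1 and counts["FCz-POz"] == 0


def test_identity_scenario_reproduces_baseline(pop3, cache):
    result = sensitivity_analysis(
        pop3[:1],
        MONTAGES,
        scenarios=[
            SensitivityScenario("baseline", ()),
            SensitivityScenario("identity", (("CSF", 1.0),)),
        ],
        settings=SETTINGS,
    )
    base = result["tables"]["baseline"]
    ident = result["tables"]["identity"]
    pd.testing.assert_frame_equal(base, ident)


def test_uniform_doubling_halves_field_preserves_ranking(pop3, cache):
    evals = [
        evaluate_montage(pop3[:1], m, settings=SETTINGS, cache=cache) for m in MONTAGES
    ]
    base = rank_montages(evals)
    table2 = conductivity_table().scaled(2.0)
    evals2 = [
        evaluate_montage(pop3[:1], m, settings=SETTINGS, table=table2) for m in MONTAGES
    ]
    halved = rank_montages(evals2)
    assert list(base["montage"]) == list(halved["montage"])
    np.testing.assert_allclose(
        halved["average_mean"].to_numpy(), 0.5 * base["average_mean"].to_numpy(), rtol=1e-6
    )


def test_bone_perturbation_changes_fields(pop3, cache):
    base = evaluate_montage(pop3[:1], MONTAGES[0], settings=SETTINGS, cache=cache)
    soft = evaluate_montage(
        pop3[:1],
        MONTAGES[0],
        settings=SETTINGS,
        table=conductivity_table().scaled({"compact_bone": 0.5, "spongy_bone": 0.5}),
    )
    assert not np.allclose(base.objective, soft.objective, rtol=1e-4)


def test_rubber_sheet_conductivity_is_immaterial(pop3, cache):
    """With uniform volumetric injection over the rubber sheet, a 10x change
    of the sheet conductivity moves cortical ROI means by well under 1%."""
    base = evaluate_montage(pop3[:1], MONTAGES[0], settings=SETTINGS, cache=cache)
    hard = evaluate_montage(
        pop3[:1],
        MONTAGES[0],
        settings=SETTINGS,
        table=conductivity_table().with_overrides({"rubber_sheet": 1.0}),
    )
    np.testing.assert_allclose(
        hard.per_model.to_numpy(), base.per_model.to_numpy(), rtol=0.01
    )


def test_nonpositive_multiplier_rejected(pop3):
    with pytest.raises(ValueError, match="multiplier"):
        sensitivity_analysis(
            pop3[:1],
            MONTAGES[:1],
            scenarios=[SensitivityScenario("bad", (("CSF", 0.0),))],
            settings=SETTINGS,
        )


def test_default_scenarios_cover_bone_and_csf():
    names = [s.name for s in default_scenarios()]
    assert names == ["baseline", "bone_x0.5", "bone_x1.5", "csf_x0.9", "csf_x1.1"]
    bone = dict(default_scenarios()[1].multipliers)
    assert bone == {"compact_bone": 0.5, "spongy_bone": 0.5}
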