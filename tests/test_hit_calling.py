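"""Error model, threshold calls, and the two-stage confirmation design."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ribiscreen.hit_calling import (
    NullModel,
    build_rearray_plan,
    call_primary_hits,
    confirm_hits,
    fit_null_model,
    pick_center_peak_controls,
    replicate_concordance,
    ReplicateStats,
    select_for_rescreen,
    tail_probability,
    z_score,
)
from ribiscreen.normalization import normalize_screen, normalize_with_controls, strain_values
from ribiscreen.plate_io import filter_wells
from ribiscreen.synthetic_data import (
    GeneratorConfig,
    generate_screen,
    simulate_rearray,
)


def _combined_null_sd(config: GeneratorConfig) -> float:
    return math.hypot(config.well_noise_sd, config.null_bio_sd)


def _screen_values(config):
    wells, truth = generate_screen(config, conditions=("KCl",))
    retained, _ = filter_wells(wells["KCl"])
    ratios, _ = normalize_screen(retained)
    return strain_values(ratios), {t.strain_id: t for t in truth}


# --- replicate concordance -------------------------------------------------


def test_identical_replicates_are_perfectly_concordant():
    rep = {f"s{i}": 0.1 * i for i in range(10)}
    stats = replicate_concordance(rep, rep)
    assert stats.pearson_r == pytest.approx(1.0)
    assert stats.mean_abs_diff == 0.0
    assert stats.n_pairs == 10


def test_constant_shift_gives_exact_mean_difference():
    rep1 = {f"s{i}": 0.1 * i for i in range(10)}
    rep2 = {s: v + 0.29 for s, v in rep1.items()}
    stats = replicate_concordance(rep1, rep2)
    assert stats.pearson_r == pytest.approx(1.0)
    assert stats.mean_abs_diff == pytest.approx(0.29)
    assert stats.sd_diff == pytest.approx(0.0, abs=1e-12)


def test_concordance_needs_three_shared_strains():
    with pytest.raises(ValueError, match="shared"):
        replicate_concordance({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0, "c": 3.0})


# --- null model ------------------------------------------------------------


@pytest.mark.parametrize("estimate, sd", [(0.29, 0.3), (0.26, 0.3), (0.55, 0.6)])
def test_null_model_rounds_estimate_to_one_decimal(estimate, sd):
    model = fit_null_model(estimate)
    assert model.mean == 0.0
    assert model.sd == pytest.approx(sd)


def test_null_model_accepts_replicate_stats():
    stats = ReplicateStats(pearson_r=0.9, mean_abs_diff=0.29, n_pairs=560)
    assert fit_null_model(stats).sd == pytest.approx(0.3)


def test_null_model_rejects_nonpositive_estimate():
    with pytest.raises(ValueError):
        fit_null_model(0.0)
    with pytest.raises(ValueError):
        fit_null_model(-0.3)
    with pytest.raises(ValueError):
        NullModel(0.0, 0.0)


@pytest.mark.parametrize(
    "threshold, sd, expected", [(1.0, 0.3, 3.3), (0.0, 0.3, 0.0), (1.0, 0.5, 2.0)]
)
def test_z_score_examples(threshold, sd, expected):
    assert round(z_score(threshold, NullModel(0.0, sd)), 1) == pytest.approx(expected)


def test_tail_probability_examples():
    model = NullModel(0.0, 0.3)
    # oracle: standard normal upper tail at z = 1/0.3
    expected = float(sps.norm.sf(1.0 / 0.3))
    assert tail_probability(1.0, model) == pytest.approx(expected, rel=1e-12)
    assert tail_probability(1.0, model) < 1e-3
    assert tail_probability(0.0, model) == pytest.approx(0.5)
    assert tail_probability(1e6, model) == pytest.approx(0.0, abs=1e-30)


# --- threshold calls -------------------------------------------------------


def test_primary_calls_are_strict():
    ratios = {"a": 0.2, "b": 1.5, "c": -0.4, "d": 3.0, "e": 1.0}
    assert call_primary_hits(ratios) == {"b", "d"}
    assert select_for_rescreen({"a": 1.2, "b": 1.4}) == {"b"}
    assert select_for_rescreen({}) == set()


@given(
    values=st.dictionaries(
        st.text(min_size=1, max_size=4),
        st.floats(min_value=-5, max_value=5),
        max_size=30,
    ),
    t1=st.floats(min_value=-1, max_value=3),
    dt=st.floats(min_value=0, max_value=2),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_raising_threshold_never_enlarges_called_set(values, t1, dt):
    assert call_primary_hits(values, t1 + dt) <= call_primary_hits(values, t1)


def test_false_positive_count_matches_analytic_tail():
    """On a null-only screen, primary calls at 1.0 are pure false positives;
    their count must match the analytic tail of the combined null SD."""
    config = GeneratorConfig(n_strains=4709, hit_fraction=0.0, seed=101)
    values, _ = _screen_values(config)
    p = float(sps.norm.sf(1.0 / _combined_null_sd(config)))
    n = len(values)
    fp = len(call_primary_hits(values, 1.0))
    assert abs(fp - n * p) <= 3 * math.sqrt(n * p * (1 - p)) + 1


# --- re-array plans --------------------------------------------------------


def test_rearray_plan_spreads_controls():
    plan = build_rearray_plan([f"s{i}" for i in range(200)], [f"c{i}" for i in range(24)],
                              n_per_plate=96, min_controls_per_plate=4)
    assert len(plan.plates) == 3
    for plate in plan.plates:
        n_ctrl = sum(1 for _, role in plate if role == "control_center_peak")
        assert n_ctrl >= 4
        assert len(plate) <= 96
    assert sorted(plan.strains) == sorted(f"s{i}" for i in range(200))


def test_rearray_plan_needs_enough_controls():
    with pytest.raises(ValueError, match="controls"):
        build_rearray_plan([f"s{i}" for i in range(200)], ["c1", "c2"], n_per_plate=96)


def test_center_peak_controls_are_nearest_zero():
    ratios = {"a": 0.01, "b": -0.02, "c": 1.5, "d": 0.3, "e": -0.001}
    assert pick_center_peak_controls(ratios, 2) == ["e", "a"]
    assert pick_center_peak_controls(ratios, 2, exclude={"e"}) == ["a", "b"]


# --- confirmation ----------------------------------------------------------


def test_confirmation_is_strict_on_rescreen_value():
    calls = confirm_hits({"a": 2.0, "b": 1.6}, {"a": 0.5, "b": 1.4})
    by = {c.strain_id: c for c in calls}
    assert not by["a"].confirmed and by["a"].final_class == "not_hit"
    assert by["b"].confirmed


def test_rescreen_strain_missing_from_primary_is_an_error():
    with pytest.raises(ValueError, match="ghost"):
        confirm_hits({"a": 2.0}, {"ghost": 1.5})


def test_confirmation_rate_matches_generator_truth():
    """Confirmation count among selected strains must agree with the
    per-strain normal confirmation probabilities implied by the truth."""
    config = GeneratorConfig(n_strains=960, seed=77)
    values, truth_map = _screen_values(config)
    selected = select_for_rescreen(values, 1.3)
    controls = pick_center_peak_controls(values, 24, exclude=selected)
    plan = build_rearray_plan(selected, controls)
    rescreen_wells = simulate_rearray(truth_map, plan, "KCl", config, seed=500)
    retained, _ = filter_wells(rescreen_wells)
    ratios, _ = normalize_screen(retained, method="controls", control_strain_ids=set(controls))
    rescreen = strain_values(ratios)
    calls = confirm_hits(values, rescreen)
    observed = sum(c.confirmed for c in calls)
    # oracle: P(confirm) = P(true level + fresh noise > 1.0) per strain
    sd = config.well_noise_sd
    probs = [
        float(sps.norm.sf(1.0, loc=truth_map[c.strain_id].true_kcl_level, scale=sd))
        for c in calls
    ]
    expected = sum(probs)
    spread = math.sqrt(sum(p * (1 - p) for p in probs))
    assert abs(observed - expected) <= 3 * spread + 1


def test_two_stage_design_reduces_null_false_positives():
    """Across seeds, requiring selection at 1.3 plus rescreen confirmation at
    1.0 passes strictly fewer null strains than one-shot calling at 1.0."""
    single = two_stage = 0
    for seed in range(15):
        config = GeneratorConfig(n_strains=480, hit_fraction=0.0, seed=900 + seed)
        values, truth_map = _screen_values(config)
        single += len(call_primary_hits(values, 1.0))
        selected = select_for_rescreen(values, 1.3)
        if not selected:
            continue
        controls = pick_center_peak_controls(values, 24, exclude=selected)
        plan = build_rearray_plan(selected, controls)
        wells = simulate_rearray(truth_map, plan, "KCl", config, seed=7000 + seed)
        retained, _ = filter_wells(wells)
        ratios, _ = normalize_screen(
            retained, method="controls", control_strain_ids=set(controls)
        )
        calls = confirm_hits(values, strain_values(ratios))
        two_stage += sum(c.confirmed for c in calls)
    assert single > 0
    assert two_stage < single
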