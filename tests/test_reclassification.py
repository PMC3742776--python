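import dataclasses

import numpy as np
import pytest
from scipy import stats

from mirapanel import (
    GeneratorConfig,
    calibrate_intercept,
    compare_models,
    generate_cohort,
    idi,
    nri_continuous,
)
from mirapanel.errors import DegenerateOutcomeError, InputError
from mirapanel.simulate import TARGET_FLOOR_FRACTION


def _toy_counts():
    """3 events: 2 up, 1 down.  4 nonevents: 3 down, 1 up.  NRI = 5/6."""
    y = np.r_[1, 1, 1, 0, 0, 0, 0]
    p_old = np.full(7, 0.5)
    p_new = np.r_[0.6, 0.7, 0.4, 0.3, 0.2, 0.1, 0.8]
    return p_old, p_new, y


def test_nri_direct_count_oracle():
    p_old, p_new, y = _toy_counts()
    r = nri_continuous(p_old, p_new, y)
    assert r.nri == pytest.approx((2 / 3 - 1 / 3) + (3 / 4 - 1 / 4), abs=1e-12)
    assert r.counts == {
        "n_event": 3, "n_nonevent": 4, "up_e": 2, "down_e": 1, "tie_e": 0,
        "up_ne": 1, "down_ne": 3, "tie_ne": 0,
    }
    # the stored counts reproduce the estimate exactly
    c = r.counts
    assert r.nri == pytest.approx(
        (c["up_e"] - c["down_e"]) / c["n_event"]
        + (c["down_ne"] - c["up_ne"]) / c["n_nonevent"]
    )


def test_nri_maximum_is_two():
    y = np.r_[1, 1, 0, 0]
    r = nri_continuous(np.full(4, 0.5), np.r_[0.9, 0.8, 0.1, 0.2], y)
    assert r.nri == pytest.approx(2.0)


def test_identical_models_all_ties():
    y = np.r_[1, 1, 0, 0]
    p = np.r_[0.7, 0.6, 0.3, 0.2]
    r = nri_continuous(p, p.copy(), y)
    assert r.nri == 0.0 and r.idi == 0.0
    assert r.counts["tie_e"] == 2 and r.counts["tie_ne"] == 2


def test_idi_forced_arithmetic():
    y = np.r_[1, 1, 0, 0]
    r = idi(np.r_[0.6, 0.6, 0.4, 0.4], np.r_[0.8, 0.8, 0.2, 0.2], y)
    assert r.idi == pytest.approx((0.8 - 0.2) - (0.6 - 0.4), abs=1e-12)


def test_idi_equals_discrimination_slope_difference():
    """Brute-force oracle on random vectors: IDI is the Yates-slope change."""
    rng = np.random.default_rng(12)
    y = np.r_[np.ones(8), np.zeros(12)]
    p_old = rng.uniform(0.05, 0.95, 20)
    p_new = rng.uniform(0.05, 0.95, 20)
    slope = lambda p: p[y == 1].mean() - p[y == 0].mean()
    r = idi(p_old, p_new, y)
    assert r.idi == pytest.approx(slope(p_new) - slope(p_old), abs=1e-12)


def test_antisymmetry_under_model_swap():
    rng = np.random.default_rng(4)
    y = np.r_[np.ones(10), np.zeros(10)]
    p_old = rng.uniform(0.1, 0.9, 20)
    p_new = rng.uniform(0.1, 0.9, 20)
    fwd = nri_continuous(p_old, p_new, y)
    rev = nri_continuous(p_new, p_old, y)
    assert fwd.nri == pytest.approx(-rev.nri, abs=1e-12)
    assert fwd.idi == pytest.approx(-rev.idi, abs=1e-12)


def test_label_swap_negates_nri():
    rng = np.random.default_rng(9)
    y = np.r_[np.ones(10), np.zeros(10)]
    p_old = rng.uniform(0.1, 0.9, 20)
    p_new = rng.uniform(0.1, 0.9, 20)
    a = nri_continuous(p_old, p_new, y).nri
    b = nri_continuous(p_old, p_new, 1 - y).nri
    assert a == pytest.approx(-b, abs=1e-12)


def test_nri_depends_only_on_difference_signs():
    rng = np.random.default_rng(2)
    y = np.r_[np.ones(10), np.zeros(10)]
    p_old = rng.uniform(0.2, 0.8, 20)
    p_new = rng.uniform(0.2, 0.8, 20)
    # rescale the movement magnitudes arbitrarily, keeping each sign
    p_new2 = p_old + np.sign(p_new - p_old) * rng.uniform(0.01, 0.1, 20)
    a = nri_continuous(p_old, p_new, y).nri
    b = nri_continuous(p_old, p_new2, y).nri
    assert a == pytest.approx(b, abs=1e-12)


def test_input_validation():
    with pytest.raises(InputError):
        nri_continuous([0.5], [0.5, 0.6], [1, 0])
    with pytest.raises(DegenerateOutcomeError):
        nri_continuous([0.5, 0.6], [0.5, 0.6], [1, 1])


def test_compare_models_empty_subset_is_null(cohort150):
    r = compare_models(cohort150, subset=())
    assert r.nri == 0.0 and r.idi == 0.0


def test_predictive_panel_positive_nri_idi():
    """With genuinely informative markers both measures are positive."""
    cfg = dataclasses.replace(GeneratorConfig(), n=2000)
    for s in range(10):
        c = generate_cohort(cfg, seed=40 + s)
        r = compare_models(c, subset=c.marker_names)
        assert r.nri > 0 and r.idi > 0


def test_nri_z_test_calibrated_for_external_risks():
    """Under the null (risk movements independent of outcome) the nullity
    z-test holds its level when the two risk vectors are given, not refitted."""
    rng = np.random.default_rng(77)
    rej = 0
    reps = 500
    for _ in range(reps):
        y = (rng.random(150) < 0.45).astype(float)
        p_old = rng.uniform(0.2, 0.8, 150)
        p_new = np.clip(p_old + rng.normal(0, 0.05, 150), 0.01, 0.99)
        rej += int(nri_continuous(p_old, p_new, y).nri_p < 0.05)
    tol = 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)
    assert rej / reps <= tol


def test_in_sample_nri_is_anticonservative():
    """Refitting a pure-noise marker inflates the apparent NRI — the very
    optimism the bootstrap validation stage is there to remove."""
    cfg = calibrate_intercept(
        GeneratorConfig(linear_coefficients={
            "ntprobnp": 0.2, "anterior": 0.12, "stemi": 0.10, "prior_mi": 0.08}),
        TARGET_FLOOR_FRACTION,
    )
    rej = 0
    reps = 200
    for s in range(reps):
        c = generate_cohort(cfg, seed=20000 + s)
        rej += int(compare_models(c, subset=("mir_16",)).nri_p < 0.05)
    assert rej / reps > 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)
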