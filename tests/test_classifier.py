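"""VDS kernel contracts, SVM training invariants, baselines and evaluation."""

import numpy as np
import pytest

import vdsmon as vm
from helpers import sequences_from_tracks, sequences_from_videos
from vdsmon.classifier import (
    FixedLengthSVM,
    KernelConfig,
    LabeledSample,
    VDSModel,
    _kernel_matrix,
    _rates,
    baseline_dtw_1nn,
    baseline_svm_fixedvec,
    classify,
    classify_batch,
    decision_value,
    evaluate,
    grid_search,
    load_model,
    resample_sequence,
    save_model,
    train,
    vds_kernel,
    velocity_term,
)
from vdsmon.dtw import dtw_distance
from vdsmon.features import VelocitySequence

RAW = KernelConfig(normalize_inputs="none", normalize_dtw_by_length=False)


def _seq(values):
    return VelocitySequence(np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# velocity term and kernel


def test_velocity_term_examples():
    assert velocity_term(_seq([5, 5]), _seq([5, 5])) == 0.0
    a, b = _seq([10, 10, 10]), _seq([13.0])
    assert velocity_term(a, b) == pytest.approx(9.0)
    assert velocity_term(a, b) == velocity_term(b, a)


def test_velocity_term_rejects_empty():
    with pytest.raises(ValueError):
        velocity_term(_seq([]), _seq([1.0]))


def test_kernel_self_similarity_is_one():
    rng = np.random.default_rng(0)
    for _ in range(10):
        a = _seq(rng.uniform(0, 60, rng.integers(2, 12)))
        assert vds_kernel(a, a, RAW) == pytest.approx(1.0, abs=1e-14)


def test_kernel_symmetry():
    rng = np.random.default_rng(1)
    for _ in range(10):
        a = _seq(rng.uniform(0, 60, rng.integers(2, 12)))
        b = _seq(rng.uniform(0, 60, rng.integers(2, 12)))
        assert abs(vds_kernel(a, b, RAW) - vds_kernel(b, a, RAW)) <= 1e-12


def test_kernel_closed_form_alpha_one():
    # single-element sequences make D = |a - b| exactly; D = 2 sigma^2 -> e^-1
    sigma = 1.5
    cfg = KernelConfig(alpha=1.0, bandwidth=sigma, normalize_inputs="none",
                       normalize_dtw_by_length=False)
    a, b = _seq([0.0]), _seq([2 * sigma**2])
    assert vds_kernel(a, b, cfg) == pytest.approx(np.exp(-1.0))


def test_kernel_alpha_limits_match_pure_terms():
    rng = np.random.default_rng(2)
    for _ in range(10):
        a = _seq(rng.uniform(0, 40, rng.integers(2, 9)))
        b = _seq(rng.uniform(0, 40, rng.integers(2, 9)))
        d = dtw_distance(a, b).distance
        v = velocity_term(a, b)
        k1 = KernelConfig(alpha=1.0, normalize_inputs="none", normalize_dtw_by_length=False)
        k0 = KernelConfig(alpha=0.0, normalize_inputs="none", normalize_dtw_by_length=False)
        assert vds_kernel(a, b, k1) == pytest.approx(np.exp(-d / 2.0))
        assert vds_kernel(a, b, k0) == pytest.approx(np.exp(-v / 2.0))


def test_kernel_decreases_with_dtw_distance():
    # same mean (V fixed at 0), increasingly different shape -> K strictly drops
    base = _seq([10.0, 20.0, 10.0, 20.0])
    wilder = _seq([5.0, 25.0, 5.0, 25.0])
    cfg = KernelConfig(alpha=1.0, normalize_inputs="none")
    k_near = vds_kernel(base, _seq([11.0, 19.0, 11.0, 19.0]), cfg)
    k_far = vds_kernel(base, wilder, cfg)
    assert k_near > k_far


def test_kernel_config_validation():
    with pytest.raises(ValueError):
        KernelConfig(alpha=1.5)
    with pytest.raises(ValueError):
        KernelConfig(bandwidth=0)
    with pytest.raises(ValueError):
        KernelConfig(normalize_inputs="bogus")


# ---------------------------------------------------------------------------
# training


def _toy_separable(n_per_class=5, seed=0, slow=10.0, fast=40.0):
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_per_class):
        samples.append(LabeledSample(_seq(rng.normal(fast, 2.0, 12).clip(0)), +1))
        samples.append(LabeledSample(_seq(rng.normal(slow, 2.0, 12).clip(0)), -1))
    return samples


def test_two_sample_training_separates_the_pair():
    fast, slow = _seq([40.0] * 8), _seq([10.0] * 8)
    samples = [LabeledSample(fast, +1), LabeledSample(slow, -1)]
    model = train(samples, KernelConfig(alpha=0.0, normalize_inputs="none", bandwidth=10.0))
    assert len(model.support_samples) == 2
    assert classify(model, fast) == +1
    assert classify(model, slow) == -1
    assert decision_value(model, fast) > 0 > decision_value(model, slow)


def test_separable_training_reaches_perfect_resubstitution():
    samples = _toy_separable(25, seed=1)
    model = train(samples, KernelConfig(penalty=100.0))
    y = np.array([s.label for s in samples])
    assert np.array_equal(classify_batch(model, [s.sequence for s in samples]), y)


def test_dual_coefficients_satisfy_kkt_equality():
    model = train(_toy_separable(10, seed=2))
    assert abs(model.dual_coefficients.sum()) <= 1e-6  # sum a_i* y_i = 0
    assert np.all(np.abs(model.dual_coefficients) <= model.kernel_config.penalty + 1e-9)
    assert np.all(np.abs(model.dual_coefficients) > 0)


def test_decision_value_two_computations_agree():
    samples = _toy_separable(8, seed=3)
    model = train(samples)
    query = _seq(np.linspace(5, 45, 10))
    via_support = decision_value(model, query)

    # independent route: full-Gram row over every training sample with a
    # coefficient vector that is zero off the support set
    coef_by_id = {id(s): c for s, c in zip(model.support_samples, model.dual_coefficients)}
    coef = np.array([coef_by_id.get(id(s), 0.0) for s in samples])
    row = np.array([vds_kernel(s.sequence, query, model.kernel_config,
                               stats=model.velocity_summary_stats) for s in samples])
    via_full = float(coef @ row + model.bias)
    assert abs(via_support - via_full) <= 1e-9


def test_training_rejects_single_class_and_degenerate_sets():
    ones = [LabeledSample(_seq([1, 2, 3]), +1), LabeledSample(_seq([2, 3, 4]), +1)]
    with pytest.raises(ValueError, match="both classes"):
        train(ones)
    same = [LabeledSample(_seq([1, 2, 3]), +1), LabeledSample(_seq([1, 2, 3]), -1)]
    with pytest.raises(ValueError, match="identical"):
        train(same)
    with pytest.raises(ValueError):
        train([LabeledSample(_seq([1, 2]), +1)])


def test_untrained_model_rejected():
    model = VDSModel([], np.array([]), 0.0, KernelConfig(), None, False, 0)
    with pytest.raises(ValueError, match="support"):
        classify(model, _seq([1, 2, 3]))


def test_gram_matrix_not_repaired_on_typical_data():
    model = train(_toy_separable(10, seed=4))
    assert model.gram_repaired is False


def test_model_roundtrips_through_json(tmp_path):
    samples = _toy_separable(6, seed=5)
    model = train(samples)
    path = tmp_path / "model.json"
    save_model(model, path)
    loaded = load_model(path)
    q = _seq(np.linspace(8, 42, 9))
    assert decision_value(loaded, q) == pytest.approx(decision_value(model, q), abs=1e-12)
    assert loaded.gram_repaired == model.gram_repaired
    assert loaded.velocity_summary_stats == pytest.approx(model.velocity_summary_stats)


# ---------------------------------------------------------------------------
# baselines


def test_dtw_1nn_returns_label_of_nearest_template():
    train_set = [LabeledSample(_seq([1, 1, 1]), -1), LabeledSample(_seq([9, 9, 9]), +1)]
    assert baseline_dtw_1nn(train_set, _seq([1, 1, 1])) == -1  # distance 0 wins
    assert baseline_dtw_1nn(train_set, _seq([8, 8, 8])) == +1  # distances 21 vs 3
    single = [LabeledSample(_seq([4, 4]), +1)]
    assert baseline_dtw_1nn(single, _seq([0, 0])) == +1
    with pytest.raises(ValueError):
        baseline_dtw_1nn([], _seq([1]))


def test_resampling_identity_and_constant():
    v = np.array([1.0, 3.0, 2.0, 5.0])
    assert resample_sequence(v, 4) == pytest.approx(v)
    assert resample_sequence(np.full(7, 2.5), 13) == pytest.approx(np.full(13, 2.5))


def test_fixed_vector_svm_fits_separable_data():
    samples = _toy_separable(10, seed=6)
    clf = FixedLengthSVM(penalty=100.0).fit(samples)
    y = np.array([s.label for s in samples])
    assert np.array_equal(clf.predict([s.sequence for s in samples]), y)
    assert baseline_svm_fixedvec(samples, samples[0].sequence, penalty=100.0) == samples[0].label


# ---------------------------------------------------------------------------
# evaluation


def test_detection_rate_arithmetic():
    y = np.array([+1, +1, -1, -1])
    perfect = _rates(y, y)
    assert perfect == {"+1": 1.0, "-1": 1.0, "overall": 1.0}
    flipped = _rates(y, -y)
    assert flipped == {"+1": 0.0, "-1": 0.0, "overall": 0.0}
    majority = _rates(y, np.full(4, +1))
    assert majority == {"+1": 1.0, "-1": 0.0, "overall": 0.5}


def test_evaluate_rejects_oversized_fold_count():
    samples = _toy_separable(3, seed=7)
    with pytest.raises(ValueError, match="fold count"):
        evaluate(samples, methods=("vds",), folds=5)


def test_evaluate_holdout_on_separable_tracks():
    samples = sequences_from_tracks(vm.separable_profiles(), 12, seed=11)
    df = evaluate(samples, folds="holdout", seed=0)
    vds_acc = df[(df["method"] == "vds") & (df["class"] == "overall")]["detection_rate"].iloc[0]
    assert vds_acc == 1.0
    assert set(df["method"]) == {"vds", "dtw_1nn", "svm_fixedvec"}


def test_detection_rate_table_layout():
    pool = sequences_from_tracks(vm.separable_profiles(), 8, seed=12)
    test_set = sequences_from_tracks(vm.separable_profiles(), 4, seed=13)
    df = vm.detection_rate_table(pool, test_set, (4, 8), methods=("vds",))
    assert list(df.index) == [4, 8]
    assert {"vds:+1", "vds:-1", "vds:overall"} <= set(df.columns)
    with pytest.raises(ValueError, match="exceeds"):
        vm.detection_rate_table(pool, test_set, (20,), methods=("vds",))


def test_grid_search_returns_valid_config():
    samples = sequences_from_tracks(vm.separable_profiles(), 6, seed=14)
    cfg, acc = grid_search(samples, alphas=(0.5,), bandwidths=(1.0,), penalties=(10.0,), folds=2)
    assert isinstance(cfg, KernelConfig)
    assert 0.0 <= acc <= 1.0


def test_end_to_end_video_training_resubstitutes_perfectly():
    samples = sequences_from_videos(vm.separable_profiles(), 5, seed=21)
    model = train(samples, KernelConfig(penalty=100.0))
    y = np.array([s.label for s in samples])
    assert np.array_equal(classify_batch(model, [s.sequence for s in samples]), y)
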