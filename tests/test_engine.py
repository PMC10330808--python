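"""Pretraining, adaptation loop mechanics, and ensemble inference."""

import numpy as np
import pytest

from mssfseg.engine import (AdaptationConfig, PretrainConfig, Sample, SourceModelBundle,
                            ablation_config, adapt, evaluate_ensemble, predict_ensemble,
                            pretrain_source)
from mssfseg.model import ModelConfig, SegmentationModel
from mssfseg.phantoms import (DEFAULT_STYLES, MockPredictorSpec, PhantomSpec,
                              apply_domain_style, generate_phantom, mock_probability_map)
from mssfseg.pseudolabel import IGNORE_LABEL, fuse_labels, hard_labels

TINY_MODEL = ModelConfig(hidden=8, sigmas=(1.0, 2.0))


def _domain(spec, style, phantom_seeds, noise_seed0):
    out = []
    for i, s in enumerate(phantom_seeds):
        img, gt, fov = generate_phantom(spec, s)
        img = apply_domain_style(img, style, noise_seed0 + i)
        out.append(Sample(image=img, mask=gt, fov=fov))
    return out


@pytest.fixture(scope="module")
def spec():
    return PhantomSpec(image_size=64, root_width_px=2.5,
                       target_vessel_frac_range=(0.05, 0.15))


@pytest.fixture(scope="module")
def source_samples(spec):
    return _domain(spec, DEFAULT_STYLES["domainA"], range(10), 500)


@pytest.fixture(scope="module")
def trained_model(source_samples):
    cfg = PretrainConfig(epochs=20, seed=3, model=TINY_MODEL)
    model, history = pretrain_source(source_samples, cfg, domain_id="domainA")
    return model, history


def constant_model(c: float) -> SegmentationModel:
    """A segmenter whose output is the constant probability c."""
    model = SegmentationModel(TINY_MODEL, seed=0)
    model.params["W1"][:] = 0.0
    model.params["b1"][:] = 0.0
    model.params["w2"][:] = 0.0
    model.params["b2"][0] = np.log(c / (1 - c))
    return model


class TestPretraining:
    def test_training_reduces_the_loss(self, trained_model):
        _, history = trained_model
        assert history[-1] < history[0]

    def test_deterministic_under_fixed_seed(self, source_samples):
        cfg = PretrainConfig(epochs=3, seed=9, model=TINY_MODEL)
        _, h1 = pretrain_source(source_samples[:4], cfg)
        _, h2 = pretrain_source(source_samples[:4], cfg)
        assert h1 == h2

    def test_source_model_separates_its_own_domain(self, trained_model, spec):
        model, _ = trained_model
        held_out = _domain(spec, DEFAULT_STYLES["domainA"], range(50, 54), 900)
        report, _ = evaluate_ensemble(SourceModelBundle([model], ["domainA"]), held_out)
        assert report.auc > 0.9

    def test_empty_or_unlabeled_dataset_rejected(self, source_samples):
        with pytest.raises(ValueError):
            pretrain_source([], PretrainConfig())
        unlabeled = [Sample(image=source_samples[0].image)]
        with pytest.raises(ValueError):
            pretrain_source(unlabeled, PretrainConfig())


@pytest.fixture(scope="module")
def adaptation_setup(spec, trained_model):
    modelA, _ = trained_model
    domB = _domain(spec, DEFAULT_STYLES["domainB"], range(20, 30), 700)
    modelB, _ = pretrain_source(domB, PretrainConfig(epochs=20, seed=5, model=TINY_MODEL), "domainB")
    bundle = SourceModelBundle([modelA, modelB], ["domainA", "domainB"])
    target = _domain(spec, DEFAULT_STYLES["target"], range(60, 68), 800)
    unlabeled = [Sample(image=s.image, fov=s.fov) for s in target]
    return bundle, unlabeled, target


class TestAdaptation:
    def test_zero_epochs_is_a_bitwise_noop(self, adaptation_setup):
        bundle, unlabeled, _ = adaptation_setup
        cfg = AdaptationConfig(total_epoch=0, seed=1)
        adapted, log = adapt(bundle, unlabeled, cfg)
        for before, after in zip(bundle.models, adapted.models):
            for k in before.params:
                assert np.array_equal(before.params[k], after.params[k])
        assert log.epoch_means == []

    def test_loss_trace_logged_per_epoch_and_iteration(self, adaptation_setup):
        bundle, unlabeled, _ = adaptation_setup
        cfg = AdaptationConfig(total_epoch=2, batch_size=4, seed=2)
        _, log = adapt(bundle, unlabeled, cfg)
        assert len(log.epoch_means) == 2
        assert len(log.rows) == 2 * 2  # 8 images / batch 4
        assert all(np.isfinite(r.loss_total) for r in log.epoch_means)

    def test_outputs_stay_in_open_interval_after_updates(self, adaptation_setup):
        bundle, unlabeled, target = adaptation_setup
        cfg = AdaptationConfig(total_epoch=2, seed=3)
        adapted, _ = adapt(bundle, unlabeled, cfg)
        prob = predict_ensemble(adapted, target[0].image, target[0].fov)
        assert prob.min() > 0.0 and prob.max() < 1.0

    def test_intra_consistency_needs_two_models(self, adaptation_setup):
        bundle, unlabeled, _ = adaptation_setup
        single = SourceModelBundle([bundle.models[0]], ["domainA"])
        with pytest.raises(ValueError):
            adapt(single, unlabeled, AdaptationConfig(use_intra_cc=True))

    def test_baseline_path_runs_and_logs(self, adaptation_setup):
        bundle, unlabeled, _ = adaptation_setup
        cfg = ablation_config("baseline", AdaptationConfig(total_epoch=2, seed=4))
        _, log = adapt(bundle, unlabeled, cfg)
        assert len(log.epoch_means) == 2
        assert all(r.valid_fraction == 1.0 for r in log.epoch_means)

    def test_contradictory_schedules_rejected(self):
        with pytest.raises(ValueError):
            AdaptationConfig(gamma_schedule=(40.0, 80.0))
        with pytest.raises(ValueError):
            AdaptationConfig(beta_schedule=(1.0, 0.0))

    def test_unknown_ablation_name_rejected(self):
        with pytest.raises(ValueError):
            ablation_config("method-z")


class TestPredictEnsemble:
    def test_single_model_is_identity(self, trained_model, source_samples):
        model, _ = trained_model
        s = source_samples[0]
        alone = predict_ensemble(SourceModelBundle([model], ["a"]), s.image, s.fov)
        from mssfseg.augment import normalize_intensity
        assert np.array_equal(alone, model.predict(normalize_intensity(s.image, s.fov)))

    def test_identical_models_average_to_themselves(self, source_samples):
        m = constant_model(0.3)
        bundle = SourceModelBundle([m, m.copy()], ["a", "b"])
        prob = predict_ensemble(bundle, source_samples[0].image)
        assert np.allclose(prob, 0.3)

    def test_two_constant_models_average(self, source_samples):
        bundle = SourceModelBundle([constant_model(0.2), constant_model(0.6)], ["a", "b"])
        prob = predict_ensemble(bundle, source_samples[0].image)
        assert np.allclose(prob, 0.4)


class TestDualConsistencyWithMockPredictors:
    """Analytic properties of agreement filtering, using fabricated predictors."""

    def test_fused_labels_beat_single_model_precision(self, spec):
        _, gt, fov = generate_phantom(PhantomSpec(image_size=256), seed=2)
        region = fov.astype(bool)
        labels = []
        for seed in (10, 11):
            prob = mock_probability_map(gt, MockPredictorSpec(0.2, 0.9, seed))
            labels.append(hard_labels(prob, 0.5))
        fused = fuse_labels(labels)
        pos_f = (fused == 1) & region
        prec_fused = gt[pos_f].mean()
        for lab in labels:
            pos = lab.astype(bool) & region
            assert prec_fused > gt[pos].mean()

    def test_valid_fraction_grows_as_predictors_improve(self):
        gt = (np.random.default_rng(0).random((128, 128)) > 0.9).astype(np.uint8)
        fracs = []
        for flip in (0.3, 0.1, 0.0):
            labels = [hard_labels(mock_probability_map(
                gt, MockPredictorSpec(flip, 0.9, seed)), 0.5) for seed in (1, 2)]
            fused = fuse_labels(labels)
            fracs.append((fused != IGNORE_LABEL).mean())
        assert fracs[0] < fracs[1] < fracs[2] == 1.0
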