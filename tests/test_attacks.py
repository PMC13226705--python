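"""Attack primitives against hand arithmetic and finite-difference oracles."""

import numpy as np
import pytest

from utap.attacks import (
    AttackConfig,
    Perturbation,
    apply_perturbation,
    compute_step_size,
    cosine_similarity,
    cross_entropy_onehot,
    csap_train,
    fgsm,
    psap_train,
    random_tile_mask,
    utap_train,
)

class TestStepSize:
    def test_study_conditions_value(self):
        """alpha(eps=20, theta=10, B=5, L=10, N=900) = 4.35e-4 to printed precision."""
        alpha = compute_step_size(20, 10, 5, 10, 900)
        assert alpha == pytest.approx(1000 / 2_295_000, rel=0, abs=0)
        assert abs(alpha - 4.35e-4) <= 0.01e-4

    def test_zero_bound_gives_zero_step(self):
        assert compute_step_size(0, 10, 5, 10, 900) == 0.0

    def test_formula_identity(self):
        assert compute_step_size(255, 1, 1, 1, 1) == 1.0

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_step_size(20, 10, 5, 0, 900)
        with pytest.raises(ValueError):
            compute_step_size(20, 10, 5, 10, 0)


class TestTileMask:
    def test_mask_geometry_at_study_conditions(self):
        rng = np.random.default_rng(0)
        m = random_tile_mask(130, rng)
        assert m.grid.shape == (16, 16)
        assert m.n_tiles_on == 130
        assert int(m.pixels.sum()) == 130 * 14 * 14 == 25_480
        assert m.pixels.shape == (224, 224)

    def test_empty_and_full_masks(self):
        rng = np.random.default_rng(0)
        assert random_tile_mask(0, rng).pixels.sum() == 0
        full = random_tile_mask(256, rng)
        assert np.all(full.pixels == 1)
        p = np.random.default_rng(1).normal(size=(224, 224, 3)).astype(np.float32)
        assert np.array_equal(p * full.pixels[..., None], p)

    def test_oversized_mask_rejected(self):
        with pytest.raises(ValueError):
            random_tile_mask(257, np.random.default_rng(0))

    def test_fresh_masks_differ_between_draws(self):
        rng = np.random.default_rng(0)
        a, b = random_tile_mask(130, rng), random_tile_mask(130, rng)
        assert not np.array_equal(a.grid, b.grid)


class TestLosses:
    def test_cosine_self_orthogonal_and_hand_value(self):
        f = np.array([0.3, -1.2, 2.0])
        assert cosine_similarity(f, f) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        # 32 / (sqrt(14) * sqrt(77))
        assert cosine_similarity([1, 2, 3], [4, 5, 6]) == pytest.approx(0.974632, abs=1e-6)

    def test_cosine_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_similarity([0, 0], [1, 1])

    def test_ce_uniform_logits_closed_form(self):
        gt = np.eye(9)[4]
        assert cross_entropy_onehot(gt, np.zeros(9)) == pytest.approx(np.log(9), abs=1e-9)
        assert cross_entropy_onehot(gt, np.full(9, 3.7)) == pytest.approx(np.log(9), abs=1e-9)

    def test_ce_binary_closed_form_and_shift_invariance(self):
        val = cross_entropy_onehot(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        assert val == pytest.approx(np.log(1 + np.exp(-1)), abs=1e-9)
        shifted = cross_entropy_onehot(np.array([1.0, 0.0]), np.array([101.0, 100.0]))
        assert shifted == pytest.approx(val, abs=1e-9)

    def test_ce_decreases_with_margin(self):
        gt = np.eye(3)[0]
        vals = [cross_entropy_onehot(gt, np.array([m, 0.0, 0.0])) for m in (0.5, 1, 2, 4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_ce_rejects_non_onehot(self):
        with pytest.raises(ValueError, match="one-hot"):
            cross_entropy_onehot(np.array([0.5, 0.5]), np.zeros(2))


class TestApplyPerturbation:
    def test_zero_perturbation_is_identity(self, toy_patchset):
        p = Perturbation(np.zeros((8, 8, 3), np.float32), epsilon_8bit=20)
        out = apply_perturbation(toy_patchset, p)
        assert np.array_equal(out.images, toy_patchset.images)

    def test_clip_ceiling(self):
        img = np.full((8, 8, 3), 255, np.uint8)
        p = Perturbation(np.full((8, 8, 3), 20 / 255, np.float32), epsilon_8bit=20)
        assert np.all(apply_perturbation(img, p) == 255)

    def test_hand_arithmetic_with_full_mask(self):
        img = np.full((8, 8, 3), 100, np.uint8)
        p = Perturbation(np.full((8, 8, 3), 20 / 255, np.float32), epsilon_8bit=20)
        rng = np.random.default_rng(0)
        mask = random_tile_mask(4, rng, grid_side=2, tile_size=4)
        assert np.all(apply_perturbation(img, p, mask) == 120)

    def test_shape_mismatch_rejected(self):
        p = Perturbation(np.zeros((8, 8, 3), np.float32), epsilon_8bit=20)
        with pytest.raises(ValueError, match="size"):
            apply_perturbation(np.zeros((4, 4, 3), np.uint8), p)


class TestAttackConfig:
    def test_step_count_arithmetic(self):
        cfg = AttackConfig()
        assert cfg.total_steps == 10 * 900 // 5 == 1800

    @pytest.mark.parametrize(
        "bad",
        [dict(batch=10, n_train=5), dict(epochs=0), dict(n_mask=300),
         dict(objective="hinge"), dict(update_rule="adam")],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            AttackConfig(**bad)


def _mini_probe(encoder, patchset):
    """Deterministic little probe over the toy encoder's features."""
    from utap.evaluation import encode_patchset, train_linear_probe

    feats = encode_patchset(encoder, patchset)
    return train_linear_probe(feats, patchset.labels)


class TestUtapTraining:
    def test_single_step_matches_finite_difference_oracle(self, toy_encoder, toy_patchset):
        """One PGD step on the linear toy encoder: p = -alpha*sign(grad)*mask
        with the gradient certified by central finite differences."""
        cfg = AttackConfig(n_train=2, batch=2, epochs=1, n_mask=2, seed=5)
        pert, trace = utap_train(toy_patchset, toy_encoder, cfg)
        assert len(trace) == 1
        # replay the single step's batch and mask draw
        rng = np.random.default_rng(cfg.seed)
        perm = rng.permutation(2)
        mask = random_tile_mask(2, rng, grid_side=2, tile_size=4)
        x01 = toy_patchset.images[:2].astype(np.float64)[perm] / 255.0

        scale = np.asarray(toy_encoder.spec.scale)

        def batch_cos_normalized(p_flat):
            p = p_flat.reshape(8, 8, 3) * mask.pixels[..., None]
            total = 0.0
            mean = np.asarray(toy_encoder.spec.mean)
            for img in x01:
                f_ori = (((img - mean) / scale).reshape(-1) @ toy_encoder.w.astype(np.float64))
                f_atk = ((((img + p) - mean) / scale).reshape(-1) @ toy_encoder.w.astype(np.float64))
                total += float(f_ori @ f_atk / (np.linalg.norm(f_ori) * np.linalg.norm(f_atk)))
            return total / len(x01)

        p0 = np.zeros(8 * 8 * 3)
        fd = np.zeros_like(p0)
        e = 1e-5
        for i in range(len(p0)):
            up, dn = p0.copy(), p0.copy()
            up[i] += e
            dn[i] -= e
            fd[i] = (batch_cos_normalized(up) - batch_cos_normalized(dn)) / (2 * e)
        alpha = compute_step_size(cfg.epsilon_8bit, cfg.theta, cfg.batch,
                                  cfg.epochs, cfg.n_train)
        expected = np.clip(
            -alpha * np.sign(fd.reshape(8, 8, 3)) * mask.pixels[..., None],
            -cfg.epsilon_8bit / 255, cfg.epsilon_8bit / 255,
        )
        decided = np.abs(fd.reshape(8, 8, 3)) > 1e-6
        assert np.allclose(pert.values[decided], expected[decided], atol=1e-7)

    def test_masking_locality(self, toy_encoder, toy_patchset):
        cfg = AttackConfig(n_train=2, batch=2, epochs=1, n_mask=1, seed=5)
        pert, _ = utap_train(toy_patchset, toy_encoder, cfg)
        rng = np.random.default_rng(cfg.seed)
        rng.permutation(2)
        mask = random_tile_mask(1, rng, grid_side=2, tile_size=4)
        outside = mask.pixels == 0
        assert np.all(pert.values[outside] == 0.0)

    def test_bound_conservation_every_step(self, utap_perturbation, attack_config):
        bound = attack_config.epsilon_8bit / 255.0
        trace = utap_perturbation.trace
        assert len(trace) == attack_config.total_steps
        assert max(trace.max_abs_p) <= bound + 1e-7
        assert utap_perturbation.check_bound()

    def test_objective_decreases_from_unity(self, utap_perturbation):
        trace = utap_perturbation.trace
        assert trace.objective[0] == pytest.approx(1.0, abs=1e-5)
        tail = np.mean(trace.objective[-50:])
        assert tail < 0.95

    def test_seeded_reproducibility_bit_identical(self, toy_encoder, toy_patchset):
        cfg = AttackConfig(n_train=8, batch=4, epochs=3, n_mask=2, seed=9)
        p1, t1 = utap_train(toy_patchset, toy_encoder, cfg)
        p2, t2 = utap_train(toy_patchset, toy_encoder, cfg)
        assert np.array_equal(p1.values, p2.values)
        assert t1.objective == t2.objective

    def test_cross_entropy_objective_ascends_probe_loss(self, toy_encoder, toy_patchset):
        """The ablation objective maximizes probe CE (trace stores -CE)."""
        probe = _mini_probe(toy_encoder, toy_patchset)
        cfg = AttackConfig(n_train=12, batch=4, epochs=6, n_mask=3, seed=8,
                           objective="cross_entropy")
        pert, trace = utap_train(toy_patchset, toy_encoder, cfg, probe=probe)
        assert pert.check_bound()
        # smoothed -CE should decrease (CE increases) from start to finish
        first = np.mean(trace.objective[:3])
        last = np.mean(trace.objective[-3:])
        assert last < first

    def test_mid_run_encoder_failure_keeps_partial_trace(self, toy_encoder, toy_patchset):
        class Flaky:
            spec = toy_encoder.spec

            def __init__(self):
                self.calls = 0

            def forward(self, x, want_cache=False):
                # clean-feature caching uses one call; fail on the second step
                self.calls += 1
                if self.calls > 2:
                    raise RuntimeError("encoder died")
                return toy_encoder.forward(x, want_cache)

            def backward(self, *a, **kw):
                return toy_encoder.backward(*a, **kw)

        cfg = AttackConfig(n_train=8, batch=4, epochs=2, n_mask=2, seed=1)
        with pytest.raises(RuntimeError, match="aborted") as excinfo:
            utap_train(toy_patchset, Flaky(), cfg)
        assert len(excinfo.value.partial_trace) == 1

    def test_cross_entropy_objective_requires_probe(self, toy_encoder, toy_patchset):
        cfg = AttackConfig(n_train=12, batch=4, epochs=1, n_mask=3, seed=8,
                           objective="cross_entropy")
        with pytest.raises(ValueError, match="probe"):
            utap_train(toy_patchset, toy_encoder, cfg)

    def test_dataset_too_small_rejected(self, toy_encoder, toy_patchset):
        with pytest.raises(ValueError, match="n_train"):
            utap_train(toy_patchset, toy_encoder, AttackConfig(n_train=100, seed=0))


class TestMultiSourcePool:
    def test_active_encoder_switches_only_on_interval(self, toy_patchset, toy_encoder_factory):
        """With a pool, the active encoder is re-drawn every switch_interval
        steps and stays fixed in between."""
        pool = [toy_encoder_factory(seed=0), toy_encoder_factory(seed=1)]
        cfg = AttackConfig(n_train=12, batch=2, epochs=4, n_mask=2, seed=2,
                           switch_interval=3)
        pert, trace = utap_train(toy_patchset, pool, cfg)
        names = trace.encoder
        assert len(names) == cfg.total_steps
        assert set(names) <= {e.spec.name for e in pool}
        for i in range(len(names)):
            if i % cfg.switch_interval != 0:
                assert names[i] == names[i - 1]
        assert pert.provenance["encoders"] == [e.spec.name for e in pool]


class TestSpecificAttacks:
    def test_psap_ascends_probe_cross_entropy(self, toy_encoder, toy_patchset):
        probe = _mini_probe(toy_encoder, toy_patchset)
        from utap.attacks import _probe_ce_grad_wrt_x01

        img, lab = toy_patchset.images[0], int(toy_patchset.labels[0])
        pert = psap_train(img, lab, toy_encoder, probe, steps=20)
        x01 = img.astype(np.float32)[None] / 255.0
        ce_before, _ = _probe_ce_grad_wrt_x01(toy_encoder, probe, x01, np.array([lab]))
        ce_after, _ = _probe_ce_grad_wrt_x01(
            toy_encoder, probe, x01 + pert.values, np.array([lab])
        )
        assert ce_after >= ce_before
        assert pert.check_bound()

    def test_psap_single_step_matches_finite_differences(self, toy_encoder, toy_patchset):
        probe = _mini_probe(toy_encoder, toy_patchset)
        img, lab = toy_patchset.images[0], int(toy_patchset.labels[0])
        pert = psap_train(img, lab, toy_encoder, probe, steps=1, step_size=0.01)
        x01 = img.astype(np.float64) / 255.0
        w = probe.weights
        mean = np.asarray(toy_encoder.spec.mean)
        scale = np.asarray(toy_encoder.spec.scale)

        def ce(p):
            f = (((x01 + p) - mean) / scale).reshape(-1) @ toy_encoder.w.astype(np.float64)
            logits = f @ w.T + probe.bias
            z = logits - logits.max()
            return float(np.log(np.exp(z).sum()) - z[lab])

        fd = np.zeros((8, 8, 3))
        e = 1e-6
        for i in np.ndindex(8, 8, 3):
            up = np.zeros((8, 8, 3))
            dn = np.zeros((8, 8, 3))
            up[i] += e
            dn[i] -= e
            fd[i] = (ce(up) - ce(dn)) / (2 * e)
        decided = np.abs(fd) > 1e-8
        expected = 0.01 * np.sign(fd)
        assert np.allclose(pert.values[decided], expected[decided], atol=1e-7)

    def test_csap_on_single_image_reduces_to_psap(self, toy_encoder, toy_patchset):
        probe = _mini_probe(toy_encoder, toy_patchset)
        img, lab = toy_patchset.images[1], int(toy_patchset.labels[1])
        p_psap = psap_train(img, lab, toy_encoder, probe, steps=30)
        p_csap = csap_train(img[None], lab, toy_encoder, probe, steps=30, batch=1, seed=0)
        assert np.array_equal(p_psap.values, p_csap.values)

    def test_csap_empty_class_rejected(self, toy_encoder, toy_patchset):
        probe = _mini_probe(toy_encoder, toy_patchset)
        with pytest.raises(ValueError, match="at least one"):
            csap_train(np.zeros((0, 8, 8, 3), np.uint8), 0, toy_encoder, probe)

    def test_fgsm_zero_magnitude_is_identity(self, toy_encoder, toy_patchset):
        probe = _mini_probe(toy_encoder, toy_patchset)
        img = toy_patchset.images[0]
        out = fgsm(img, int(toy_patchset.labels[0]), toy_encoder, probe, 0.0)
        assert np.array_equal(out, img.astype(np.float32) / np.float32(255.0))

    def test_fgsm_sign_structure_and_oracle(self, toy_encoder, toy_patchset):
        """Changed pixels move by exactly +/-magnitude (pre-clip), and the sign
        pattern matches central finite differences on >=99% of non-tied pixels."""
        probe = _mini_probe(toy_encoder, toy_patchset)
        img, lab = toy_patchset.images[2], int(toy_patchset.labels[2])
        mag = 8 / 255.0
        out = fgsm(img, lab, toy_encoder, probe, mag)
        x01 = img.astype(np.float32) / np.float32(255.0)
        delta = out - x01
        unclipped = (out > 0.0) & (out < 1.0)
        moved = np.abs(delta) > 1e-9
        assert np.all(
            np.isclose(np.abs(delta[unclipped & moved]), mag, atol=1e-7)
        )
        mean = np.asarray(toy_encoder.spec.mean)
        scale = np.asarray(toy_encoder.spec.scale)
        w = probe.weights
        x64 = img.astype(np.float64) / 255.0

        def ce(p):
            f = (((x64 + p) - mean) / scale).reshape(-1) @ toy_encoder.w.astype(np.float64)
            logits = f @ w.T + probe.bias
            z = logits - logits.max()
            return float(np.log(np.exp(z).sum()) - z[lab])

        fd = np.zeros((8, 8, 3))
        e = 1e-6
        for i in np.ndindex(8, 8, 3):
            up = np.zeros((8, 8, 3)); dn = np.zeros((8, 8, 3))
            up[i] += e; dn[i] -= e
            fd[i] = (ce(up) - ce(dn)) / (2 * e)
        non_tied = np.abs(fd) > 1e-8
        agree = np.sign(delta[non_tied & unclipped]) == np.sign(fd[non_tied & unclipped])
        assert agree.mean() >= 0.99


class TestSaturation:
    def test_large_theta_drives_values_to_the_bounds(self):
        """With theta=100 most perturbation entries saturate at +/-eps/255."""
        from utap.data import SynthesisConfig, generate_synthetic_patches
        from utap.encoder import build_tiny_vit

        ds = generate_synthetic_patches(
            SynthesisConfig(n_classes=2, per_class=10, image_size=28, seed=2)
        )
        enc = build_tiny_vit(4, input_size=28, feature_dim=48, n_heads=3)
        cfg = AttackConfig(n_train=20, batch=5, epochs=20, n_mask=2, theta=100, seed=6)
        pert, _ = utap_train(ds, enc, cfg)
        bound = cfg.epsilon_8bit / 255.0
        saturated = np.abs(np.abs(pert.values) - bound) <= 1e-6
        assert saturated.mean() >= 0.80
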