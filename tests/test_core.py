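import numpy as np
import pytest

from cglo.core import (ReconstructionTask, SinogramStack, SliceStack,
                       TrainConfig, augment_profiles, check_convergence,
                       pretrain_glo, reconstruct_cglo,
                       simulate_sinogram_stack)
from cglo.decoder import Decoder, DecoderConfig
from cglo.geometry import make_parallel_geometry, radon_forward
from cglo.phantoms import PhantomSpec, generate_phantom_stack


@pytest.fixture(scope="module")
def tiny_task_parts():
    stack = generate_phantom_stack(PhantomSpec(side=32, n_slices=4, seed=2))
    geom = make_parallel_geometry(32, 12)
    sinos = simulate_sinogram_stack(stack, geom)
    return stack, geom, sinos


def tiny_decoder(seed=0):
    return Decoder(DecoderConfig(latent_dim=16, first_channels=32,
                                 out_side=32, seed=seed))


class TestAugmentProfiles:
    def test_factor_one_is_identity(self, tiny_task_parts):
        _, _, sinos = tiny_task_parts
        assert augment_profiles(sinos, 1) is sinos

    def test_midpoint_is_elementwise_mean(self, tiny_task_parts):
        _, _, sinos = tiny_task_parts
        pair = SinogramStack(sinos.sinograms[:2])
        out = augment_profiles(pair, 2)
        assert len(out) == 3
        assert out[1].is_interpolated
        assert np.allclose(out[1].values,
                           0.5 * (out[0].values + out[2].values))

    def test_counts_and_flags_k3_f8(self, tiny_task_parts):
        _, _, sinos = tiny_task_parts
        triple = SinogramStack(sinos.sinograms[:3])
        out = augment_profiles(triple, 8)
        assert len(out) == 3 + 2 * 7
        assert int(out.is_interpolated.sum()) == 14
        # originals preserved in order
        kept = [s for s in out.sinograms if not s.is_interpolated]
        for a, b in zip(kept, triple.sinograms):
            assert np.array_equal(a.values, b.values)

    def test_interpolation_weights(self, tiny_task_parts):
        _, _, sinos = tiny_task_parts
        pair = SinogramStack(sinos.sinograms[:2])
        out = augment_profiles(pair, 4)
        for j in range(1, 4):
            t = j / 4
            expect = (1 - t) * pair[0].values + t * pair[1].values
            assert np.allclose(out[j].values, expect)

    def test_errors(self, tiny_task_parts):
        _, _, sinos = tiny_task_parts
        with pytest.raises(ValueError):
            augment_profiles(sinos, 0)
        single = SinogramStack(sinos.sinograms[:1])
        with pytest.raises(ValueError):
            augment_profiles(single, 2)


class TestCheckConvergence:
    @pytest.mark.parametrize("pair,expected", [
        ((1.00, 0.995), True),   # 0.5% < 1%
        ((1.00, 0.90), False),   # 10% >= 1%
        ((1.00, 0.99), False),   # exactly 1%: strict inequality
    ])
    def test_doubling_rule(self, pair, expected):
        assert check_convergence(*pair) is expected

    def test_nonpositive_losses_rejected(self):
        with pytest.raises(ValueError):
            check_convergence(0.0, 1.0)
        with pytest.raises(ValueError):
            check_convergence(1.0, -2.0)


class TestTrainConfig:
    def test_schedule_must_be_nondecreasing(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_schedule=[(0, 16), (100, 8)])

    def test_default_schedule_doubles_from_eight(self):
        cfg = TrainConfig(n_iterations=1000)
        assert cfg.resolved_schedule() == [(0, 8), (250, 16), (500, 32),
                                           (750, 64)]

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_latent=-1.0)


class TestPretrainGLO:
    def test_memorizes_tiny_slice_set(self):
        """Over-parameterized GLO must fit a tiny slice set to near-zero
        image-domain error (memorization regime)."""
        stack = generate_phantom_stack(PhantomSpec(side=32, n_slices=4,
                                                   seed=3))
        # transposed-conv upsampling: the fastest-fitting generator variant,
        # appropriate here where raw capacity (not the smoothness prior) is
        # under test
        dec = Decoder(DecoderConfig(latent_dim=32, first_channels=128,
                                    out_side=32, seed=0,
                                    upsample_mode="convtranspose"))
        cfg = TrainConfig(lr_latent=1e-3, lr_weights=1e-3, n_iterations=2000,
                          batch_schedule=[(0, 4)], seed=0)
        dec = pretrain_glo(dec, stack, cfg)
        assert dec.pretrain_history_[-1] <= 1e-3

    def test_seeded_determinism(self, tiny_task_parts):
        stack, _, _ = tiny_task_parts
        cfg = TrainConfig(lr_latent=1e-3, lr_weights=1e-3, n_iterations=3,
                          seed=5)
        a = pretrain_glo(tiny_decoder(1), stack, cfg)
        b = pretrain_glo(tiny_decoder(1), stack, cfg)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_shape_mismatch_rejected(self, tiny_task_parts):
        stack, _, _ = tiny_task_parts
        dec = Decoder(DecoderConfig(16, 32, 16, seed=0))
        with pytest.raises(ValueError):
            pretrain_glo(dec, stack, TrainConfig(n_iterations=1))


class TestReconstructCGLO:
    @pytest.fixture(scope="class")
    def short_result(self, tiny_task_parts):
        _, _, sinos = tiny_task_parts
        task = ReconstructionTask(
            sinograms=sinos, decoder_init=tiny_decoder(0),
            interpolation_factor=2,
            config=TrainConfig(lr_latent=1e-2, lr_weights=1e-2,
                               n_iterations=60, seed=0))
        return reconstruct_cglo(task)

    def test_interpolated_entries_discarded(self, tiny_task_parts,
                                            short_result):
        stack, _, _ = tiny_task_parts
        assert len(short_result.slices) == len(stack)

    def test_loss_descends_from_initialization(self, short_result):
        assert short_result.final_loss <= short_result.initial_loss
        assert len(short_result.loss_history) == 60

    def test_latents_remain_on_unit_sphere(self, short_result):
        norms = np.linalg.norm(short_result.latents.vectors, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_seeded_determinism(self, tiny_task_parts):
        _, _, sinos = tiny_task_parts

        def run():
            task = ReconstructionTask(
                sinograms=sinos, decoder_init=tiny_decoder(0),
                interpolation_factor=1,
                config=TrainConfig(lr_latent=1e-2, lr_weights=1e-2,
                                   n_iterations=20, seed=7))
            return reconstruct_cglo(task)

        a, b = run(), run()
        assert np.array_equal(a.slices.slices, b.slices.slices)
        assert np.array_equal(a.latents.vectors, b.latents.vectors)

    def test_decoder_geometry_mismatch_rejected(self, tiny_task_parts):
        _, _, sinos = tiny_task_parts
        task = ReconstructionTask(
            sinograms=sinos,
            decoder_init=Decoder(DecoderConfig(16, 32, 16, seed=0)),
            config=TrainConfig(n_iterations=1))
        with pytest.raises(ValueError):
            reconstruct_cglo(task)


def test_frozen_latents_degenerate_to_single_image_prior_fit():
    """With K = 1, no augmentation and a frozen latent code (zero latent
    learning rate) the joint optimization reduces to a reparameterized
    single-image fit; on an easy 60-view task the data loss must fall at
    least 10x below its initial value."""
    stack = generate_phantom_stack(PhantomSpec(side=32, n_slices=1, seed=6))
    geom = make_parallel_geometry(32, 60)
    sinos = simulate_sinogram_stack(stack, geom)
    task = ReconstructionTask(
        sinograms=sinos,
        decoder_init=Decoder(DecoderConfig(16, 64, 32, seed=0)),
        interpolation_factor=1,
        config=TrainConfig(lr_latent=0.0, lr_weights=1e-2, n_iterations=400,
                           seed=0))
    res = reconstruct_cglo(task)
    assert res.final_loss <= res.initial_loss / 10.0


class TestSinogramStack:
    def test_mixed_geometries_rejected(self, tiny_task_parts):
        _, geom, sinos = tiny_task_parts
        other = make_parallel_geometry(32, 5)
        bad = radon_forward(np.zeros((32, 32)), other)
        with pytest.raises(ValueError):
            SinogramStack([sinos[0], bad])

    def test_per_slice_angle_offsets_allowed(self, tiny_task_parts):
        stack, geom, _ = tiny_task_parts
        rng = np.random.default_rng(0)
        offsets = rng.uniform(0, 180 / geom.n_angles, size=len(stack))
        sinos = simulate_sinogram_stack(stack, geom, offsets)
        assert not sinos.shares_geometry()
        assert len(sinos) == len(stack)
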