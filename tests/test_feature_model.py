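"""Feature extractor: normalization, receptive fields, weights, populations."""

import numpy as np
import pytest

from v2texture.feature_model import (
    ArchitectureSpec,
    LayerSpec,
    PopulationSelector,
    WeightSet,
    extract_population,
    gabor_weight_bank,
    init_weights,
    load_bundled_spec,
    local_response_norm,
    receptive_field_size,
    run_network,
)


def simple_spec(layers):
    return ArchitectureSpec(layers=layers)


class TestLocalResponseNorm:
    def test_zero_input_gives_zero(self):
        np.testing.assert_array_equal(local_response_norm(np.zeros((3, 4, 4))), np.zeros((3, 4, 4)))

    def test_single_channel_scalar_value(self):
        out = local_response_norm(np.ones((1, 1, 1)))
        assert np.isclose(out[0, 0, 0], 1.0 / (2.0 + 1e-4) ** 0.75)

    def test_identity_when_alpha_zero_k_one(self, rng):
        a = np.abs(rng.standard_normal((6, 5, 5)))
        np.testing.assert_allclose(local_response_norm(a, k=1.0, alpha=0.0), a)

    def test_bounded_by_a_over_k_beta(self, rng):
        a = np.abs(rng.standard_normal((8, 6, 6)))
        b = local_response_norm(a, k=2.0, alpha=1e-4, beta=0.75, m=5)
        assert np.all(b >= 0)
        assert np.all(b <= a / 2.0**0.75 + 1e-12)

    def test_channel_edge_clamping_matches_direct_sum(self, rng):
        """The depth window is clamped at channel edges exactly as a direct
        per-channel evaluation prescribes."""
        a = np.abs(rng.standard_normal((7, 3, 3)))
        k, alpha, beta, m = 1.5, 0.3, 0.6, 5
        b = local_response_norm(a, k, alpha, beta, m)
        for i in range(7):
            lo, hi = max(0, i - m // 2), min(6, i + m // 2)
            denom = (k + alpha * np.sum(a[lo : hi + 1] ** 2, axis=0)) ** beta
            np.testing.assert_allclose(b[i], a[i] / denom)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            local_response_norm(-np.ones((2, 2, 2)))


class TestReceptiveFieldSize:
    @pytest.mark.parametrize(
        "spec_name,tap,expected",
        [
            ("alexnet_stride2", "pool1", 15),
            ("alexnet_stride2", "pool2", 39),
            ("alexnet_stride4", "pool2", 67),
            ("vgg16", "pool2", 16),
            ("vgg16", "pool3", 44),
        ],
    )
    def test_bundled_geometries(self, spec_name, tap, expected):
        spec = load_bundled_spec(spec_name)
        side, _ = receptive_field_size(spec, tap)
        assert side == expected

    def test_unknown_tap_raises(self):
        with pytest.raises(KeyError):
            receptive_field_size(load_bundled_spec("vgg16"), "pool99")

    def test_agrees_with_perturbation_oracle(self, rng):
        """RF arithmetic matches the measured input support of a center
        output unit, probed by large single-pixel perturbations through a
        positive-weight network (where influence cannot vanish)."""
        spec = simple_spec(
            [
                LayerSpec(name="c1", kind="conv", n_filters=1, kernel_side=3, stride=1, pad=0, n_input_channels=1),
                LayerSpec(name="r1", kind="relu"),
                LayerSpec(name="p1", kind="maxpool", window=2, stride=2),
                LayerSpec(name="c2", kind="conv", n_filters=1, kernel_side=3, stride=2, pad=0, n_input_channels=1),
            ]
        )
        weights = WeightSet(
            filters={
                "c1": rng.uniform(0.1, 1.0, (1, 1, 3, 3)),
                "c2": rng.uniform(0.1, 1.0, (1, 1, 3, 3)),
            },
            mode="provided",
        )
        side = 21
        base = rng.uniform(0.1, 1.0, (side, side))
        rf, _ = receptive_field_size(spec, "c2")

        out0 = run_network([base], spec, weights, "c2")[0, 0]
        unit = (out0.shape[0] // 2, out0.shape[1] // 2)
        touched = []
        row = side // 2
        for col in range(side):
            img = base.copy()
            img[row, col] += 100.0
            out = run_network([img], spec, weights, "c2")[0, 0]
            if not np.isclose(out[unit], out0[unit]):
                touched.append(col)
        assert max(touched) - min(touched) + 1 == rf


class TestInitWeights:
    def test_random_mode_range_and_reproducibility(self):
        spec = load_bundled_spec("alexnet_stride2")
        a = init_weights(spec, "random", seed=0)
        b = init_weights(spec, "random", seed=0)
        for name in a.filters:
            np.testing.assert_array_equal(a.filters[name], b.filters[name])
            assert np.all(np.abs(a.filters[name]) <= 1.0)

    def test_shuffled_preserves_per_channel_multiset(self, rng):
        spec = simple_spec(
            [LayerSpec(name="c1", kind="conv", n_filters=4, kernel_side=3, stride=1, pad=0, n_input_channels=2)]
        )
        base = WeightSet(filters={"c1": rng.standard_normal((4, 2, 3, 3))}, mode="provided")
        shuffled = init_weights(spec, "shuffled", seed=1, base=base)
        for i in range(4):
            for c in range(2):
                np.testing.assert_array_equal(
                    np.sort(shuffled.filters["c1"][i, c].ravel()),
                    np.sort(base.filters["c1"][i, c].ravel()),
                )

    def test_shuffled_1x1_kernels_identical(self, rng):
        spec = simple_spec(
            [LayerSpec(name="c1", kind="conv", n_filters=3, kernel_side=1, stride=1, pad=0, n_input_channels=2)]
        )
        base = WeightSet(filters={"c1": rng.standard_normal((3, 2, 1, 1))}, mode="provided")
        shuffled = init_weights(spec, "shuffled", seed=0, base=base)
        np.testing.assert_array_equal(shuffled.filters["c1"], base.filters["c1"])

    def test_shuffled_requires_base(self):
        with pytest.raises(ValueError):
            init_weights(load_bundled_spec("vgg16"), "shuffled", seed=0)

    def test_shape_mismatch_rejected(self):
        spec = simple_spec(
            [LayerSpec(name="c1", kind="conv", n_filters=2, kernel_side=3, stride=1, pad=0, n_input_channels=1)]
        )
        bad = WeightSet(filters={"c1": np.zeros((2, 1, 5, 5))}, mode="provided")
        with pytest.raises(ValueError):
            init_weights(spec, "provided", base=bad)

    def test_save_load_roundtrip(self, tmp_path):
        spec = simple_spec(
            [LayerSpec(name="c1", kind="conv", n_filters=2, kernel_side=3, stride=1, pad=0, n_input_channels=1)]
        )
        ws = init_weights(spec, "random", seed=7)
        ws.save(tmp_path / "w.npz")
        back = WeightSet.load(tmp_path / "w.npz")
        np.testing.assert_array_equal(back.filters["c1"], ws.filters["c1"])
        assert back.mode == "random" and back.seed == 7


class TestRunNetwork:
    def test_relu_outputs_nonnegative(self, rng):
        spec = simple_spec(
            [
                LayerSpec(name="c1", kind="conv", n_filters=2, kernel_side=3, stride=1, pad=0, n_input_channels=1),
                LayerSpec(name="r1", kind="relu"),
            ]
        )
        weights = init_weights(spec, "random", seed=0)
        out = run_network([rng.standard_normal((10, 10))], spec, weights, "r1")
        assert np.all(out >= 0)

    def test_identity_conv_reproduces_input(self, rng):
        spec = simple_spec(
            [LayerSpec(name="c1", kind="conv", n_filters=1, kernel_side=1, stride=1, pad=0, n_input_channels=1)]
        )
        weights = WeightSet(filters={"c1": np.ones((1, 1, 1, 1))}, mode="provided")
        img = rng.standard_normal((6, 6))
        out = run_network([img], spec, weights, "c1")
        np.testing.assert_allclose(out[0, 0], img)

    def test_averaging_filter_matches_direct_convolution(self, rng):
        spec = simple_spec(
            [LayerSpec(name="c1", kind="conv", n_filters=1, kernel_side=3, stride=1, pad=0, n_input_channels=1)]
        )
        weights = WeightSet(filters={"c1": np.full((1, 1, 3, 3), 1.0 / 9)}, mode="provided")
        img = rng.standard_normal((8, 8))
        out = run_network([img], spec, weights, "c1")[0, 0]
        direct = np.array(
            [[img[i : i + 3, j : j + 3].mean() for j in range(6)] for i in range(6)]
        )
        np.testing.assert_allclose(out, direct, atol=1e-12)

    def test_constant_image_constant_interior(self):
        spec = simple_spec(
            [LayerSpec(name="c1", kind="conv", n_filters=1, kernel_side=3, stride=1, pad=1, n_input_channels=1)]
        )
        weights = WeightSet(filters={"c1": np.full((1, 1, 3, 3), 1.0 / 9)}, mode="provided")
        out = run_network([np.full((8, 8), 2.0)], spec, weights, "c1")[0, 0]
        np.testing.assert_allclose(out[1:-1, 1:-1], 2.0)

    def test_translation_covariance_on_interior(self, rng):
        spec = simple_spec(
            [
                LayerSpec(name="c1", kind="conv", n_filters=2, kernel_side=3, stride=1, pad=0, n_input_channels=1),
                LayerSpec(name="r1", kind="relu"),
            ]
        )
        weights = init_weights(spec, "random", seed=2)
        img = rng.standard_normal((14, 14))
        shifted = np.roll(img, 1, axis=0)
        a = run_network([img], spec, weights, "r1")[0]
        b = run_network([shifted], spec, weights, "r1")[0]
        np.testing.assert_allclose(b[:, 2:-2, 2:-2], np.roll(a, 1, axis=1)[:, 2:-2, 2:-2], atol=1e-10)

    def test_grayscale_replication_to_three_channels(self, rng):
        spec = simple_spec(
            [LayerSpec(name="c1", kind="conv", n_filters=1, kernel_side=1, stride=1, pad=0, n_input_channels=3)]
        )
        weights = WeightSet(filters={"c1": np.full((1, 3, 1, 1), 1.0 / 3)}, mode="provided")
        img = rng.standard_normal((5, 5))
        out = run_network([img], spec, weights, "c1")
        np.testing.assert_allclose(out[0, 0], img, atol=1e-12)

    def test_vanishing_map_names_layer(self, rng):
        spec = simple_spec(
            [
                LayerSpec(name="c1", kind="conv", n_filters=1, kernel_side=3, stride=1, pad=0, n_input_channels=1),
                LayerSpec(name="p1", kind="maxpool", window=8, stride=2),
            ]
        )
        weights = init_weights(spec, "random", seed=0)
        with pytest.raises(ValueError, match="p1"):
            run_network([rng.standard_normal((6, 6))], spec, weights, "p1")


class TestExtractPopulation:
    def test_counts_filters_times_neighborhood(self, rng):
        maps = rng.standard_normal((3, 128, 6, 6))
        sel = PopulationSelector(filter_indices=tuple(range(128)), spatial_neighborhood=2)
        pop = extract_population(maps, sel)
        assert pop.shape == (512, 3)

    def test_center_pixel_on_odd_map(self, rng):
        maps = rng.standard_normal((2, 4, 5, 5))
        sel = PopulationSelector(filter_indices=(1, 3), spatial_neighborhood=1)
        pop = extract_population(maps, sel)
        np.testing.assert_array_equal(pop[0], maps[:, 1, 2, 2])
        np.testing.assert_array_equal(pop[1], maps[:, 3, 2, 2])

    def test_full_map_neighborhood_takes_all_units(self, rng):
        maps = rng.standard_normal((1, 3, 4, 4))
        sel = PopulationSelector(filter_indices=(0, 1, 2), spatial_neighborhood=4)
        assert extract_population(maps, sel).shape == (48, 1)

    def test_ordering_filter_major_then_row_col(self, rng):
        maps = rng.standard_normal((1, 2, 4, 4))
        sel = PopulationSelector(filter_indices=(0, 1), spatial_neighborhood=2)
        pop = extract_population(maps, sel)[:, 0]
        expected = maps[0][:, 1:3, 1:3].reshape(-1)
        np.testing.assert_array_equal(pop, expected)

    def test_oversized_neighborhood_rejected(self, rng):
        maps = rng.standard_normal((1, 2, 3, 3))
        with pytest.raises(ValueError):
            extract_population(maps, PopulationSelector(filter_indices=(0,), spatial_neighborhood=4))


class TestGaborBank:
    def test_shapes_and_zero_mean(self):
        bank = gabor_weight_bank(orientations=4, frequencies=(0.15,), kernel_side=5)
        assert bank.shape == (16, 1, 5, 5)  # 4 ori x 1 freq x 2 phase x 2 sign
        np.testing.assert_allclose(bank.sum(axis=(2, 3)), 0.0, atol=1e-12)

    def test_signed_pairs_negate(self):
        bank = gabor_weight_bank(orientations=2, frequencies=(0.2,), kernel_side=5)
        np.testing.assert_allclose(bank[0], -bank[1])
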