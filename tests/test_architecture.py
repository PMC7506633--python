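"""Layer-graph construction, shape propagation and the closed-form audit."""

import numpy as np
import pytest

from wavecnn import (
    ArchitectureGraph,
    LayerSpec,
    audit_parameters,
    avg_pool,
    build_architecture,
    forward_shapes,
)
from wavecnn.exceptions import DimensionError, ShapeError

# Reference model summary at num_classes=4, input 512x512x3, width 1:
# every printed (output shape, total parameters) cell.  Batchnorm cells are
# totals (trainable 2C + non-trainable 2C = 4C); norm_4 is the BN(256) row
# implied by relu_4's input and by the 13,440 non-trainable total.
REFERENCE_TABLE = {
    "input": ((512, 512, 3), 0),
    "wavelet": ((256, 256, 12), 0),
    "conv_1": ((256, 256, 64), 6976),
    "norm_1": ((256, 256, 64), 256),
    "relu_1": ((256, 256, 64), 0),
    "conv_1_2": ((128, 128, 64), 36928),
    "conv_a": ((128, 128, 128), 13952),
    "norm_1_2": ((128, 128, 64), 256),
    "norm_a": ((128, 128, 128), 512),
    "relu_1_2": ((128, 128, 64), 0),
    "relu_a": ((128, 128, 128), 0),
    "concate_1": ((128, 128, 192), 0),
    "conv_2": ((128, 128, 128), 221312),
    "conv_b": ((64, 64, 64), 6976),
    "norm_2": ((128, 128, 128), 512),
    "norm_b": ((64, 64, 64), 256),
    "relu_2": ((128, 128, 128), 0),
    "relu_b": ((64, 64, 64), 0),
    "conv_2_2": ((64, 64, 128), 147584),
    "conv_b_2": ((64, 64, 128), 73856),
    "norm_2_2": ((64, 64, 128), 512),
    "norm_b_2": ((64, 64, 128), 512),
    "conv_c": ((32, 32, 256), 27904),
    "relu_2_2": ((64, 64, 128), 0),
    "relu_b_2": ((64, 64, 128), 0),
    "norm_c": ((32, 32, 256), 1024),
    "concate_2": ((64, 64, 256), 0),
    "relu_c": ((32, 32, 256), 0),
    "conv_3": ((64, 64, 256), 590080),
    "conv_c_2": ((32, 32, 256), 590080),
    "norm_3": ((64, 64, 256), 1024),
    "norm_c_2": ((32, 32, 256), 1024),
    "relu_3": ((64, 64, 256), 0),
    "relu_c_2": ((32, 32, 256), 0),
    "conv_3_2": ((32, 32, 256), 590080),
    "conv_c_3": ((32, 32, 256), 590080),
    "norm_3_2": ((32, 32, 256), 1024),
    "norm_c_3": ((32, 32, 256), 1024),
    "relu_3_2": ((32, 32, 256), 0),
    "relu_c_3": ((32, 32, 256), 0),
    "concate_3": ((32, 32, 512), 0),
    "conv_4": ((32, 32, 256), 1179904),
    "norm_4": ((32, 32, 256), 1024),
    "relu_4": ((32, 32, 256), 0),
    "conv_4_2": ((16, 16, 256), 590080),
    "norm_4_2": ((16, 16, 256), 1024),
    "relu_4_2": ((16, 16, 256), 0),
    "conv_5_1": ((16, 16, 128), 295040),
    "norm_5_1": ((16, 16, 128), 512),
    "relu_5_1": ((16, 16, 128), 0),
    "pool_5_1": ((16, 16, 128), 0),
    "flat_5_1": ((32768,), 0),
    "fc_5": ((2048,), 67110912),
    "norm_5": ((2048,), 8192),
    "relu_5": ((2048,), 0),
    "drop_5": ((2048,), 0),
    "fc_6": ((2048,), 4196352),
    "norm_6": ((2048,), 8192),
    "relu_6": ((2048,), 0),
    "drop_6": ((2048,), 0),
    "fc_7": ((4,), 8196),
}

TRAINABLE_TOTAL = 76_289_732
NON_TRAINABLE_TOTAL = 13_440


@pytest.fixture(scope="module")
def default_graph():
    return build_architecture(num_classes=4, input_size=(512, 512, 3))


@pytest.fixture(scope="module")
def default_audit(default_graph):
    return audit_parameters(default_graph)


@pytest.fixture(scope="module")
def default_shapes(default_graph):
    return forward_shapes(default_graph)


class TestDefaultGraph:
    def test_every_reference_shape_cell(self, default_graph, default_shapes):
        for name, (shape, _) in REFERENCE_TABLE.items():
            assert default_shapes[name] == shape, name
        # The summary prints a single "wavelet" row; the other pyramid taps
        # appear only as "wavelet[k]" inputs of their consumers.
        extra = set(default_graph.names) - set(REFERENCE_TABLE)
        assert extra == {"wavelet[1]", "wavelet[2]", "wavelet[3]"}
        for name in extra:
            assert default_shapes[name][2] == 12

    def test_every_reference_parameter_cell(self, default_audit):
        for name, (_, params) in REFERENCE_TABLE.items():
            assert default_audit.layer_total(name) == params, name

    def test_totals(self, default_audit):
        assert default_audit.trainable == TRAINABLE_TOTAL
        assert default_audit.non_trainable == NON_TRAINABLE_TOTAL

    def test_seventeen_batchnorm_layers(self, default_graph):
        assert sum(1 for l in default_graph.layers if l.kind == "batchnorm") == 17

    def test_wavelet_taps_are_parameter_free(self, default_graph, default_audit):
        taps = [l for l in default_graph.layers if l.kind == "wavelet"]
        assert len(taps) == 4
        assert {l.hyper["level"] for l in taps} == {1, 2, 3, 4}
        for l in taps:
            assert default_audit.per_layer[l.name] == (0, 0)

    def test_exactly_three_concatenations(self, default_graph):
        concats = [l.name for l in default_graph.layers if l.kind == "concat"]
        assert concats == ["concate_1", "concate_2", "concate_3"]

    def test_wavelet_taps_feed_their_dedicated_convs(self, default_graph):
        assert default_graph["conv_1"].inputs == ("wavelet",)
        assert default_graph["conv_a"].inputs == ("wavelet[1]",)
        assert default_graph["conv_b"].inputs == ("wavelet[2]",)
        assert default_graph["conv_c"].inputs == ("wavelet[3]",)

    def test_all_convolutions_are_3x3(self, default_graph):
        for l in default_graph.layers:
            if l.kind == "conv":
                assert l.hyper["kernel"] == 3

    def test_only_four_stride2_convolutions(self, default_graph):
        strided = [l.name for l in default_graph.layers
                   if l.kind == "conv" and l.hyper["stride"] == 2]
        assert strided == ["conv_1_2", "conv_2_2", "conv_3_2", "conv_4_2"]


class TestVariants:
    def test_binary_head_parameter_count(self):
        graph = build_architecture(num_classes=2)
        assert audit_parameters(graph).per_layer["fc_7"] == ((2048 + 1) * 2, 0)

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_class_head_scaling(self, k):
        base = audit_parameters(build_architecture(num_classes=4)).trainable
        totals = audit_parameters(build_architecture(num_classes=k)).trainable
        assert totals - base == 2049 * (k - 4)

    def test_flat_size_at_smaller_input(self):
        shapes = forward_shapes(build_architecture(input_size=(256, 256, 3)))
        assert shapes["flat_5_1"] == (8192,)

    def test_width_multiplier_scales_channels(self):
        shapes = forward_shapes(build_architecture(width_multiplier=0.25))
        assert shapes["conv_1"] == (256, 256, 16)
        assert shapes["fc_5"] == (512,)

    def test_fractional_width_rounds_with_warning(self):
        with pytest.warns(UserWarning, match="rounded"):
            build_architecture(width_multiplier=0.3)

    def test_input_not_divisible_by_16_rejected(self):
        with pytest.raises(DimensionError):
            build_architecture(input_size=(100, 100, 3))


class TestGraphValidation:
    def test_concat_spatial_mismatch_names_both_layers(self):
        graph = ArchitectureGraph(
            layers=(
                LayerSpec("input", "input"),
                LayerSpec("wavelet", "wavelet", {"level": 1}, ("input",)),
                LayerSpec("wavelet[1]", "wavelet", {"level": 2}, ("input",)),
                LayerSpec("bad", "concat", {}, ("wavelet", "wavelet[1]")),
            ),
            num_classes=2,
            input_size=(32, 32, 3),
        )
        with pytest.raises(ShapeError, match="wavelet"):
            forward_shapes(graph)

    def test_unknown_kind_rejected_at_construction(self):
        from wavecnn.exceptions import AuditError

        with pytest.raises(AuditError):
            ArchitectureGraph(
                layers=(LayerSpec("x", "maxpool"),), num_classes=2, input_size=(32, 32, 3)
            )

    def test_duplicate_names_rejected(self):
        with pytest.raises(ShapeError):
            ArchitectureGraph(
                layers=(LayerSpec("a", "input"), LayerSpec("a", "input")),
                num_classes=2,
                input_size=(32, 32, 3),
            )


class TestAvgPool:
    def test_block_mean(self):
        assert avg_pool(np.array([[1.0, 2.0], [3.0, 4.0]]), 2, 2, "valid") == np.array([[2.5]])

    def test_window_one_is_identity(self, rng):
        x = rng.random((5, 7, 2))
        assert np.array_equal(avg_pool(x, 1, 1, "valid"), x)

    def test_same_padding_stride_one_preserves_shape(self, rng):
        x = rng.random((16, 16, 128))
        assert avg_pool(x, 2, 1, "same").shape == (16, 16, 128)

    def test_same_padding_excludes_pad_cells_from_mean(self):
        # Bottom-right output of a 2x2 input with window 2/stride 1 'same'
        # sees only the single valid cell.
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = avg_pool(x, 2, 1, "same")
        assert out[1, 1] == 4.0
        assert out[0, 0] == 2.5

    def test_oversized_window_rejected(self):
        with pytest.raises(DimensionError):
            avg_pool(np.zeros((2, 2)), 3, 1, "valid")
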