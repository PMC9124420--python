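"""Architecture contracts for MS-GCN and the baselines."""

import numpy as np
import pytest

from fogseg import autodiff as ad
from fogseg.graph import build_graph, default_graph
from fogseg.nn import (BiLSTM, BiLSTMRecognizer, ConfigurationError, MSGCN,
                       MSTCN, ModelConfig, build_baseline, forward_msgcn,
                       graph_conv, input_adjust, stage_head)

RNG = np.random.default_rng(3)

TINY = dict(num_stages=2, layers_per_stage=3, filters=8,
            dilation_schedule=(1, 2, 4))


def tiny_model(**over):
    cfg = ModelConfig(**{**TINY, **over})
    return MSGCN(cfg, rng=0), cfg


class TestInputAdjust:
    def test_zero_input_zero_bias(self):
        w = RNG.standard_normal((3, 8))
        out = input_adjust(np.zeros((5, 9, 3)), w, np.zeros(8))
        np.testing.assert_allclose(out, 0.0)

    def test_hand_linear_map(self):
        w = np.array([[1.0, 2.0]])         # C_in=1 -> C=2
        x = np.full((4, 9, 1), 3.0)
        out = input_adjust(x, w)
        np.testing.assert_allclose(out[..., 0], 3.0)
        np.testing.assert_allclose(out[..., 1], 6.0)

    def test_temporal_locality(self):
        w = RNG.standard_normal((3, 4))
        x = RNG.standard_normal((10, 9, 3))
        base = input_adjust(x, w)
        x2 = x.copy()
        x2[4] += 1.0
        pert = input_adjust(x2, w)
        diff = np.abs(pert - base).sum(axis=(1, 2))
        assert diff[4] > 0
        np.testing.assert_allclose(np.delete(diff, 4), 0.0)


class TestGraphConv:
    def test_isolated_self_loops_identity(self):
        parts = np.zeros((3, 4, 4))
        parts[0] = np.eye(4)
        w = np.stack([np.eye(5)] * 3)
        x = RNG.standard_normal((6, 4, 5))
        out = graph_conv(x, parts, w, masks=np.concatenate(
            [np.ones((1, 4, 4)), np.zeros((2, 4, 4))]))
        np.testing.assert_allclose(out, x, atol=1e-5)

    def test_two_node_chain_sums_partitionwise_averages(self):
        # uniform features, W_p = I: every node receives its own value from
        # the root subset plus the (row-normalized) average of each nonempty
        # neighbor subset -> 2x for a 2-node chain
        g = build_graph(["A", "B"], edges=[(0, 1)], center_node=0)
        w = np.stack([np.eye(3)] * 3)
        x = np.ones((4, 2, 3)) * 2.5
        out = graph_conv(x, g.partitions, w)
        np.testing.assert_allclose(out, 2 * x, atol=1e-5)

    def test_zero_mask_zeroes_output(self):
        g = default_graph()
        w = RNG.standard_normal((3, 4, 4))
        x = RNG.standard_normal((5, 9, 4))
        out = graph_conv(x, g.partitions, w, masks=np.zeros((3, 9, 9)),
                         bias=np.zeros(4))
        np.testing.assert_allclose(out, 0.0)


class TestStageHead:
    def test_uniform_logits_give_uniform_probs(self):
        _, probs = stage_head(np.zeros((7, 9, 4)), np.zeros((4, 2)))
        np.testing.assert_allclose(probs, 0.5)

    def test_node_permutation_invariance(self):
        x = RNG.standard_normal((6, 9, 4))
        w = RNG.standard_normal((4, 2))
        _, p1 = stage_head(x, w)
        _, p2 = stage_head(x[:, RNG.permutation(9)], w)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_dominant_logit_wins(self):
        logits = np.array([[5.0, -5.0], [-5.0, 5.0]])
        _, probs = stage_head(logits)
        np.testing.assert_array_equal(probs.argmax(axis=1), [0, 1])


class TestForward:
    def test_output_shapes_and_softmax_rows(self):
        model, cfg = tiny_model()
        x = RNG.standard_normal((20, 9, 3)).astype(np.float32)
        out = forward_msgcn(x, model=model)
        assert out.probabilities.shape == (2, 20, 2)
        np.testing.assert_allclose(out.probabilities.sum(axis=-1), 1.0,
                                   atol=1e-5)

    def test_variable_length_same_weights(self):
        model, _ = tiny_model()
        for T in (15, 33, 60):
            out = model.predict_proba(
                RNG.standard_normal((T, 9, 3)).astype(np.float32))
            assert out.probabilities.shape[1] == T

    def test_length_preserved_for_every_default_dilation(self):
        cfg = ModelConfig(num_stages=1)
        assert cfg.dilation_schedule == tuple(2 ** i for i in range(10))
        w = ad.Tensor(RNG.standard_normal((3, 4, 4)).astype(np.float32))
        b = ad.Tensor(np.zeros(4, np.float32))
        x = ad.Tensor(RNG.standard_normal((1, 50, 1, 4)).astype(np.float32))
        for d in cfg.dilation_schedule:
            y = ad.dilated_conv_time(x, w, b, d)
            assert y.shape == x.shape

    def test_marker_permutation_equivariance(self):
        """Permuting markers together with the adjacency leaves output unchanged."""
        model, cfg = tiny_model(num_stages=1)
        x = RNG.standard_normal((25, 9, 3)).astype(np.float32)
        base = model.predict_proba(x).probabilities
        perm = RNG.permutation(9)
        g = default_graph()
        for blk in model.blocks:
            blk.gcn.partitions = np.ascontiguousarray(
                blk.gcn.partitions[:, perm][:, :, perm])
            blk.gcn.edge_mask.data = np.ascontiguousarray(
                blk.gcn.edge_mask.data[:, perm][:, :, perm])
        out = model.predict_proba(x[:, perm]).probabilities
        np.testing.assert_allclose(out, base, atol=1e-4)

    def test_parameter_count_independent_of_length(self):
        model, _ = tiny_model()
        n1 = model.num_parameters()
        model.predict(RNG.standard_normal((40, 9, 3)).astype(np.float32))
        model.predict(RNG.standard_normal((80, 9, 3)).astype(np.float32))
        assert model.num_parameters() == n1

    def test_parameter_count_matches_hand_count_for_tiny_config(self):
        cfg = ModelConfig(num_stages=1, layers_per_stage=1, filters=4,
                          dilation_schedule=(1,), num_nodes=2,
                          input_channels=3)
        g = build_graph(["A", "B"], edges=[(0, 1)], center_node=0)
        model = MSGCN(cfg, graph=g, rng=0)
        expected = (
            2 * 3            # input BN gamma/beta
            + 3 * 4 + 4      # 1x1 adjust
            + (3 * 2 * 2     # edge masks
               + 3 * 4 * 4 + 4   # graph conv W_p, bias
               + 2 * 4 + 2 * 4   # two BNs
               + 3 * 4 * 4 + 4)  # temporal conv k=3
            + 4 * 2 + 2      # head
        )
        assert model.num_parameters() == expected


class TestRefinement:
    def test_refinement_consumes_probability_channels_only(self):
        model, cfg = tiny_model()
        for stage in model.refinements:
            assert stage.adjust.weight.shape == (cfg.num_classes, cfg.filters)

    def test_single_stage_weight_isomorphic_to_stgcn_baseline(self):
        cfg = ModelConfig(**{**TINY, "num_stages": 1})
        msgcn = MSGCN(cfg, rng=0)
        stgcn = build_baseline("stgcn", ModelConfig(**TINY), rng=0)
        a = {k: v.shape for k, v in msgcn.state_dict().items()}
        b = {k: v.shape for k, v in stgcn.state_dict().items()}
        assert a == b

    def test_default_config_has_five_stages(self):
        cfg = ModelConfig()
        assert cfg.num_stages == 5 and len(cfg.dilation_schedule) == 10
        assert cfg.filters == 64 and cfg.kernel_size == 3 and not cfg.causal


class TestBaselines:
    def test_mstcn_flattens_input_to_27_channels(self):
        model = build_baseline("mstcn", ModelConfig(**TINY), rng=0)
        assert model.adjust.weight.shape[0] == 27

    def test_tcn_equals_single_stage_mstcn_weights(self):
        tcn = build_baseline("tcn", ModelConfig(**TINY), rng=0)
        mstcn1 = MSTCN(ModelConfig(**{**TINY, "num_stages": 1}), rng=0)
        assert {k: v.shape for k, v in tcn.state_dict().items()} == \
               {k: v.shape for k, v in mstcn1.state_dict().items()}

    def test_bilstm_per_sample_output(self):
        model = BiLSTM(ModelConfig(**TINY), hidden=8, rng=0)
        out = model.predict_proba(RNG.standard_normal((30, 9, 3)).astype(np.float32))
        assert out.probabilities.shape == (1, 30, 2)
        np.testing.assert_allclose(out.probabilities.sum(-1), 1.0, atol=1e-5)

    def test_recognizer_single_label_per_window(self):
        model = BiLSTMRecognizer(ModelConfig(**TINY), hidden=8, rng=0)
        labels = model.predict_windows(
            RNG.standard_normal((5, 20, 9, 3)).astype(np.float32))
        assert labels.shape == (5,)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            build_baseline("transformer")


class TestResidualPassThrough:
    def test_zero_convs_reduce_block_to_identity(self):
        model, _ = tiny_model(num_stages=1)
        model.eval()   # BN with unit running stats is the identity map
        blk = model.blocks[0]
        for t in (blk.gcn.weight, blk.gcn.bias, blk.tcn.weight, blk.tcn.bias):
            t.data[...] = 0.0
        x = ad.Tensor(RNG.standard_normal((1, 12, 9, 8)).astype(np.float32))
        out = blk.forward(x)
        np.testing.assert_allclose(out.data, x.data, atol=1e-6)
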