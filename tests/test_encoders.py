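"""Per-modality encoders: shapes, determinism, invariances, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ncfuse as nf
from ncfuse.encoders import (ConfigError, SequenceEncoder, StructureEncoder,
                             ExpressionEncoder, batch_graphs, prepare_graph)
from ncfuse.io_formats import StructureRecord, dotbracket_to_graph
from ncfuse.nn.tensor import Tensor


def hairpin_graph(n=30, stem=8):
    loop = n - 2 * stem
    db = "(" * stem + "." * loop + ")" * stem
    seq = "G" * stem + "A" * loop + "C" * stem
    return dotbracket_to_graph(StructureRecord("h", seq, db))


class TestOnehot:
    def test_definition_and_padding(self):
        m = nf.onehot_sequence("ACGU", 6)
        assert m.shape == (4, 6)
        assert np.array_equal(m[:, :4], np.eye(4))
        assert (m[:, 4:] == 0).all()

    def test_degenerate_gives_zero_column(self):
        m = nf.onehot_sequence("N", 2)
        assert (m == 0).all()

    def test_truncation_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            m = nf.onehot_sequence("ACGUACGU", 4)
        assert m.shape == (4, 4)
        assert m.sum() == 4

    def test_max_len_validation(self):
        with pytest.raises(ValueError):
            nf.onehot_sequence("ACGU", 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACGUNRY", min_size=1, max_size=60),
           st.integers(min_value=1, max_value=50))
    def test_column_sums_count_nucleotides(self, seq, max_len):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = nf.onehot_sequence(seq, max_len)
        head = seq[:max_len]
        for j, nuc in enumerate("ACGU"):
            assert m[j].sum() == head.count(nuc)


class TestSequenceEncoder:
    CFG = nf.SequenceEncoderConfig(conv_channels=[8, 8], kernel_size=5,
                                   fc_sizes=[16, 8], max_len=32)

    def test_eval_mode_deterministic(self, rng):
        enc = SequenceEncoder(self.CFG, np.random.default_rng(0))
        x = nf.onehot_sequence("ACGUACGUACGU", 32)
        assert np.array_equal(enc.encode(x), enc.encode(x))

    @pytest.mark.parametrize("fc_sizes", [[128, 64], [64, 32]])
    def test_output_length_is_last_fc_size(self, fc_sizes):
        cfg = nf.SequenceEncoderConfig(conv_channels=[8, 8], kernel_size=5,
                                       fc_sizes=fc_sizes, max_len=32)
        enc = SequenceEncoder(cfg, np.random.default_rng(0))
        out = enc.encode(nf.onehot_sequence("ACGU", 32))
        assert out.shape == (fc_sizes[-1],)
        assert np.isfinite(out).all()

    def test_sensitive_to_input(self):
        enc = SequenceEncoder(self.CFG, np.random.default_rng(0))
        zero = enc.encode(np.zeros((4, 32), dtype=np.float32))
        one = enc.encode(nf.onehot_sequence("ACGUGGCC", 32))
        assert not np.allclose(zero, one)

    def test_too_many_pooling_stages_rejected_with_minimum(self):
        with pytest.raises(ConfigError, match="minimum is 32"):
            nf.SequenceEncoderConfig(conv_channels=[4] * 5, max_len=16).validate()


class TestStructureEncoder:
    CFG = nf.StructureEncoderConfig(conv_size=16, n_blocks=2)

    def test_single_node_graph(self):
        g = dotbracket_to_graph(StructureRecord("x", "A", "."))
        enc = StructureEncoder(self.CFG, np.random.default_rng(0))
        out = enc.encode(g)
        assert out.shape == (32,)                   # Set2Set doubles conv_size
        assert np.isfinite(out).all()

    def test_permutation_invariance(self, rng):
        from ncfuse.io_formats import StructureGraph
        g = hairpin_graph()
        enc = StructureEncoder(self.CFG, np.random.default_rng(1))
        ref = enc.encode(g)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        g2 = StructureGraph(
            node_types=tuple(g.node_types[inv[i]] for i in range(g.n_nodes)),
            backbone_edges=tuple((perm[i], perm[j]) for i, j in g.backbone_edges),
            pair_edges=tuple((perm[i], perm[j]) for i, j in g.pair_edges))
        assert np.allclose(enc.encode(g2), ref, atol=1e-5)

    def test_pair_edges_change_output(self):
        from ncfuse.io_formats import StructureGraph
        g = hairpin_graph()
        g_nopairs = StructureGraph(node_types=g.node_types,
                                   backbone_edges=g.backbone_edges,
                                   pair_edges=())
        enc = StructureEncoder(self.CFG, np.random.default_rng(2))
        assert not np.allclose(enc.encode(g), enc.encode(g_nopairs))

    def test_batched_equals_single(self):
        graphs = [hairpin_graph(24, 6), hairpin_graph(30, 8), hairpin_graph(21, 4)]
        enc = StructureEncoder(self.CFG, np.random.default_rng(3))
        enc.eval()
        gb = batch_graphs([prepare_graph(g) for g in graphs])
        batched = enc.forward(gb).data
        singles = np.stack([enc.encode(g) for g in graphs])
        assert np.allclose(batched, singles, atol=1e-5)

    def test_empty_graph_rejected(self):
        enc = StructureEncoder(self.CFG, np.random.default_rng(0))
        from ncfuse.io_formats import StructureGraph
        with pytest.raises(ValueError, match="empty"):
            enc.encode(StructureGraph(node_types=(), backbone_edges=(),
                                      pair_edges=()))


class TestExpressionEncoder:
    CFG = nf.ExpressionEncoderConfig(layer_sizes=[32, 16], dropout=0.2)

    def test_zero_vector_finite(self):
        enc = ExpressionEncoder(self.CFG, 10, np.random.default_rng(0))
        out = enc.encode(np.zeros(10))
        assert out.shape == (16,)
        assert np.isfinite(out).all()

    def test_default_config_outputs_64(self):
        enc = ExpressionEncoder(nf.ExpressionEncoderConfig(), 10,
                                np.random.default_rng(0))
        assert enc.encode(np.ones(10)).shape == (64,)

    def test_scaling_input_changes_output(self, rng):
        enc = ExpressionEncoder(self.CFG, 10, np.random.default_rng(0))
        v = rng.lognormal(size=10)
        assert not np.allclose(enc.encode(v), enc.encode(10 * v))

    def test_length_mismatch_rejected(self):
        enc = ExpressionEncoder(self.CFG, 10, np.random.default_rng(0))
        with pytest.raises(ValueError, match="expected"):
            enc.encode(np.ones(7))


@pytest.mark.parametrize("modality", ["sequence", "structure", "expression"])
def test_gradient_flows_into_every_encoder(modality, tiny_dataset):
    """End-to-end trainability: the loss gradient reaches encoder weights."""
    from ncfuse.model import prepare_dataset
    from ncfuse.classifier import cross_entropy_from_logits
    cfg = nf.ModelConfig.compact(n_classes=3, n_conditions=10, max_len=128)
    model = nf.MultiModalClassifier(cfg, seed=0)
    model.train()
    prep = prepare_dataset(tiny_dataset, cfg)[:16]
    labels = tiny_dataset.labels()[:16]
    logits, _, _, _ = model.forward(prep)
    loss = cross_entropy_from_logits(logits, labels)
    loss.backward()
    grads = [p.grad for p in model.encoders[modality].parameters()]
    assert any(g is not None and np.abs(g).max() > 0 for g in grads)
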