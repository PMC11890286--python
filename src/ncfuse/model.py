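"""End-to-end multi-modal classifier: encoders -> attention fusion -> head.

A :class:`MultiModalClassifier` is built from a :class:`ModelConfig` and a
seed; all parameters, dropout masks and initialisation derive from that seed.
Per the encoded-modality contract, a sample's missing modality contributes an
all-zero encoded vector (the encoder never sees raw data for it), the
projection turns that into its bias column, and fusion masking zeroes the
modality's attention coefficient and fused block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .classifier import ClassifierHead, HeadConfig, softmax_probs
from .encoders import (ExpressionEncoder, ExpressionEncoderConfig,
                       PreparedGraph, SequenceEncoder, SequenceEncoderConfig,
                       StructureEncoder, StructureEncoderConfig, batch_graphs,
                       onehot_sequence, prepare_graph)
from .fusion import AttentionFusion
from .io_formats import MODALITY_NAMES, MultiModalDataset
from .nn.tensor import DEFAULT_DTYPE, Tensor


@dataclass
class ModelConfig:
    """All architectural hyperparameters of the classifier."""
    n_classes: int = 2
    n_conditions: int = 0
    modality_names: Tuple[str, ...] = MODALITY_NAMES
    sequence: SequenceEncoderConfig = field(default_factory=SequenceEncoderConfig)
    structure: StructureEncoderConfig = field(default_factory=StructureEncoderConfig)
    expression: ExpressionEncoderConfig = field(default_factory=ExpressionEncoderConfig)
    fusion_dim: int = 64
    head: HeadConfig = field(default_factory=lambda: HeadConfig(hidden_sizes=[64, 32]))

    def __post_init__(self):
        self.modality_names = tuple(self.modality_names)
        self.head.n_classes = max(self.head.n_classes, self.n_classes)

    @classmethod
    def compact(cls, n_classes: int, n_conditions: int = 0,
                modality_names: Sequence[str] = MODALITY_NAMES,
                max_len: int = 128) -> "ModelConfig":
        """Desk-scale configuration: same architecture, small layer sizes.

        Suited to the bundled synthetic data (short sequences, few
        conditions) and to CPU-minute training budgets.
        """
        return cls(
            n_classes=n_classes, n_conditions=n_conditions,
            modality_names=tuple(modality_names),
            sequence=SequenceEncoderConfig(conv_channels=[32, 32, 32],
                                           kernel_size=10, dropout=0.2,
                                           fc_sizes=[64, 64], max_len=max_len),
            structure=StructureEncoderConfig(conv_size=32, n_blocks=2, dropout=0.2),
            expression=ExpressionEncoderConfig(layer_sizes=[64, 64], dropout=0.2),
            fusion_dim=32,
            head=HeadConfig(hidden_sizes=[32], n_classes=n_classes))

    @classmethod
    def from_dataset(cls, dataset: MultiModalDataset, compact: bool = True,
                     max_len: Optional[int] = None) -> "ModelConfig":
        if max_len is None:
            lengths = [len(s.seq) for s in dataset.samples if s.seq]
            max_len = max(lengths) if lengths else 128
        if compact:
            return cls.compact(n_classes=max(len(dataset.class_names), 2),
                               n_conditions=dataset.n_conditions or 0,
                               modality_names=dataset.modality_names,
                               max_len=max_len)
        cfg = cls(n_classes=max(len(dataset.class_names), 2),
                  n_conditions=dataset.n_conditions or 0,
                  modality_names=dataset.modality_names)
        cfg.sequence.max_len = max(max_len, 2 ** len(cfg.sequence.conv_channels))
        cfg.head.n_classes = cfg.n_classes
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modality_names"] = list(self.modality_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key, sub in (("sequence", SequenceEncoderConfig),
                         ("structure", StructureEncoderConfig),
                         ("expression", ExpressionEncoderConfig),
                         ("head", HeadConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


@dataclass
class PreparedSample:
    """Raw modalities turned into model-ready arrays (cached per dataset)."""
    id: str
    onehot: Optional[np.ndarray]
    graph: Optional[PreparedGraph]
    expression: Optional[np.ndarray]
    mask: np.ndarray
    label: Optional[int]


def prepare_dataset(dataset: MultiModalDataset,
                    cfg: ModelConfig) -> List[PreparedSample]:
    prepared = []
    for s in dataset.samples:
        onehot = graph = expr = None
        if "sequence" in cfg.modality_names and s.seq is not None:
            onehot = onehot_sequence(s.seq, cfg.sequence.max_len)
        if "structure" in cfg.modality_names and s.graph is not None:
            graph = prepare_graph(s.graph)
        if "expression" in cfg.modality_names and s.expression is not None:
            expr = np.asarray(s.expression, dtype=DEFAULT_DTYPE)
        prepared.append(PreparedSample(id=s.id, onehot=onehot, graph=graph,
                                       expression=expr, mask=s.mask.copy(),
                                       label=s.label))
    return prepared


def _scatter_rows(x: Tensor, idx: np.ndarray, n_rows: int) -> Tensor:
    """Place rows of x at positions idx of an (n_rows, d) zero matrix."""
    s = np.zeros((n_rows, x.shape[0]), dtype=DEFAULT_DTYPE)
    s[idx, np.arange(len(idx))] = 1.0
    return Tensor(s) @ x


class MultiModalClassifier(nn.Module):
    """Encoders, attention fusion and classification head, trained jointly."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        cfg.head.validate()
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoders: Dict[str, nn.Module] = {}
        dims = []
        for name in cfg.modality_names:
            if name == "sequence":
                enc = SequenceEncoder(cfg.sequence, rng)
            elif name == "structure":
                enc = StructureEncoder(cfg.structure, rng)
            elif name == "expression":
                if cfg.n_conditions < 1:
                    raise ValueError("n_conditions must be set for the "
                                     "expression modality")
                enc = ExpressionEncoder(cfg.expression, cfg.n_conditions, rng)
            else:
                raise ValueError(f"unknown modality {name!r}")
            self.encoders[name] = enc
            dims.append(enc.out_dim)
        # expose encoders for Module.parameters() discovery
        self._encoder_list = list(self.encoders.values())
        self.fusion = AttentionFusion(dims, cfg.fusion_dim, rng)
        self.head = ClassifierHead(len(dims) * cfg.fusion_dim, cfg.head, rng)
        self.fitted = False

    # ----------------------------------------------------------------- forward
    def _encode_modality(self, name: str, batch: Sequence[PreparedSample],
                         col_mask: np.ndarray) -> Tensor:
        n = len(batch)
        enc = self.encoders[name]
        idx = np.flatnonzero(col_mask)
        if len(idx) == 0:
            return Tensor(np.zeros((n, enc.out_dim), dtype=DEFAULT_DTYPE))
        if name == "sequence":
            x = Tensor(np.stack([batch[i].onehot for i in idx]))
            out = enc.forward(x)
        elif name == "structure":
            out = enc.forward(batch_graphs([batch[i].graph for i in idx]))
        else:
            x = Tensor(np.stack([batch[i].expression for i in idx]))
            out = enc.forward(x)
        if len(idx) == n:
            return out
        return _scatter_rows(out, idx, n)

    def forward(self, batch: Sequence[PreparedSample],
                subset_mask: Optional[np.ndarray] = None):
        """Returns (logits, A, C, fused) tensors for a batch of samples."""
        masks = np.stack([s.mask for s in batch])            # (N, M)
        if subset_mask is not None:
            masks = masks & np.asarray(subset_mask, dtype=bool)[None, :]
        if not masks.any(axis=1).all():
            bad = [batch[i].id for i in np.flatnonzero(~masks.any(axis=1))]
            raise ValueError(f"no modality present for sample(s) {bad[:5]}")
        encoded = [self._encode_modality(name, batch, masks[:, m])
                   for m, name in enumerate(self.cfg.modality_names)]
        fused, A, C = self.fusion.forward(encoded, masks)
        logits = self.head.forward(fused)
        return logits, A, C, fused

    # --------------------------------------------------------------- inference
    def predict_proba(self, batch: Sequence[PreparedSample],
                      subset_mask: Optional[np.ndarray] = None,
                      return_attention: bool = False):
        self.eval()
        logits, A, _, _ = self.forward(batch, subset_mask)
        probs = softmax_probs(logits.data.astype(float))
        if return_attention:
            return probs, A.data.astype(float)
        return probs

    def predict(self, batch: Sequence[PreparedSample],
                subset_mask: Optional[np.ndarray] = None) -> np.ndarray:
        return self.predict_proba(batch, subset_mask).argmax(axis=1)

    # ------------------------------------------------------------- persistence
    def save(self, path, class_names: Optional[Sequence[str]] = None) -> None:
        """Serialise config + parameters to an .npz archive."""
        import json
        state = self.state_dict()
        np.savez_compressed(
            path,
            __config__=np.frombuffer(
                json.dumps({"model": self.cfg.to_dict(), "seed": self.seed,
                            "fitted": self.fitted,
                            "class_names": list(class_names or [])}).encode(),
                dtype=np.uint8),
            **state)

    @classmethod
    def load(cls, path) -> Tuple["MultiModalClassifier", List[str]]:
        import json
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__config__"]).decode())
            state = {k: archive[k] for k in archive.files if k != "__config__"}
        model = cls(ModelConfig.from_dict(meta["model"]), seed=meta["seed"])
        model.load_state_dict(state)
        model.fitted = meta["fitted"]
        return model, meta["class_names"]
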