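"""Synthetic multi-modal ncRNA-like datasets with planted class signal.

The generator emulates the structure of a real multi-cohort dataset: a FASTA
file of sequences, a dot-bracket file of secondary structures, a TSV
expression matrix with a controllable fraction of transcripts absent from it
(missing expression), and a labels table. Class signal is planted per
modality and independently switchable:

* sequence — a short class-specific motif inserted at a random unpaired
  position with probability ``signal_strengths['sequence']``;
* structure — a stem-loop whose stem length is class-specific with
  probability ``signal_strengths['structure']`` (otherwise a random stem);
  paired positions are made complementary (A-U / G-C) in the emitted
  sequence so sequence and structure stay mutually consistent;
* expression — lognormal noise around a class-specific mean profile,
  interpolated toward the global mean as the signal strength decreases.

Exactly ``round(missing_expr_frac * n)`` transcripts, chosen uniformly, are
omitted from the expression file (missingness is exact, not expected).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import (ExpressionTable, MultiModalDataset, SequenceRecord,
                         StructureRecord, assemble_dataset, write_dotbracket,
                         write_expression, write_fasta, write_labels)
import pandas as pd

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_NUCS = np.array(list("ACGU"))


@dataclass
class ClassSpec:
    """Planted signal for one class: a sequence motif, a characteristic
    hairpin stem length, and a mean expression profile over conditions."""
    name: str
    seq_motif: str
    hairpin_stem_len: int
    expr_profile: np.ndarray

    def __post_init__(self):
        self.expr_profile = np.asarray(self.expr_profile, dtype=float)
        if self.hairpin_stem_len < 0:
            raise ValueError("stem length must be >= 0")


def default_classes(n_conditions: int = 10) -> List[ClassSpec]:
    """Three classes whose signals echo the field's intuition: a conserved
    motif, a distinctive hairpin, and condition-specific expression."""
    profiles = np.full((3, n_conditions), 1.0)
    third = max(n_conditions // 3, 1)
    for c in range(3):
        profiles[c, c * third:(c + 1) * third] = 8.0
    return [
        ClassSpec("mir-like", "UGAGGUAG", 16, profiles[0]),
        ClassSpec("sno-like", "AUGAUGAC", 5, profiles[1]),
        ClassSpec("snr-like", "GGCUCAGU", 10, profiles[2]),
    ]


@dataclass
class SynthConfig:
    n_per_class: int = 200
    classes: Optional[List[ClassSpec]] = None
    seq_len_range: Tuple[int, int] = (40, 120)
    n_conditions: int = 10
    missing_expr_frac: float = 0.23
    seed: int = 0
    signal_strengths: Dict[str, float] = field(default_factory=lambda: {
        "sequence": 0.9, "structure": 0.9, "expression": 0.9})
    expr_noise_sigma: float = 0.5
    modalities: Tuple[str, ...] = ("sequence", "structure", "expression")

    def __post_init__(self):
        if self.classes is None:
            self.classes = default_classes(self.n_conditions)
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.missing_expr_frac <= 1.0:
            raise ValueError("missing_expr_frac must be in [0,1]")
        if self.seq_len_range[0] < 20:
            raise ValueError("minimum sequence length must be >= 20")
        for s in self.signal_strengths.values():
            if not 0.0 <= s <= 1.0:
                raise ValueError("signal strengths must be in [0,1]")
        for spec in self.classes:
            if len(spec.seq_motif) >= self.seq_len_range[0]:
                raise ValueError(
                    f"motif {spec.seq_motif!r} does not fit the minimum "
                    f"sequence length {self.seq_len_range[0]}")
            if spec.expr_profile.shape != (self.n_conditions,):
                raise ValueError(
                    f"class {spec.name!r}: expression profile length "
                    f"{spec.expr_profile.shape[0]} != n_conditions "
                    f"{self.n_conditions}")


@dataclass
class GeneratedDataset:
    sequences: List[SequenceRecord]
    structures: List[StructureRecord]
    expression: ExpressionTable
    labels: Dict[str, str]
    manifest: "pd.DataFrame"
    config: SynthConfig


# ----------------------------------------------------------------- plumbing

def _random_hairpin(length: int, stem_len: int,
                    rng: np.random.Generator) -> Tuple[str, List[Tuple[int, int]]]:
    """Dot-bracket with one stem-loop: prefix, stem, loop (>=3 nt), stem
    close, suffix. The stem is shortened if the sequence is too short."""
    loop = int(rng.integers(3, 9))
    stem = min(stem_len, max((length - loop - 2) // 2, 0))
    free = length - 2 * stem - loop
    prefix = int(rng.integers(0, free + 1))
    suffix = free - prefix
    db = "." * prefix + "(" * stem + "." * loop + ")" * stem + "." * suffix
    pairs = [(prefix + i, prefix + 2 * stem + loop - 1 - i) for i in range(stem)]
    return db, pairs


def _plant_motif(seq: List[str], motif: str, unpaired: np.ndarray,
                 rng: np.random.Generator) -> Optional[int]:
    """Write `motif` at a random run of unpaired positions and return the
    start index; returns None (no planting) when no unpaired run is long
    enough, so paired positions always stay complementary."""
    k = len(motif)
    runs = []
    start = None
    for i, u in enumerate(list(unpaired) + [False]):
        if u and start is None:
            start = i
        elif not u and start is not None:
            if i - start >= k:
                runs.append((start, i - k))
            start = None
    if not runs:
        return None
    lo, hi = runs[int(rng.integers(0, len(runs)))]
    pos = int(rng.integers(lo, hi + 1))
    seq[pos:pos + k] = list(motif)
    return pos


def simulate(cfg: SynthConfig) -> GeneratedDataset:
    """Generate a dataset in memory; see the module docstring for the model."""
    rng = np.random.default_rng(cfg.seed)
    s_seq = cfg.signal_strengths.get("sequence", 0.0)
    s_struct = cfg.signal_strengths.get("structure", 0.0)
    s_expr = cfg.signal_strengths.get("expression", 0.0)
    global_profile = np.mean([c.expr_profile for c in cfg.classes], axis=0)

    seqs: List[SequenceRecord] = []
    structs: List[StructureRecord] = []
    labels: Dict[str, str] = {}
    expr_rows: Dict[str, np.ndarray] = {}
    manifest_rows = []

    n_classes = len(cfg.classes)
    width = len(str(n_classes * cfg.n_per_class))
    counter = 0
    for spec in cfg.classes:
        for _ in range(cfg.n_per_class):
            counter += 1
            rid = f"nc{counter:0{width}d}"
            length = int(rng.integers(cfg.seq_len_range[0],
                                      cfg.seq_len_range[1] + 1))
            seq = list(rng.choice(_NUCS, size=length))

            if rng.random() < s_struct:
                stem_len = spec.hairpin_stem_len
            else:
                stem_len = int(rng.integers(4, 21))
            db, pairs = _random_hairpin(length, stem_len, rng)
            for i, j in pairs:
                seq[j] = _COMPLEMENT[seq[i]]

            motif_pos = None
            if rng.random() < s_seq:
                unpaired = np.array([ch == "." for ch in db])
                motif_pos = _plant_motif(seq, spec.seq_motif, unpaired, rng)

            mu = (1.0 - s_expr) * global_profile + s_expr * spec.expr_profile
            expr = np.exp(rng.normal(np.log(mu), cfg.expr_noise_sigma))

            seq_str = "".join(seq)
            seqs.append(SequenceRecord(id=rid, seq=seq_str))
            structs.append(StructureRecord(id=rid, seq=seq_str, db=db))
            expr_rows[rid] = expr
            labels[rid] = spec.name
            manifest_rows.append({
                "id": rid, "class": spec.name, "length": length,
                "motif_planted": motif_pos is not None,
                "motif_pos_1based": (motif_pos + 1) if motif_pos is not None else 0,
                "stem_len": db.count("("), "expr_present": True})

    n = len(seqs)
    n_missing = int(round(cfg.missing_expr_frac * n))
    missing_ids = set()
    if n_missing > 0 and "expression" in cfg.modalities:
        all_ids = [s.id for s in seqs]
        missing_ids = set(rng.choice(all_ids, size=n_missing, replace=False))
        for row in manifest_rows:
            if row["id"] in missing_ids:
                row["expr_present"] = False

    conditions = [f"cond{j + 1}" for j in range(cfg.n_conditions)]
    kept = [(rid, expr_rows[rid]) for rid, _ in sorted(expr_rows.items())
            if rid not in missing_ids]
    table = ExpressionTable(values=pd.DataFrame(
        [v for _, v in kept], index=[r for r, _ in kept], columns=conditions),
        missing_rows=missing_ids)

    return GeneratedDataset(sequences=seqs, structures=structs,
                            expression=table, labels=labels,
                            manifest=pd.DataFrame(manifest_rows), config=cfg)


def generate(cfg: SynthConfig, out_dir) -> Dict[str, Path]:
    """Generate a dataset and write the four data files plus a manifest.

    Returns the paths keyed by role: sequences, structures, expression,
    labels, manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate(cfg)
    paths = {
        "sequences": out / "sequences.fasta",
        "structures": out / "structures.db",
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "manifest": out / "manifest.tsv",
    }
    write_fasta(data.sequences, paths["sequences"])
    write_dotbracket(data.structures, paths["structures"])
    write_expression(data.expression, paths["expression"])
    write_labels(data.labels, paths["labels"])
    with open(paths["manifest"], "w") as fh:
        fh.write(f"# seed={cfg.seed} n_per_class={cfg.n_per_class} "
                 f"missing_expr_frac={cfg.missing_expr_frac}\n")
        data.manifest.to_csv(fh, sep="\t", index=False)
    return paths


def to_dataset(data: GeneratedDataset) -> MultiModalDataset:
    """Assemble a generated dataset without touching disk."""
    mods = data.config.modalities
    return assemble_dataset(
        data.sequences if "sequence" in mods else None,
        data.structures if "structure" in mods else None,
        data.expression if "expression" in mods else None,
        data.labels, modality_names=mods)


def simulate_dataset(cfg: SynthConfig) -> MultiModalDataset:
    """simulate() + to_dataset() in one call."""
    return to_dataset(simulate(cfg))


# ------------------------------------------------------------ worked example

WORKED_EXAMPLE_SEED = 7


def worked_example_config() -> SynthConfig:
    """Tiny frozen dataset: 12 samples, 3 classes, sequence + structure."""
    return SynthConfig(n_per_class=4, seq_len_range=(30, 48), n_conditions=4,
                       missing_expr_frac=0.0, seed=WORKED_EXAMPLE_SEED,
                       modalities=("sequence", "structure"),
                       classes=[
                           ClassSpec("alpha", "UGAGGUAG", 10, np.ones(4)),
                           ClassSpec("beta", "AUGAUGAC", 4, np.ones(4)),
                           ClassSpec("gamma", "GGCUCAGU", 7, np.ones(4)),
                       ])


def worked_example(out_dir=None):
    """Generate the frozen 12-sample example; byte-identical across runs.

    With `out_dir` the files are written and their paths returned; without,
    the in-memory GeneratedDataset is returned.
    """
    cfg = worked_example_config()
    if out_dir is None:
        return simulate(cfg)
    return generate(cfg, out_dir)


def dataset_checksum(out_dir) -> str:
    """SHA256 over the concatenated data files (sorted by name)."""
    h = hashlib.sha256()
    for p in sorted(Path(out_dir).iterdir()):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
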