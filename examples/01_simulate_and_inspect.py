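"""Generate a synthetic multi-modal ncRNA dataset and inspect its files.

The generator plants a class-specific sequence motif, a class-specific
hairpin stem length, and a class-specific expression profile, and omits a
fixed fraction of transcripts from the expression matrix (missing modality).
"""

import tempfile
from pathlib import Path

import ncfuse as nf

out = Path(tempfile.mkdtemp(prefix="ncfuse_demo_"))
cfg = nf.SynthConfig(n_per_class=50, seed=7)
paths = nf.generate(cfg, out)

seqs = nf.read_fasta(paths["sequences"])
structs = nf.read_dotbracket(paths["structures"])
expr = nf.read_expression(paths["expression"])
labels = nf.read_labels(paths["labels"])

print(f"wrote dataset to {out}")
print(f"  {len(seqs)} sequences, lengths {min(r.length for r in seqs)}-"
      f"{max(r.length for r in seqs)} nt")
print(f"  {len(structs)} structures; first: {structs[0].db[:40]}...")
print(f"  expression matrix {expr.values.shape[0]} x {expr.values.shape[1]} "
      f"({len(labels) - expr.values.shape[0]} transcripts missing, i.e. "
      f"{(len(labels) - expr.values.shape[0]) / len(labels):.0%})")

ds = nf.load_dataset(fasta=paths["sequences"], structures=paths["structures"],
                     expression=paths["expression"], labels=paths["labels"])
masks = ds.masks()
print(f"assembled {len(ds)} samples over modalities {ds.modality_names}")
print(f"  presence per modality: {masks.sum(axis=0).tolist()}")
# The mask is what lets the model use samples whose expression is missing:
# those samples keep sequence+structure and get attention 0 on expression.
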