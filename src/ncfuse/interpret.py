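"""Export and aggregation of per-sample modality attention for class
annotation.

Each classified sample carries an attention vector A over the modalities:
nonnegative, zero on missing modalities, summing to one over present ones.
Rows grouped by class and rendered as a heatmap show which modality the
model leans on for each class; the per-class mean +/- SD summary and the
resulting modality ranking are the package's annotation output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import MultiModalDataset
from .model import MultiModalClassifier, prepare_dataset


@dataclass
class AttentionTable:
    """Per-sample attention rows plus the per-class summary.

    `rows`: DataFrame with columns id, true_class (when labelled),
    predicted_class, then one attention column per modality; ordered by
    class then id. `class_summary`: per (class, modality) mean and SD.
    """
    rows: pd.DataFrame
    class_summary: pd.DataFrame
    modality_names: Tuple[str, ...]


def export_attention(model: MultiModalClassifier, dataset: MultiModalDataset,
                     batch_size: int = 64) -> AttentionTable:
    """Run eval-mode forward passes and collect each sample's attention
    coefficients exactly as the fusion layer produced them (no
    renormalisation)."""
    if not model.fitted:
        raise ValueError("model has not been trained; call train() first")
    prepared = prepare_dataset(dataset, model.cfg)
    mods = dataset.modality_names
    probs_all, attn_all = [], []
    for start in range(0, len(prepared), batch_size):
        probs, attn = model.predict_proba(prepared[start:start + batch_size],
                                          return_attention=True)
        probs_all.append(probs)
        attn_all.append(attn)
    probs = np.concatenate(probs_all)
    attn = np.concatenate(attn_all)
    pred_idx = probs.argmax(axis=1)
    class_names = dataset.class_names or [str(i) for i in range(probs.shape[1])]

    rows = pd.DataFrame({"id": [s.id for s in dataset.samples]})
    labelled = all(s.label is not None for s in dataset.samples)
    if labelled:
        rows["true_class"] = [class_names[s.label] for s in dataset.samples]
    rows["predicted_class"] = [class_names[i] if i < len(class_names) else str(i)
                               for i in pred_idx]
    for m, name in enumerate(mods):
        rows[name] = attn[:, m]
    group_col = "true_class" if labelled else "predicted_class"
    rows = rows.sort_values([group_col, "id"], kind="stable").reset_index(drop=True)

    summary = rows.groupby(group_col, sort=True)[list(mods)].agg(["mean", "std"])
    summary.columns = [f"{mod}_{stat}" for mod, stat in summary.columns]
    summary = summary.fillna(0.0)
    return AttentionTable(rows=rows, class_summary=summary,
                          modality_names=tuple(mods))


def class_annotation(table: AttentionTable,
                     tie_tol: float = 1e-9,
                     ) -> Dict[str, List[List[Tuple[str, float, float]]]]:
    """Rank modalities by mean attention per class.

    Returns, per class, a list of tie groups in decreasing mean order; each
    group holds (modality, mean, sd) tuples whose means differ by less than
    `tie_tol` (ties are reported, not broken).
    """
    if table.rows.empty:
        raise ValueError("attention table is empty")
    out: Dict[str, List[List[Tuple[str, float, float]]]] = {}
    for cls, row in table.class_summary.iterrows():
        entries = sorted(
            ((m, float(row[f"{m}_mean"]), float(row[f"{m}_std"]))
             for m in table.modality_names),
            key=lambda e: -e[1])
        groups: List[List[Tuple[str, float, float]]] = []
        for e in entries:
            if groups and abs(groups[-1][-1][1] - e[1]) < tie_tol:
                groups[-1].append(e)
            else:
                groups.append([e])
        out[str(cls)] = groups
    return out


def write_attention_tsv(table: AttentionTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False, float_format="%.8g")


def plot_attention_heatmap(table: AttentionTable, path,
                           cmap: str = "Greys") -> None:
    """Render the attention rows as a class-grouped heatmap (darker =
    stronger), one row per ncRNA and one column per modality."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mods = list(table.modality_names)
    data = table.rows[mods].to_numpy(dtype=float)
    group_col = "true_class" if "true_class" in table.rows else "predicted_class"
    classes = table.rows[group_col].to_numpy()

    fig, ax = plt.subplots(figsize=(3 + 0.6 * len(mods),
                                    max(3.0, 0.02 * len(data) + 2)))
    ax.imshow(data, aspect="auto", cmap=cmap, vmin=0, vmax=1)
    ax.set_xticks(range(len(mods)), mods, rotation=30, ha="right")
    boundaries = np.flatnonzero(classes[1:] != classes[:-1]) + 1
    for b in boundaries:
        ax.axhline(b - 0.5, color="tab:red", lw=0.8)
    ticks = np.concatenate([[0], boundaries, [len(data)]])
    centers = (ticks[:-1] + ticks[1:]) / 2
    ax.set_yticks(centers, [classes[int(t)] for t in ticks[:-1]])
    ax.set_ylabel("ncRNA (grouped by class)")
    ax.set_title("Modality attention")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
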