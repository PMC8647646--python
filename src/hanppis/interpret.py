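"""Attention-weight extraction: which residues and K-mers drove a call.

The two attention levels of the trained network double as importance
scores: residue-level weights say how much each amino acid contributed to
its K-mer's representation, K-mer-level weights how much each K-mer
contributed to the window representation.  For interaction-site windows
the central, site-bearing K-mer is expected to dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TrainConfig
from .fragmenter import extract_window, segment_kmers, truncate_record
from .han_model import HanParams, forward
from .io_features import ProteinRecord

__all__ = [
    "AttentionReport",
    "explain",
    "export_attention",
    "plot_attention",
    "mean_kmer_attention",
    "mean_residue_attention",
]


def mean_kmer_attention(params: HanParams, fragments, config: TrainConfig,
                        chunk: int = 512) -> np.ndarray:
    """Mean K-mer-level attention weight per K-mer slot over many fragments.

    Fully padded K-mers carry weight 0 and still enter the mean, so the
    result reflects what the model attends to across the corpus.
    """
    from . import autodiff as ad
    from .han_model import forward_batch

    sums = None
    with ad.no_grad():
        for start in range(0, len(fragments), chunk):
            batch = fragments[start : start + chunk]
            windows = np.stack([f.window_features for f in batch]).astype(np.float64)
            masks = np.stack([f.pad_mask for f in batch]).astype(np.float64)
            _, traces = forward_batch(windows, masks, params, config, need_trace=True)
            w = np.stack([t.kmer_weights for t in traces]).sum(axis=0)
            sums = w if sums is None else sums + w
    return sums / len(fragments)


def mean_residue_attention(params: HanParams, fragments, config: TrainConfig,
                           chunk: int = 512) -> np.ndarray:
    """Mean residue-level attention per window position (K-mers concatenated)."""
    from . import autodiff as ad
    from .han_model import forward_batch

    sums = None
    with ad.no_grad():
        for start in range(0, len(fragments), chunk):
            batch = fragments[start : start + chunk]
            windows = np.stack([f.window_features for f in batch]).astype(np.float64)
            masks = np.stack([f.pad_mask for f in batch]).astype(np.float64)
            _, traces = forward_batch(windows, masks, params, config, need_trace=True)
            w = np.stack(
                [np.concatenate(t.residue_weights) for t in traces]
            ).sum(axis=0)
            sums = w if sums is None else sums + w
    return sums / len(fragments)


@dataclass
class AttentionReport:
    """Two-level attention distribution for one residue's prediction."""

    protein_id: str
    position: int          # 1-based residue position
    window: str            # length-w residue string, '-' at pads
    p_site: float
    kmers: list[str]
    kmer_weights: np.ndarray
    residue_weights: list[np.ndarray]  # one vector per K-mer


def explain(
    params: HanParams,
    record: ProteinRecord,
    feature_source,
    position: int,
    config: TrainConfig,
) -> AttentionReport:
    """Run one forward pass on the window centred at ``position`` (1-based)."""
    rec = truncate_record(record, config.max_len)
    if not 1 <= position <= len(rec.sequence):
        raise ValueError(
            f"position {position} outside 1..{len(rec.sequence)} "
            f"(truncated length of {record.id!r})"
        )
    features = np.asarray(feature_source.features(rec), dtype=np.float64)
    fragment = extract_window(
        features, rec.sequence, rec.labels, position - 1, config.window, rec.id
    )
    probs, trace = forward(fragment, params, config)
    seg = segment_kmers(fragment, config.kmer)
    return AttentionReport(
        protein_id=rec.id,
        position=position,
        window=fragment.window_residues,
        p_site=float(probs[1]),
        kmers=seg.kmers,
        kmer_weights=trace.kmer_weights,
        residue_weights=trace.residue_weights,
    )


def _report_frame(report: AttentionReport) -> pd.DataFrame:
    rows = []
    for j, (kmer, w) in enumerate(zip(report.kmers, report.kmer_weights)):
        rows.append(
            {"level": "kmer", "index": j, "unit": kmer, "weight": float(w)}
        )
    pos = 0
    for j, weights in enumerate(report.residue_weights):
        for offset, w in enumerate(weights):
            rows.append(
                {
                    "level": "residue",
                    "index": pos + offset,
                    "unit": report.window[pos + offset],
                    "weight": float(w),
                }
            )
        pos += len(weights)
    return pd.DataFrame(rows, columns=["level", "index", "unit", "weight"])


def export_attention(report: AttentionReport, path) -> None:
    """Write one TSV row per (level, unit, weight)."""
    _report_frame(report).to_csv(path, sep="\t", index=False, float_format="%.6f")


def plot_attention(report: AttentionReport, path) -> None:
    """Bar charts of the K-mer-level and residue-level distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
    ax1.bar(report.kmers, report.kmer_weights, color="#4878a8")
    ax1.set_title("K-mer-level attention")
    ax1.set_ylabel("weight")
    residues = list(report.window)
    flat = np.concatenate(report.residue_weights)
    ax2.bar(range(len(residues)), flat, color="#a85448")
    ax2.set_xticks(range(len(residues)), residues)
    ax2.set_title("Residue-level attention")
    fig.suptitle(
        f"{report.protein_id} position {report.position} "
        f"(p_site={report.p_site:.3f})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
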