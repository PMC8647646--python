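"""From labeled proteins to per-residue training samples.

Every residue of a (truncated) protein yields one sample: a length-w
window of raw feature vectors centred on it, zero-padded past the
sequence ends with an explicit mask.  Windows are segmented into
consecutive non-overlapping K-mers (the "sentences" of the hierarchical
model), and the corpus is split into train/test at the *protein* level so
no protein contributes fragments to both partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import TrainConfig
from .io_features import ProteinRecord

__all__ = [
    "Fragment",
    "KmerSegmentation",
    "DatasetSplit",
    "truncate_record",
    "extract_window",
    "segment_kmers",
    "kmer_slices",
    "fragment_protein",
    "build_dataset",
]

PAD_CHAR = "-"


@dataclass
class Fragment:
    """One per-residue sample: a masked feature window plus its label."""

    protein_id: str
    center: int                   # 0-based residue index in the truncated protein
    window_features: np.ndarray   # [w, D_raw]; zero rows at padded positions
    pad_mask: np.ndarray          # [w] 0/1; 1 = real residue
    label: int
    window_residues: str          # length w, '-' at padded positions

    @property
    def window(self) -> int:
        return len(self.pad_mask)


@dataclass
class KmerSegmentation:
    """Consecutive non-overlapping chunks of one window."""

    k: int
    slices: list[slice]
    kmers: list[str]


@dataclass
class DatasetSplit:
    """Protein-level train/test partition of the fragment corpus."""

    train: list[Fragment]
    test: list[Fragment]
    seed: int

    @property
    def train_protein_ids(self) -> set:
        return {f.protein_id for f in self.train}

    @property
    def test_protein_ids(self) -> set:
        return {f.protein_id for f in self.test}


def truncate_record(record: ProteinRecord, max_len: int = 500) -> ProteinRecord:
    """Cut sequence (and labels) to the first ``max_len`` residues."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(record.sequence) <= max_len:
        return record
    labels = None if record.labels is None else record.labels[:max_len]
    return ProteinRecord(record.id, record.sequence[:max_len], labels)


def extract_window(
    features: np.ndarray,
    residues: str,
    labels: Optional[np.ndarray],
    center: int,
    w: int = 7,
    protein_id: str = "",
) -> Fragment:
    """Slice the length-w window centred on ``center``, zero-padding ends."""
    if w % 2 == 0 or w < 1:
        raise ValueError(f"window length must be odd, got {w}")
    L = features.shape[0]
    if not 0 <= center < L:
        raise ValueError(f"center {center} out of range 0..{L - 1}")
    half = (w - 1) // 2
    window = np.zeros((w, features.shape[1]), dtype=features.dtype)
    mask = np.zeros(w, dtype=np.int8)
    chars = [PAD_CHAR] * w
    lo = max(0, center - half)
    hi = min(L, center + half + 1)
    off = lo - (center - half)
    window[off : off + hi - lo] = features[lo:hi]
    mask[off : off + hi - lo] = 1
    for j, pos in enumerate(range(lo, hi)):
        chars[off + j] = residues[pos]
    label = int(labels[center]) if labels is not None else 0
    return Fragment(protein_id, center, window, mask, label, "".join(chars))


def kmer_slices(w: int, k: int) -> list[slice]:
    """Non-overlapping chunk boundaries; the last chunk may be shorter."""
    if not 1 <= k <= w:
        raise ValueError(f"k must be in 1..{w}, got {k}")
    return [slice(s, min(s + k, w)) for s in range(0, w, k)]


def segment_kmers(fragment: Fragment, k: int = 3) -> KmerSegmentation:
    """Segment a fragment's window into K-mers."""
    slices = kmer_slices(fragment.window, k)
    return KmerSegmentation(
        k=k,
        slices=slices,
        kmers=[fragment.window_residues[s] for s in slices],
    )


def fragment_protein(
    record: ProteinRecord,
    feature_source,
    config: TrainConfig,
) -> list[Fragment]:
    """One fragment per residue of the truncated protein."""
    if record.labels is None:
        raise ValueError(f"record {record.id!r} lacks labels")
    rec = truncate_record(record, config.max_len)
    features = np.asarray(feature_source.features(rec), dtype=np.float32)
    if features.shape[0] != len(rec.sequence):
        raise ValueError(
            f"feature source returned {features.shape[0]} rows for "
            f"{len(rec.sequence)} residues of {rec.id!r}"
        )
    return [
        extract_window(
            features, rec.sequence, rec.labels, center, config.window, rec.id
        )
        for center in range(len(rec.sequence))
    ]


def build_dataset(
    records: Sequence[ProteinRecord],
    feature_source,
    config: TrainConfig,
) -> DatasetSplit:
    """Protein-level split, then per-residue fragmenting of each partition.

    Proteins are shuffled with the config seed; the first
    ceil(split_fraction * N) go to the train partition.
    """
    for rec in records:
        if rec.labels is None:
            raise ValueError(f"record {rec.id!r} lacks labels")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(records))
    n_train = math.ceil(config.split_fraction * len(records))
    train, test = [], []
    for rank, idx in enumerate(order):
        frags = fragment_protein(records[idx], feature_source, config)
        (train if rank < n_train else test).extend(frags)
    return DatasetSplit(train=train, test=test, seed=config.seed)
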