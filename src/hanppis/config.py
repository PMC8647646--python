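"""Run configuration shared by the data pipeline and the model.

Defaults reproduce the published training settings: sliding window 7,
sequences truncated at 500 residues, batch size 3, 86 hidden/attention
units, a 50-unit embedding projection, and a 7x positive-class weight
countering the ~1:5.5 site / non-site imbalance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

FEATURE_BLOCKS = ("one_hot", "pssm", "ss9", "hydropathy", "rel_pos", "embedding")

_BLOCK_WIDTHS = {"one_hot": 20, "pssm": 20, "ss9": 9, "hydropathy": 1, "rel_pos": 1}


@dataclass
class TrainConfig:
    """Every tunable of the pipeline and the network."""

    # fragmenting
    window: int = 7            # sliding-window length w (odd)
    kmer: int = 3              # K-mer size within a window
    max_len: int = 500         # proteins truncated beyond this length
    split_fraction: float = 0.8  # protein-level train fraction
    # architecture
    hidden: int = 86           # GRU hidden units u per direction, both levels
    attention: int = 86        # attention-layer width a, both levels
    projection: int = 50       # embedding projection width P
    embed_dim: int = 1024      # language-model embedding width E
    cell: str = "gru"
    dropped_blocks: tuple = ()  # feature blocks removed from the fused vector
    # optimisation
    batch_size: int = 3
    pos_weight: float = 7.0    # positive-class loss weight (~1:7)
    learning_rate: float = 1e-3
    epochs: int = 10
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    val_fraction: float = 0.1  # train proteins held out for best-epoch choice
    threshold: float = 0.5     # p(site) binarisation cut-off
    seed: int = 0

    def __post_init__(self):
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError(f"window must be odd and positive, got {self.window}")
        if not 1 <= self.kmer <= self.window:
            raise ValueError(f"kmer must be in 1..window, got {self.kmer}")
        if self.cell != "gru":
            raise ValueError(f"unsupported recurrent cell {self.cell!r}")
        unknown = set(self.dropped_blocks) - set(FEATURE_BLOCKS)
        if unknown:
            raise ValueError(f"unknown feature block(s): {sorted(unknown)}")
        self.dropped_blocks = tuple(self.dropped_blocks)
        for name in ("max_len", "hidden", "attention", "projection", "embed_dim",
                     "batch_size", "pos_weight", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def active_blocks(self) -> tuple:
        return tuple(b for b in FEATURE_BLOCKS if b not in self.dropped_blocks)

    @property
    def fused_width(self) -> int:
        """Width of the fused per-residue vector fed to the network."""
        width = 0
        for block in self.active_blocks:
            width += self.projection if block == "embedding" else _BLOCK_WIDTHS[block]
        return width

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dropped_blocks"] = list(self.dropped_blocks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "dropped_blocks" in d:
            d = dict(d, dropped_blocks=tuple(d["dropped_blocks"]))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
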