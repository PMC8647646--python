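"""Seeded generator of proteins, labels, and surrogate feature files.

Emulates the statistical structure of the residue-level interaction-site
benchmarks (proteins of 50-500 residues, roughly 1:5.5 negative:positive
imbalance) with a label rule the model family can actually learn: a short
motif is planted at seeded non-overlapping positions and a residue is
positive iff it is the central residue of a planted occurrence.  Labels
therefore depend only on local sequence context, the assumption behind
window-based classification.  A motif-free mode (``motif=None``) draws
labels independently of the sequence as a negative control.

The generator also fabricates the three derived feature channels in the
exact file dialects :mod:`hanppis.io_features` parses, so the whole
pipeline is exercisable with no external tools: PSSM log-odds derived
from the one-hot identity (plus optional Gaussian noise), secondary
structure drawn from a seeded categorical, and hash-provider embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .io_features import (
    AA_ALPHABET,
    HashEmbeddingProvider,
    ProteinRecord,
    assemble_bundles,
    bundles_to_matrix,
)

__all__ = [
    "SynthConfig",
    "generate_proteins",
    "SynthFeatureSource",
    "synth_feature_source",
    "write_corpus",
]

# one-hot derived log-odds: the true residue column gets +PSSM_SCALE/2,
# the rest -PSSM_SCALE/2 (integers, so the ASCII round trip is exact at sigma=0)
PSSM_SCALE = 4

# secondary-structure states with rough globular-protein frequencies;
# ' ' is the DSSP blank (coil/"other")
_SS_CODES = np.array(["H", "E", "T", "S", "G", "B", "I", " "])
_SS_PROBS = np.array([0.32, 0.21, 0.11, 0.08, 0.04, 0.01, 0.01, 0.22])


@dataclass
class SynthConfig:
    """Study conditions for the synthetic corpus."""

    n_proteins: int = 200
    min_len: int = 50
    max_len: int = 500
    motif: Optional[str] = "KD"
    background: Optional[Sequence[float]] = None  # composition over AA_ALPHABET
    neg_pos_ratio: float = 5.5
    sigma: float = 0.0      # PSSM log-odds noise
    seed: int = 0

    def __post_init__(self):
        if self.motif is not None:
            if not self.motif or any(aa not in AA_ALPHABET for aa in self.motif):
                raise ValueError(f"motif {self.motif!r} must use canonical residues")
            if len(self.motif) > self.min_len:
                raise ValueError("motif longer than the minimum protein length")
        if self.neg_pos_ratio <= 0:
            raise ValueError("neg_pos_ratio must be positive")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid length range")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or bg.min() < 0 or bg.sum() == 0:
                raise ValueError("background must be 20 non-negative weights")
            self.background = bg / bg.sum()


def _plant_positions(
    rng: np.random.Generator, length: int, m: int, n_plants: int
) -> list[int]:
    """Seeded non-overlapping motif start positions (greedy rejection)."""
    starts: list[int] = []
    candidates = rng.permutation(length - m + 1)
    for s in candidates:
        if all(abs(s - t) >= m for t in starts):
            starts.append(int(s))
            if len(starts) == n_plants:
                break
    return sorted(starts)


def generate_proteins(
    cfg: SynthConfig,
) -> tuple[list[ProteinRecord], list[list[int]]]:
    """Generate the labeled corpus; returns (records, per-protein plant starts).

    The per-protein plant count targets the configured negative:positive
    ratio; the realised corpus-wide ratio is checked to be within 20% of
    the target (infeasible combinations raise).
    """
    rng = np.random.default_rng(cfg.seed)
    bg = cfg.background if cfg.background is not None else np.full(20, 0.05)
    alphabet = np.array(list(AA_ALPHABET))
    records: list[ProteinRecord] = []
    plant_log: list[list[int]] = []
    pos_frac = 1.0 / (1.0 + cfg.neg_pos_ratio)
    for i in range(cfg.n_proteins):
        L = int(rng.integers(cfg.min_len, cfg.max_len + 1))
        seq = rng.choice(alphabet, size=L, p=bg)
        labels = np.zeros(L, dtype=np.int8)
        starts: list[int] = []
        n_plants = max(1, round(L * pos_frac))
        if cfg.motif is not None:
            m = len(cfg.motif)
            starts = _plant_positions(rng, L, m, n_plants)
            for s in starts:
                seq[s : s + m] = list(cfg.motif)
                labels[s + (m - 1) // 2] = 1
        else:
            pos = rng.choice(L, size=min(n_plants, L), replace=False)
            labels[pos] = 1
        records.append(ProteinRecord(f"synth_{i:04d}", "".join(seq), labels))
        plant_log.append(starts)
    n_pos = sum(int(r.labels.sum()) for r in records)
    n_neg = sum(len(r) for r in records) - n_pos
    if n_pos == 0:
        raise ValueError("no positive residues generated")
    realised = n_neg / n_pos
    if not 0.8 * cfg.neg_pos_ratio <= realised <= 1.2 * cfg.neg_pos_ratio:
        raise ValueError(
            f"realised negative:positive ratio {realised:.2f} misses the "
            f"target {cfg.neg_pos_ratio} by more than 20%; "
            f"infeasible motif/length combination"
        )
    return records, plant_log


def _record_rng(seed: int, record_id: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes (unlike str.__hash__)
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(record_id.encode())])
    )


class SynthFeatureSource:
    """Deterministic surrogate for PSI-BLAST / DSSP / embedding outputs."""

    def __init__(self, records: Sequence[ProteinRecord], sigma: float = 0.0,
                 seed: int = 0, embed_dim: int = 1024):
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        self.sigma = sigma
        self.seed = seed
        self.embed_dim = embed_dim
        self.provider = HashEmbeddingProvider(embed_dim, seed)
        self._cache: dict[str, np.ndarray] = {}

    def raw_pssm(self, record: ProteinRecord) -> np.ndarray:
        """Raw log-odds: one-hot-derived +/- PSSM_SCALE/2, plus N(0, sigma)."""
        rng = _record_rng(self.seed, record.id + "|pssm")
        one_hot = np.zeros((len(record.sequence), 20))
        for i, aa in enumerate(record.sequence):
            j = AA_ALPHABET.find(aa)
            if j >= 0:
                one_hot[i, j] = 1.0
        raw = PSSM_SCALE * one_hot - PSSM_SCALE / 2
        if self.sigma > 0:
            raw = raw + rng.normal(0.0, self.sigma, raw.shape)
        return raw

    def ss_states(self, record: ProteinRecord) -> list[str]:
        rng = _record_rng(self.seed, record.id + "|ss")
        idx = rng.choice(len(_SS_CODES), size=len(record.sequence), p=_SS_PROBS)
        return [str(_SS_CODES[i]) for i in idx]

    def features(self, record: ProteinRecord) -> np.ndarray:
        """Raw L x (51+E) matrix, aligned to the sequence; cached per protein."""
        cached = self._cache.get(record.id)
        if cached is not None and cached.shape[0] == len(record.sequence):
            return cached
        pssm = expit(self.raw_pssm(record))
        bundles = assemble_bundles(
            record, pssm, self.ss_states(record), self.provider(record)
        )
        matrix = bundles_to_matrix(bundles)
        self._cache[record.id] = matrix
        return matrix


def synth_feature_source(
    records: Sequence[ProteinRecord], sigma: float = 0.0, seed: int = 0,
    embed_dim: int = 1024,
) -> SynthFeatureSource:
    return SynthFeatureSource(records, sigma=sigma, seed=seed, embed_dim=embed_dim)


# -- corpus export in the parsed dialects ------------------------------------


def _write_pssm_file(path: Path, record: ProteinRecord, raw: np.ndarray) -> None:
    """PSI-BLAST ``-out_ascii_pssm`` dialect (log-odds rounded to integers)."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted "
                 "observed percentages rounded down\n")
        fh.write("            " + "".join(f"{aa:>3}" for aa in AA_ALPHABET) * 2 + "\n")
        for i, aa in enumerate(record.sequence):
            ints = "".join(f"{int(round(x)):4d}" for x in raw[i])
            pcts = "".join(f"{0:4d}" for _ in range(20))
            fh.write(f"{i + 1:5d} {aa} {ints} {pcts}  0.00 0.00\n")
        fh.write("\n")


def _write_dssp_file(path: Path, record: ProteinRecord, states: Sequence[str]) -> None:
    """Classic DSSP text dialect (state code in column 17, 1-based)."""
    with open(path, "w") as fh:
        fh.write("==== Secondary Structure Definition ====\n")
        fh.write("  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n")
        for i, (aa, ss) in enumerate(zip(record.sequence, states)):
            fh.write(f"{i + 1:5d}{i + 1:5d} A {aa}  {ss}   0   0    0\n")


def write_corpus(
    out_dir,
    records: Sequence[ProteinRecord],
    source: SynthFeatureSource,
    plant_log: Optional[Sequence[Sequence[int]]] = None,
) -> None:
    """Write FASTA + labels + per-protein PSSM/DSSP/embedding files.

    Every file uses the exact dialect :mod:`hanppis.io_features` parses,
    so a written corpus can be read back through the standard loaders.
    """
    out = Path(out_dir)
    for sub in ("pssm", "dssp", "emb"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    with open(out / "proteins.fasta", "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
    with open(out / "labels.txt", "w") as fh:
        for rec in records:
            bits = "".join(str(int(b)) for b in rec.labels)
            fh.write(f"{rec.id} {bits}\n")
    if plant_log is not None:
        with open(out / "plants.txt", "w") as fh:
            for rec, starts in zip(records, plant_log):
                fh.write(f"{rec.id} {','.join(map(str, starts)) or '-'}\n")
    for rec in records:
        _write_pssm_file(out / "pssm" / f"{rec.id}.pssm", rec, source.raw_pssm(rec))
        _write_dssp_file(out / "dssp" / f"{rec.id}.dssp", rec, source.ss_states(rec))
        np.savetxt(out / "emb" / f"{rec.id}.tsv", source.provider(rec), fmt="%.17g")
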