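"""Residue-level feature encoding and the file formats that feed it.

Each residue of a protein is described by six feature blocks, concatenated
in a fixed order into a "raw" vector (the trainable embedding projection
happens later, inside the model):

====================  =====  =======================================================
block                 width  source
====================  =====  =======================================================
``one_hot``           20     indicator over the 20 canonical amino acids
``pssm``              20     PSI-BLAST log-odds, squashed by the logistic function
``ss9``               9      8-state secondary structure one-hot + availability flag
``hydropathy``        1      Kyte-Doolittle free-energy-of-transfer scale
``rel_pos``           1      1-based position / protein length, in (0, 1]
``embedding``         E      per-residue language-model embedding (default E=1024)
====================  =====  =======================================================

PSSM and secondary structure come from PSI-BLAST ASCII PSSM files and
classic DSSP output respectively; running those programs is out of scope,
their outputs are parsed.  The embedding source is pluggable: a
file-backed provider reads precomputed L x E tables, and a deterministic
hash-seeded provider stands in when no precomputed embeddings exist.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from scipy.special import expit

__all__ = [
    "AA_ALPHABET",
    "SS_STATES",
    "KYTE_DOOLITTLE",
    "ProteinRecord",
    "ResidueFeatureBundle",
    "FormatError",
    "read_fasta",
    "read_labels",
    "one_hot_encode",
    "parse_pssm",
    "encode_secondary_structure",
    "parse_dssp",
    "hydropathy",
    "position_feature",
    "HashEmbeddingProvider",
    "FileEmbeddingProvider",
    "get_embedding",
    "assemble_bundles",
    "bundles_to_matrix",
    "raw_block_slices",
    "raw_width",
    "FileFeatureSource",
]

#: Canonical amino-acid alphabet fixing the one-hot (and PSSM column) order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: DSSP 8-state codes with an explicit one-hot slot; anything else ("other
#: states", including the DSSP blank for coil) falls in slot 7.
SS_STATES = "GHIBETS"
_SS_INDEX = {s: i for i, s in enumerate(SS_STATES)}

#: Kyte-Doolittle hydropathy scale (free energy of water->organic-solvent
#: transfer, dimensionless index; positive = hydrophobic).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


class FormatError(ValueError):
    """A parsed file violates its expected dialect."""


@dataclass
class ProteinRecord:
    """A protein sequence with optional per-residue interaction-site labels."""

    id: str
    sequence: str
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if len(self.labels) != len(self.sequence):
                raise FormatError(
                    f"record {self.id!r}: {len(self.labels)} labels for "
                    f"{len(self.sequence)} residues"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise FormatError(f"record {self.id!r}: labels must be 0/1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ResidueFeatureBundle:
    """The six raw feature blocks for one residue, pre-projection."""

    one_hot: np.ndarray
    pssm: np.ndarray
    ss9: np.ndarray
    hydropathy: float
    rel_pos: float
    embedding: np.ndarray

    def raw_vector(self) -> np.ndarray:
        """Concatenate the blocks in the fixed order (width 51 + E)."""
        return np.concatenate(
            [
                self.one_hot,
                self.pssm,
                self.ss9,
                [self.hydropathy],
                [self.rel_pos],
                self.embedding,
            ]
        )


def raw_block_slices(embed_dim: int = 1024) -> dict[str, slice]:
    """Column ranges of each block within the raw (pre-projection) vector."""
    return {
        "one_hot": slice(0, 20),
        "pssm": slice(20, 40),
        "ss9": slice(40, 49),
        "hydropathy": slice(49, 50),
        "rel_pos": slice(50, 51),
        "embedding": slice(51, 51 + embed_dim),
    }


def raw_width(embed_dim: int = 1024) -> int:
    return 51 + embed_dim


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def read_labels(path) -> dict[str, np.ndarray]:
    """Parse a two-column ``id  0/1-string`` label file."""
    labels: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'id 0/1-string'")
            pid, bits = parts
            if pid in labels:
                raise FormatError(f"{path}:{lineno}: duplicate id {pid!r}")
            if set(bits) - {"0", "1"}:
                raise FormatError(
                    f"{path}:{lineno}: label string for {pid!r} contains "
                    f"characters outside 0/1"
                )
            labels[pid] = np.fromiter((int(b) for b in bits), dtype=np.int8)
    return labels


def one_hot_encode(residue: str) -> np.ndarray:
    """20-d indicator; nonstandard residues (X, B, Z, U, O, ...) map to zeros."""
    v = np.zeros(20)
    idx = _AA_INDEX.get(residue)
    if idx is not None:
        v[idx] = 1.0
    return v


def parse_pssm(path, expected_length: int, raw: bool = False) -> np.ndarray:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into an L x 20 matrix.

    The first 20 numeric columns (the log-odds block, in PSI-BLAST column
    order) are extracted; unless ``raw`` is set, each value x is squashed
    by the logistic map 1/(1+exp(-x)) so entries lie in (0, 1).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 22:
                continue
            if not parts[0].isdigit() or len(parts[1]) != 1 or not parts[1].isalpha():
                continue
            try:
                values = [float(x) for x in parts[2:22]]
            except ValueError as err:
                raise FormatError(f"{path}: malformed PSSM row {line!r}") from err
            rows.append(values)
    matrix = np.asarray(rows, dtype=np.float64)
    if len(rows) != expected_length:
        raise FormatError(
            f"{path}: {len(rows)} PSSM rows for expected length {expected_length}"
        )
    return matrix if raw else expit(matrix)


def encode_secondary_structure(state: Optional[str]) -> np.ndarray:
    """9-d encoding: one-hot over (G,H,I,B,E,T,S,other) + availability flag.

    ``state=None`` means the residue is absent from the DSSP output; the
    whole vector is zero.  Any known-but-unlisted code (DSSP blank, '-',
    'C', ...) goes to the "other" slot with the flag set.
    """
    v = np.zeros(9)
    if state is None:
        return v
    v[_SS_INDEX.get(state, 7)] = 1.0
    v[8] = 1.0
    return v


def parse_dssp(path, record: ProteinRecord) -> list[Optional[str]]:
    """Extract per-residue secondary-structure codes from classic DSSP output.

    Data rows follow the ``#  RESIDUE`` header; the state code sits in
    column 17 (1-based).  Rows are aligned to the sequence by the DSSP
    residue number; residues with no row get ``None``; chain-break rows
    ('!') are skipped.
    """
    states: list[Optional[str]] = [None] * len(record.sequence)
    in_data = False
    n_rows = 0
    with open(path) as fh:
        for line in fh:
            if not in_data:
                if line.lstrip().startswith("#  RESIDUE"):
                    in_data = True
                continue
            if len(line) < 17 or line[13] == "!":
                continue
            try:
                resnum = int(line[5:10])
            except ValueError:
                continue
            if not 1 <= resnum <= len(record.sequence):
                raise FormatError(
                    f"{path}: residue number {resnum} outside sequence "
                    f"{record.id!r} (length {len(record.sequence)})"
                )
            code = line[16]
            states[resnum - 1] = code
            n_rows += 1
    if not in_data:
        raise FormatError(f"{path}: no '#  RESIDUE' header line")
    if n_rows == 0:
        raise FormatError(f"{path}: no data rows")
    return states


def hydropathy(residue: str, scale: Optional[dict] = None) -> float:
    """Hydropathy of one residue; unknown residues are neutral (0.0)."""
    return (scale or KYTE_DOOLITTLE).get(residue, 0.0)


def position_feature(position: int, length: int) -> float:
    """Relative location ``position/length`` for a 1-based position, in (0,1]."""
    if not 1 <= position <= length:
        raise ValueError(f"position {position} out of range 1..{length}")
    return position / length


class HashEmbeddingProvider:
    """Deterministic per-residue embeddings from a hash of (residue, seed).

    A stand-in for precomputed language-model embeddings: each residue
    type maps to a fixed pseudo-random vector in [-1, 1]^E, so identical
    sequences always receive bit-identical matrices.
    """

    def __init__(self, dim: int = 1024, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def _vector(self, residue: str) -> np.ndarray:
        v = self._cache.get(residue)
        if v is None:
            digest = hashlib.sha256(f"{residue}|{self.seed}".encode()).digest()
            rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
            v = rng.uniform(-1.0, 1.0, self.dim)
            self._cache[residue] = v
        return v

    def __call__(self, record: ProteinRecord) -> np.ndarray:
        if not record.sequence:
            raise ValueError("empty sequence")
        return np.stack([self._vector(aa) for aa in record.sequence])


class FileEmbeddingProvider:
    """Per-protein L x E embedding tables stored as whitespace-delimited text."""

    def __init__(self, directory, dim: int = 1024, suffix: str = ".tsv"):
        self.directory = Path(directory)
        self.dim = dim
        self.suffix = suffix

    def __call__(self, record: ProteinRecord) -> np.ndarray:
        path = self.directory / f"{record.id}{self.suffix}"
        matrix = np.atleast_2d(np.loadtxt(path))
        if matrix.shape != (len(record.sequence), self.dim):
            raise FormatError(
                f"{path}: embedding shape {matrix.shape}, expected "
                f"({len(record.sequence)}, {self.dim})"
            )
        return matrix


def get_embedding(provider, record: ProteinRecord) -> np.ndarray:
    """Fetch the L x E embedding matrix for ``record`` from ``provider``."""
    return provider(record)


def assemble_bundles(
    record: ProteinRecord,
    pssm: np.ndarray,
    ss_states: Sequence[Optional[str]],
    embedding: np.ndarray,
) -> list[ResidueFeatureBundle]:
    """Combine the per-residue feature blocks, aligned to the sequence."""
    L = len(record.sequence)
    if pssm.shape[0] != L:
        raise ValueError(f"PSSM has {pssm.shape[0]} rows for {L} residues")
    if len(ss_states) != L:
        raise ValueError(f"{len(ss_states)} SS states for {L} residues")
    if embedding.shape[0] != L:
        raise ValueError(f"embedding has {embedding.shape[0]} rows for {L} residues")
    bundles = []
    for i, aa in enumerate(record.sequence):
        bundles.append(
            ResidueFeatureBundle(
                one_hot=one_hot_encode(aa),
                pssm=np.asarray(pssm[i], dtype=np.float64),
                ss9=encode_secondary_structure(ss_states[i]),
                hydropathy=hydropathy(aa),
                rel_pos=position_feature(i + 1, L),
                embedding=np.asarray(embedding[i], dtype=np.float64),
            )
        )
    return bundles


def bundles_to_matrix(bundles: Sequence[ResidueFeatureBundle]) -> np.ndarray:
    """Stack raw bundle vectors into an L x (51+E) matrix."""
    return np.stack([b.raw_vector() for b in bundles])


@dataclass
class FileFeatureSource:
    """Feature source backed by per-protein PSSM / DSSP / embedding files.

    Any directory may be ``None``; the corresponding block then falls back
    to a neutral default (PSSM of logistic(0)=0.5, secondary structure
    "absent", hash-provider embeddings), mirroring the behaviour on
    datasets where an upstream tool was never run.
    """

    pssm_dir: Optional[Path] = None
    dssp_dir: Optional[Path] = None
    embedding_provider: object = None
    embed_dim: int = 1024
    seed: int = 0
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.embedding_provider is None:
            self.embedding_provider = HashEmbeddingProvider(self.embed_dim, self.seed)

    def features(self, record: ProteinRecord) -> np.ndarray:
        """Raw L x (51+E) feature matrix for one protein."""
        cached = self._cache.get(record.id)
        if cached is not None and cached.shape[0] == len(record.sequence):
            return cached
        L = len(record.sequence)
        if self.pssm_dir is not None:
            pssm = parse_pssm(Path(self.pssm_dir) / f"{record.id}.pssm", L)
        else:
            pssm = np.full((L, 20), 0.5)
        if self.dssp_dir is not None:
            ss = parse_dssp(Path(self.dssp_dir) / f"{record.id}.dssp", record)
        else:
            ss = [None] * L
        emb = get_embedding(self.embedding_provider, record)
        matrix = bundles_to_matrix(assemble_bundles(record, pssm, ss, emb))
        self._cache[record.id] = matrix
        return matrix
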