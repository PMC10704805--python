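"""Per-protein feature sources and the symmetric pair combiner.

Three per-protein representations are supported: amino-acid composition
(AAC, 20 monomer frequencies), dipeptide composition (DPC, 400
overlapping 2-mer frequencies), and externally computed embedding tables
(e.g. 1280-dim mean-pooled protein-language-model vectors) loaded from a
keyed-vector file. A pair of proteins is combined into a single vector
by the Hadamard (elementwise) product, which is symmetric in member
order — the model can therefore not learn an artifactual pair-order
bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: Row-major dipeptide order over the alphabetical amino-acid alphabet.
DIPEPTIDES = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
_DP_INDEX = {dp: i for i, dp in enumerate(DIPEPTIDES)}


@dataclass(frozen=True)
class FeatureVector:
    """A dense per-protein feature vector with its source tag."""

    values: np.ndarray
    source: str

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("feature vector must be 1-D and nonempty")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)


def aac(sequence: str) -> FeatureVector:
    """Amino-acid composition: 20 per-residue frequencies.

    Frequencies are over the alphabetical one-letter alphabet; residues
    outside the 20 standard letters (e.g. 'X') are excluded from both
    numerator and denominator, so the components sum to 1 whenever at
    least one standard residue is present.
    """
    if not sequence:
        raise ValueError("empty sequence")
    counts = np.zeros(20)
    for ch in sequence.upper():
        i = _AA_INDEX.get(ch)
        if i is not None:
            counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no standard amino acids")
    return FeatureVector(counts / total, "aac")


def dpc(sequence: str) -> FeatureVector:
    """Dipeptide composition: 400 overlapping 2-mer frequencies.

    The denominator is the number of valid dipeptides (L-1 when all
    residues are standard); windows touching a non-standard residue are
    dropped from numerator and denominator alike.
    """
    if len(sequence) < 2:
        raise ValueError("dpc requires sequence length >= 2")
    seq = sequence.upper()
    counts = np.zeros(400)
    for i in range(len(seq) - 1):
        j = _DP_INDEX.get(seq[i : i + 2])
        if j is not None:
            counts[j] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no standard dipeptides")
    return FeatureVector(counts / total, "dpc")


def mean_pool(residue_matrix: np.ndarray) -> FeatureVector:
    """Average an L x D per-residue matrix over the residue axis.

    This is the pooling contract used to turn a language model's final
    hidden layer into one fixed-length vector per protein.
    """
    m = np.asarray(residue_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
        raise ValueError("residue matrix must be a nonempty L x D matrix")
    return FeatureVector(m.mean(axis=0), "embedding:mean_pool")


class EmbeddingTable:
    """Keyed per-protein dense vectors with a single fixed dimensionality."""

    def __init__(self, entries: Mapping[str, np.ndarray], name: str = "embedding"):
        if not entries:
            raise ValueError("embedding table is empty")
        self.name = name
        self._entries: dict[str, np.ndarray] = {}
        dim: int | None = None
        for pid, vec in entries.items():
            v = np.asarray(vec, dtype=float)
            if v.ndim != 1:
                raise ValueError(f"vector for {pid!r} is not 1-D")
            if dim is None:
                dim = v.shape[0]
            elif v.shape[0] != dim:
                raise ValueError(
                    f"ragged vector length for {pid!r}: {v.shape[0]} != {dim}"
                )
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in vector for {pid!r}")
            if pid in self._entries:
                raise ValueError(f"duplicate protein id {pid!r}")
            self._entries[pid] = v
        assert dim is not None
        self.dim = dim

    def __contains__(self, pid: str) -> bool:
        return pid in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def ids(self) -> list[str]:
        return list(self._entries)

    def vector(self, pid: str) -> np.ndarray:
        try:
            return self._entries[pid]
        except KeyError:
            raise KeyError(f"no embedding for protein {pid!r}") from None

    def save(self, path: str | Path) -> None:
        """Write the table; .h5/.hdf5 suffix selects HDF5, else TSV."""
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            with h5py.File(path, "w") as fh:
                for pid, vec in self._entries.items():
                    fh.create_dataset(pid, data=vec)
        else:
            with open(path, "w") as fh:
                for pid, vec in self._entries.items():
                    fh.write(pid + "\t" + "\t".join(repr(float(x)) for x in vec) + "\n")


def load_embeddings(
    path: str | Path, expected_dim: int | None = None
) -> EmbeddingTable:
    """Load a keyed-vector file (HDF5 dataset-per-protein, or TSV rows of
    id followed by D floats). A dimensionality contract can be enforced
    with expected_dim."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    entries: dict[str, np.ndarray] = {}
    if h5py.is_hdf5(str(path)):
        with h5py.File(path, "r") as fh:
            for pid in fh:
                entries[pid] = np.asarray(fh[pid][()], dtype=float)
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: no vector values")
                pid = parts[0]
                if pid in entries:
                    raise ValueError(f"duplicate protein id {pid!r}")
                entries[pid] = np.array([float(x) for x in parts[1:]])
    table = EmbeddingTable(entries, name=path.stem)
    if expected_dim is not None and table.dim != expected_dim:
        raise ValueError(
            f"embedding dimension mismatch: expected {expected_dim}, "
            f"file has {table.dim}"
        )
    return table


class SequenceEncoder:
    """Adapter presenting aac/dpc over a sequence dict as a feature source."""

    def __init__(self, sequences: Mapping[str, str], kind: str = "aac"):
        if kind not in ("aac", "dpc"):
            raise ValueError(f"unknown encoder kind {kind!r}")
        self._sequences = dict(sequences)
        self._encode = aac if kind == "aac" else dpc
        self.kind = kind
        self.dim = 20 if kind == "aac" else 400

    def __contains__(self, pid: str) -> bool:
        return pid in self._sequences

    def vector(self, pid: str) -> np.ndarray:
        try:
            seq = self._sequences[pid]
        except KeyError:
            raise KeyError(f"no sequence for protein {pid!r}") from None
        return self._encode(seq).values


@dataclass(frozen=True)
class PairFeature:
    """The Hadamard (elementwise) product of two member feature vectors."""

    values: np.ndarray

    @property
    def dim(self) -> int:
        return self.values.shape[0]


def pair_feature(pair: tuple[str, str], source) -> PairFeature:
    """Hadamard-combine the two member vectors of a protein pair.

    ``source`` is any object exposing ``vector(id) -> ndarray`` (an
    EmbeddingTable or SequenceEncoder). Symmetric in member order.
    """
    u = source.vector(pair[0])
    v = source.vector(pair[1])
    return PairFeature(u * v)


def pair_feature_matrix(pairs, source) -> np.ndarray:
    """Stack pair features for a list of (idA, idB) pairs into an N x D
    matrix, in input order."""
    return np.array([pair_feature((a, b), source).values for a, b in pairs])
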