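"""Synthetic latent-factor interaction world.

Stands in for a curated interactome download so the full pipeline can be
exercised and stress-tested offline. Each protein i carries a latent
vector z_i ~ N(0, I_k); the probability that proteins i and j interact
is sigmoid(signal * <z_i, z_j> + bias), with the bias calibrated so the
overall positive prevalence matches 1/(ratio+1). Observed embeddings are
a fixed random linear map of z plus Gaussian noise, so a model fed
embedding Hadamard products can in principle recover the bilinear ground
truth — signal controls how deterministic interactions are, noise_sd how
corrupted the observed features are, and signal = 0 yields a world where
interactions are independent of the embeddings (no learnable skill).

Random plausible amino-acid sequences are attached to every protein for
encoder and identity-filter testing; they carry no interaction signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .features import EmbeddingTable
from .ingest import PairSet, ProteinRecord


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Size, geometry and signal strength of the generated world."""

    n_proteins: int = 500
    latent_dim: int = 8
    embed_dim: int = 32
    signal: float = 4.0
    noise_sd: float = 0.6
    seed: int = 0
    n_positives: int = 1000
    ratio: int = 10
    seq_len_range: tuple[int, int] = (50, 250)

    def __post_init__(self) -> None:
        if self.n_proteins < 4:
            raise ValueError("need at least 4 proteins")
        if self.latent_dim > self.embed_dim:
            raise ValueError("latent_dim must be <= embed_dim")
        if self.n_positives < 1:
            raise ValueError("n_positives must be >= 1")
        if self.signal < 0 or self.noise_sd < 0:
            raise ValueError("signal and noise_sd must be >= 0")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")


@dataclass
class SyntheticWorld:
    """Generated proteins, embeddings and the ground-truth interactions."""

    config: SyntheticWorldConfig
    proteins: list[ProteinRecord]
    embeddings: EmbeddingTable
    latent: np.ndarray  # n x k
    probabilities: np.ndarray  # n x n symmetric interaction probabilities
    labels: np.ndarray  # n x n symmetric boolean ground truth
    bias: float

    def protein_id(self, i: int) -> str:
        return self.proteins[i].id

    def interacts(self, id_a: str, id_b: str) -> bool:
        i = self._index[id_a]
        j = self._index[id_b]
        return bool(self.labels[i, j])

    def __post_init__(self) -> None:
        self._index = {rec.id: i for i, rec in enumerate(self.proteins)}


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_sequences(
    n: int, rng: np.random.Generator, len_range: tuple[int, int]
) -> list[str]:
    lo, hi = len_range
    lengths = rng.integers(lo, hi + 1, size=n)
    return ["".join(rng.choice(_AA, size=L)) for L in lengths]


def _calibrate_bias(dots: np.ndarray, signal: float, target: float) -> float:
    """Solve mean(sigmoid(signal*dots + b)) = target for the bias b."""

    def prevalence_gap(b: float) -> float:
        return float(np.mean(expit(signal * dots + b))) - target

    lo, hi = -50.0, 50.0
    if prevalence_gap(lo) > 0 or prevalence_gap(hi) < 0:
        raise ValueError(
            f"cannot calibrate prevalence {target} with signal {signal}"
        )
    return float(brentq(prevalence_gap, lo, hi, xtol=1e-10))


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a fully seed-reproducible synthetic interaction world."""
    rng = np.random.default_rng(config.seed)
    n, k, d = config.n_proteins, config.latent_dim, config.embed_dim

    z = rng.standard_normal((n, k))
    dots = z @ z.T
    iu = np.triu_indices(n, k=1)
    target = 1.0 / (config.ratio + 1)
    bias = _calibrate_bias(dots[iu], config.signal, target)

    probs = expit(config.signal * dots + bias)
    np.fill_diagonal(probs, 0.0)  # self-interactions excluded from the world
    labels = np.zeros((n, n), dtype=bool)
    draws = rng.random(iu[0].size) < probs[iu]
    labels[iu] = draws
    labels |= labels.T

    projection = rng.standard_normal((k, d)) / np.sqrt(k)
    embeddings_matrix = z @ projection + config.noise_sd * rng.standard_normal((n, d))

    width = len(str(n - 1))
    ids = [f"SP{i:0{width}d}" for i in range(n)]
    sequences = _random_sequences(n, rng, config.seq_len_range)
    proteins = [ProteinRecord(pid, seq) for pid, seq in zip(ids, sequences)]
    table = EmbeddingTable(
        {pid: embeddings_matrix[i] for i, pid in enumerate(ids)},
        name="synthetic",
    )
    return SyntheticWorld(
        config=config,
        proteins=proteins,
        embeddings=table,
        latent=z,
        probabilities=probs,
        labels=labels,
        bias=bias,
    )


def sample_labeled_pairs(
    world: SyntheticWorld,
    n_positives: int | None = None,
    ratio: int | None = None,
    seed: int | None = None,
) -> PairSet:
    """Draw a labeled benchmark: n_positives interacting pairs and
    ratio x n_positives non-interacting pairs, uniformly without
    replacement from the world's ground truth."""
    cfg = world.config
    n_positives = cfg.n_positives if n_positives is None else n_positives
    ratio = cfg.ratio if ratio is None else ratio
    seed = cfg.seed if seed is None else seed

    n = cfg.n_proteins
    iu = np.triu_indices(n, k=1)
    pos_mask = world.labels[iu]
    pos_idx = np.flatnonzero(pos_mask)
    neg_idx = np.flatnonzero(~pos_mask)
    n_negatives = ratio * n_positives
    if pos_idx.size < n_positives:
        raise ValueError(
            f"world has only {pos_idx.size} interacting pairs, "
            f"need {n_positives}"
        )
    if neg_idx.size < n_negatives:
        raise ValueError(
            f"world has only {neg_idx.size} non-interacting pairs, "
            f"need {n_negatives}"
        )
    rng = np.random.default_rng(seed)
    chosen_pos = rng.choice(pos_idx, size=n_positives, replace=False)
    chosen_neg = rng.choice(neg_idx, size=n_negatives, replace=False)

    pairs = PairSet()
    for flat, label in ((chosen_pos, 1), (chosen_neg, 0)):
        for m in np.sort(flat):
            i, j = iu[0][m], iu[1][m]
            pairs.add(world.protein_id(i), world.protein_id(j), label)
    return pairs
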