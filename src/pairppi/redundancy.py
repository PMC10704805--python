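"""Negative-sample construction with sequence-identity filtering.

Presumed non-interacting pairs are built by random pairing over a
candidate pool that excludes (1) every protein that occurs in a positive
pair, (2) proteins sharing >= 40% global-alignment identity with any
positive-set protein, and (3) within-pool redundancy at the same cutoff.
Negatives are drawn uniformly without replacement at a configured
positive:negative ratio (default 1:10), never colliding with a positive
pair, and reproducibly under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .ingest import PairSet, ProteinRecord, canonical_pair

# Global-alignment scoring used for all identity computations:
# match +1, mismatch 0, gap open -10, gap extend -0.5.
MATCH_SCORE = 1.0
MISMATCH_SCORE = 0.0
GAP_OPEN = -10.0
GAP_EXTEND = -0.5


@dataclass(frozen=True)
class NegativeSamplingConfig:
    """Ratio, identity cutoff and seed for negative-set construction."""

    ratio: int = 10
    identity_cutoff: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if not 0.0 < self.identity_cutoff <= 1.0:
            raise ValueError("identity_cutoff must lie in (0, 1]")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity of two amino-acid sequences.

    Identity = identical aligned positions / alignment length (columns,
    gaps included), computed on an optimal global alignment under the
    module's scoring scheme. Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    alignment = _ALIGNER.align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def build_candidate_pool(
    all_proteins: Sequence[ProteinRecord],
    positives: PairSet,
    config: NegativeSamplingConfig | None = None,
) -> list[ProteinRecord]:
    """Filter the proteome down to the negative-sampling candidate pool.

    Three sequential filters: drop proteins occurring in positive pairs;
    drop proteins with identity >= cutoff to any positive-set protein;
    greedily remove within-pool redundancy at the same cutoff (longest
    sequences considered first, CD-HIT style: a protein is kept unless it
    hits >= cutoff identity against an already-kept one).
    """
    config = config or NegativeSamplingConfig()
    cutoff = config.identity_cutoff
    positive_ids = positives.proteins()
    by_id = {rec.id: rec for rec in all_proteins}

    # step 1: remove positive-set proteins
    remaining = [rec for rec in all_proteins if rec.id not in positive_ids]
    positive_seqs = [by_id[pid].sequence for pid in positive_ids if pid in by_id]

    # step 2: remove homologs of positive-set proteins
    nonhomologous = [
        rec
        for rec in remaining
        if all(pairwise_identity(rec.sequence, ps) < cutoff for ps in positive_seqs)
    ]

    # step 3: greedy redundancy reduction, descending length (ties by id)
    ordered = sorted(nonhomologous, key=lambda r: (-len(r.sequence), r.id))
    kept: list[ProteinRecord] = []
    for rec in ordered:
        if all(
            pairwise_identity(rec.sequence, k.sequence) < cutoff for k in kept
        ):
            kept.append(rec)
    return kept


def sample_negatives(
    positives: PairSet,
    eligible_proteins: Iterable[str],
    config: NegativeSamplingConfig | None = None,
) -> PairSet:
    """Draw ratio x |positives| non-positive unordered pairs, uniformly.

    The pairing universe is eligible_proteins plus the positive-set
    proteins (the candidate pool is mixed back with interacting proteins
    before random pairing). Self-pairs are excluded; no sampled pair may
    equal a positive pair; sampling is without replacement and
    deterministic under the configured seed.
    """
    config = config or NegativeSamplingConfig()
    n_needed = config.ratio * len(positives)
    universe = sorted(set(eligible_proteins) | positives.proteins())
    n = len(universe)
    total_pairs = n * (n - 1) // 2
    n_positive_in_universe = sum(
        1 for a, b in positives.pairs if a != b  # self-positives not in universe
    )
    available = total_pairs - n_positive_in_universe
    if available < n_needed:
        raise ValueError(
            f"negative-pair space too small: need {n_needed}, "
            f"only {available} distinct non-positive pairs available "
            f"(shortfall {n_needed - available})"
        )

    rng = np.random.default_rng(config.seed)
    negatives = PairSet()
    chosen: set[tuple[str, str]] = set()
    if n_needed > 0.5 * available:
        # dense regime: enumerate, mask out positives, sample exactly
        all_keys = [
            canonical_pair(universe[i], universe[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        candidates = [k for k in all_keys if k not in positives.labels]
        idx = rng.choice(len(candidates), size=n_needed, replace=False)
        for i in sorted(idx):
            negatives.add(*candidates[i], 0)
        return negatives
    # sparse regime: rejection sampling over index pairs
    while len(chosen) < n_needed:
        batch = max(1024, int(1.2 * (n_needed - len(chosen))))
        ii = rng.integers(0, n, size=batch)
        jj = rng.integers(0, n, size=batch)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            key = canonical_pair(universe[i], universe[j])
            if key in positives.labels or key in chosen:
                continue
            chosen.add(key)
            if len(chosen) == n_needed:
                break
    for key in sorted(chosen):
        negatives.add(*key, 0)
    return negatives
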