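"""Park-Marcotte pair-input benchmark splitting.

Pair-input learning leaks information through shared pair members: a
random split of *pairs* puts most test pairs' proteins in the training
set, overestimating performance. The remedy is to hold out *proteins*:
pairs with both members among training proteins form C1 (train), pairs
with exactly one held-out member form C2, and pairs with both members
held out form C3 — the stratum measuring extrapolation to entirely
novel proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ingest import PairSet

C1, C2, C3 = "C1", "C2", "C3"

#: Default held-out protein fraction. With proteins held out independently
#: at rate h, expected pair shares are (1-h)^2 / 2h(1-h) / h^2 for
#: C1/C2/C3; h = 0.32 gives ~46%/44%/10%, matching the observed positive
#: split proportions 3519/3404/806 of the benchmark design.
DEFAULT_HELDOUT_FRACTION = 0.32


@dataclass(frozen=True)
class ProteinGrouping:
    """Disjoint train/held-out protein sets covering the pair universe."""

    train_proteins: frozenset[str]
    heldout_proteins: frozenset[str]
    seed: int
    heldout_fraction: float

    def __post_init__(self) -> None:
        if self.train_proteins & self.heldout_proteins:
            raise ValueError("train and heldout protein sets must be disjoint")

    def write_manifest(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "heldout_fraction": self.heldout_fraction,
            "assignment": {
                **{p: "train" for p in sorted(self.train_proteins)},
                **{p: "heldout" for p in sorted(self.heldout_proteins)},
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def read_manifest(cls, path: str | Path) -> "ProteinGrouping":
        doc = json.loads(Path(path).read_text())
        train = frozenset(
            p for p, g in doc["assignment"].items() if g == "train"
        )
        heldout = frozenset(
            p for p, g in doc["assignment"].items() if g == "heldout"
        )
        return cls(train, heldout, doc["seed"], doc["heldout_fraction"])


@dataclass
class BenchmarkSplit:
    """Labeled pairs partitioned into C1/C2/C3 plus the inducing grouping."""

    c1: PairSet
    c2: PairSet
    c3: PairSet
    grouping: ProteinGrouping

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.c1.write_tsv(directory / "c1.tsv")
        self.c2.write_tsv(directory / "c2.tsv")
        self.c3.write_tsv(directory / "c3.tsv")
        self.grouping.write_manifest(directory / "grouping.json")


def assign_grouping(
    protein_ids: set[str] | frozenset[str],
    heldout_fraction: float = DEFAULT_HELDOUT_FRACTION,
    seed: int = 0,
) -> ProteinGrouping:
    """Uniformly draw a held-out protein set of size round(fraction * n)."""
    if not 0.0 < heldout_fraction < 1.0:
        raise ValueError("heldout_fraction must lie in (0, 1)")
    if len(protein_ids) < 2:
        raise ValueError("need at least 2 proteins to split")
    ordered = sorted(protein_ids)
    n_heldout = round(heldout_fraction * len(ordered))
    if n_heldout == 0 or n_heldout == len(ordered):
        raise ValueError(
            f"heldout_fraction {heldout_fraction} yields an empty "
            f"{'heldout' if n_heldout == 0 else 'train'} set for "
            f"{len(ordered)} proteins"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ordered), size=n_heldout, replace=False)
    heldout = frozenset(ordered[i] for i in idx)
    train = frozenset(ordered) - heldout
    return ProteinGrouping(train, heldout, seed, heldout_fraction)


def classify_pair(pair: tuple[str, str], grouping: ProteinGrouping) -> str:
    """C1 if both members are train proteins, C2 if exactly one is held
    out, C3 if both are held out. A self-pair follows its single protein."""
    for p in pair:
        if (
            p not in grouping.train_proteins
            and p not in grouping.heldout_proteins
        ):
            raise KeyError(f"protein {p!r} is not assigned in the grouping")
    a, b = pair
    if a == b:
        return C1 if a in grouping.train_proteins else C3
    n_held = (a in grouping.heldout_proteins) + (b in grouping.heldout_proteins)
    return (C1, C2, C3)[n_held]


def build_split(
    positives: PairSet,
    negatives: PairSet,
    heldout_fraction: float = DEFAULT_HELDOUT_FRACTION,
    ratio: int = 10,
    seed: int = 0,
) -> BenchmarkSplit:
    """Split labeled pairs into C1/C2/C3 and enforce the class ratio.

    One protein grouping is drawn over every protein occurring in the
    positives or negatives; each pair is classified by held-out
    membership; then, within each of C1/C2/C3, negatives are
    down-sampled (seeded, uniform) to exactly ratio x that split's
    positive count. Positives are never down-sampled.
    """
    overlap = set(positives.labels) & set(negatives.labels)
    if overlap:
        raise ValueError(f"pairs labeled both positive and negative: {sorted(overlap)[:3]}")
    proteins = positives.proteins() | negatives.proteins()
    grouping = assign_grouping(proteins, heldout_fraction, seed)

    pos_by = {C1: [], C2: [], C3: []}
    neg_by = {C1: [], C2: [], C3: []}
    for a, b, _ in positives:
        pos_by[classify_pair((a, b), grouping)].append((a, b))
    for a, b, _ in negatives:
        neg_by[classify_pair((a, b), grouping)].append((a, b))

    rng = np.random.default_rng(seed + 1)
    out: dict[str, PairSet] = {}
    for split in (C1, C2, C3):
        n_pos = len(pos_by[split])
        n_neg_needed = ratio * n_pos
        candidates = neg_by[split]
        if len(candidates) < n_neg_needed:
            raise ValueError(
                f"{split}: {n_pos} positives need {n_neg_needed} negatives "
                f"but only {len(candidates)} fall in this split "
                f"(shortfall {n_neg_needed - len(candidates)})"
            )
        keep_idx = rng.choice(len(candidates), size=n_neg_needed, replace=False)
        ps = PairSet()
        for a, b in pos_by[split]:
            ps.add(a, b, 1)
        for i in sorted(keep_idx):
            ps.add(*candidates[i], 0)
        out[split] = ps
    return BenchmarkSplit(out[C1], out[C2], out[C3], grouping)
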