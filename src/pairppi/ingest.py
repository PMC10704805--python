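"""Sequence and interaction-evidence ingestion.

Reads protein sequences (FASTA) and interaction evidence (tab-separated
PSI-MI-TAB-like records), applies the positive-set quality filters —
interaction type restricted to direct interaction / physical association
and a minimum MIscore confidence — and canonicalizes protein pairs so
that (A, B) and (B, A) collapse to one unordered pair.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

DEFAULT_MISCORE_MIN = 0.45
DEFAULT_ALLOWED_TYPES = frozenset({"direct interaction", "physical association"})

_MISCORE_RE = re.compile(r"intact-miscore:\s*([0-9.eE+-]+)")
# psi-mi:"MI:0915"(physical association) or MI:0915(physical association)
_PAREN_TERM_RE = re.compile(r"\(([^()]*)\)\s*$")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier and its amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"sequence for {self.id!r} contains whitespace")


@dataclass(frozen=True)
class InteractionEvidence:
    """One parsed evidence line: two interactors, a type term, a confidence."""

    id_a: str
    id_b: str
    interaction_type: str
    miscore: float

    def __post_init__(self) -> None:
        if not self.id_a or not self.id_b:
            raise ValueError("interactor ids must be nonempty")
        if not 0.0 <= self.miscore <= 1.0:
            raise ValueError(f"miscore {self.miscore} outside [0, 1]")


@dataclass(frozen=True)
class FilterConfig:
    """Positive-set filter: minimum MIscore and allowed interaction types."""

    miscore_min: float = DEFAULT_MISCORE_MIN
    allowed_types: frozenset[str] = DEFAULT_ALLOWED_TYPES

    def __post_init__(self) -> None:
        if not 0.0 <= self.miscore_min <= 1.0:
            raise ValueError("miscore_min must lie in [0, 1]")
        if not self.allowed_types:
            raise ValueError("allowed_types must be nonempty")


def canonical_pair(id_a: str, id_b: str) -> tuple[str, str]:
    """Order-free canonical form of a protein pair: lexicographically sorted."""
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


@dataclass
class PairSet:
    """Unordered protein-ID pairs with binary labels (1 interaction, 0 not).

    Pairs are stored canonicalized; inserting a duplicate unordered pair
    is an error regardless of member order.
    """

    labels: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, id_a: str, id_b: str, label: int) -> None:
        if label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {label!r}")
        key = canonical_pair(id_a, id_b)
        if key in self.labels:
            raise ValueError(f"duplicate pair {key}")
        self.labels[key] = label

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[tuple[str, str, int]]:
        for (a, b), y in self.labels.items():
            yield a, b, y

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.labels)

    def proteins(self) -> set[str]:
        """All protein IDs occurring in any pair."""
        out: set[str] = set()
        for a, b in self.labels:
            out.add(a)
            out.add(b)
        return out

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, str, int]]) -> "PairSet":
        ps = cls()
        for a, b, y in items:
            ps.add(a, b, y)
        return ps

    def subset(self, keys: Iterable[tuple[str, str]]) -> "PairSet":
        out = PairSet()
        for key in keys:
            a, b = canonical_pair(*key)
            out.labels[(a, b)] = self.labels[(a, b)]
        return out

    def write_tsv(self, path: str | Path) -> None:
        """Write as TSV: idA <TAB> idB <TAB> label."""
        with open(path, "w") as fh:
            for a, b, y in self:
                fh.write(f"{a}\t{b}\t{y}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PairSet":
        ps = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 3 tab-separated fields, "
                        f"got {len(parts)}"
                    )
                ps.add(parts[0], parts[1], int(parts[2]))
        return ps


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The ID is the header token up to the first whitespace; sequences are
    uppercased. Duplicate IDs and empty sequences are rejected with the
    offending header named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA entry {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, seq))
    return records


def normalize_type_term(raw: str) -> str:
    """Normalize an interaction-type field to its human-readable term.

    Accepts a bare term ("physical association"), or a PSI-MI-styled field
    such as 'psi-mi:"MI:0915"(physical association)'; matching is
    case-insensitive on the parenthesised term when one is present.
    """
    m = _PAREN_TERM_RE.search(raw.strip())
    term = m.group(1) if m else raw
    return term.strip().strip('"').lower()


def parse_miscore(confidence_field: str) -> float:
    """Extract the intact-miscore value; rows without one score 0."""
    m = _MISCORE_RE.search(confidence_field)
    if not m:
        return 0.0
    try:
        value = float(m.group(1))
    except ValueError:
        return 0.0
    return min(max(value, 0.0), 1.0)


def _strip_db_prefix(identifier: str) -> str:
    # MITAB interactor ids look like "uniprotkb:P49597"
    _, _, rest = identifier.partition(":")
    return rest if rest else identifier


def read_evidence(
    path: str | Path, format: str = "auto"
) -> list[InteractionEvidence]:
    """Read interaction evidence from a tab-separated file.

    Two dialects are supported:

    * ``minimal`` — 4 columns: idA, idB, interaction type, confidence.
    * ``mitab27`` — full PSI-MI TAB 2.7; the same four fields are taken
      by column index (1, 2, 12, 15, one-based) and database prefixes
      are stripped from the interactor IDs.

    ``auto`` picks mitab27 for rows with >= 15 columns. Malformed lines
    are skipped with a logged warning carrying the line number. The
    miscore is parsed from an ``intact-miscore:<float>`` token in the
    confidence column; rows without one get miscore 0.
    """
    if format not in ("auto", "minimal", "mitab27"):
        raise ValueError(f"unknown evidence format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    out: list[InteractionEvidence] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            fmt = format
            if fmt == "auto":
                fmt = "mitab27" if len(cols) >= 15 else "minimal"
            try:
                if fmt == "mitab27":
                    if len(cols) < 15:
                        raise ValueError("fewer than 15 columns")
                    id_a = _strip_db_prefix(cols[0])
                    id_b = _strip_db_prefix(cols[1])
                    itype = normalize_type_term(cols[11])
                    miscore = parse_miscore(cols[14])
                else:
                    if len(cols) != 4:
                        raise ValueError(f"expected 4 columns, got {len(cols)}")
                    id_a, id_b = cols[0], cols[1]
                    itype = normalize_type_term(cols[2])
                    miscore = parse_miscore(cols[3])
                out.append(InteractionEvidence(id_a, id_b, itype, miscore))
            except ValueError as exc:
                logger.warning("%s:%d: skipping malformed line (%s)", path, lineno, exc)
    return out


def filter_positives(
    evidence: Iterable[InteractionEvidence],
    config: FilterConfig | None = None,
) -> PairSet:
    """Apply the positive-set filters and return canonical labeled pairs.

    Evidence is retained when its interaction type is in the allowed set
    and its MIscore is >= the threshold (an evidence line scoring exactly
    at the threshold is kept: the removal rule is strictly-below).
    Surviving pairs are canonicalized unordered, duplicates collapsed,
    and all labeled 1.
    """
    config = config or FilterConfig()
    allowed = {normalize_type_term(t) for t in config.allowed_types}
    ps = PairSet()
    for ev in evidence:
        if normalize_type_term(ev.interaction_type) not in allowed:
            continue
        if ev.miscore < config.miscore_min:
            continue
        key = canonical_pair(ev.id_a, ev.id_b)
        ps.labels.setdefault(key, 1)
    return ps


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
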