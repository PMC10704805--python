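import numpy as np
import pytest

from pairppi import (
    NegativeSamplingConfig,
    PairSet,
    ProteinRecord,
    build_candidate_pool,
    pairwise_identity,
    sample_negatives,
)
from pairppi.redundancy import GAP_EXTEND, GAP_OPEN, MATCH_SCORE, MISMATCH_SCORE


def enumerate_alignment_identities(a: str, b: str) -> tuple[float, set[float]]:
    """Brute-force global-alignment oracle.

    Enumerates every global alignment path (match/mismatch, gap-in-a,
    gap-in-b) of two short sequences, scores them with the module's
    affine scheme (a gap of length k costs open + (k-1)*extend), and
    returns the optimal score plus the set of identity fractions
    achieved by optimal alignments.
    """
    best: dict[str, object] = {"score": -np.inf, "identities": set()}

    def walk(i, j, score, ident, length, prev):
        if i == len(a) and j == len(b):
            if score > best["score"]:
                best["score"] = score
                best["identities"] = {ident / length}
            elif score == best["score"]:
                best["identities"].add(ident / length)
            return
        if i < len(a) and j < len(b):
            s = MATCH_SCORE if a[i] == b[j] else MISMATCH_SCORE
            walk(i + 1, j + 1, score + s, ident + (a[i] == b[j]), length + 1, "M")
        if i < len(a):
            g = GAP_EXTEND if prev == "A" else GAP_OPEN
            walk(i + 1, j, score + g, ident, length + 1, "A")
        if j < len(b):
            g = GAP_EXTEND if prev == "B" else GAP_OPEN
            walk(i, j + 1, score + g, ident, length + 1, "B")

    walk(0, 0, 0.0, 0, 0, None)
    return best["score"], best["identities"]


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDE", "ACDE") == 1.0

    def test_disjoint_sequences(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_single_substitution(self):
        # unique optimal alignment: 5 identities over 6 columns
        assert pairwise_identity("ACDEFG", "ACDKFG") == pytest.approx(5 / 6)

    def test_symmetry(self):
        a, b = "MKWVTFISLLF", "MKWVTFIS"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACDE")

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_alignment_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        alphabet = np.array(list("ACDE"))
        a = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
        b = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
        _, identities = enumerate_alignment_identities(a, b)
        observed = pairwise_identity(a, b)
        assert any(observed == pytest.approx(x) for x in identities)


def _records(seqs):
    return [ProteinRecord(f"p{i}", s) for i, s in enumerate(seqs)]


class TestBuildCandidatePool:
    def test_pool_of_positive_proteins_only_is_emptied(self):
        recs = _records(["ACDEACDE", "MKWVTFIS"])
        positives = PairSet.from_items([(recs[0].id, recs[1].id, 1)])
        assert build_candidate_pool(recs, positives) == []

    def test_survivors_satisfy_exhaustive_identity_constraints(self):
        rng = np.random.default_rng(42)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seqs = ["".join(rng.choice(alphabet, size=30)) for _ in range(12)]
        # make p2 a homolog of the positive protein p0, p5 a copy of p4
        seqs[2] = seqs[0][:25] + seqs[2][25:]
        seqs[5] = seqs[4]
        recs = _records(seqs)
        positives = PairSet.from_items([("p0", "p1", 1)])
        config = NegativeSamplingConfig(identity_cutoff=0.40)
        pool = build_candidate_pool(recs, positives, config)
        pool_ids = {r.id for r in pool}

        by_id = {r.id: r for r in recs}
        # oracle: re-check every constraint exhaustively
        assert not pool_ids & {"p0", "p1"}
        for rid in pool_ids:
            for pos_id in ("p0", "p1"):
                assert (
                    pairwise_identity(by_id[rid].sequence, by_id[pos_id].sequence)
                    < 0.40
                )
        pool_list = sorted(pool_ids)
        for i, r1 in enumerate(pool_list):
            for r2 in pool_list[i + 1 :]:
                assert (
                    pairwise_identity(by_id[r1].sequence, by_id[r2].sequence) < 0.40
                )
        # the planted homolog and the duplicate cannot both survive
        assert "p2" not in pool_ids
        assert not {"p4", "p5"} <= pool_ids


class TestSampleNegatives:
    def test_exact_count_and_exclusions(self):
        positives = PairSet.from_items([("P1", "P2", 1)])
        config = NegativeSamplingConfig(ratio=2, seed=3)
        negatives = sample_negatives(positives, ["P1", "P2", "P3", "P4"], config)
        assert len(negatives) == 2
        assert ("P1", "P2") not in negatives
        assert all(label == 0 for _, _, label in negatives)
        assert all(a != b for a, b, _ in negatives)

    def test_deterministic_under_seed(self):
        positives = PairSet.from_items([(f"P{i}", f"P{i+1}", 1) for i in range(0, 20, 2)])
        pool = [f"Q{i}" for i in range(30)]
        config = NegativeSamplingConfig(ratio=10, seed=11)
        first = sample_negatives(positives, pool, config)
        second = sample_negatives(positives, pool, config)
        assert first.labels == second.labels

    def test_disjoint_from_positives_always(self):
        rng = np.random.default_rng(5)
        ids = [f"P{i}" for i in range(12)]
        positives = PairSet()
        for i in range(0, 12, 2):
            positives.add(ids[i], ids[i + 1], 1)
        negatives = sample_negatives(
            positives, ids, NegativeSamplingConfig(ratio=3, seed=int(rng.integers(1 << 30)))
        )
        assert not set(negatives.labels) & set(positives.labels)
        assert len(negatives) == 3 * len(positives)

    def test_shortfall_reported(self):
        positives = PairSet.from_items([("P1", "P2", 1)])
        with pytest.raises(ValueError, match="shortfall"):
            sample_negatives(positives, ["P1", "P2"], NegativeSamplingConfig(ratio=2))
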