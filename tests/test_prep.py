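import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnafam import (
    LabeledDataset,
    NoiseSpec,
    SequenceRecord,
    SplitConfig,
    add_boundary_noise,
    dinucleotide_counts,
    dinucleotide_shuffle,
    normalized_similarity,
    screen_length_predictable,
    similarity_aware_split,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestNormalizedSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 1.0),
            ("AAAA", "TTTT", 0.0),
            ("AAAA", "AA", 0.5),  # overhang counts as mismatch, normalize by longer
            ("ACGT", "ACGA", 0.75),
        ],
    )
    def test_examples(self, a, b, expected):
        assert normalized_similarity(a, b) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(dna, dna)
    def test_symmetric_and_bounded(self, a, b):
        s = normalized_similarity(a, b)
        assert s == pytest.approx(normalized_similarity(b, a))
        assert 0.0 <= s <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalized_similarity("", "ACGT")


def make_class(label, seqs):
    return [SequenceRecord(f"{label}_{i}", s, label) for i, s in enumerate(seqs)]


class TestSimilarityAwareSplit:
    def test_dissimilar_class_splits_near_fractions(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(100)]
        ds = LabeledDataset(make_class("fam", seqs))
        result = similarity_aware_split(ds, SplitConfig(seed=0))
        assert len(result.train) == 84
        assert len(result.validation) == 8
        assert len(result.test) == 8

    def test_identical_copies_all_forced_to_train(self):
        ds = LabeledDataset(make_class("fam", ["ACGTACGT"] * 100))
        result = similarity_aware_split(ds, SplitConfig(seed=0))
        assert len(result.train) == 100
        assert len(result.validation) == 0 and len(result.test) == 0

    def test_threshold_one_gives_plain_stratified_split(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(50)]
        ds = LabeledDataset(make_class("fam", seqs))
        result = similarity_aware_split(ds, SplitConfig(similarity_threshold=1.0, seed=1))
        assert len(result.validation) == 4 and len(result.test) == 4

    def test_partition_is_exact(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(60)]
        ds = LabeledDataset(make_class("a", seqs[:30]) + make_class("b", seqs[30:]))
        result = similarity_aware_split(ds, SplitConfig(seed=3))
        ids = sorted(result.train.ids() + result.validation.ids() + result.test.ids())
        assert ids == sorted(ds.ids())

    def test_constraint_audit_holds(self, rng):
        # planted near-duplicates: pairs differing in one position
        base = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(30)]
        seqs = []
        for s in base:
            seqs.append(s)
            seqs.append("A" + s[1:])
        ds = LabeledDataset(make_class("fam", seqs))
        result = similarity_aware_split(ds, SplitConfig(seed=5))
        train_seqs = result.train.sequences()
        for part in (result.validation, result.test):
            for rec in part:
                sims = [normalized_similarity(rec.sequence, t) for t in train_seqs]
                assert max(sims) < 0.50

    def test_tiny_class_goes_to_train_with_warning(self):
        ds = LabeledDataset(make_class("tiny", ["ACGT", "TTTT"]))
        with pytest.warns(UserWarning, match="fewer than 3"):
            result = similarity_aware_split(ds, SplitConfig(seed=0))
        assert len(result.train) == 2

    def test_deterministic_under_seed(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(40)]
        ds = LabeledDataset(make_class("fam", seqs))
        r1 = similarity_aware_split(ds, SplitConfig(seed=9))
        r2 = similarity_aware_split(ds, SplitConfig(seed=9))
        assert r1.train.ids() == r2.train.ids()
        assert r1.test.ids() == r2.test.ids()


class TestBoundaryNoise:
    def test_zero_percent_is_identity(self):
        rec = SequenceRecord("x", "ACGTACGT")
        assert add_boundary_noise(rec, NoiseSpec(percent=0, seed=1)).sequence == rec.sequence

    @pytest.mark.parametrize("percent", [0, 25, 50, 75, 100, 125, 150, 175, 200])
    def test_output_length_exact(self, percent):
        rec = SequenceRecord("x", "ACGT" * 25)  # 100 nt
        out = add_boundary_noise(rec, NoiseSpec(percent=percent, seed=2))
        assert len(out.sequence) == 100 + round(percent / 100 * 100)

    def test_rounding_half_up(self):
        rec = SequenceRecord("x", "ACGTACGTAC")  # 10 nt, 25% -> 2.5 -> 3
        out = add_boundary_noise(rec, NoiseSpec(percent=25, seed=0))
        assert len(out.sequence) == 13

    def test_original_sequence_intact_and_contiguous(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=80))
        out = add_boundary_noise(SequenceRecord("x", seq), NoiseSpec(percent=150, seed=3))
        assert seq in out.sequence

    def test_negative_percent_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(percent=-5)

    def test_flank_dinucleotide_frequencies_match_source(self):
        # biased source composition; pooled flank dinucleotide frequencies
        # must track the source's within +/-0.05
        seq = ("AAAC" * 10 + "GGAT" * 10 + "AACC" * 5)  # 100 nt, biased
        rec = SequenceRecord("x", seq)
        src = dinucleotide_counts(seq)
        src_total = sum(src.values())
        pooled: dict[str, int] = {}
        for i in range(1000):
            out = add_boundary_noise(rec, NoiseSpec(percent=100, seed=i)).sequence
            start = out.index(seq)
            for flank in (out[:start], out[start + len(seq):]):
                for a, b in zip(flank, flank[1:]):
                    pooled[a + b] = pooled.get(a + b, 0) + 1
        total = sum(pooled.values())
        for d in set(src) | set(pooled):
            f_src = src.get(d, 0) / src_total
            f_flank = pooled.get(d, 0) / total
            assert abs(f_src - f_flank) <= 0.05, d


def enumerate_shuffles(seq):
    """Brute-force oracle: all arrangements with the same dinucleotide
    multiset and the same endpoints."""
    target = sorted(a + b for a, b in zip(seq, seq[1:]))
    out = set()
    for perm in itertools.permutations(seq):
        cand = "".join(perm)
        if cand[0] == seq[0] and cand[-1] == seq[-1]:
            if sorted(a + b for a, b in zip(cand, cand[1:])) == target:
                out.add(cand)
    return out


class TestDinucleotideShuffle:
    def test_unique_arrangement_returned_verbatim(self):
        assert dinucleotide_shuffle("AAAA", seed=0) == "AAAA"

    def test_counts_and_endpoints_conserved(self, random_sequences):
        for seed, seq in enumerate(random_sequences(200, 20, 200)):
            out = dinucleotide_shuffle(seq, seed=seed)
            assert dinucleotide_counts(out) == dinucleotide_counts(seq)
            assert out[0] == seq[0] and out[-1] == seq[-1]
            assert len(out) == len(seq)

    def test_outputs_lie_in_exhaustive_enumeration(self, rng):
        for length in range(2, 7):
            for _ in range(5):
                seq = "".join(rng.choice(list("ACGT"), size=length))
                valid = enumerate_shuffles(seq)
                produced = {dinucleotide_shuffle(seq, seed=s) for s in range(30)}
                assert produced <= valid

    def test_multiple_arrangements_reachable(self):
        seq = "ACGTACGTACGTAAGGTTCC"
        outs = {dinucleotide_shuffle(seq, seed=s) for s in range(50)}
        assert len(outs) > 1

    def test_record_wrapper_keeps_id_and_label(self):
        rec = SequenceRecord("x", "ACGTAC", "fam")
        out = dinucleotide_shuffle(rec, seed=1)
        assert out.id == "x" and out.label == "fam"

    def test_deterministic_under_seed(self):
        seq = "ACGGTTACCAGT"
        assert dinucleotide_shuffle(seq, seed=4) == dinucleotide_shuffle(seq, seed=4)


class TestLengthScreen:
    def _dataset(self, rng, specs):
        records = []
        for label, mean, spread, n in specs:
            for i in range(n):
                L = max(5, int(rng.normal(mean, spread)))
                records.append(
                    SequenceRecord(f"{label}_{i}", "".join(rng.choice(list("ACGT"), size=L)), label)
                )
        return LabeledDataset(records)

    def test_length_separable_class_flagged(self, rng):
        ds = self._dataset(
            rng, [("short", 50, 2, 60), ("a", 100, 30, 60), ("b", 110, 30, 60)]
        )
        flagged, table = screen_length_predictable(ds, seed=0)
        assert "short" in flagged
        assert set(table["label"]) == {"short", "a", "b"}

    def test_shared_length_distribution_flags_nothing(self, rng):
        ds = self._dataset(rng, [("a", 100, 30, 60), ("b", 100, 30, 60)])
        flagged, _ = screen_length_predictable(ds, seed=0)
        assert flagged == []

    def test_unattainable_cutoff_flags_nothing(self, rng):
        ds = self._dataset(rng, [("short", 50, 2, 60), ("long", 150, 2, 60)])
        flagged, _ = screen_length_predictable(ds, f1_cutoff=1.01, seed=0)
        assert flagged == []

    def test_requires_two_classes(self, rng):
        ds = self._dataset(rng, [("only", 100, 10, 30)])
        with pytest.raises(ValueError):
            screen_length_predictable(ds)
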