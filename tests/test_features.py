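import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytomir.duplex_align import Duplex, align_duplex
from phytomir.features import (
    FEATURE_NAMES,
    accessibility,
    au_content,
    extract_features,
    featurize_record,
    frame_to_examples,
    examples_to_frame,
    longest_consecutive_pairings,
    me_motif,
    me_reference_profile,
)
from phytomir.io_formats import DataError, InteractionRecord, MiRNA, Transcript
from phytomir.synthetic import reverse_complement

from .oracles import pairing_counts_oracle

MIR21 = "UGGAGUGUGACAAUGGUGUUU"  # 21 nt

pairing_vectors = st.lists(st.sampled_from([0, 1, 2]), min_size=16, max_size=30).map(
    lambda v: np.array(v, dtype=np.int8)
)


class TestLongestRun:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([1, 1, 0, 1, 1, 1], (3, 4)),
            ([0] * 21, (0, 0)),
            ([1] * 5, (5, 1)),
            ([1, 0, 1], (1, 1)),  # tie -> smallest start
        ],
    )
    def test_examples(self, vec, expected):
        assert longest_consecutive_pairings(np.array(vec)) == expected

    def test_empty_vector_is_error(self):
        with pytest.raises(DataError):
            longest_consecutive_pairings(np.array([]))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(pairing_vectors)
    def test_agrees_with_exhaustive_enumeration(self, vec):
        oracle = pairing_counts_oracle([bool(p) for p in vec])
        assert longest_consecutive_pairings(vec) == (
            oracle["longest_run"],
            oracle["longest_run_pos"],
        )

    def test_agrees_with_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            vec = rng.integers(0, 3, size=rng.integers(16, 31)).astype(np.int8)
            oracle = pairing_counts_oracle([bool(p) for p in vec])
            assert longest_consecutive_pairings(vec) == (
                oracle["longest_run"],
                oracle["longest_run_pos"],
            )


class TestAuContent:
    @pytest.mark.parametrize(
        "site,expected", [("AUAUAU", 1.0), ("GCGC", 0.0), ("AUGC", 0.5)]
    )
    def test_flankless(self, site, expected):
        assert au_content(site, 1, len(site), flank=0) == expected

    def test_flank_clipped_at_ends(self):
        # site = GC at positions 3-4 of AAGCAA; flank 10 clips to whole sequence
        assert au_content("AAGCAA", 3, 4, flank=10) == pytest.approx(4 / 6)


class TestAccessibility:
    def test_unstructured_context_is_fully_accessible(self):
        seq = "A" * 120
        assert accessibility(seq, 50, 70) == pytest.approx(1.0, abs=1e-6)

    def test_site_inside_stable_hairpin_is_inaccessible(self):
        stem = "G" * 10 + "C" * 10
        hairpin = stem + "AAAA" + reverse_complement(stem)
        seq = "A" * 30 + hairpin + "A" * 30
        # site = the first stem arm, buried in the 20-bp helix
        assert accessibility(seq, 31, 50) < 0.5

    def test_invariant_to_sequence_beyond_context(self):
        rng = np.random.default_rng(8)
        core = "".join(rng.choice(list("ACGU"), size=200))
        left = "".join(rng.choice(list("ACGU"), size=50))
        right = "".join(rng.choice(list("ACGU"), size=50))
        a = accessibility(core, 90, 110, context=70)
        b = accessibility(left + core + right, 140, 160, context=70)
        assert a == pytest.approx(b, abs=1e-12)


class TestMeMotif:
    def test_profile_self_match_is_one(self):
        prof = me_reference_profile(21)
        pairing = prof.astype(np.int8)
        assert me_motif(pairing) == 1.0

    def test_profile_complement_is_zero(self):
        prof = me_reference_profile(21)
        pairing = (~prof).astype(np.int8)
        assert me_motif(pairing) == 0.0

    def test_equals_hamming_similarity(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            L = int(rng.integers(16, 31))
            vec = rng.integers(0, 3, size=L).astype(np.int8)
            prof = me_reference_profile(L)
            hamming = int(np.sum((vec != 0) != prof))
            assert me_motif(vec) == pytest.approx((L - hamming) / L)


class TestExtractFeatures:
    def _perfect_example(self):
        mirna = MiRNA(id="m", seq=MIR21)
        site = reverse_complement(MIR21)
        rng = np.random.default_rng(2)
        pad = "".join(rng.choice(list("ACGU"), size=100))
        tx = Transcript(id="t", seq=pad + site + pad)
        dup = align_duplex(MIR21, site, mirna_id="m", transcript_id="t", site_offset=100)
        return dup, mirna, tx

    def test_perfect_duplex_counts(self):
        dup, mirna, tx = self._perfect_example()
        fv = extract_features(dup, mirna, tx)
        assert fv.seed_match == 7
        assert fv.n_paired == 21
        assert fv.longest_run == 21
        assert fv.longest_run_pos == 1
        assert fv.n_paired_3p == 9  # positions 13-21
        assert fv.seed_minus_3p == -2
        assert fv.site_length == 21
        assert fv.folding_energy < 0

    def test_vector_has_exactly_11_features(self):
        dup, mirna, tx = self._perfect_example()
        fv = extract_features(dup, mirna, tx)
        assert len(FEATURE_NAMES) == 11
        assert fv.to_array().shape == (11,)

    def test_unpaired_duplex_zeroes_pairing_features(self):
        mirna = MiRNA(id="m", seq="A" * 21)
        tx = Transcript(id="t", seq="A" * 200)
        dup = align_duplex(mirna.seq, tx.seq[:40], mirna_id="m", transcript_id="t")
        fv = extract_features(dup, mirna, tx)
        assert fv.n_paired == 0
        assert fv.folding_energy == 0.0
        assert fv.seed_match == 0
        assert fv.seed_minus_3p == 0
        assert fv.longest_run_pos == 0

    def test_mismatched_ids_rejected(self):
        dup, mirna, tx = self._perfect_example()
        with pytest.raises(DataError):
            extract_features(dup, MiRNA(id="other", seq=MIR21), tx)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(pairing_vectors)
    def test_pairing_feature_identities(self, vec):
        from phytomir.features import pairing_features

        got = pairing_features(vec)
        assert got == pairing_counts_oracle([bool(p) for p in vec])
        assert got["seed_minus_3p"] == got["seed_match"] - got["n_paired_3p"]
        assert got["longest_run"] <= got["n_paired"] <= len(vec)

    def test_permuting_transcript_outside_windows_changes_nothing(self):
        rng = np.random.default_rng(3)
        mirna = MiRNA(id="m", seq=MIR21)
        site = reverse_complement(MIR21)
        pad = "".join(rng.choice(list("ACGU"), size=200))
        tx1 = Transcript(id="t", seq=pad + site + pad)
        # permute only the first 100 nt: beyond flank (10) and context (70)
        shuffled = "".join(rng.permutation(list(pad[:100]))) + pad[100:]
        tx2 = Transcript(id="t", seq=shuffled + site + pad)
        rec = InteractionRecord(
            mirna_id="m", transcript_id="t", site_start=201, site_end=221
        )
        fv1 = featurize_record(mirna, tx1, rec).features
        fv2 = featurize_record(mirna, tx2, rec).features
        assert fv1 == fv2


class TestFeatureFrameRoundTrip:
    def test_examples_survive_serialisation(self, small_examples):
        df = examples_to_frame(small_examples[:10])
        back = frame_to_examples(df)
        assert [e.features for e in back] == [e.features for e in small_examples[:10]]
        assert [e.label for e in back] == [e.label for e in small_examples[:10]]
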