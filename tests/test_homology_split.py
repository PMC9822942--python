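import numpy as np
import pytest

from phytomir.features import FeatureVector, LabeledExample
from phytomir.homology_split import (
    DatasetSplit,
    cluster_mirnas,
    make_split,
    pairwise_identity,
)
from phytomir.io_formats import DataError, MiRNA

from .oracles import nw_identity_oracle


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


def mutate(rng, seq, n_mut):
    s = list(seq)
    for p in rng.choice(len(s), size=n_mut, replace=False):
        s[p] = rng.choice([b for b in "ACGU" if b != s[p]])
    return "".join(s)


def make_example(mirna, site_length=21, salt=0.0):
    fv = FeatureVector(
        folding_energy=-20.0 - salt,
        seed_match=7,
        accessibility=0.5,
        au_content=0.5,
        me_motif=0.5,
        n_paired=18,
        site_length=site_length,
        longest_run=10,
        longest_run_pos=1,
        n_paired_3p=8,
        seed_minus_3p=-1,
    )
    return LabeledExample(
        mirna=mirna,
        transcript_id=f"t_{mirna.id}_{salt}",
        site_start=1,
        site_end=site_length,
        label="positive",
        features=fv,
    )


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGUACGUACGUACGUACGUA", "ACGUACGUACGUACGUACGUA") == 1.0

    def test_disjoint_alphabets(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a, b = random_rna(rng, 21), random_rna(rng, 23)
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_matches_needleman_wunsch_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = random_rna(rng, int(rng.integers(18, 25)))
            b = random_rna(rng, int(rng.integers(18, 25)))
            assert pairwise_identity(a, b) == pytest.approx(nw_identity_oracle(a, b))

    def test_point_mutations_give_expected_identity(self):
        rng = np.random.default_rng(2)
        seq = random_rna(rng, 20)
        mutated = mutate(rng, seq, 3)
        assert pairwise_identity(seq, mutated) >= 17 / 20

    def test_empty_sequence_is_error(self):
        with pytest.raises(DataError):
            pairwise_identity("", "ACGU")


class TestClustering:
    def test_identical_sequences_share_a_cluster(self):
        seqs = [MiRNA(id=f"m{i}", seq="ACGUACGUACGUACGUACGUA") for i in range(3)]
        assert len(cluster_mirnas(seqs, 0.7)) == 1

    def test_dissimilar_sequences_stay_singletons(self):
        mirnas = [
            MiRNA(id="a", seq="A" * 10 + "C" * 11),
            MiRNA(id="b", seq="G" * 10 + "U" * 11),
        ]
        assert len(cluster_mirnas(mirnas, 0.7)) == 2

    def test_planted_families_recovered(self):
        rng = np.random.default_rng(3)
        mirnas = []
        n_families = 5
        for f in range(n_families):
            seed_seq = random_rna(rng, 22)
            mirnas.append(MiRNA(id=f"fam{f}_seed", seq=seed_seq))
            for c in range(3):  # copies at ~86% identity
                mirnas.append(MiRNA(id=f"fam{f}_c{c}", seq=mutate(rng, seed_seq, 3)))
        clusters = cluster_mirnas(mirnas, 0.7)
        assert len(clusters) == n_families
        for cluster in clusters:
            families = {m.id.split("_")[0] for m in cluster}
            assert len(families) == 1


class TestMakeSplit:
    def _corpus(self, rng, n_train=12, n_test=5, homologous=0):
        test_mirnas = [
            MiRNA(id=f"test{i}", seq=random_rna(rng, 21), species="gma")
            for i in range(n_test)
        ]
        train_mirnas = [
            MiRNA(id=f"train{i}", seq=random_rna(rng, 21), species="osa")
            for i in range(n_train - homologous)
        ]
        for i in range(homologous):
            train_mirnas.append(
                MiRNA(
                    id=f"hom{i}",
                    seq=mutate(rng, test_mirnas[i % n_test].seq, 3),
                    species="osa",
                )
            )
        # distinct salt -> distinct feature vectors (dedup must not collapse them)
        examples = [
            make_example(m, salt=0.1 * i)
            for i, m in enumerate(train_mirnas + test_mirnas)
        ]
        return examples, train_mirnas, test_mirnas

    def test_no_homologs_keeps_all_training(self):
        rng = np.random.default_rng(4)
        examples, train_mirnas, _ = self._corpus(rng)
        split = make_split(examples, "gma")
        kept = {ex.mirna.id for ex in split.train}
        expected = {
            m.id
            for m in train_mirnas
            if all(
                pairwise_identity(m.seq, t.mirna.seq) < 0.7
                for t in examples
                if t.species == "gma"
            )
        }
        assert kept == expected

    def test_identical_mirna_is_excluded_from_training(self):
        rng = np.random.default_rng(5)
        examples, _, test_mirnas = self._corpus(rng)
        clone = MiRNA(id="clone", seq=test_mirnas[0].seq, species="osa")
        split = make_split(examples + [make_example(clone)], "gma")
        assert all(ex.mirna.id != "clone" for ex in split.train)
        assert split.n_train_removed_homology >= 1

    def test_homologous_examples_removed_and_audit_clean(self):
        rng = np.random.default_rng(6)
        examples, _, _ = self._corpus(rng, homologous=4)
        split = make_split(examples, "gma")
        assert split.n_train_removed_homology >= 4
        assert split.max_cross_identity() < 0.7

    def test_duplicate_test_features_removed(self):
        rng = np.random.default_rng(7)
        examples, _, test_mirnas = self._corpus(rng)
        dup = next(ex for ex in examples if ex.species == "gma")
        split = make_split(examples + [dup], "gma")
        assert split.n_test_removed_duplicates == 1
        keys = [ex.features.to_tuple() for ex in split.test]
        assert len(keys) == len(set(keys))

    def test_exclusion_list_drops_matching_test_examples(self):
        rng = np.random.default_rng(8)
        examples, _, test_mirnas = self._corpus(rng)
        split = make_split(examples, "gma", exclude_like=[test_mirnas[0].seq])
        assert split.n_test_removed_exclusion == 1
        assert all(ex.mirna.id != test_mirnas[0].id for ex in split.test)

    def test_absent_species_is_error(self):
        rng = np.random.default_rng(9)
        examples, _, _ = self._corpus(rng)
        with pytest.raises(DataError, match="zzz"):
            make_split(examples, "zzz")

    def test_homolog_removal_shrinks_training_monotonically(self):
        rng = np.random.default_rng(10)
        plain, _, _ = self._corpus(rng, homologous=0)
        rng = np.random.default_rng(10)
        seeded, _, _ = self._corpus(rng, homologous=4)
        assert len(make_split(seeded, "gma").train) <= len(make_split(plain, "gma").train)
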