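import numpy as np
import pytest

from phytomir.duplex_align import (
    UNPAIRED,
    WC,
    WOBBLE,
    Duplex,
    ScanParams,
    align_duplex,
    duplex_energy,
    scan_candidate_sites,
)
from phytomir.io_formats import DataError, MiRNA, Transcript
from phytomir.synthetic import reverse_complement

from .oracles import sw_score_oracle

MIR = "UGGAGUGUGACAAUGGUGUUUG"  # 22 nt


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestAlignDuplex:
    def test_perfect_complement_pairs_every_position(self):
        d = align_duplex(MIR, reverse_complement(MIR))
        assert d.n_paired == len(MIR)
        assert np.all(d.pairing == WC)
        assert d.alignment_score == 5.0 * len(MIR)
        assert (d.site_start, d.site_end) == (1, len(MIR))

    def test_gu_wobble_counts_as_paired(self):
        # site carries a U opposite miRNA position 15 (G) -> G:U wobble
        site = list(reverse_complement(MIR))
        mir_pos = 15
        assert MIR[mir_pos - 1] == "G"
        site[len(MIR) - mir_pos] = "U"
        d = align_duplex(MIR, "".join(site))
        assert d.pairing[mir_pos - 1] == WOBBLE
        assert d.n_paired == len(MIR)

    def test_wobble_disabled_leaves_position_unpaired(self):
        site = list(reverse_complement(MIR))
        mir_pos = 15
        site[len(MIR) - mir_pos] = "U"
        d = align_duplex(MIR, "".join(site), ScanParams(allow_wobble=False))
        assert d.pairing[mir_pos - 1] == UNPAIRED

    def test_antiparallel_site_mapping_is_monotone_decreasing(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = align_duplex(random_rna(rng, 21), random_rna(rng, 40))
            mapped = d.mirna_site_map[d.mirna_site_map > 0]
            assert np.all(np.diff(mapped) < 0)

    def test_non_acgu_rejected(self):
        with pytest.raises(DataError):
            align_duplex("ACGX", "ACGU")

    def test_score_matches_brute_force_dp(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            a = random_rna(rng, int(rng.integers(20, 25)))
            b = random_rna(rng, int(rng.integers(20, 25)))
            assert align_duplex(a, b).alignment_score == pytest.approx(
                sw_score_oracle(a, b)
            )

    def test_no_complementarity_gives_empty_duplex(self):
        d = align_duplex("A" * 21, "A" * 21)
        assert d.alignment_score == 0.0
        assert d.n_paired == 0
        assert d.energy == 0.0


class TestDuplexEnergy:
    def test_no_pairing_possible_is_zero(self):
        assert duplex_energy("AAAA", "AAAA") == 0.0

    def test_perfect_complement_is_strictly_stabler_than_mismatched(self):
        site = reverse_complement(MIR)
        mism = list(site)
        for k in (9, 10, 11):  # central mismatches
            mism[k] = "A" if site[k] != "A" else "C"
        assert duplex_energy(MIR, site) < duplex_energy(MIR, "".join(mism))

    def test_gc_stacks_are_stabler_than_au(self):
        assert duplex_energy("GGGGG", "CCCCC") < duplex_energy("AAAAA", "UUUUU")

    def test_energy_never_positive(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            assert duplex_energy(random_rna(rng, 21), random_rna(rng, 21)) <= 0.0


class TestScan:
    def _transcript_with_sites(self, rng, mirna_seq, starts0, length=500):
        seq = list(random_rna(rng, length))
        site = reverse_complement(mirna_seq)
        for s in starts0:
            seq[s : s + len(site)] = site
        return "".join(seq)

    def test_planted_site_recovered(self):
        rng = np.random.default_rng(1)
        tx = Transcript(id="t", seq=self._transcript_with_sites(rng, MIR, [100]))
        hits = scan_candidate_sites(MiRNA(id="m", seq=MIR), tx)
        assert len(hits) == 1
        h = hits[0]
        assert h.site_start <= 101 and h.site_end >= 100 + len(MIR)

    def test_poly_a_yields_nothing(self):
        hits = scan_candidate_sites(
            MiRNA(id="m", seq="A" * 21), Transcript(id="t", seq="A" * 300)
        )
        assert hits == []

    def test_two_distant_sites_reported_in_order(self):
        rng = np.random.default_rng(2)
        tx = Transcript(id="t", seq=self._transcript_with_sites(rng, MIR, [50, 200]))
        hits = scan_candidate_sites(MiRNA(id="m", seq=MIR), tx)
        assert len(hits) == 2
        assert hits[0].site_start < hits[1].site_start
        assert hits[0].site_end < hits[1].site_start  # non-overlapping

    def test_transcript_shorter_than_mirna_is_empty_not_error(self):
        hits = scan_candidate_sites(
            MiRNA(id="m", seq=MIR), Transcript(id="t", seq="ACGUACGUAC")
        )
        assert hits == []

    def test_padding_outside_site_does_not_change_score_or_energy(self):
        rng = np.random.default_rng(4)
        core = self._transcript_with_sites(rng, MIR, [60], length=150)
        padded = random_rna(rng, 80) + core + random_rna(rng, 80)
        h1 = scan_candidate_sites(MiRNA(id="m", seq=MIR), Transcript(id="t", seq=core))
        h2 = scan_candidate_sites(MiRNA(id="m", seq=MIR), Transcript(id="t", seq=padded))
        best1 = max(h1, key=lambda d: d.alignment_score)
        best2 = max(
            (d for d in h2 if abs(d.site_start - 80 - best1.site_start) < 5),
            key=lambda d: d.alignment_score,
        )
        assert best1.alignment_score == best2.alignment_score
        assert best1.energy == best2.energy

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        tx = Transcript(id="t", seq=self._transcript_with_sites(rng, MIR, [120]))
        m = MiRNA(id="m", seq=MIR)
        a = scan_candidate_sites(m, tx)
        b = scan_candidate_sites(m, tx)
        assert [(d.site_start, d.site_end, d.alignment_score, d.energy) for d in a] == [
            (d.site_start, d.site_end, d.alignment_score, d.energy) for d in b
        ]
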