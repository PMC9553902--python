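"""Seed-site scanning: canonical classes, bulged sponge sites, duplex scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spongescope.mre import (
    MIR16,
    Mirna,
    annotate_interactome,
    bulged_site_strings,
    canonical_site_strings,
    duplex_score,
    find_bulged_sites,
    find_canonical_sites,
    reverse_complement,
)
from spongescope.interactome import InteractomeCall
from spongescope.simulate import SitePlanEntry, simulate_transcripts


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,alphabet,expected",
        [
            ("AGCAGCA", "DNA", "TGCTGCT"),
            ("", "DNA", ""),
            ("AGCAGCA", "RNA", "UGCUGCU"),
            ("acgt", "DNA", "acgt"),
        ],
    )
    def test_examples(self, seq, alphabet, expected):
        assert reverse_complement(seq, alphabet) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=1000))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq, "DNA"), "DNA") == seq

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            reverse_complement("ACUT", "DNA")


class TestCanonicalStrings:
    def test_mir16_site_strings(self):
        # derived by reverse complement of the miR-16 seed (positions 2-7/2-8)
        s = canonical_site_strings(MIR16)
        assert s == {
            "6mer": "GCTGCT",
            "7mer-m8": "TGCTGCT",
            "7mer-A1": "GCTGCTA",
            "8mer": "TGCTGCTA",
        }

    def test_brute_force_pairing_of_8mer(self):
        # every base of rc(2-8) must Watson-Crick pair with the miRNA, antiparallel
        s = canonical_site_strings(MIR16)["8mer"]
        core = s[:-1]  # drop the A1 adenosine
        mir = MIR16.sequence[1:8]  # positions 2-8
        pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        for m, t in zip(mir, core.replace("T", "U")[::-1]):
            assert (m, t) in pairs

    def test_self_complementary_seed(self):
        # seed GCGCGC: rc equals itself, so the 6mer equals positions 2-7
        mirna = Mirna("pal", "AGCGCGCA", seed_start=2, seed_end=8)
        assert canonical_site_strings(mirna)["6mer"] == "GCGCGC"

    def test_seed_window_validation(self):
        with pytest.raises(ValueError, match="seed window"):
            Mirna("bad", "UAGC", seed_start=2, seed_end=8)


class TestCanonicalScan:
    def test_longest_type_wins_at_a_locus(self):
        hits = find_canonical_sites("AATGCTGCTAAA", MIR16, "tx")
        assert [(h.start, h.end, h.site_type) for h in hits] == [(2, 10, "8mer")]

    def test_no_gc_sequence_has_no_hits(self):
        assert find_canonical_sites("ATATATATATAT", MIR16) == []

    def test_tandem_overlaps_match_bruteforce(self):
        seq = "GCTGCTGCTGCT"
        got = {(h.start, h.end, h.site_type) for h in find_canonical_sites(seq, MIR16)}
        assert got == _naive_canonical(seq)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=300))
    def test_equals_naive_enumerator_on_random_sequences(self, seq):
        got = {(h.start, h.end, h.site_type) for h in find_canonical_sites(seq, MIR16)}
        assert got == _naive_canonical(seq)

    def test_u_t_interchangeable(self):
        seq = "AATGCTGCTAAAGCTGTCTAA"
        rna = seq.replace("T", "U")
        as_dna = [(h.start, h.end, h.site_type) for h in find_canonical_sites(seq, MIR16)]
        as_rna = [(h.start, h.end, h.site_type) for h in find_canonical_sites(rna, MIR16)]
        assert as_dna == as_rna
        bd = [(h.start, h.site_type) for h in find_bulged_sites(seq, MIR16)]
        br = [(h.start, h.site_type) for h in find_bulged_sites(rna, MIR16)]
        assert bd == br


def _naive_canonical(seq: str) -> set[tuple[int, int, str]]:
    """O(n*m) char-by-char enumerator with longest-type subsumption."""
    seq = seq.upper().replace("U", "T")
    strings = {
        "6mer": "GCTGCT", "7mer-m8": "TGCTGCT", "7mer-A1": "GCTGCTA", "8mer": "TGCTGCTA",
    }
    raw = []
    for stype, s in strings.items():
        for i in range(len(seq) - len(s) + 1):
            if all(seq[i + k] == s[k] for k in range(len(s))):
                raw.append((i, i + len(s), stype))
    return {
        (s, e, t)
        for (s, e, t) in raw
        if not any(e2 - s2 > e - s and s2 <= s and e <= e2 for (s2, e2, _) in raw)
    }


class TestBulgedScan:
    def test_inserted_t_at_position_5(self):
        hits = find_bulged_sites("AAGCTGTCTAA", MIR16, "tx")
        assert [(h.start, h.end, h.site_type, h.inserted_base) for h in hits] == [
            (2, 9, "bulged", "T")
        ]

    def test_inserted_c_not_allowed_by_default(self):
        assert find_bulged_sites("AAGCTGCCTAA", MIR16) == []

    def test_canonical_locus_not_reported_as_bulged(self):
        seq = "AAGCTGCTAA"  # perfect 6mer + A1
        assert [h.site_type for h in find_canonical_sites(seq, MIR16)] == ["7mer-A1"]
        assert find_bulged_sites(seq, MIR16) == []

    def test_all_allowed_bases(self):
        for base in "GTA":
            seq = f"AAGCTG{base}CTAA"
            hits = find_bulged_sites(seq, MIR16)
            assert len(hits) == 1 and hits[0].inserted_base == base

    def test_deleting_inserted_base_restores_canonical_6mer(self):
        plan = {"sponge": SitePlanEntry(n_transcripts=40, bulged_fraction=1.0)}
        seqs, _, _ = simulate_transcripts(40, 150, plan, rng_seed=9)
        six = canonical_site_strings(MIR16)["6mer"]
        n_hits = 0
        for tid, seq in seqs.items():
            for h in find_bulged_sites(seq, MIR16, tid):
                window = seq[h.start : h.end]
                restored = window[:4] + window[5:]  # default bulge position 5
                assert restored == six
                n_hits += 1
        assert n_hits >= 30

    def test_invalid_bulge_position(self):
        with pytest.raises(ValueError, match="bulge_position"):
            bulged_site_strings(MIR16, bulge_position=1)
        with pytest.raises(ValueError, match="bulge_position"):
            find_bulged_sites("AAGCTGTCTAA", MIR16, bulge_position=9)


class TestDuplexScore:
    def test_perfect_duplex_scores_twice_length(self):
        window = reverse_complement(MIR16.sequence, "RNA")
        assert duplex_score(MIR16, window) == 2 * len(MIR16.sequence)

    def test_nonpairing_window_scores_nonpositive(self):
        # poly-C cannot pair with any miR-16 base except G positions; use the
        # brute-force guarantee: score of an all-mismatch duplex is negative
        mirna = Mirna("toy", "AAAAAAAA", seed_start=2, seed_end=8)
        assert duplex_score(mirna, "CCCCCCCC") <= 0

    def test_canonical_beats_bulged_window(self):
        backbone = "TTTT{}TTTT"
        canonical = backbone.format(canonical_site_strings(MIR16)["8mer"])
        bulged = backbone.format(bulged_site_strings(MIR16)["T"])
        assert duplex_score(MIR16, canonical) > duplex_score(MIR16, bulged)

    def test_canonical_context_beats_scrambled_site(self):
        # site-focused windows (site +/- 3 nt), as scored by the scanner;
        # long flanks dilute discrimination because the best gapless offset
        # may ignore the site region entirely
        rng = np.random.default_rng(4)
        site = canonical_site_strings(MIR16)["8mer"]
        wins = 0
        n = 1000
        for _ in range(n):
            flank5 = "".join(rng.choice(list("ACGT"), 3))
            flank3 = "".join(rng.choice(list("ACGT"), 3))
            scrambled = site
            while scrambled == site:
                scrambled = "".join(rng.permutation(list(site)))
            s_can = duplex_score(MIR16, flank5 + site + flank3)
            s_scr = duplex_score(MIR16, flank5 + scrambled + flank3)
            wins += s_can > s_scr
        assert wins / n >= 0.95

    def test_wobble_counts_less_than_wc(self):
        # G:U wobble opposite miRNA position is worth +1, a WC pair +2
        mirna = Mirna("toy", "GGGGGGGG", seed_start=2, seed_end=8)
        wc = duplex_score(mirna, "CCCCCCCC", max_bulges=0)
        wobble = duplex_score(mirna, "TTTTTTTT", max_bulges=0)
        assert wc == 16 and wobble == 8

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            duplex_score(MIR16, "")


class TestAnnotate:
    def _calls(self, labels):
        return [
            InteractomeCall(f"G{i}", "stable", "none", None, None, lab)
            for i, lab in enumerate(labels)
        ]

    def test_planted_fractions_recovered_exactly(self):
        plan = {
            "target": SitePlanEntry(n_transcripts=20, canonical_fraction=0.30, canonical_type="8mer"),
            "sponge_candidate": SitePlanEntry(
                n_transcripts=50, canonical_fraction=0.02, bulged_fraction=1.0
            ),
        }
        seqs, _, classes = simulate_transcripts(70, 150, plan, rng_seed=21)
        calls = [
            InteractomeCall(tid, "stable", "none", None, None, classes[tid])
            for tid in seqs
        ]
        summary = annotate_interactome(calls, seqs, MIR16)
        assert summary.loc["target", "frac_canonical"] == pytest.approx(0.30)
        assert summary.loc["sponge_candidate", "frac_canonical"] == pytest.approx(0.02)
        assert summary.loc["sponge_candidate", "frac_bulged"] == pytest.approx(1.0)

    def test_class_without_transcripts_is_undefined(self):
        calls = self._calls(["target", "none"])
        summary = annotate_interactome(calls, {"G1": "ACGTACGTACGT"}, MIR16)
        assert np.isnan(summary.loc["target", "frac_canonical"])
        assert summary.loc["target", "n_missing_transcript"] == 1

    def test_all_sponges_canonical_gives_one(self):
        site = canonical_site_strings(MIR16)["8mer"]
        seqs = {f"G{i}": "TTTT" + site + "TTTT" for i in range(3)}
        calls = self._calls(["sponge_candidate"] * 3)
        summary = annotate_interactome(calls, seqs, MIR16)
        assert summary.loc["sponge_candidate", "frac_canonical"] == 1.0
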