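import shutil

import numpy as np
import pytest

from oracles import enumerate_max_pairs

from srnaome.discover import (
    HairpinCriteria,
    classify_novel,
    dinucleotide_shuffle,
    discover_mirnas,
    evaluate_hairpin,
    extract_precursor_windows,
    fold_max_pairing,
    fold_rnafold,
    locus_verdicts,
)
from srnaome.io import CollapsedRead, collapse, revcomp


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFold:
    def test_no_complementary_bases(self):
        assert fold_max_pairing("AAAAAA").n_pairs == 0

    def test_simple_stem(self):
        fold = fold_max_pairing("GGGAAACCC", min_loop=3)
        assert fold.n_pairs == 3
        assert fold.dot_bracket() == "(((...)))"

    def test_invalid_characters_raise(self):
        with pytest.raises(ValueError, match="invalid character"):
            fold_max_pairing("ACGX")

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            fold_max_pairing("")
        with pytest.raises(ValueError):
            fold_max_pairing("A" * 1001)

    def test_accepts_rna_alphabet(self):
        assert fold_max_pairing("GGGAAACCC").n_pairs == fold_max_pairing("GGGAAACCC".replace("G", "G")).n_pairs
        assert fold_max_pairing("GGGAAAUUU").n_pairs == 3  # G-U wobble counts

    def test_matches_enumeration_oracle_small(self):
        rng = np.random.default_rng(2024)
        for _ in range(80):
            seq = _rand_seq(rng, int(rng.integers(4, 15)))
            assert fold_max_pairing(seq).n_pairs == enumerate_max_pairs(seq)

    def test_structure_validity_properties(self):
        rng = np.random.default_rng(9)
        ok_pairs = {"AT", "TA", "GC", "CG", "GT", "TG"}
        for _ in range(10):
            seq = _rand_seq(rng, 60)
            fold = fold_max_pairing(seq, min_loop=3)
            opened = []
            for i, j in enumerate(fold.pairs):
                if j is None:
                    continue
                assert fold.pairs[j] == i  # symmetric
                if j > i:
                    assert j - i - 1 >= 3  # loop size
                    assert seq[i] + seq[j] in ok_pairs
                    # non-crossing: every pair inside (i, j) stays inside
                    for a in range(i + 1, j):
                        b = fold.pairs[a]
                        if b is not None:
                            assert i < b < j
            assert fold.n_pairs == sum(p is not None for p in fold.pairs) // 2

    def test_deterministic(self):
        seq = "GCGCGAAATTTCGCGCAAAGGGCCC"
        assert fold_max_pairing(seq).pairs == fold_max_pairing(seq).pairs


@pytest.mark.skipif(shutil.which("RNAfold") is None, reason="ViennaRNA not on PATH")
class TestRnafoldPlugin:
    def test_same_contract_on_perfect_stem(self):
        seq = "GGGGGGGGGGAAAACCCCCCCCCC"
        mfe = fold_rnafold(seq)
        assert mfe.n_pairs == 10
        assert mfe.pairs[0] == 23
        # pluggable behind evaluate_hairpin
        arm = "TGACTGACTGACTGACTGACT"
        hp = arm + "ATTA" + "CCCCCCCC" + revcomp("ATTA") + revcomp(arm)
        ev = evaluate_hairpin(hp, 0, 21, fold_fn=fold_rnafold)
        assert ev.passed and ev.arm == "5p"


class TestWindows:
    def test_window_arithmetic(self):
        rng = np.random.default_rng(3)
        scaffold = _rand_seq(rng, 1000)
        seq = scaffold[300:321]
        wins = [
            w for w in extract_precursor_windows(seq, "s", scaffold, flank=250)
            if w.strand == "+"
        ]
        assert [(w.start, w.end) for w in wins] == [(50, 336), (285, 571)]
        assert all(w.sequence[w.mature_offset : w.mature_offset + 21] == seq for w in wins)

    def test_clipping_at_scaffold_start(self):
        scaffold = "TGACTGACTGACTGACTGACT" + "A" * 50
        wins = extract_precursor_windows(scaffold[:21], "s", scaffold, flank=250)
        assert wins[0].start == 0

    def test_absent_sequence(self):
        rng = np.random.default_rng(12)
        scaffold = _rand_seq(rng, 100)
        probe = "TGCA" * 6  # occurs on neither strand of this scaffold
        assert probe not in scaffold and revcomp(probe) not in scaffold
        assert extract_precursor_windows(probe, "s", scaffold) == []

    def test_antisense_occurrence_oriented(self):
        rng = np.random.default_rng(4)
        scaffold = _rand_seq(rng, 200)
        seq = revcomp(scaffold[80:101])
        wins = extract_precursor_windows(seq, "s", scaffold, flank=50)
        minus = [w for w in wins if w.strand == "-"]
        assert minus
        for w in minus:
            assert w.sequence[w.mature_offset : w.mature_offset + 21] == seq


def _perfect_hairpin(arm_len=21, loop="CCCC"):
    # arm over {A,T,C} with an all-C loop: the loop pairs only with G, so
    # the cross-arm duplex is the unique maximum-pairing structure
    rng = np.random.default_rng(5)
    arm = "T" + "".join(rng.choice(list("ATC"), size=arm_len - 1))
    return arm + loop + revcomp(arm), arm


class TestEvaluateHairpin:
    def test_perfect_duplex_geometry(self):
        hairpin, arm = _perfect_hairpin()
        ev = evaluate_hairpin(hairpin, 0, len(arm))
        assert ev.passed and ev.arm == "5p"
        # star: pairing span shifted by 2 for the 2-nt 3' overhangs
        assert ev.star_offset == len(arm) + 4 + 2
        assert ev.star_len == len(arm)

    def test_mature_centered_on_loop_rejected(self):
        hairpin, arm = _perfect_hairpin()
        mid = len(arm) - 5  # spans the 4-nt loop
        ev = evaluate_hairpin(hairpin, mid, 12)
        assert ev.status == "loop_overlap"

    def test_unpaired_window_rejected(self):
        ev = evaluate_hairpin("A" * 60, 10, 21)
        assert ev.status == "low_pairing"

    def test_star_of_star_recovers_mature(self):
        # involution on the designed-precursor geometry (paired flanks)
        rng = np.random.default_rng(6)
        arm = "T" + _rand_seq(rng, 20)
        flank = "".join(rng.choice(list("AC"), size=20))
        ext, loop = "ATTA", "CCCCCCCC"
        scaffold = flank + arm + ext + loop + revcomp(ext) + revcomp(arm) + revcomp(flank)
        ev = evaluate_hairpin(scaffold, 20, 21)
        assert ev.passed and ev.arm == "5p"
        star_start, star_len = ev.star_offset, ev.star_len
        ev2 = evaluate_hairpin(scaffold, star_start, star_len)
        assert ev2.passed and ev2.arm == "3p"
        assert (ev2.star_offset, ev2.star_len) == (20, 21)

    def test_shuffled_windows_pass_less_often(self):
        rng = np.random.default_rng(8)
        hairpins = []
        for _ in range(12):
            arm = "T" + "".join(rng.choice(list("ATC"), size=20))
            hairpins.append((arm + "CCCC" + revcomp(arm), 21))
        real_pass = sum(
            evaluate_hairpin(h, 0, m).passed for h, m in hairpins
        )
        shuffled_pass = sum(
            evaluate_hairpin(dinucleotide_shuffle(h, rng), 0, m).passed
            for h, m in hairpins
        )
        assert real_pass == len(hairpins)
        assert shuffled_pass < real_pass


class TestClassifyNovel:
    def _passing_candidate(self):
        hairpin, arm = _perfect_hairpin()
        hairpin = hairpin + "AA"  # room for the star's 2-nt 3' overhang
        from srnaome.discover import HairpinCandidate

        ev = evaluate_hairpin(hairpin, 0, len(arm))
        assert ev.passed
        cand = HairpinCandidate(
            mature_seq=arm,
            scaffold_id="s",
            window_start=0,
            window_end=len(hairpin),
            strand="+",
            evaluation=ev,
            mature_offset=0,
        )
        window = ev.fold.sequence
        exact_star = window[ev.star_offset : ev.star_offset + ev.star_len]
        return cand, exact_star, window, ev

    def test_star_at_exact_locus_is_novel(self):
        cand, star, _, _ = self._passing_candidate()
        out = classify_novel([cand], {star: CollapsedRead(star, {"d": 2})})
        assert out[0].verdict == "novel"
        assert out[0].star_observed_counts == {"d": 2}

    def test_star_one_nt_off_is_novel(self):
        cand, _, window, ev = self._passing_candidate()
        shifted = window[ev.star_offset - 1 : ev.star_offset - 1 + ev.star_len]
        out = classify_novel([cand], {shifted: CollapsedRead(shifted, {"d": 1})})
        assert out[0].verdict == "novel"

    def test_star_three_nt_away_is_candidate(self):
        cand, _, window, ev = self._passing_candidate()
        far = window[ev.star_offset - 3 : ev.star_offset - 3 + ev.star_len]
        out = classify_novel([cand], {far: CollapsedRead(far, {"d": 5})})
        assert out[0].verdict == "candidate"

    def test_no_reads_is_candidate(self):
        cand, _, _, _ = self._passing_candidate()
        assert classify_novel([cand], {})[0].verdict == "candidate"


class TestDiscovery:
    def test_generator_truth_verdicts(self, small_sim):
        from srnaome.annotate import annotate_collapsed
        from srnaome.preprocess import clean_reads

        collapsed = {}
        for lib in ("dormant", "germinated"):
            seqs, _ = clean_reads(small_sim.reads[lib])
            from srnaome.io import merge_collapsed

            collapsed = merge_collapsed(collapsed, collapse(seqs, lib))
        assignments = annotate_collapsed(collapsed, small_sim.catalog)
        unknown = {
            s: c for s, c in collapsed.items() if assignments[s].category == "unknown"
        }
        cands = discover_mirnas(unknown, small_sim.scaffolds)
        verdicts = locus_verdicts(cands)
        expected = dict(
            zip(small_sim.truth.loci["scaffold"], small_sim.truth.loci["expected_verdict"])
        )
        assert verdicts == expected
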