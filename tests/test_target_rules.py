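import numpy as np
import pytest

import cernaforge as cf
from cernaforge.target_rules import (
    EnergyModel,
    duplex_align,
    evaluate_rules,
    perfect_energy,
    reverse_complement,
    scan_transcript,
)
from cernaforge.synthetic_data import (
    DECOY_RULES,
    _decoy_window,
    make_scaffold_mirna,
)
from oracles import naive_rules, naive_scan, naive_score, naive_states

MI = "GCAUGCAUGCAUGCAUGCAUG"  # 21-nt template


def rand_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestDuplexAlign:
    def test_perfect_complement_all_watson_crick(self):
        aln = duplex_align(MI, reverse_complement(MI))
        assert set(aln.states) == {"WC"}
        assert aln.mismatch_score == 0.0
        assert aln.mfe_ratio == pytest.approx(1.0)

    def test_gu_wobble_scores_half(self):
        # miRNA G's paired against window U's (antiparallel): G:U wobbles
        aln = duplex_align("GGGG", "UUUU")
        assert set(aln.states) == {"GU"}
        assert aln.mismatch_score == pytest.approx(2.0)

    def test_toy_eight_mer_states_by_hand(self):
        mirna = "GACUGGUC"
        window = "UACCAGUC"
        # position i pairs window position 9-i:
        # G:C WC, A:U WC, C:G WC, U:A WC, G:C WC, G:C WC, U:A WC, C:U MM
        aln = duplex_align(mirna, window)
        assert list(aln.states) == ["WC"] * 7 + ["MM"]
        assert list(aln.states) == naive_states(mirna, window)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            duplex_align("ACGU", "ACG")

    def test_dna_alphabet_rejected(self):
        with pytest.raises(ValueError, match="RNA"):
            duplex_align("ACGT", "ACGT")


class TestRules:
    def test_perfect_duplex_passes_everything(self):
        aln = duplex_align(MI, reverse_complement(MI))
        for ruleset in "AB":
            v = evaluate_rules(aln, ruleset)
            assert v.passed and v.violated() == ()

    @pytest.mark.parametrize("ruleset", "AB")
    def test_mismatch_at_position_ten_fails_r4(self, ruleset):
        window = list(reverse_complement(MI))
        window[len(MI) - 10] = "A"  # pairs miRNA position 10 (C) as C:A
        v = evaluate_rules(duplex_align(MI, "".join(window)), ruleset)
        assert not v.r4

    def test_nine_wobbles_fail_r1(self):
        mirna = "G" * 9 + "CAUGCAUGCAUG"
        window = list(reverse_complement(mirna))
        for pos in range(1, 10):  # wobble the 9 leading G's
            window[len(mirna) - pos] = "U"
        aln = duplex_align(mirna, "".join(window))
        assert aln.mismatch_score == pytest.approx(4.5)
        assert not evaluate_rules(aln, "A").r1

    def test_score_decomposes_over_position_blocks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mirna, window = rand_rna(rng, 21), rand_rna(rng, 21)
            aln = duplex_align(mirna, window)
            states = naive_states(mirna, window)
            assert aln.mismatch_score == pytest.approx(
                naive_score(states[:12]) + naive_score(states[12:])
            )

    def test_unknown_ruleset_rejected(self):
        aln = duplex_align(MI, reverse_complement(MI))
        with pytest.raises(ValueError):
            evaluate_rules(aln, "C")


class TestEnergy:
    def test_all_gc_perfect_energy(self):
        assert perfect_energy("G" * 10) == pytest.approx(-30.0)

    def test_single_mismatch_ratio(self):
        mirna = "G" * 10
        window = list(reverse_complement(mirna))
        window[0] = "A"  # breaks the pair of miRNA position 10
        aln = duplex_align(mirna, "".join(window))
        assert aln.mfe_ratio == pytest.approx(27.0 / 30.0)

    def test_model_constants_validated(self):
        with pytest.raises(ValueError):
            EnergyModel(gc=1.0)
        with pytest.raises(ValueError):
            EnergyModel(mm=-0.5)


class TestDecoys:
    @pytest.mark.parametrize("ruleset", "AB")
    def test_each_decoy_violates_exactly_its_rule(self, ruleset):
        rng = np.random.default_rng(1)
        for idx, rule in enumerate(DECOY_RULES[ruleset]):
            mirna = make_scaffold_mirna(rng, "m", ortho_index=idx % 8).sequence
            window = _decoy_window(mirna, rule, ruleset)
            verdict = evaluate_rules(duplex_align(mirna, window), ruleset)
            assert verdict.violated() == (rule,)
            oracle = naive_rules(mirna, window, ruleset)
            assert [r for r, ok in oracle.items() if not ok] == [rule]

    def test_planted_decoys_invisible_to_scan(self, small_study):
        mirnas = {m.id: m.as_rna() for m in small_study.mirnas}
        seqs = {t.id: t.as_rna() for t in small_study.transcripts}
        decoys = small_study.truth.sites.query("kind == 'decoy'")
        assert len(decoys) > 0
        for row in decoys.itertuples(index=False):
            hits = scan_transcript(
                mirnas[row.mirna], seqs[row.transcript], ruleset=row.ruleset
            )
            assert hits == []


class TestScan:
    def test_exact_complement_single_hit(self):
        tr = cf.SeqRecord("t", reverse_complement(MI))
        hits = scan_transcript(cf.SeqRecord("m", MI), tr)
        assert len(hits) == 1 and hits[0].alignment.window_start == 0

    def test_transcript_shorter_than_mirna_warns_empty(self):
        with pytest.warns(UserWarning):
            hits = scan_transcript(cf.SeqRecord("m", MI), cf.SeqRecord("t", "ACGU"))
        assert hits == []

    def test_polya_transcript_has_no_hits(self):
        hits = scan_transcript(
            cf.SeqRecord("m", "A" * 21), cf.SeqRecord("t", "A" * 100)
        )
        assert hits == []

    @pytest.mark.parametrize("ruleset", "AB")
    def test_matches_bruteforce_oracle_on_random_sequences(self, ruleset):
        rng = np.random.default_rng(2)
        mirnas = [cf.SeqRecord(f"m{i}", rand_rna(rng, 21)) for i in range(3)]
        # seed windows related to the miRNAs so some hits actually occur
        transcripts = []
        for i in range(25):
            seq = rand_rna(rng, int(rng.integers(30, 100)))
            if i % 3 == 0:
                mi = mirnas[i % 3].sequence
                w = list(reverse_complement(mi))
                for pos in rng.choice(21, size=int(rng.integers(0, 3)), replace=False):
                    w[pos] = rand_rna(rng, 1)
                pos = int(rng.integers(0, len(seq) - 21 + 1))
                seq = seq[:pos] + "".join(w) + seq[pos + 21 :]
            transcripts.append(cf.SeqRecord(f"t{i}", seq))
        n_hits = 0
        for m in mirnas:
            for t in transcripts:
                got = [
                    h.alignment.window_start
                    for h in scan_transcript(m, t, ruleset=ruleset)
                ]
                assert got == naive_scan(m.sequence, t.sequence, ruleset)
                n_hits += len(got)
        assert n_hits > 0

    def test_ruleset_b_hits_subset_of_a(self):
        rng = np.random.default_rng(3)
        mirna = make_scaffold_mirna(rng, "m", 0)
        for _ in range(30):
            seq = rand_rna(rng, 80)
            w = list(reverse_complement(mirna.sequence))
            for pos in rng.choice(21, size=int(rng.integers(0, 4)), replace=False):
                w[pos] = rand_rna(rng, 1)
            tr = cf.SeqRecord("t", seq[:30] + "".join(w) + seq[51:])
            hits_a = {
                h.alignment.window_start
                for h in scan_transcript(mirna, tr, ruleset="A", mfe_threshold=0.6)
            }
            hits_b = {
                h.alignment.window_start
                for h in scan_transcript(mirna, tr, ruleset="B", mfe_threshold=0.6)
            }
            assert hits_b <= hits_a
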