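"""Saturation mutagenesis, codon swaps, stop-codon analyses, variant effects."""

import numpy as np
import pandas as pd
import pytest

from m6alens import perturbation as pert
from m6alens.synthetic_grammar import GrammarScorer, PlantedGrammar, make_grammar
from tests.conftest import random_seq, seq_with_site


class TestSaturationMutagenesis:
    def test_event_count_full_span(self, rng, oracle):
        seq = seq_with_site(rng, length=800, site=380)
        ev = pert.saturation_mutagenesis(oracle, seq, 380, span=(-250, 250))
        assert len(ev) == 501 * 3

    def test_deltas_bounded_and_reference_excluded(self, rng, oracle):
        seq = seq_with_site(rng, length=300, site=150)
        ev = pert.saturation_mutagenesis(oracle, seq, 150, span=(-20, 20))
        assert (ev.ref != ev.alt).all()
        assert (ev.delta.abs() <= 1).all()

    def test_outside_window_events_have_zero_delta(self, rng, oracle,
                                                   linear_grammar):
        # grammar window is [+1, +50]; pentamers changed by a mutation at
        # +60 start at >= +56, all outside, so the focal delta is exactly 0
        seq = seq_with_site(rng, length=400, site=150)
        ev = pert.saturation_mutagenesis(oracle, seq, 150, span=(56, 120))
        assert (ev.delta == 0).all()

    def test_revert_restores_reference(self, rng, oracle):
        seq = seq_with_site(rng, length=300, site=150)
        ev = pert.saturation_mutagenesis(oracle, seq, 150, span=(3, 10))
        base = oracle.score_at(seq, 150)
        for e in ev.head(6).itertuples():
            p = 150 + e.offset
            mut = seq[:p] + e.alt + seq[p + 1:]
            back = mut[:p] + e.ref + mut[p + 1:]
            assert back == seq
            assert oracle.score_at(back, 150) == base

    def test_exclude_consensus_flag(self, rng, oracle):
        seq = seq_with_site(rng, length=300, site=150)
        ev = pert.saturation_mutagenesis(oracle, seq, 150, span=(-3, 3),
                                         exclude_consensus=True)
        assert set(ev.offset) == {-3, -2, 2, 3}

    def test_non_consensus_site_rejected(self, rng, oracle):
        seq = "T" * 300
        with pytest.raises(ValueError, match="consensus"):
            pert.saturation_mutagenesis(oracle, seq, 150, span=(-5, 5))

    def test_span_beyond_sequence_rejected(self, rng, oracle):
        seq = seq_with_site(rng, length=100, site=50)
        with pytest.raises(ValueError, match="span"):
            pert.saturation_mutagenesis(oracle, seq, 50, span=(-250, 250))

    def test_matrix_shape(self, rng, oracle):
        seq = seq_with_site(rng, length=300, site=150)
        ev = pert.saturation_mutagenesis(oracle, seq, 150, span=(-5, 5))
        mat = pert.mutagenesis_matrix(ev)
        assert mat.shape[0] == 11  # offsets; ref base excluded per row


class TestSynonymousSwaps:
    def build_cds(self, rng, n_codons=60, site_codon=25):
        codons = list(rng.choice(pert.SYNONYMS and
                                 [c for c in pert.CODON_TO_AA
                                  if pert.CODON_TO_AA[c] != "*"],
                                 size=n_codons))
        codons[site_codon], codons[site_codon + 1] = "GGA", "CTG"
        cds = "".join(codons)
        seq = random_seq(rng, 60) + cds + random_seq(rng, 60)
        return seq, 60, 60 + len(cds), 60 + 3 * site_codon + 2

    def test_codon_synonym_table(self):
        assert pert.SYNONYMS["ATG"] == []          # Met
        assert pert.SYNONYMS["TGG"] == []          # Trp
        assert sorted(pert.SYNONYMS["AGA"]) == ["AGG", "CGA", "CGC",
                                                "CGG", "CGT"]

    def test_swaps_preserve_peptide(self, rng, oracle):
        seq, cs, ce, site = self.build_cds(rng)
        swaps = pert.synonymous_swap_scan(oracle, seq, site, cs, ce)
        assert (swaps.apply(lambda r: pert.CODON_TO_AA[r.ref_codon]
                            == pert.CODON_TO_AA[r.alt_codon], axis=1)).all()

    def test_no_effect_grammar_gives_zero_deltas(self, rng):
        grammar = PlantedGrammar(enhancers={}, silencers={}, baseline=0.4)
        scorer = GrammarScorer(grammar)
        seq, cs, ce, site = self.build_cds(rng)
        swaps = pert.synonymous_swap_scan(scorer, seq, site, cs, ce)
        keep = swaps[~swaps.breaks_consensus]
        assert np.allclose(keep.delta, 0.0)
        # consensus-destroying swaps (the A sits in codon 0, its C is the
        # first base of codon +1) drop the probability to 0
        broke = swaps[swaps.breaks_consensus]
        assert set(broke.codon_offset) <= {0, 1}
        assert np.allclose(broke.delta, -0.4)

    def test_site_outside_cds_rejected(self, rng, oracle):
        seq, cs, ce, site = self.build_cds(rng)
        with pytest.raises(ValueError, match="CDS"):
            pert.synonymous_swap_scan(oracle, seq, 10, cs, ce)

    def test_margin_enforced(self, rng, oracle):
        seq, cs, ce, _ = self.build_cds(rng, site_codon=5)
        site = cs + 3 * 5 + 2
        with pytest.raises(ValueError, match="60"):
            pert.synonymous_swap_scan(oracle, seq, site, cs, ce)


class TestStopCodonAnalyses:
    def test_stop_adjacent_motif_geometry(self):
        #            0123456789
        seq = "TTTTGACTTTTT"
        # stop TGA at 3, followed by C at 6 -> TRACN with A at +2
        sites = pert.stop_adjacent_sites(seq, 3)
        assert sites == {"TRACN": 5}

    def test_swap_requires_different_stop(self, rng, oracle):
        seq = random_seq(rng, 100) + "TGA" + random_seq(rng, 100)
        with pytest.raises(ValueError):
            pert.stop_codon_swap(oracle, seq, 100, "TGA")
        with pytest.raises(ValueError, match="stop"):
            pert.stop_codon_swap(oracle, seq, 10, "TAA")

    def test_no_adjacent_a_gives_empty_result(self, oracle):
        seq = "G" * 50 + "TGA" + "G" * 50
        out = pert.stop_codon_swap(oracle, seq, 50, "TAA")
        assert out.empty

    def test_tga_favoring_grammar_direction(self):
        # enhancers containing TGA, window covering the stop upstream of
        # the TRACN site's A: removing TGA must lower the probability
        enh = {p: 0.3 for p in
               ("ATGAC", "TTGAC", "GTGAC", "CTGAC")}
        grammar = PlantedGrammar(enhancers=enh, silencers={}, window=(-4, 5),
                                 baseline=0.3)
        scorer = GrammarScorer(grammar)
        seq = "CCCCC" + "ATGACT" + "CCCCC"
        # stop TGA at index 6; A of TRACN at index 8
        out = pert.stop_codon_swap(scorer, seq, 6, "TAA")
        tracn = out[out.motif == "TRACN"]
        assert len(tracn) == 1
        assert tracn.delta.iloc[0] < 0

    def test_stop_profile_single_and_duplicate_transcripts(self, rng, oracle):
        seq = seq_with_site(rng, 400, 200)
        stop = 150
        seq = seq[:stop] + "TGA" + seq[stop + 3:]
        one = pert.stop_profile(oracle, [(seq, stop)], span=(-50, 50))
        two = pert.stop_profile(oracle, [(seq, stop), (seq, stop)],
                                span=(-50, 50))
        probs = oracle.score(seq)
        for df in (one, two):
            assert set(df.stop) == {"TGA"}
            row = df[df.offset == 50]
            assert row.mean_prob.iloc[0] == pytest.approx(probs[stop + 50])
        pd.testing.assert_frame_equal(
            one.drop(columns="n"), two.drop(columns="n"))


class TestVariantEffects:
    def test_reference_mismatch_and_indels_rejected(self, rng, oracle):
        seq = seq_with_site(rng, 300, 150)
        with pytest.raises(ValueError, match="SNV"):
            pert.variant_delta(oracle, seq, 10, "AC", "A")
        wrong = "C" if seq[10] != "C" else "G"
        with pytest.raises(ValueError, match="mismatch"):
            pert.variant_delta(oracle, seq, 10, wrong, "T")

    def test_destroying_consensus_c_zeroes_site(self, rng, oracle):
        seq = seq_with_site(rng, 300, 150)
        base = oracle.score_at(seq, 150)
        assert base > 0
        df = pert.variant_delta(oracle, seq, 151, "C", "G",
                                site_search_radius=30)
        row = df[df.site_pos == 150]
        assert row.delta.iloc[0] == pytest.approx(-base)
        assert df.attrs["classification"] in ("at_site", "downstream",
                                              "upstream")

    def test_mutating_the_a_itself(self, rng, oracle):
        seq = seq_with_site(rng, 300, 150)
        base = oracle.score_at(seq, 150)
        df = pert.variant_delta(oracle, seq, 150, "A", "C",
                                site_search_radius=10)
        row = df[df.site_pos == 150]
        assert row.mut_prob.iloc[0] == 0.0
        assert row.delta.iloc[0] == pytest.approx(-base)


class TestDeltaEffectiveValue:
    def test_zero_table_gives_zero(self, rng):
        seq = random_seq(rng, 40)
        ref = seq[20]
        alt = "A" if ref != "A" else "C"
        val, trunc = pert.delta_effective_value(seq, 20, ref, alt, {})
        assert val == 0.0 and not trunc

    def test_hand_enumerated_example(self, rng):
        # independent enumeration of the <=5 created/broken pentamers
        effects = {"ACTGA": 0.2, "CCGTT": -0.1}
        for _ in range(200):
            seq = random_seq(rng, 30)
            p = int(rng.integers(4, 26))
            ref = seq[p]
            alt = str(rng.choice([c for c in "ACGT" if c != ref]))
            mut = seq[:p] + alt + seq[p + 1:]
            expected = 0.0
            for s in range(p - 4, p + 1):
                if 0 <= s and s + 5 <= len(seq):
                    expected += effects.get(mut[s:s + 5], 0.0)
                    expected -= effects.get(seq[s:s + 5], 0.0)
            val, _ = pert.delta_effective_value(seq, p, ref, alt, effects)
            assert val == pytest.approx(expected)

    def test_planted_creation_and_break(self):
        # one substitution creating ACTGA while breaking ACGGA
        seq = "TTTTACGGATTTT"
        #          4
        # mutate G at index 6 -> T: ACGGA (start 4) becomes ACTGA
        effects = {"ACTGA": 0.2, "ACGGA": -0.1}
        val, trunc = pert.delta_effective_value(seq, 6, "G", "T", effects)
        assert val == pytest.approx(0.2 - (-0.1))
        assert not trunc

    def test_edge_truncation_flagged(self):
        seq = "ACGTACGT"
        val, trunc = pert.delta_effective_value(seq, 1, "C", "T", {})
        assert trunc
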