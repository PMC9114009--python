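"""Window extraction, encoding, labelling and block splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from m6alens import genome_io as gio

SEQ_ALPHABET = "ACGT"


def gene(exons, strand="+", chrom="chr1", gid="g", tid="t", cds=None):
    return gio.GeneModel(gene_id=gid, transcript_id=tid, chrom=chrom,
                         strand=strand, exons=tuple(exons), cds=cds)


# ---------------------------------------------------------------------------
# transcript selection
# ---------------------------------------------------------------------------

class TestSelectLongestTranscript:
    def test_picks_largest_mature_length(self):
        t1 = gene([(0, 100), (200, 400)], tid="A")     # 300 exonic nt
        t2 = gene([(0, 450)], tid="B")                 # 450 exonic nt
        assert gio.select_longest_transcript([t1, t2]) is t2

    def test_single_transcript_is_identity(self):
        t = gene([(5, 50)])
        assert gio.select_longest_transcript([t]) is t

    @pytest.mark.parametrize("order", [("T1", "T2"), ("T2", "T1")])
    def test_tie_breaks_to_smallest_id(self, order):
        ts = [gene([(0, 300)], tid=t) for t in order]
        assert gio.select_longest_transcript(ts).transcript_id == "T1"

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no transcripts"):
            gio.select_longest_transcript([])

    def test_mixed_genes_rejected(self):
        ts = [gene([(0, 10)], gid="a"), gene([(0, 10)], gid="b")]
        with pytest.raises(ValueError):
            gio.select_longest_transcript(ts)


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

class TestExtractWindow:
    def make_store(self, seq):
        return gio.SequenceStore({"chr1": seq})

    def test_plus_strand_window(self, rng):
        seq = "".join(rng.choice(list(SEQ_ALPHABET), size=1000))
        store = self.make_store(seq)
        win = gio.extract_premrna_window(store, gene([(100, 200)]), flank=10)
        assert len(win.sequence) == 120
        assert win.origin == 90
        assert win.sequence == seq[90:210]
        assert win.body == seq[100:200]

    def test_minus_strand_is_reverse_complement(self, rng):
        seq = "".join(rng.choice(list(SEQ_ALPHABET), size=300))
        store = self.make_store(seq)
        win = gio.extract_premrna_window(store, gene([(50, 120)], strand="-"),
                                         flank=5)
        assert win.sequence == gio.reverse_complement(seq[45:125])
        # coordinate map round-trips
        for off in (0, 3, 40):
            assert win.to_window(win.to_genomic(off)) == off

    def test_large_flank_pads_with_n(self, rng):
        seq = "".join(rng.choice(list(SEQ_ALPHABET), size=1000))
        store = self.make_store(seq)
        win = gio.extract_premrna_window(store, gene([(100, 200)]), flank=5000)
        assert win.sequence[:4900] == "N" * 4900
        assert win.sequence[4900:5000] == seq[:100]

    def test_unknown_chromosome_errors(self):
        store = self.make_store("ACGT")
        with pytest.raises(KeyError):
            gio.extract_premrna_window(store, gene([(0, 2)], chrom="chrX"), 0)


# ---------------------------------------------------------------------------
# one-hot encoding
# ---------------------------------------------------------------------------

class TestOneHot:
    def test_channel_order(self):
        mat = gio.one_hot_encode("ACGTN")
        expected = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0],
                             [0, 0, 0, 1], [0, 0, 0, 0]], dtype=float)
        np.testing.assert_array_equal(mat, expected)

    def test_empty_sequence(self):
        assert gio.one_hot_encode("").shape == (0, 4)

    def test_lowercase_and_iupac_coercion(self):
        mat = gio.one_hot_encode("aK")
        np.testing.assert_array_equal(mat, [[1, 0, 0, 0], [0, 0, 0, 0]])
        assert gio.decode_one_hot(mat) == "AN"

    @given(st.text(alphabet="ACGTN", max_size=60))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip(self, s):
        assert gio.decode_one_hot(gio.one_hot_encode(s)) == s


# ---------------------------------------------------------------------------
# consensus search
# ---------------------------------------------------------------------------

def brute_force_sites(seq, mode):
    """Independent position-by-position scan."""
    R, H = set("AG"), set("ACT")
    hits = []
    for i, c in enumerate(seq):
        if c != "A":
            continue
        if mode == "RAC":
            ok = (i >= 1 and i + 1 < len(seq)
                  and seq[i - 1] in R and seq[i + 1] == "C")
        else:
            ok = (i >= 2 and i + 2 < len(seq) and seq[i - 2] in R
                  and seq[i - 1] in R and seq[i + 1] == "C" and seq[i + 2] in H)
        if ok:
            hits.append(i)
    return hits


class TestConsensusSites:
    @pytest.mark.parametrize("seq,mode,expected", [
        ("GGACT", "RRACH", [2]),
        ("CCCCC", "RAC", []),
        ("CCCCC", "RRACH", []),
        ("AACAACA", "RAC", [1, 4]),
    ])
    def test_known_patterns(self, seq, mode, expected):
        assert gio.find_consensus_sites(seq, mode) == expected

    @given(st.text(alphabet="ACGT", min_size=5, max_size=80))
    @settings(derandomize=True, max_examples=80)
    def test_matches_brute_force_and_containment(self, seq):
        rac = gio.find_consensus_sites(seq, "RAC")
        rrach = gio.find_consensus_sites(seq, "RRACH")
        assert rac == brute_force_sites(seq, "RAC")
        assert rrach == brute_force_sites(seq, "RRACH")
        assert set(rrach) <= set(rac)

    def test_minus_strand_sites_match_revcomp(self, rng):
        seq = "".join(rng.choice(list(SEQ_ALPHABET), size=400))
        store = gio.SequenceStore({"chr1": seq})
        win = gio.extract_premrna_window(store, gene([(40, 360)], strand="-"), 10)
        direct = gio.find_consensus_sites(gio.reverse_complement(seq[30:370]), "RAC")
        assert gio.find_consensus_sites(win.sequence, "RAC") == direct


# ---------------------------------------------------------------------------
# labels and blocks
# ---------------------------------------------------------------------------

class TestLabelsAndBlocks:
    def make_window(self, rng, body=12000, flank=50):
        seq = "".join(rng.choice(list(SEQ_ALPHABET), size=body + 2 * flank))
        return gio.PreMrnaWindow(gene_id="g", chrom="chr1", strand="+",
                                 sequence=seq, flank=flank, origin=0)

    def test_block_count_and_spans(self, rng):
        win = self.make_window(rng, body=12000, flank=100)
        labels = np.zeros(12000, dtype=np.int8)
        blocks = gio.split_blocks(win, labels, B=5000, C=5000)
        assert len(blocks) == 3
        # block 2 input covers body positions 0..15000 clipped to the window
        assert all(len(b.sequence) == 15000 for b in blocks)
        assert all(len(b.labels) == 5000 for b in blocks)

    def test_single_block_no_context(self, rng):
        win = self.make_window(rng, body=5, flank=0)
        labels = np.array([0, 1, 0, 0, 1], dtype=np.int8)
        (block,) = gio.split_blocks(win, labels, B=5, C=0)
        assert block.sequence == win.sequence
        np.testing.assert_array_equal(block.labels, labels)

    def test_final_block_padded_and_masked(self, rng):
        win = self.make_window(rng, body=8, flank=0)
        labels = np.arange(8) % 2
        blocks = gio.split_blocks(win, labels.astype(np.int8), B=5, C=5)
        assert len(blocks) == 2
        assert len(blocks[0].sequence) == 15
        assert blocks[0].sequence[:5] == "N" * 5  # no flank to draw from
        np.testing.assert_array_equal(blocks[1].mask, [1, 1, 1, 0, 0])

    def test_partition_round_trip_random_geometries(self, rng):
        for _ in range(100):
            body = int(rng.integers(1, 400))
            B = int(rng.integers(1, 60))
            C = int(rng.integers(0, 30))
            flank = int(rng.integers(0, 20))
            seq = "".join(rng.choice(list(SEQ_ALPHABET), size=body + 2 * flank))
            win = gio.PreMrnaWindow("g", "chr1", "+", seq, flank, 0)
            labels = rng.integers(0, 2, size=body).astype(np.int8)
            blocks = gio.split_blocks(win, labels, B=B, C=C)
            np.testing.assert_array_equal(gio.concat_blocks(blocks), labels)
            assert all(len(b.sequence) == B + 2 * C for b in blocks)

    def test_bad_block_size_errors(self, rng):
        win = self.make_window(rng, body=10, flank=0)
        with pytest.raises(ValueError):
            gio.split_blocks(win, np.zeros(10, dtype=np.int8), B=0, C=5)

    def test_labels_must_be_consensus(self, rng):
        seq = "TTGGACTTTT"
        win = gio.PreMrnaWindow("g", "chr1", "+", seq, 0, 0)
        labels = gio.build_label_track(win, [4])  # the A of GGACT
        assert labels[4] == 1 and labels.sum() == 1
        with pytest.raises(ValueError, match="consensus"):
            gio.build_label_track(win, [1])


# ---------------------------------------------------------------------------
# GTF / BED round trips
# ---------------------------------------------------------------------------

class TestFileFormats:
    def test_gtf_round_trip(self, tmp_path, small_genome):
        from m6alens.synthetic_grammar import write_gtf

        path = tmp_path / "ann.gtf"
        write_gtf(small_genome.genes, path)
        parsed = gio.read_gtf(path)
        assert set(parsed) == {g.gene_id for g in small_genome.genes}
        for g in small_genome.genes:
            (p,) = parsed[g.gene_id]
            assert p.exons == g.exons
            assert p.strand == g.strand
            assert p.cds == g.cds

    def test_site_bed_round_trip(self, tmp_path, small_genome):
        bed = tmp_path / "sites.bed"
        pos = small_genome.truth[small_genome.truth.label == 1]
        with open(bed, "w") as fh:
            for _, r in pos.iterrows():
                fh.write(f"{r.chrom}\t{r.genomic_pos}\t{r.genomic_pos + 1}"
                         f"\t{r.gene_id}\t0\t{r.strand}\n")
        df = gio.read_site_bed(bed)
        assert len(df) == len(pos)
        assert (df["end"] - df["start"] == 1).all()

    def test_fasta_store_padding(self, tmp_path):
        from m6alens.synthetic_grammar import write_fasta

        write_fasta({"c1": "ACGTACGT"}, tmp_path / "g.fa")
        store = gio.SequenceStore.from_fasta(tmp_path / "g.fa")
        assert store.fetch("c1", -3, 2) == "NNNAC"
        assert store.fetch("c1", 6, 11) == "GTNNN"
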