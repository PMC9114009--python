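"""Annotation/sequence I/O and pre-mRNA window construction.

All genomic coordinates are 0-based, half-open.  Transcript windows are
always handed downstream in *sense* orientation: minus-strand genes are
reverse-complemented exactly once here and never again.  Labels exist only
inside the gene body; the flanks are context for the classifier and are
excluded from loss and evaluation via the block masks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
#: fixed one-hot channel order
ALPHABET = "ACGT"
_ONE_HOT = {c: i for i, c in enumerate(ALPHABET)}

R_SET = frozenset("AG")
H_SET = frozenset("ACT")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Stranded exon/CDS structure of one transcript.

    ``exons`` are genomic intervals sorted by genomic coordinate and
    non-overlapping; ``cds`` (optional) is the genomic interval spanned by
    the coding sequence, contained in the exon union.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ex = tuple(sorted(tuple(e) for e in self.exons))
        if not ex:
            raise ValueError("gene model needs at least one exon")
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if s1 < e0:
                raise ValueError("overlapping exons")
        object.__setattr__(self, "exons", ex)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        lo, hi = self.span
        return lo if self.strand == "+" else hi - 1

    @property
    def tes(self) -> int:
        lo, hi = self.span
        return hi - 1 if self.strand == "+" else lo

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def body_length(self) -> int:
        lo, hi = self.span
        return hi - lo


def select_longest_transcript(transcripts: list[GeneModel]) -> GeneModel:
    """Pick the transcript with the largest mature (exonic) length.

    Ties break on lexicographically smallest transcript_id so the choice is
    deterministic regardless of input order.
    """
    if not transcripts:
        raise ValueError("no transcripts")
    gids = {t.gene_id for t in transcripts}
    if len(gids) != 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(gids)}")
    return max(transcripts, key=lambda t: (t.mature_length, _neg_lex(t.transcript_id)))


def _neg_lex(s: str):
    # max() helper: prefer lexicographically smaller id on equal length
    return tuple(-ord(c) for c in s)


# ---------------------------------------------------------------------------
# FASTA / GTF / BED
# ---------------------------------------------------------------------------

class SequenceStore:
    """Chromosome sequences with N-padding outside chromosome bounds.

    Wraps either a plain ``dict`` of contig -> sequence or a
    :class:`pyfaidx.Fasta`.
    """

    def __init__(self, source):
        self._src = source

    @classmethod
    def from_fasta(cls, path) -> "SequenceStore":
        from pyfaidx import Fasta

        return cls(Fasta(str(path), as_raw=True, sequence_always_upper=True))

    def __contains__(self, chrom: str) -> bool:
        try:
            self._src[chrom]
        except KeyError:
            return False
        return True

    def length(self, chrom: str) -> int:
        return len(self._src[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Genomic slice [start, end); positions outside bounds become N."""
        if chrom not in self:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = self.length(chrom)
        lo, hi = max(start, 0), min(end, n)
        core = str(self._src[chrom][lo:hi]).upper() if hi > lo else ""
        return "N" * (lo - start) + core + "N" * (end - hi)


def read_gtf(path) -> dict[str, list[GeneModel]]:
    """Parse exon/CDS features of a GTF into GeneModels keyed by gene_id."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[tuple[str, str], dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid = feat.attributes["gene_id"][0]
        tid = feat.attributes["transcript_id"][0]
        rec = exons.setdefault((gid, tid), {
            "chrom": feat.seqid, "strand": feat.strand,
            "exons": [], "cds": [],
        })
        # gffutils exposes 1-based inclusive coords; convert to 0-based half-open
        iv = (feat.start - 1, feat.end)
        rec["exons" if feat.featuretype == "exon" else "cds"].append(iv)

    out: dict[str, list[GeneModel]] = {}
    for (gid, tid), rec in exons.items():
        cds = None
        if rec["cds"]:
            cds = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        out.setdefault(gid, []).append(GeneModel(
            gene_id=gid, transcript_id=tid, chrom=rec["chrom"],
            strand=rec["strand"], exons=tuple(sorted(rec["exons"])), cds=cds,
        ))
    return out


def read_site_bed(path) -> pd.DataFrame:
    """Read a 6-column BED of single-nucleotide, stranded m6A sites."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    bad = df["end"] - df["start"] != 1
    if bad.any():
        raise ValueError(f"{int(bad.sum())} BED intervals are not single-nucleotide")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("BED strand column required")
    return df


def write_site_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "name", "score", "strand"])


# ---------------------------------------------------------------------------
# pre-mRNA windows
# ---------------------------------------------------------------------------

@dataclass
class PreMrnaWindow:
    """Sense-orientation pre-mRNA sequence with flanks.

    ``origin`` is the genomic coordinate of window position 0 (for minus
    strand genes this is the *highest* genomic coordinate of the window and
    coordinates decrease along the window).
    """

    gene_id: str
    chrom: str
    strand: str
    sequence: str
    flank: int
    origin: int
    model: GeneModel | None = field(default=None, repr=False)

    @property
    def body_length(self) -> int:
        return len(self.sequence) - 2 * self.flank

    @property
    def body(self) -> str:
        return self.sequence[self.flank:self.flank + self.body_length]

    def to_genomic(self, offset: int) -> int:
        if self.strand == "+":
            return self.origin + offset
        return self.origin - offset

    def to_window(self, gpos: int) -> int:
        if self.strand == "+":
            return gpos - self.origin
        return self.origin - gpos


def extract_premrna_window(genome: SequenceStore, model: GeneModel,
                           flank: int = 5000) -> PreMrnaWindow:
    """Sense-strand window covering flank..gene body..flank.

    Out-of-chromosome positions are 'N'; minus-strand genes are reverse
    complemented so position 0 is the 5'-most (TSS-side) flank base.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    lo, hi = model.span
    raw = genome.fetch(model.chrom, lo - flank, hi + flank)
    if model.strand == "+":
        seq, origin = raw, lo - flank
    else:
        seq, origin = reverse_complement(raw), hi + flank - 1
    return PreMrnaWindow(
        gene_id=model.gene_id, chrom=model.chrom, strand=model.strand,
        sequence=seq, flank=flank, origin=origin, model=model,
    )


# ---------------------------------------------------------------------------
# encoding and labels
# ---------------------------------------------------------------------------

def clean_sequence(seq: str) -> str:
    """Uppercase and coerce non-ACGTN characters (IUPAC codes etc.) to N."""
    s = seq.upper()
    if not set(s) <= set("ACGTN"):
        n_bad = sum(c not in "ACGTN" for c in s)
        log.warning("coercing %d non-ACGTN characters to N", n_bad)
        s = "".join(c if c in "ACGTN" else "N" for c in s)
    return s


def one_hot_encode(seq: str) -> np.ndarray:
    """(L, 4) matrix with channel order A,C,G,T; N rows are all-zero."""
    s = clean_sequence(seq)
    out = np.zeros((len(s), 4), dtype=np.float64)
    for i, c in enumerate(s):
        j = _ONE_HOT.get(c)
        if j is not None:
            out[i, j] = 1.0
    return out


def decode_one_hot(mat: np.ndarray) -> str:
    out = []
    for row in np.asarray(mat):
        hits = np.flatnonzero(row)
        out.append(ALPHABET[hits[0]] if len(hits) == 1 else "N")
    return "".join(out)


def find_consensus_sites(seq: str, mode: str = "RAC") -> list[int]:
    """0-based positions of the methylatable A under the chosen consensus.

    RAC: R at -1, A at 0, C at +1.  RRACH: R,R,A,C,H at -2..+2.
    """
    s = clean_sequence(seq)
    hits = []
    if mode == "RAC":
        for i in range(1, len(s) - 1):
            if s[i] == "A" and s[i - 1] in R_SET and s[i + 1] == "C":
                hits.append(i)
    elif mode == "RRACH":
        for i in range(2, len(s) - 2):
            if (s[i] == "A" and s[i - 2] in R_SET and s[i - 1] in R_SET
                    and s[i + 1] == "C" and s[i + 2] in H_SET):
                hits.append(i)
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    return hits


def build_label_track(window: PreMrnaWindow, site_genomic: list[int],
                      mode: str = "RAC", strict: bool = True) -> np.ndarray:
    """Per-gene-body 0/1 labels from genomic A coordinates.

    Positives must fall on consensus-matching A positions of the sense
    sequence; violations raise (strict) or are dropped with a warning.
    """
    labels = np.zeros(window.body_length, dtype=np.int8)
    consensus = set(find_consensus_sites(window.sequence, mode))
    for g in site_genomic:
        w = window.to_window(g)
        b = w - window.flank
        if not (0 <= b < window.body_length):
            raise ValueError(f"site {g} outside gene body of {window.gene_id}")
        if w not in consensus:
            msg = f"site {g} in {window.gene_id} does not match {mode} consensus"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg)
            continue
        labels[b] = 1
    return labels


# ---------------------------------------------------------------------------
# training blocks
# ---------------------------------------------------------------------------

@dataclass
class BlockPair:
    """One training example: B labelled positions with C context per side.

    ``sequence`` has length B + 2C (N-padded past the window ends); labels
    and mask have length B, mask 0 marking positions beyond the gene end
    (their labels are zero-padding, not data).
    """

    gene_id: str
    index: int  # 1-based
    sequence: str
    labels: np.ndarray
    mask: np.ndarray

    @property
    def inputs(self) -> np.ndarray:
        return one_hot_encode(self.sequence)


def split_blocks(window: PreMrnaWindow, labels: np.ndarray,
                 B: int = 5000, C: int = 5000) -> list[BlockPair]:
    """Split a window into ceil(body/B) blocks.

    Label block i (1-based) covers gene-body positions [B(i-1), B*i); its
    input covers the same span widened by C on each side, drawn from the
    window (flanks included) and N-padded beyond it.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    if C < 0:
        raise ValueError("C must be >= 0")
    body = window.body_length
    if len(labels) != body:
        raise ValueError("labels must cover the gene body")
    seq, flank = window.sequence, window.flank
    n_blocks = max(1, -(-body // B))
    out = []
    for i in range(1, n_blocks + 1):
        b0, b1 = B * (i - 1), B * i
        lab = np.zeros(B, dtype=np.int8)
        msk = np.zeros(B, dtype=np.int8)
        take = min(b1, body) - b0
        lab[:take] = labels[b0:b0 + take]
        msk[:take] = 1
        w0, w1 = flank + b0 - C, flank + b1 + C
        lo, hi = max(w0, 0), min(w1, len(seq))
        blockseq = "N" * (lo - w0) + seq[lo:hi] + "N" * (w1 - hi)
        out.append(BlockPair(window.gene_id, i, blockseq, lab, msk))
    return out


def concat_blocks(blocks: list[BlockPair]) -> np.ndarray:
    """Inverse of split_blocks on the label track (masked positions dropped)."""
    parts = [b.labels[b.mask.astype(bool)] for b in sorted(blocks, key=lambda b: b.index)]
    return np.concatenate(parts) if parts else np.zeros(0, dtype=np.int8)
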