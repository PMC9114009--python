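"""Synthetic genomes with a planted m6A cis-element grammar.

The generator emits a genome whose methylation probability at every
consensus A is a *known* function of the downstream pentamer content:

    linear link:    p = clip(b0 + sum_m e_m * count_m(window), 0, 1)
    logistic link:  p = sigmoid(b0 + sum_m e_m * count_m(window))

where count_m counts occurrences of pentamer m whose start offset (relative
to the methylated A at 0) lies in the grammar's active window.  Probability
is 0 at non-consensus positions.  The grammar doubles as an analytic scorer
satisfying the same contract as the trained ensemble, which makes every
perturbation/regression analysis exactly checkable.

Default motif families imitate the biology the package targets: enhancers
carry GAC/AAC cores (fragments of the RRACH consensus), silencers carry
CG/GT/CT dinucleotides.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (GeneModel, PreMrnaWindow, SequenceStore,
                        extract_premrna_window, find_consensus_sites,
                        reverse_complement)

ALL_PENTAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=5)]
STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedGrammar:
    """Ground-truth generative rule: pentamer effects in a downstream window."""

    enhancers: dict[str, float]
    silencers: dict[str, float]
    window: tuple[int, int] = (1, 50)  # inclusive start-offset interval
    baseline: float = 0.25
    link: str = "linear"
    consensus: str = "RAC"

    def __post_init__(self):
        if set(self.enhancers) & set(self.silencers):
            raise ValueError("enhancer and silencer sets must be disjoint")
        if any(e <= 0 for e in self.enhancers.values()):
            raise ValueError("enhancer effects must be positive")
        if any(e >= 0 for e in self.silencers.values()):
            raise ValueError("silencer effects must be negative")
        if self.link not in ("linear", "logistic"):
            raise ValueError(f"unknown link {self.link!r}")

    @property
    def effects(self) -> dict[str, float]:
        return {**self.enhancers, **self.silencers}

    def raw_score(self, seq: str, pos: int) -> float:
        """baseline + sum of planted effects over in-window pentamers."""
        lo, hi = self.window
        s = self.baseline
        eff = self.effects
        for start in range(pos + lo, pos + hi + 1):
            if 0 <= start and start + 5 <= len(seq):
                s += eff.get(seq[start:start + 5], 0.0)
        return s

    def site_probability(self, seq: str, pos: int) -> float:
        sites = find_consensus_sites(seq[max(0, pos - 2):pos + 3], self.consensus)
        if pos - max(0, pos - 2) not in sites:
            return 0.0
        s = self.raw_score(seq, pos)
        if self.link == "linear":
            return float(np.clip(s, 0.0, 1.0))
        return float(1.0 / (1.0 + np.exp(-s)))

    def is_clipped(self, seq: str, pos: int) -> bool:
        """True when the linear score left [0, 1] (linearity broken)."""
        if self.link != "linear":
            return False
        s = self.raw_score(seq, pos)
        return s < 0.0 or s > 1.0


class GrammarScorer:
    """Scorer-contract adapter around a PlantedGrammar."""

    def __init__(self, grammar: PlantedGrammar):
        self.grammar = grammar

    @property
    def margin(self) -> int:
        lo, hi = self.grammar.window
        return max(abs(lo), abs(hi)) + 4 + 2  # pentamer reach + consensus reach

    def score(self, seq: str) -> np.ndarray:
        out = np.zeros(len(seq))
        for pos in find_consensus_sites(seq, self.grammar.consensus):
            out[pos] = self.grammar.site_probability(seq, pos)
        return out

    def score_at(self, seq: str, pos: int) -> float:
        return self.grammar.site_probability(seq, pos)


def _family(substrings: tuple[str, ...], forbidden: tuple[str, ...] = ()):
    out = []
    for p in ALL_PENTAMERS:
        if any(s in p for s in substrings) and not any(s in p for s in forbidden):
            out.append(p)
    return out


ENHANCER_FAMILY = _family(("GAC", "AAC"))
SILENCER_FAMILY = _family(("CG", "GT", "CT"), forbidden=("GAC", "AAC"))


def make_grammar(n_enhancers: int = 10, n_silencers: int = 10,
                 enhancer_effects: tuple[float, float] = (0.12, 0.22),
                 silencer_effects: tuple[float, float] = (-0.22, -0.12),
                 baseline: float = 0.25, link: str = "linear",
                 window: tuple[int, int] = (1, 50), consensus: str = "RAC",
                 symmetric_effects: bool = False,
                 seed: int = 0) -> PlantedGrammar:
    """Sample a reproducible grammar from the enhancer/silencer families.

    ``symmetric_effects`` pairs each silencer with an enhancer and assigns
    it the negated enhancer effect, so all planted effects sum to zero (the
    centred gauge representative the joint regression reports).
    """
    if n_enhancers > len(ENHANCER_FAMILY) or n_silencers > len(SILENCER_FAMILY):
        raise ValueError("requested more motifs than the families contain")
    rng = np.random.default_rng(seed)
    enh = rng.choice(ENHANCER_FAMILY, size=n_enhancers, replace=False)
    sil = rng.choice(SILENCER_FAMILY, size=n_silencers, replace=False)
    e_lo, e_hi = enhancer_effects
    e_vals = rng.uniform(e_lo, e_hi, n_enhancers)
    if symmetric_effects:
        if n_silencers != n_enhancers:
            raise ValueError("symmetric effects need equal enhancer/silencer counts")
        s_vals = -e_vals
    else:
        s_lo, s_hi = silencer_effects
        s_vals = rng.uniform(s_lo, s_hi, n_silencers)
    return PlantedGrammar(
        enhancers={str(m): float(v) for m, v in zip(enh, e_vals)},
        silencers={str(m): float(v) for m, v in zip(sil, s_vals)},
        window=window, baseline=baseline, link=link, consensus=consensus,
    )


def default_logistic_grammar(seed: int = 0) -> PlantedGrammar:
    """Grammar on the logit scale, for classifier-training experiments."""
    return make_grammar(baseline=-3.0, link="logistic",
                        enhancer_effects=(0.8, 1.2),
                        silencer_effects=(-1.2, -0.8), seed=seed)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    """Study conditions for the synthetic genome.

    50 genes over two contigs (the second held out for independent testing),
    2-4 exons per gene with the CDS contained in the last exon, two planted
    high-probability sites per gene in the noncoding last exon with 4 planted
    enhancer occurrences each, and one consensus site inside the CDS for the
    codon-swap analyses.
    """

    n_genes: int = 50
    contigs: tuple[str, ...] = ("chrS1", "chrS2")
    test_contig: str = "chrS2"
    test_fraction: float = 0.3
    intergenic: tuple[int, int] = (250, 450)
    first_exon: tuple[int, int] = (80, 150)
    last_exon: tuple[int, int] = (450, 600)
    intron: tuple[int, int] = (100, 200)
    n_exons: tuple[int, int] = (2, 4)
    cds_len_codons: tuple[int, int] = (50, 70)
    positives_per_gene: int = 2
    enhancers_per_site: int = 4
    stop_tga_bias: float = 0.5        # P(stop == TGA); remainder split evenly
    stop_adjacent_site_prob: float = 0.5
    label_mode: str = "threshold"     # or "bernoulli"
    label_threshold: float = 0.5


@dataclass
class SyntheticGenome:
    contigs: dict[str, str]
    genes: list[GeneModel]
    truth: pd.DataFrame
    conservation: dict[str, list[tuple[int, float]]]
    grammar: PlantedGrammar
    config: GenomeConfig
    seed: int

    def store(self) -> SequenceStore:
        return SequenceStore(self.contigs)

    def window(self, gene: GeneModel, flank: int = 300) -> PreMrnaWindow:
        return extract_premrna_window(self.store(), gene, flank)

    def train_test_genes(self):
        test = [g for g in self.genes if g.chrom == self.config.test_contig]
        train = [g for g in self.genes if g.chrom != self.config.test_contig]
        return train, test

    # -- writers ----------------------------------------------------------
    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "bed": outdir / "m6a_sites.bed",
            "truth": outdir / "truth_sites.tsv",
            "bedgraph": outdir / "conservation.bedGraph",
        }
        write_fasta(self.contigs, paths["fasta"])
        write_gtf(self.genes, paths["gtf"])
        pos = self.truth[self.truth["label"] == 1]
        with open(paths["bed"], "w") as fh:
            for _, r in pos.iterrows():
                fh.write(f"{r.chrom}\t{r.genomic_pos}\t{r.genomic_pos + 1}\t"
                         f"{r.gene_id}\t{r.probability:.4f}\t{r.strand}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["bedgraph"], "w") as fh:
            for chrom in sorted(self.conservation):
                for gpos, val in sorted(self.conservation[chrom]):
                    fh.write(f"{chrom}\t{gpos}\t{gpos + 1}\t{val:.4f}\n")
        manifest = {
            "seed": self.seed,
            "config": asdict(self.config),
            "grammar": {
                "enhancers": self.grammar.enhancers,
                "silencers": self.grammar.silencers,
                "window": list(self.grammar.window),
                "baseline": self.grammar.baseline,
                "link": self.grammar.link,
                "consensus": self.grammar.consensus,
            },
            "files": {k: _md5(p) for k, p in paths.items()},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def _md5(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def write_fasta(contigs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}";'
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")
            if g.cds:
                s, e = g.cds
                fh.write(f"{g.chrom}\tsynthetic\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")


_NONSTOP_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)
                   if "".join(c) not in STOP_CODONS]


def _random_seq(rng, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


@dataclass
class _GeneDraft:
    sense: list[str]
    exon_rel: list[tuple[int, int]]      # body-relative, sense orientation
    cds_rel: tuple[int, int] | None
    planted_sites: list[int]             # body-relative A positions (sense)
    cds_site: int | None


def _draft_gene(rng: np.random.Generator, cfg: GenomeConfig,
                grammar: PlantedGrammar) -> _GeneDraft:
    n_ex = int(rng.integers(cfg.n_exons[0], cfg.n_exons[1] + 1))
    exon_lens = [int(rng.integers(*cfg.first_exon)) for _ in range(n_ex - 1)]
    exon_lens.append(int(rng.integers(*cfg.last_exon)))
    intron_lens = [int(rng.integers(*cfg.intron)) for _ in range(n_ex - 1)]
    exon_rel, cursor = [], 0
    for i, el in enumerate(exon_lens):
        exon_rel.append((cursor, cursor + el))
        cursor += el
        if i < len(intron_lens):
            cursor += intron_lens[i]
    body_len = cursor
    sense = _random_seq(rng, body_len)

    last_s, last_e = exon_rel[-1]
    # CDS inside the last exon, ending with a stop codon
    n_codons = int(rng.integers(*cfg.cds_len_codons))
    cds_start = last_s + int(rng.integers(15, 40))
    cds_end = cds_start + 3 * n_codons
    codons = list(rng.choice(_NONSTOP_CODONS, size=n_codons - 1))
    u = rng.random()
    if u < cfg.stop_tga_bias:
        stop = "TGA"
    else:
        stop = "TAA" if u < cfg.stop_tga_bias + (1 - cfg.stop_tga_bias) / 2 else "TAG"
    codons.append(stop)
    sense[cds_start:cds_end] = list("".join(codons))
    if rng.random() < cfg.stop_adjacent_site_prob:
        # stop-adjacent consensus (TRACN geometry): TGA followed by C
        sense[cds_end - 3:cds_end] = list("TGA")
        if cds_end < body_len:
            sense[cds_end] = "C"

    # one consensus site inside the CDS (codon pair GGA|CTG -> GGACT)
    cds_site = None
    if n_codons >= 40:
        ci = int(rng.integers(22, n_codons - 22))
        sense[cds_start + 3 * ci:cds_start + 3 * ci + 6] = list("GGACTG")
        cds_site = cds_start + 3 * ci + 2

    # planted high-probability sites in the noncoding last exon, with
    # enhancer occurrences written into their downstream window
    planted = []
    enh_motifs = sorted(grammar.enhancers)
    region_lo, region_hi = cds_end + 10, last_e - 60
    slots = np.arange(region_lo, region_hi, 65)
    rng.shuffle(slots)
    for p in slots[:cfg.positives_per_gene]:
        p = int(p)
        sense[p:p + 5] = list("GGACT")  # A of the site at p+2
        a = p + 2
        offsets = rng.choice([6, 12, 18, 24, 30, 36, 42],
                             size=cfg.enhancers_per_site, replace=False)
        picks = rng.choice(enh_motifs, size=cfg.enhancers_per_site,
                           replace=len(enh_motifs) < cfg.enhancers_per_site)
        for off, motif in zip(offsets, picks):
            sense[a + int(off):a + int(off) + 5] = list(motif)
        planted.append(a)
    return _GeneDraft(sense, exon_rel, (cds_start, cds_end), planted, cds_site)


def generate_genome(grammar: PlantedGrammar, config: GenomeConfig | None = None,
                    seed: int = 0) -> SyntheticGenome:
    """Build contigs, annotation, truth table and conservation track.

    Deterministic given (grammar, config, seed).  Truth labels come from
    the oracle probability, thresholded or Bernoulli-sampled per config.
    """
    cfg = config or GenomeConfig()
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(cfg.n_genes * cfg.test_fraction)))
    assignment = [cfg.test_contig] * n_test
    train_contigs = [c for c in cfg.contigs if c != cfg.test_contig]
    if not train_contigs:
        raise ValueError("config needs at least one non-test contig")
    assignment += [train_contigs[i % len(train_contigs)]
                   for i in range(cfg.n_genes - n_test)]
    rng.shuffle(assignment)

    contig_parts: dict[str, list[str]] = {c: [] for c in cfg.contigs}
    cursors: dict[str, int] = {c: 0 for c in cfg.contigs}
    genes: list[GeneModel] = []
    drafts: dict[str, _GeneDraft] = {}
    for gi in range(cfg.n_genes):
        chrom = assignment[gi]
        draft = _draft_gene(rng, cfg, grammar)
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(*cfg.intergenic))
        contig_parts[chrom].append("".join(_random_seq(rng, gap)))
        start = cursors[chrom] + gap
        body_len = len(draft.sense)
        sense_str = "".join(draft.sense)
        if strand == "+":
            genomic = sense_str
            exons = tuple((start + s, start + e) for s, e in draft.exon_rel)
            cds = (start + draft.cds_rel[0], start + draft.cds_rel[1])
        else:
            genomic = reverse_complement(sense_str)
            exons = tuple(sorted((start + body_len - e, start + body_len - s)
                                 for s, e in draft.exon_rel))
            cds = (start + body_len - draft.cds_rel[1],
                   start + body_len - draft.cds_rel[0])
        contig_parts[chrom].append(genomic)
        cursors[chrom] = start + body_len
        gid = f"G{gi:03d}"
        gene = GeneModel(gene_id=gid, transcript_id=f"{gid}.T1", chrom=chrom,
                         strand=strand, exons=exons, cds=cds)
        genes.append(gene)
        drafts[gid] = draft
    for c in cfg.contigs:
        tail = int(rng.integers(*cfg.intergenic))
        contig_parts[c].append("".join(_random_seq(rng, tail)))
    contigs = {c: "".join(parts) for c, parts in contig_parts.items()}

    # truth table: every consensus site in every gene body, oracle-scored
    store = SequenceStore(contigs)
    rows = []
    conservation: dict[str, list[tuple[int, float]]] = {c: [] for c in cfg.contigs}
    for gene in genes:
        win = extract_premrna_window(store, gene, flank=0)
        body = win.sequence
        cons_scores = rng.normal(0.0, 0.3, size=len(body))
        for pos in find_consensus_sites(body, grammar.consensus):
            p = grammar.site_probability(body, pos)
            if cfg.label_mode == "threshold":
                label = int(p >= cfg.label_threshold)
            elif cfg.label_mode == "bernoulli":
                label = int(rng.random() < p)
            else:
                raise ValueError(f"unknown label_mode {cfg.label_mode!r}")
            if label:
                lo, hi = grammar.window
                lo_c = max(0, pos + max(lo, 1))
                hi_c = min(len(body), pos + hi + 1)
                cons_scores[lo_c:hi_c] += 1.5
            rows.append({
                "gene_id": gene.gene_id, "chrom": gene.chrom,
                "strand": gene.strand, "body_offset": pos,
                "genomic_pos": win.to_genomic(pos),
                "probability": p, "label": label,
                "in_cds": bool(gene.cds and
                               min(win.to_genomic(pos), win.to_genomic(pos)) in
                               range(gene.cds[0], gene.cds[1])),
            })
        for i, v in enumerate(cons_scores):
            conservation[gene.chrom].append((win.to_genomic(i), float(v)))
    truth = pd.DataFrame(rows)
    return SyntheticGenome(contigs=contigs, genes=genes, truth=truth,
                           conservation=conservation, grammar=grammar,
                           config=cfg, seed=seed)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def generate_variants(genome: SyntheticGenome, n: int, seed: int = 0,
                      offset_range: tuple[int, int] = (-100, 100),
                      flank: int = 300) -> pd.DataFrame:
    """SNVs near truth sites with their expected oracle ΔProbability.

    The expected delta is the oracle probability of the focal site after the
    substitution minus before, computed on the sense-strand window; alleles
    are reported on the genomic plus strand as in VCF.
    """
    rng = np.random.default_rng(seed)
    scorer = GrammarScorer(genome.grammar)
    sites = genome.truth[genome.truth["probability"] > 0.05]
    if sites.empty:
        raise ValueError("no scoreable truth sites")
    rows = []
    windows = {g.gene_id: genome.window(g, flank) for g in genome.genes}
    idx = rng.integers(0, len(sites), size=n)
    for vi, si in enumerate(idx):
        site = sites.iloc[si]
        win = windows[site.gene_id]
        w_site = int(site.body_offset) + flank
        off = int(rng.integers(offset_range[0], offset_range[1] + 1))
        w_var = w_site + off
        if not (0 <= w_var < len(win.sequence)):
            continue
        ref_sense = win.sequence[w_var]
        if ref_sense == "N":
            continue
        alt_sense = str(rng.choice([c for c in "ACGT" if c != ref_sense]))
        mutated = win.sequence[:w_var] + alt_sense + win.sequence[w_var + 1:]
        before = scorer.score_at(win.sequence, w_site)
        after = scorer.score_at(mutated, w_site)
        gpos = win.to_genomic(w_var)
        if win.strand == "+":
            ref_g, alt_g = ref_sense, alt_sense
        else:
            ref_g, alt_g = (reverse_complement(ref_sense),
                            reverse_complement(alt_sense))
        rows.append({
            "variant_id": f"snv{vi:04d}", "chrom": win.chrom, "pos": gpos,
            "ref": ref_g, "alt": alt_g, "gene_id": site.gene_id,
            "site_genomic_pos": int(site.genomic_pos), "offset": off,
            "expected_delta": after - before,
        })
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt",
                                       "gene_id", "site_genomic_pos", "offset",
                                       "expected_delta"])


def write_vcf(variants: pd.DataFrame, contigs: dict[str, str], path) -> None:
    """Plain-text VCF 4.2 with the expected delta in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in sorted(contigs):
            fh.write(f"##contig=<ID={name},length={len(contigs[name])}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
        fh.write('##INFO=<ID=SITE,Number=1,Type=Integer,'
                 'Description="Genomic position of the affected m6A site">\n')
        fh.write('##INFO=<ID=EXPDELTA,Number=1,Type=Float,'
                 'Description="Expected probability change at the site">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in variants.sort_values(["chrom", "pos"]).iterrows():
            info = (f"GENE={r.gene_id};SITE={r.site_genomic_pos};"
                    f"EXPDELTA={r.expected_delta:.6f}")
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.variant_id}\t{r.ref}\t"
                     f"{r.alt}\t.\t.\t{info}\n")
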