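"""In-silico perturbation engine.

Every operation takes a scorer satisfying the scorer contract (``score(seq)``
per-position probabilities; optional ``score_at(seq, pos)``; ``margin``
receptive half-width) plus a sense-strand sequence, mutates the sequence,
and reports ΔProbability = P(mutant) - P(reference) at a focal site.  To
keep saturation scans cheap the rescoring is restricted to a subwindow
around the focal site wide enough to contain both the perturbation span and
the scorer's receptive field — by locality the result is identical to
rescoring the full sequence.
"""

from __future__ import annotations

import pandas as pd

from .genome_io import find_consensus_sites

#: codon -> amino acid (standard genetic code), built from biopython
from Bio.Data.CodonTable import standard_dna_table as _STD

CODON_TO_AA = dict(_STD.forward_table)
for _stop in _STD.stop_codons:
    CODON_TO_AA[_stop] = "*"

SYNONYMS: dict[str, list[str]] = {
    c: sorted(c2 for c2, a2 in CODON_TO_AA.items() if a2 == CODON_TO_AA[c] and c2 != c)
    for c in CODON_TO_AA
}

STOP_CODONS = ("TAA", "TAG", "TGA")

#: stop-adjacent consensus geometries; offsets are relative to the stop's T
#: at 0 and name the methylatable A of each motif
STOP_ADJACENT_MOTIFS = {
    "NRACTRR": -2,
    "TRACN": 2,
    "TRRACN": 3,
}

_IUPAC = {"N": "ACGT", "R": "AG", "H": "ACT",
          "A": "A", "C": "C", "G": "G", "T": "T"}


def _score_at(scorer, seq: str, pos: int) -> float:
    if hasattr(scorer, "score_at"):
        return float(scorer.score_at(seq, pos))
    return float(scorer.score(seq)[pos])


def _subwindow(seq: str, site: int, reach: int, margin: int):
    """Slice wide enough that the focal probability is unchanged."""
    radius = reach + margin
    lo = max(0, site - radius)
    hi = min(len(seq), site + radius + 1)
    return seq[lo:hi], site - lo


def _require_consensus(seq: str, site: int, mode: str = "RAC"):
    lo = max(0, site - 2)
    if site - lo not in find_consensus_sites(seq[lo:site + 3], mode):
        raise ValueError(f"position {site} does not match the {mode} consensus")


# ---------------------------------------------------------------------------
# single-nucleotide saturation mutagenesis
# ---------------------------------------------------------------------------

def saturation_mutagenesis(scorer, seq: str, site: int,
                           span: tuple[int, int] = (-250, 250),
                           site_id: str = "site",
                           exclude_consensus: bool = False) -> pd.DataFrame:
    """Substitute every position in ``span`` by the three other nucleotides.

    Returns one row per event: offset (A of the site = 0, downstream
    positive), ref/alt base, and delta = P(mutant) - P(reference) at the
    focal site.  Offset 0 (the methylated A itself) is included by default;
    ``exclude_consensus`` drops the events touching the RAC triplet
    (offsets -1, 0, +1), isolating the flanking cis-element signal from
    consensus destruction.
    """
    lo, hi = span
    if site + lo < 0 or site + hi >= len(seq):
        raise ValueError("span extends beyond the sequence")
    _require_consensus(seq, site)
    margin = int(getattr(scorer, "margin", 100))
    sub, s = _subwindow(seq, site, max(abs(lo), abs(hi)), margin)
    ref_prob = _score_at(scorer, sub, s)
    rows = []
    for off in range(lo, hi + 1):
        if exclude_consensus and -1 <= off <= 1:
            continue
        p = s + off
        ref = sub[p]
        if ref == "N":
            continue
        for alt in "ACGT":
            if alt == ref:
                continue
            mut = sub[:p] + alt + sub[p + 1:]
            delta = _score_at(scorer, mut, s) - ref_prob
            rows.append({"site_id": site_id, "offset": off, "ref": ref,
                         "alt": alt, "ref_prob": ref_prob, "delta": delta})
    return pd.DataFrame(rows, columns=["site_id", "offset", "ref", "alt",
                                       "ref_prob", "delta"])


def mutagenesis_matrix(events: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-ready (offset x alt) ΔProbability matrix for one site."""
    return events.pivot_table(index="offset", columns="alt", values="delta")


# ---------------------------------------------------------------------------
# synonymous codon swaps
# ---------------------------------------------------------------------------

def synonymous_swap_scan(scorer, seq: str, site: int,
                         cds_start: int, cds_end: int,
                         codon_span: tuple[int, int] = (-15, 15),
                         site_id: str = "site",
                         min_margin: int = 60) -> pd.DataFrame:
    """Swap each codon around the site by each of its synonymous codons.

    Codon 0 is the codon containing the methylated A, with the frame
    anchored at ``cds_start``.  The site must lie inside the CDS at least
    ``min_margin`` nt from both CDS ends.  Swaps of codon 0 that destroy the
    consensus are kept but flagged.
    """
    if not (cds_start <= site < cds_end):
        raise ValueError("site outside the CDS")
    if site - cds_start < min_margin or cds_end - site < min_margin:
        raise ValueError(f"site closer than {min_margin} nt to a CDS end")
    if (cds_end - cds_start) % 3:
        raise ValueError("CDS length not divisible by 3")
    _require_consensus(seq, site)
    codon0_start = site - (site - cds_start) % 3
    margin = int(getattr(scorer, "margin", 100))
    reach = 3 * (max(map(abs, codon_span)) + 1) + 3
    sub, s = _subwindow(seq, site, reach, margin)
    shift = s - site
    ref_prob = _score_at(scorer, sub, s)
    rows = []
    for ci in range(codon_span[0], codon_span[1] + 1):
        c0 = codon0_start + 3 * ci + shift
        if c0 < 0 or c0 + 3 > len(sub):
            continue
        if not (cds_start + shift <= c0 and c0 + 3 <= cds_end + shift):
            continue
        ref_codon = sub[c0:c0 + 3]
        if "N" in ref_codon:
            continue
        for alt_codon in SYNONYMS[ref_codon]:
            mut = sub[:c0] + alt_codon + sub[c0 + 3:]
            delta = _score_at(scorer, mut, s) - ref_prob
            lo2 = max(0, s - 2)
            breaks = s - lo2 not in find_consensus_sites(mut[lo2:s + 3], "RAC")
            rows.append({"site_id": site_id, "codon_offset": ci,
                         "ref_codon": ref_codon, "alt_codon": alt_codon,
                         "aa": CODON_TO_AA[ref_codon], "ref_prob": ref_prob,
                         "delta": delta, "breaks_consensus": breaks})
    return pd.DataFrame(rows, columns=["site_id", "codon_offset", "ref_codon",
                                       "alt_codon", "aa", "ref_prob", "delta",
                                       "breaks_consensus"])


# ---------------------------------------------------------------------------
# stop-codon analyses
# ---------------------------------------------------------------------------

def _matches(seq: str, start: int, pattern: str) -> bool:
    if start < 0 or start + len(pattern) > len(seq):
        return False
    return all(seq[start + i] in _IUPAC[p] for i, p in enumerate(pattern))


def stop_adjacent_sites(seq: str, stop_pos: int) -> dict[str, int]:
    """Stop-adjacent consensus A positions present around a stop codon.

    ``stop_pos`` indexes the stop's T.  Returns motif -> absolute A position
    for each of NRACTRR (A at -2), TRACN (A at +2) and TRRACN (A at +3)
    whose full context matches.
    """
    out = {}
    a_idx = {"NRACTRR": 2, "TRACN": 2, "TRRACN": 3}
    for motif, a_off in STOP_ADJACENT_MOTIFS.items():
        start = stop_pos + a_off - a_idx[motif]
        if _matches(seq, start, motif):
            out[motif] = stop_pos + a_off
    return out


def stop_codon_swap(scorer, seq: str, stop_pos: int, new_stop: str,
                    transcript_id: str = "tx") -> pd.DataFrame:
    """Replace the stop codon and report deltas at stop-adjacent A motifs.

    Only motifs whose A exists and matches in the *reference* sequence are
    reported; positions without a matching A are absent from the result.
    """
    old_stop = seq[stop_pos:stop_pos + 3]
    if old_stop not in STOP_CODONS:
        raise ValueError(f"no stop codon at position {stop_pos} (found {old_stop!r})")
    if new_stop not in STOP_CODONS or new_stop == old_stop:
        raise ValueError(f"new stop must be a different stop codon, got {new_stop!r}")
    mut = seq[:stop_pos] + new_stop + seq[stop_pos + 3:]
    rows = []
    for motif, a_pos in stop_adjacent_sites(seq, stop_pos).items():
        before = _score_at(scorer, seq, a_pos)
        after = _score_at(scorer, mut, a_pos)
        rows.append({"transcript_id": transcript_id, "motif": motif,
                     "stop_offset": a_pos - stop_pos, "old_stop": old_stop,
                     "new_stop": new_stop, "ref_prob": before,
                     "delta": after - before})
    return pd.DataFrame(rows, columns=["transcript_id", "motif", "stop_offset",
                                       "old_stop", "new_stop", "ref_prob",
                                       "delta"])


def stop_profile(scorer, transcripts: list[tuple[str, int]],
                 span: tuple[int, int] = (-500, 500)) -> pd.DataFrame:
    """Mean probability curve around the stop per stop-codon group.

    ``transcripts`` is a list of (sense sequence, stop T position).  Offset 0
    is the stop's T; positions outside a transcript are simply excluded from
    that transcript's contribution (mean over covering transcripts).
    """
    lo, hi = span
    groups: dict[str, tuple[list, list]] = {s: ([0.0] * (hi - lo + 1),
                                                [0] * (hi - lo + 1))
                                            for s in STOP_CODONS}
    for seq, stop_pos in transcripts:
        stop = seq[stop_pos:stop_pos + 3]
        if stop not in STOP_CODONS:
            raise ValueError(f"no stop codon at {stop_pos}")
        probs = scorer.score(seq)
        total, count = groups[stop]
        for i, off in enumerate(range(lo, hi + 1)):
            p = stop_pos + off
            if 0 <= p < len(seq):
                total[i] += float(probs[p])
                count[i] += 1
    rows = []
    for stop, (total, count) in groups.items():
        for i, off in enumerate(range(lo, hi + 1)):
            if count[i]:
                rows.append({"stop": stop, "offset": off,
                             "mean_prob": total[i] / count[i], "n": count[i]})
    return pd.DataFrame(rows, columns=["stop", "offset", "mean_prob", "n"])


# ---------------------------------------------------------------------------
# variant effects
# ---------------------------------------------------------------------------

def variant_delta(scorer, seq: str, var_pos: int, ref: str, alt: str,
                  site_search_radius: int = 500,
                  mode: str = "RAC") -> pd.DataFrame:
    """ΔProbability at every consensus site within reach of one SNV.

    The variant is classified upstream / at-site / downstream relative to
    the site with the largest |delta|.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only SNVs are supported")
    if seq[var_pos] != ref:
        raise ValueError(f"reference mismatch at {var_pos}: "
                         f"sequence has {seq[var_pos]!r}, variant says {ref!r}")
    mut = seq[:var_pos] + alt + seq[var_pos + 1:]
    lo = max(0, var_pos - site_search_radius)
    hi = min(len(seq), var_pos + site_search_radius + 1)
    # sites are read from the reference; a variant can also create sites,
    # but deltas are anchored at reference consensus positions
    sites = [p + lo for p in find_consensus_sites(seq[lo:hi], mode)]
    rows = []
    for site in sites:
        before = _score_at(scorer, seq, site)
        after = _score_at(scorer, mut, site)
        d = after - before
        if alt == ref:
            d = 0.0
        rows.append({"site_pos": site, "offset": var_pos - site,
                     "ref_prob": before, "mut_prob": after, "delta": d})
    df = pd.DataFrame(rows, columns=["site_pos", "offset", "ref_prob",
                                     "mut_prob", "delta"])
    if not df.empty:
        top = df.loc[df["delta"].abs().idxmax()]
        side = ("at_site" if top.offset == 0
                else "downstream" if top.offset > 0 else "upstream")
        df.attrs["classification"] = side
        df.attrs["top_site_pos"] = int(top.site_pos)
    return df


def delta_effective_value(seq: str, var_pos: int, ref: str, alt: str,
                          effects: dict[str, float]) -> tuple[float, bool]:
    """Sum of effects of created pentamers minus broken pentamers.

    A substitution touches the 5 pentamers whose start offsets span it;
    incomplete pentamers at sequence edges are skipped and flagged.
    Missing motifs count as effect 0.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only SNVs are supported")
    if seq[var_pos] != ref:
        raise ValueError("reference mismatch")
    mut = seq[:var_pos] + alt + seq[var_pos + 1:]
    total, truncated = 0.0, False
    for start in range(var_pos - 4, var_pos + 1):
        if start < 0 or start + 5 > len(seq):
            truncated = True
            continue
        created = mut[start:start + 5]
        broken = seq[start:start + 5]
        total += effects.get(created, 0.0) - effects.get(broken, 0.0)
    return total, truncated
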