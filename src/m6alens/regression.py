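"""Per-pentamer / per-codon effect estimation by linear regression.

Each substitution event simultaneously creates and breaks up to five
overlapping pentamers (or exactly one codon for a synonymous swap).  The
design assigns predictor value count_created(m) - count_broken(m) to each
motif m and regresses ΔProbability on all motifs jointly (default) or on
one motif at a time (marginal mode, for sensitivity analysis).  The fitted
slope is the motif's "effect value"; positive effects are m6A enhancers,
negative ones silencers.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ALL_PENTAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=5)]
ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


@dataclass
class DesignRow:
    response: float
    created: Counter
    broken: Counter
    site_id: str = "site"
    offset: int = 0

    def predictors(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m, c in self.created.items():
            out[m] = out.get(m, 0) + c
        for m, c in self.broken.items():
            out[m] = out.get(m, 0) - c
        return {m: v for m, v in out.items() if v != 0}


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_pentamer_design(seq: str, site: int, events: pd.DataFrame,
                          positions: tuple[int, int] = (3, 46),
                          motif_window: tuple[int, int] | None = None,
                          ) -> list[DesignRow]:
    """Design rows from single-nucleotide mutagenesis events at one site.

    ``events`` is the output of saturation_mutagenesis.  Events outside
    ``positions`` are skipped (count logged).  Created pentamers are read
    from the mutant sequence at the five start offsets covering the
    substituted position, broken ones from the reference at the same
    offsets; ``motif_window`` optionally restricts the counted start
    offsets (relative to the site's A) when the causal window is known.
    """
    lo, hi = positions
    rows, skipped = [], 0
    for ev in events.itertuples():
        if not (lo <= ev.offset <= hi):
            skipped += 1
            continue
        p = site + ev.offset
        if seq[p] != ev.ref:
            raise ValueError(f"event ref {ev.ref!r} does not match sequence at {p}")
        mut = seq[:p] + ev.alt + seq[p + 1:]
        created, broken = Counter(), Counter()
        for s_rel in range(ev.offset - 4, ev.offset + 1):
            if motif_window is not None and not (motif_window[0] <= s_rel <= motif_window[1]):
                continue
            start = site + s_rel
            if start < 0 or start + 5 > len(seq):
                continue
            created[mut[start:start + 5]] += 1
            broken[seq[start:start + 5]] += 1
        rows.append(DesignRow(response=float(ev.delta), created=created,
                              broken=broken, site_id=str(ev.site_id),
                              offset=int(ev.offset)))
    if skipped:
        log.info("build_pentamer_design: skipped %d events outside %s",
                 skipped, positions)
    return rows


def build_codon_design(swaps: pd.DataFrame,
                       positions: tuple[int, int] = (1, 15)) -> list[DesignRow]:
    """Design rows from synonymous codon swaps: one created, one broken codon."""
    from .perturbation import CODON_TO_AA

    lo, hi = positions
    rows, skipped = [], 0
    for ev in swaps.itertuples():
        if not (lo <= ev.codon_offset <= hi):
            skipped += 1
            continue
        if CODON_TO_AA[ev.ref_codon] != CODON_TO_AA[ev.alt_codon]:
            raise ValueError(f"{ev.ref_codon}->{ev.alt_codon} is not synonymous")
        rows.append(DesignRow(response=float(ev.delta),
                              created=Counter([ev.alt_codon]),
                              broken=Counter([ev.ref_codon]),
                              site_id=str(ev.site_id),
                              offset=int(ev.codon_offset)))
    if skipped:
        log.info("build_codon_design: skipped %d swaps outside %s", skipped, positions)
    return rows


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class MotifEffectTable:
    """Per-motif regression slopes with p-values and ranks.

    Motifs never observed with a nonzero predictor are non-identifiable:
    their effect and p-value are NaN, not 0.
    """

    table: pd.DataFrame
    mode: str
    positions: tuple[int, int] | None = None

    @property
    def identifiable(self) -> pd.DataFrame:
        return self.table[self.table["effect"].notna()]

    def effects_dict(self, fill: float = 0.0) -> dict[str, float]:
        eff = self.table["effect"].fillna(fill)
        return dict(zip(self.table["motif"], eff))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _universe(rows: list[DesignRow]) -> list[str]:
    for r in rows:
        for m in (*r.created, *r.broken):
            return ALL_PENTAMERS if len(m) == 5 else ALL_CODONS
    raise ValueError("no motifs in design")


def fit_effects(rows: list[DesignRow], mode: str = "joint",
                positions: tuple[int, int] | None = None) -> MotifEffectTable:
    """Fit motif effects over the full motif universe (1024 or 64).

    joint: one multiple regression of response on all identifiable motif
    predictors plus an intercept; effects are the coefficients, p-values
    two-sided coefficient t-tests.  marginal: per-motif simple regression.
    """
    if not rows:
        raise ValueError("no design rows")
    motifs = _universe(rows)
    midx = {m: j for j, m in enumerate(motifs)}
    n, p = len(rows), len(motifs)
    X = np.zeros((n, p))
    y = np.empty(n)
    for i, r in enumerate(rows):
        y[i] = r.response
        for m, v in r.predictors().items():
            X[i, midx[m]] = v
    observed = (X != 0).any(axis=0)
    n_events = (X != 0).sum(axis=0)

    effect = np.full(p, np.nan)
    pval = np.full(p, np.nan)
    if mode == "joint":
        cols = np.flatnonzero(observed)
        Xi = np.column_stack([X[:, cols], np.ones(n)])
        G = Xi.T @ Xi
        # The design carries an intrinsic gauge: every substitution creates
        # and breaks equally many motifs, so the predictors of each row sum
        # to zero and effects are identified only up to a uniform shift.
        # The pseudoinverse gives the minimum-norm (centred) representative.
        Ginv = np.linalg.pinv(G, rcond=1e-10, hermitian=True)
        rank = int(np.linalg.matrix_rank(G, tol=1e-10 * float(np.trace(G))))
        beta = Ginv @ (Xi.T @ y)
        resid = y - Xi @ beta
        dof = n - rank
        if dof > 0:
            sigma2 = float(resid @ resid) / dof
            se = np.sqrt(np.clip(np.diag(Ginv) * sigma2, 0, None))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, beta / se,
                             np.where(beta == 0, 0.0, np.inf))
            pv = 2 * stats.t.sf(np.abs(t), dof)
        else:
            pv = np.full(Xi.shape[1], np.nan)
        effect[cols] = beta[:-1]
        pval[cols] = pv[:-1]
    elif mode == "marginal":
        for j in np.flatnonzero(observed):
            res = stats.linregress(X[:, j], y)
            effect[j] = res.slope
            pval[j] = res.pvalue
    else:
        raise ValueError(f"unknown mode {mode!r}")

    df = pd.DataFrame({"motif": motifs, "effect": effect, "p_value": pval,
                       "n_events": n_events})
    # rank by effect descending among identifiable motifs
    order = df["effect"].rank(ascending=False, method="first")
    df["rank"] = order.astype("Int64")
    df["q_value"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return MotifEffectTable(table=df, mode=mode, positions=positions)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return q
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    q[ok] = out
    return q


def top_motifs(table: MotifEffectTable, n: int) -> dict[str, list[str]]:
    """Top-n enhancers (largest effects) and silencers (most negative).

    Ties break by p-value then lexicographically; n is truncated to the
    number of identifiable motifs with a warning.
    """
    ident = table.identifiable
    if n > len(ident):
        log.warning("requested top %d of %d identifiable motifs", n, len(ident))
        n = len(ident)
    enh = ident.sort_values(["effect", "p_value", "motif"],
                            ascending=[False, True, True])
    sil = ident.sort_values(["effect", "p_value", "motif"],
                            ascending=[True, True, True])
    return {"enhancers": list(enh["motif"].head(n)),
            "silencers": list(sil["motif"].head(n))}


def motif_dendrogram(motifs: list[str]):
    """Average-linkage clustering of motifs on Hamming distance.

    Presentational companion to the top-motif lists; returns the scipy
    linkage matrix.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    k = len(motifs)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = sum(a != b for a, b in zip(motifs[i], motifs[j]))
    return linkage(squareform(D), method="average")
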