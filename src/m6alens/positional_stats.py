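"""Positional profiles and the statistical tests used by the analyses.

Profiles report mean ± SEM of per-site indicator counts (motif occurrence,
conservation score) at each offset relative to the methylated A (offset 0).
The tests are thin, uniformly-shaped wrappers around scipy: exact binomial
upper tail, two-sided Fisher's exact, two-sample KS, and the simple linear
regression used for genotype/methylation association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    p_value: float
    effect: float | None = None
    effect_name: str | None = None

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# positional profiles
# ---------------------------------------------------------------------------

@dataclass
class PositionalProfile:
    offsets: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_sites: int
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean,
                             "sem": self.sem, "n": self.n_sites,
                             "group": self.group})


def _sem(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    if n < 2:
        return np.zeros(values.shape[1])
    return values.std(axis=0, ddof=1) / np.sqrt(n)


def motif_positional_profile(sequences: list[str], sites: list[int],
                             motif_set: set[str],
                             span: tuple[int, int] = (-50, 50),
                             group: str = "") -> PositionalProfile:
    """Frequency of motif-set occurrences by start offset around sites.

    A motif occurrence is assigned to the offset of its *start* relative to
    the site's A.  Sites whose span is not fully covered by their sequence
    are excluded (count reflected in n_sites).
    """
    if not motif_set:
        k = 5
    else:
        ks = {len(m) for m in motif_set}
        if len(ks) != 1:
            raise ValueError("motif set must be of uniform length")
        k = ks.pop()
    lo, hi = span
    per_site = []
    for seq, site in zip(sequences, sites):
        if site + lo < 0 or site + hi + k > len(seq):
            continue
        row = [1.0 if seq[site + off:site + off + k] in motif_set else 0.0
               for off in range(lo, hi + 1)]
        per_site.append(row)
    if not per_site:
        raise ValueError("no site has full span coverage")
    vals = np.asarray(per_site)
    return PositionalProfile(np.arange(lo, hi + 1), vals.mean(axis=0),
                             _sem(vals), len(per_site), group)


def conservation_profile(scores_per_site: list[np.ndarray],
                         span: tuple[int, int] = (-50, 50),
                         group: str = "") -> PositionalProfile:
    """Mean ± SEM conservation score per offset.

    Each entry of ``scores_per_site`` is the per-base score vector over the
    span (length hi-lo+1), already extracted around one site; NaNs mark
    positions without coverage and are excluded from the mean.
    """
    lo, hi = span
    width = hi - lo + 1
    vals = np.asarray([np.asarray(s, dtype=float) for s in scores_per_site])
    if vals.size == 0:
        raise ValueError("no conservation coverage")
    if vals.shape[1] != width:
        raise ValueError(f"score vectors must have length {width}")
    mean = np.nanmean(vals, axis=0)
    n = np.sum(~np.isnan(vals), axis=0)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(vals, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return PositionalProfile(np.arange(lo, hi + 1), mean, sem,
                             vals.shape[0], group)


def extract_conservation(track: dict[int, float], center: int,
                         span: tuple[int, int] = (-50, 50)) -> np.ndarray:
    """Score vector around one genomic position; missing positions are NaN."""
    lo, hi = span
    return np.array([track.get(center + off, np.nan)
                     for off in range(lo, hi + 1)])


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def binomial_tail(k: int, n: int, p: float) -> TestResult:
    """Exact one-sided upper tail P(X >= k) for X ~ Binomial(n, p)."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < p < 1.0):
        raise ValueError("need 0 < p < 1")
    pv = float(stats.binom.sf(k - 1, n, p))
    return TestResult(statistic=float(k), p_value=pv,
                      effect=n * p, effect_name="expectation")


def fisher_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test; effect is the odds ratio ad/bc."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        raise ValueError("table has an all-zero margin")
    odds, pv = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(pv),
                      effect=float(odds), effect_name="odds_ratio")


def ks_two_sample(x, y) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov, asymptotic p-value."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      effect=float(res.statistic), effect_name="D")


def genotype_association(levels, genotypes) -> TestResult:
    """Linear regression of a methylation level on genotype codes {0, .5, 1}."""
    levels = np.asarray(levels, dtype=float)
    genotypes = np.asarray(genotypes, dtype=float)
    if len(levels) != len(genotypes) or len(levels) < 3:
        raise ValueError("need >= 3 paired samples")
    if len(np.unique(genotypes)) < 2:
        raise ValueError("genotype is constant")
    res = stats.linregress(genotypes, levels)
    # perfect fits give rvalue == 1 and p 0; guard nan from zero variance in y
    pv = 0.0 if np.isnan(res.pvalue) else float(res.pvalue)
    t = np.inf if res.stderr == 0 else float(res.slope / res.stderr)
    return TestResult(statistic=t, p_value=pv,
                      effect=float(res.slope), effect_name="slope")


# ---------------------------------------------------------------------------
# site grouping
# ---------------------------------------------------------------------------

def group_sites(predictions: pd.DataFrame,
                thresholds: tuple[float, float] = (0.7, 0.1),
                prob_column: str = "probability") -> dict[str, pd.DataFrame]:
    """Split consensus sites into positive / control / discarded groups.

    ``thresholds`` is (high, low): probability >= high is positive,
    < low is the consensus-matched control, anything between is discarded.
    """
    high, low = thresholds
    if low >= high:
        raise ValueError("thresholds must satisfy low < high")
    p = predictions[prob_column]
    return {
        "positive": predictions[p >= high],
        "control": predictions[p < low],
        "discarded": predictions[(p >= low) & (p < high)],
    }


# ---------------------------------------------------------------------------
# plots (presentational)
# ---------------------------------------------------------------------------

def plot_profiles(profiles: list[PositionalProfile], ax=None, title: str = ""):
    """Line profiles with SEM ribbons, one line per group."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    for prof in profiles:
        ax.plot(prof.offsets, prof.mean, label=prof.group or None)
        ax.fill_between(prof.offsets, prof.mean - prof.sem,
                        prof.mean + prof.sem, alpha=0.3)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("offset from m6A site (nt)")
    ax.set_ylabel("mean ± SEM")
    if title:
        ax.set_title(title)
    if any(p.group for p in profiles):
        ax.legend()
    return ax


def plot_cdf(samples: dict[str, np.ndarray], ax=None, title: str = ""):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    for name, x in samples.items():
        xs = np.sort(np.asarray(x))
        ax.step(xs, np.arange(1, len(xs) + 1) / len(xs), where="post", label=name)
    ax.set_xlabel("value")
    ax.set_ylabel("CDF")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
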