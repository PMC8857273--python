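"""Sequence composition statistics: AT%, oligonucleotide usage deviation
under a zero-order Markov expectation, and their relation to protein
recruitment (ChIP enrichment fold).

The usage deviation of a word W in a region is observed/expected where
the expectation removes mononucleotide-frequency bias:
``expected(W) = (L - k + 1) * prod_i f(W_i)`` with f the region's own
base frequencies.  A deviation above 1 means the word is over-represented
given base composition alone; TpA steps (the most flexible dinucleotide)
are the signature of silencer-bound DNA.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"


def at_percent(seq: str) -> float:
    """AT content in percent, computed over unambiguous bases only.

    N contributes to neither numerator nor denominator; an all-N (or
    empty) sequence is an error.
    """
    seq = seq.upper()
    counts = {b: seq.count(b) for b in BASES}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous bases in sequence")
    return 100.0 * (counts["A"] + counts["T"]) / total


def words(k: int) -> list[str]:
    return ["".join(w) for w in itertools.product(BASES, repeat=k)]


@dataclass
class OligoDeviationTable:
    """Observed/expected usage deviations for all 4^k words of a region."""

    region_id: str
    k: int
    values: dict[str, float]  # word -> deviation; NaN = undefined
    observed: dict[str, int]
    expected: dict[str, float]


def oligo_deviation(seq: str, k: int, region_id: str = "") -> OligoDeviationTable:
    """Zero-order-Markov usage deviation for every word of length k.

    Observed counts use overlapping, non-circular windows.  Expected
    counts derive from the region's own mononucleotide frequencies
    (N excluded).  A word containing a base absent from the region has
    expected 0; its deviation is undefined and reported as NaN.
    """
    if k not in (2, 3, 4):
        raise ValueError("k must be 2, 3 or 4")
    seq = seq.upper()
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    n_windows = len(seq) - k + 1
    base_counts = {b: seq.count(b) for b in BASES}
    n_bases = sum(base_counts.values())
    if n_bases == 0:
        raise ValueError("no unambiguous bases in sequence")
    freqs = {b: base_counts[b] / n_bases for b in BASES}

    observed: dict[str, int] = {w: 0 for w in words(k)}
    for i in range(n_windows):
        w = seq[i : i + k]
        if w in observed:  # windows containing N match no word
            observed[w] += 1

    expected: dict[str, float] = {}
    values: dict[str, float] = {}
    for w in observed:
        e = n_windows * float(np.prod([freqs[b] for b in w]))
        expected[w] = e
        values[w] = observed[w] / e if e > 0 else float("nan")
    return OligoDeviationTable(region_id, k, values, observed, expected)


@dataclass
class BindingPreference:
    """Per-word rank correlation between usage deviation and recruitment."""

    word: str
    rho: float
    p_value: float
    n: int


def binding_preference(
    peak_regions: Sequence[tuple[str, str, float]],
    k: int = 2,
    bh_correct: bool = False,
) -> list[BindingPreference]:
    """Spearman's rho between per-peak word deviations and enrichment fold.

    ``peak_regions`` holds (region_id, sequence, enrichment_fold) per peak.
    Ties get average ranks (scipy default); peaks with an undefined
    deviation for a word are excluded pairwise.  With ``bh_correct`` the
    p-values are Benjamini–Hochberg adjusted across the 4^k words.
    """
    if len(peak_regions) < 3:
        raise ValueError("need at least 3 peaks")
    folds = np.array([f for _, _, f in peak_regions], dtype=float)
    if np.allclose(folds, folds[0]):
        raise ValueError("enrichment folds are constant; rho undefined")
    tables = [oligo_deviation(seq, k, rid) for rid, seq, _ in peak_regions]
    prefs: list[BindingPreference] = []
    for w in words(k):
        dev = np.array([t.values[w] for t in tables], dtype=float)
        mask = ~np.isnan(dev)
        if mask.sum() < 3:
            prefs.append(BindingPreference(w, float("nan"), float("nan"), int(mask.sum())))
            continue
        rho, p = stats.spearmanr(dev[mask], folds[mask])
        prefs.append(BindingPreference(w, float(rho), float(p), int(mask.sum())))
    if bh_correct:
        ok = [i for i, pr in enumerate(prefs) if not np.isnan(pr.p_value)]
        adj = stats.false_discovery_control(
            [prefs[i].p_value for i in ok], method="bh"
        )
        for i, q in zip(ok, adj):
            prefs[i].p_value = float(q)
    return prefs


def preference_vs_genome_deviation(
    preferences: Sequence[BindingPreference],
    genome_deviation: OligoDeviationTable,
) -> dict[str, float]:
    """OLS of binding preference (rho) on genome-wide usage deviation.

    Words over-represented genome-wide tend to be avoided by the
    silencer and vice versa; the regression summarises that relation
    across all 4^k words.  Returns slope, intercept, R² and n.
    """
    xs, ys = [], []
    for pref in preferences:
        x = genome_deviation.values.get(pref.word, float("nan"))
        if np.isnan(x) or np.isnan(pref.rho):
            continue
        xs.append(x)
        ys.append(pref.rho)
    if len(xs) < 3:
        raise ValueError("fewer than 3 words with data")
    res = stats.linregress(xs, ys)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n_words": len(xs),
    }


def recruitment_correlations(
    peaks: Sequence[tuple[float, int, float]],
    binning: Sequence[float] | None = None,
) -> dict:
    """Pearson correlations of enrichment fold with AT% and motif count.

    ``peaks`` holds (at_percent, motif_count, enrichment_fold) per peak.
    Without ``binning`` the correlations are computed on raw peaks; with
    fold-bin edges they are computed on per-bin means (matching a binned
    box-plot presentation), and per-bin medians/quartiles are emitted.
    Empty bins are dropped with a warning field.
    """
    if len(peaks) < 3:
        raise ValueError("need at least 3 peaks")
    at = np.array([p[0] for p in peaks], dtype=float)
    mot = np.array([p[1] for p in peaks], dtype=float)
    fold = np.array([p[2] for p in peaks], dtype=float)

    out: dict = {}
    r_at, p_at = stats.pearsonr(fold, at)
    r_m, p_m = stats.pearsonr(fold, mot)
    out["raw"] = {
        "pearson_at": float(r_at),
        "p_at": float(p_at),
        "pearson_motif": float(r_m),
        "p_motif": float(p_m),
        "n": len(peaks),
    }

    if binning is not None:
        edges = list(binning)
        rows, dropped = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (fold >= lo) & (fold < hi)
            if not mask.any():
                dropped.append((lo, hi))
                continue
            rows.append(
                {
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "bin_mid": (lo + hi) / 2 if np.isfinite(hi) else lo,
                    "n": int(mask.sum()),
                    "mean_fold": float(fold[mask].mean()),
                    "mean_at": float(at[mask].mean()),
                    "mean_motif": float(mot[mask].mean()),
                    "median_at": float(np.median(at[mask])),
                    "q1_at": float(np.percentile(at[mask], 25)),
                    "q3_at": float(np.percentile(at[mask], 75)),
                    "median_motif": float(np.median(mot[mask])),
                }
            )
        bins = pd.DataFrame(rows)
        out["bins"] = bins
        out["dropped_bins"] = dropped
        if len(bins) >= 3:
            r_at_b, p_at_b = stats.pearsonr(bins["mean_fold"], bins["mean_at"])
            r_m_b, p_m_b = stats.pearsonr(bins["mean_fold"], bins["mean_motif"])
            out["binned"] = {
                "pearson_at": float(r_at_b),
                "p_at": float(p_at_b),
                "pearson_motif": float(r_m_b),
                "p_motif": float(p_m_b),
                "n_bins": len(bins),
            }
    return out


DEFAULT_FOLD_BINS = [1.0, 2.0, 5.0, 10.0, float("inf")]


def deviation_frame(tables: Sequence[OligoDeviationTable]) -> pd.DataFrame:
    """Long-format DataFrame of deviations (region_id, word, deviation)."""
    rows = [
        {"region_id": t.region_id, "k": t.k, "word": w, "deviation": v,
         "observed": t.observed[w], "expected": t.expected[w]}
        for t in tables
        for w, v in t.values.items()
    ]
    return pd.DataFrame(rows)
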