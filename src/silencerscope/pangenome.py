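"""Hierarchical pangenome conservation classes and target-set statistics.

Genes of the focal strain are classified from an ortholog-cluster table
into four mutually exclusive subsets: I (genus core — present in every
genus strain), II (species core, excluding I), III (shared by the focal
strain's closest relatives, excluding I-II) and IV (strain-specific).
On top of the classification the module runs Fisher enrichment tests of
the target set by replicon and subset, compares gene AT% and expression
across groups, and relates subset composition of targets to recruitment
level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from silencerscope.composition import at_percent
from silencerscope.genome_io import GeneModel, Genome, extract_interval
from silencerscope.peaks import MergedPeak, TargetAssignment

SUBSETS = ("I", "II", "III", "IV")


@dataclass
class StrainGroups:
    """Nested strain universes: focal in close, close in species, species
    in genus."""

    genus: frozenset[str]
    species: frozenset[str]
    close: frozenset[str]
    focal: str

    def __post_init__(self) -> None:
        if self.focal not in self.close:
            raise ValueError("focal strain must belong to the close group")
        if not (self.close <= self.species <= self.genus):
            raise ValueError("strain groups must be nested: close ⊆ species ⊆ genus")


def read_cluster_table(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read gene_id -> (cluster_id, strains) from a TSV with columns
    gene_id, cluster_id, strains (comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, tuple[str, frozenset[str]]] = {}
    for r in df.itertuples(index=False):
        if r.gene_id in out:
            raise ValueError(f"gene {r.gene_id!r} listed twice in cluster table")
        out[r.gene_id] = (r.cluster_id, frozenset(str(r.strains).split(",")))
    return out


def assign_subsets(
    clusters: Mapping[str, tuple[str, frozenset[str]]],
    groups: StrainGroups,
    gene_ids: Sequence[str],
) -> dict[str, str]:
    """Classify each focal gene into conservation subsets I-IV.

    Subset I iff the gene's cluster spans all genus strains; else II iff
    all species strains; else III iff all close strains; else IV.  A gene
    absent from the cluster table is strain-specific by absence of
    orthologs and lands in IV.
    """
    assignment: dict[str, str] = {}
    for gid in gene_ids:
        if gid not in clusters:
            assignment[gid] = "IV"
            continue
        _, strains = clusters[gid]
        if groups.genus <= strains:
            assignment[gid] = "I"
        elif groups.species <= strains:
            assignment[gid] = "II"
        elif groups.close <= strains:
            assignment[gid] = "III"
        else:
            assignment[gid] = "IV"
    return assignment


def enrichment_tests(
    targets: set[str],
    genes: Sequence[GeneModel],
    stratify_by: str = "replicon",
) -> pd.DataFrame:
    """Two-sided Fisher exact test of target enrichment per stratum.

    Strata are replicons (``stratify_by='replicon'``) or conservation
    subsets (``'subset'``).  For each stratum the 2x2 table crosses
    in-stratum/out-of-stratum with target/non-target.  Benjamini-Hochberg
    adjusted p-values are reported alongside the raw ones.
    """
    if stratify_by not in ("replicon", "subset"):
        raise ValueError("stratify_by must be 'replicon' or 'subset'")
    unknown = targets - {g.gene_id for g in genes}
    if unknown:
        raise ValueError(f"targets not in gene set: {sorted(unknown)[:5]}")
    key = (lambda g: g.replicon_id) if stratify_by == "replicon" else (lambda g: g.subset)
    strata = sorted({key(g) for g in genes})
    rows = []
    for stratum in strata:
        in_t = sum(1 for g in genes if key(g) == stratum and g.gene_id in targets)
        in_n = sum(1 for g in genes if key(g) == stratum and g.gene_id not in targets)
        out_t = sum(1 for g in genes if key(g) != stratum and g.gene_id in targets)
        out_n = len(genes) - in_t - in_n - out_t
        if in_t + in_n == 0:
            continue
        odds, p = stats.fisher_exact([[in_t, in_n], [out_t, out_n]])
        rows.append(
            {
                "stratum": stratum,
                "n_target_in": in_t,
                "n_nontarget_in": in_n,
                "n_target_out": out_t,
                "n_nontarget_out": out_n,
                "odds_ratio": float(odds),
                "p_value": float(p),
                "direction": "enriched" if odds > 1 else "depleted",
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj_bh"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df


def gene_at_percent(gene: GeneModel, genome: Genome) -> float:
    """AT% over the annotated coding span (strand-symmetric)."""
    return at_percent(
        extract_interval(genome, gene.replicon_id, gene.start, gene.end, "+")
    )


def at_by_group(
    genes: Sequence[GeneModel],
    genome: Genome,
    targets: set[str],
    group_by: str = "subset",
) -> pd.DataFrame:
    """Gene AT% summarised per (stratum, target-status) group.

    Emits mean, s.e. and n per group plus a Welch t-test of target vs
    non-target AT% within each stratum.
    """
    key = (lambda g: g.replicon_id) if group_by == "replicon" else (lambda g: g.subset)
    df = pd.DataFrame(
        {
            "stratum": [key(g) for g in genes],
            "gene_id": [g.gene_id for g in genes],
            "at": [gene_at_percent(g, genome) for g in genes],
            "is_target": [g.gene_id in targets for g in genes],
        }
    )
    rows = []
    for stratum, grp in df.groupby("stratum"):
        tgt = grp.loc[grp.is_target, "at"].to_numpy()
        non = grp.loc[~grp.is_target, "at"].to_numpy()
        row = {
            "stratum": stratum,
            "n_target": len(tgt),
            "n_nontarget": len(non),
            "mean_target": float(tgt.mean()) if len(tgt) else float("nan"),
            "mean_nontarget": float(non.mean()) if len(non) else float("nan"),
            "se_target": float(tgt.std(ddof=1) / np.sqrt(len(tgt)))
            if len(tgt) > 1 else float("nan"),
            "se_nontarget": float(non.std(ddof=1) / np.sqrt(len(non)))
            if len(non) > 1 else float("nan"),
        }
        if len(tgt) >= 2 and len(non) >= 2:
            t, p = stats.ttest_ind(tgt, non, equal_var=False)
            row["t_stat"], row["p_value"] = float(t), float(p)
        else:
            row["t_stat"] = row["p_value"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def expression_by_group(
    expr: pd.DataFrame,
    assignment: Mapping[str, str],
    targets: set[str],
    mutant_vs_wt: tuple[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Expression summaries per (subset, target-status, condition).

    ``expr`` is the gene x condition table.  Within each subset a Welch
    t-test compares target vs non-target expression per condition; with
    ``mutant_vs_wt = (wt_label, mutant_label)`` an additional contrast
    compares target-gene expression between the two conditions.
    Descriptive only — no differential-expression calling.
    """
    if mutant_vs_wt is not None:
        for label in mutant_vs_wt:
            if label not in expr.columns:
                raise ValueError(f"unknown condition label {label!r}")
    meta = pd.DataFrame(
        {
            "subset": [assignment.get(g, "unassigned") for g in expr.index],
            "is_target": [g in targets for g in expr.index],
        },
        index=expr.index,
    )
    group_rows, test_rows = [], []
    for cond in expr.columns:
        vals = expr[cond]
        for subset, grp in meta.groupby("subset"):
            tgt = vals.loc[grp.index[grp.is_target]].to_numpy()
            non = vals.loc[grp.index[~grp.is_target]].to_numpy()
            for status, arr in (("target", tgt), ("nontarget", non)):
                if len(arr):
                    group_rows.append(
                        {
                            "condition": cond,
                            "subset": subset,
                            "status": status,
                            "n": len(arr),
                            "mean": float(arr.mean()),
                            "median": float(np.median(arr)),
                        }
                    )
            if len(tgt) >= 2 and len(non) >= 2:
                t, p = stats.ttest_ind(tgt, non, equal_var=False)
                test_rows.append(
                    {
                        "condition": cond,
                        "subset": subset,
                        "contrast": "target_vs_nontarget",
                        "t_stat": float(t),
                        "p_value": float(p),
                        "mean_diff": float(tgt.mean() - non.mean()),
                    }
                )
    out = {
        "groups": pd.DataFrame(group_rows),
        "tests": pd.DataFrame(test_rows),
    }
    if mutant_vs_wt is not None:
        wt, mut = mutant_vs_wt
        tgt_idx = [g for g in expr.index if g in targets]
        wt_vals = expr.loc[tgt_idx, wt].to_numpy()
        mut_vals = expr.loc[tgt_idx, mut].to_numpy()
        t, p = stats.ttest_rel(mut_vals, wt_vals)
        out["mutant_contrast"] = pd.DataFrame(
            [
                {
                    "contrast": f"{mut}_vs_{wt}_targets",
                    "n": len(tgt_idx),
                    "mean_wt": float(wt_vals.mean()),
                    "mean_mutant": float(mut_vals.mean()),
                    "t_stat": float(t),
                    "p_value": float(p),
                }
            ]
        )
    return out


def recruitment_by_conservation(
    merged_peaks: Sequence[MergedPeak],
    assignments: Sequence[TargetAssignment],
    subset_of: Mapping[str, str],
    fold_bins: Sequence[float] = (1.0, 2.0, 5.0, 10.0, float("inf")),
) -> dict:
    """Subset composition of target genes per enrichment-fold bin.

    Each target gene is placed in the bin of its strongest associated
    peak; per bin the fraction of genes in each subset is reported, and a
    Spearman trend test relates the genus-core (subset I) fraction to the
    bin midpoint.  Erosion of binding sites predicts a falling subset-I
    share with rising recruitment.
    """
    fold_of = {p.peak_id: p.max_enrichment for p in merged_peaks}
    gene_fold: dict[str, float] = {}
    for a in assignments:
        f = fold_of.get(a.peak_id)
        if f is None:
            continue
        gene_fold[a.gene_id] = max(gene_fold.get(a.gene_id, 0.0), f)

    edges = list(fold_bins)
    rows = []
    per_bin_fracI, mids = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [g for g, f in gene_fold.items() if lo <= f < hi]
        if not in_bin:
            continue
        counts = {s: 0 for s in SUBSETS}
        for g in in_bin:
            s = subset_of.get(g)
            if s in counts:
                counts[s] += 1
        total = sum(counts.values())
        if total == 0:
            continue
        mid = (lo + hi) / 2 if np.isfinite(hi) else lo
        fracs = {f"frac_{s}": counts[s] / total for s in SUBSETS}
        rows.append({"bin_lo": lo, "bin_hi": hi, "bin_mid": mid, "n": total, **fracs})
        per_bin_fracI.append(fracs["frac_I"])
        mids.append(mid)
    result: dict = {"bins": pd.DataFrame(rows)}
    if len(mids) >= 3:
        rho, p = stats.spearmanr(mids, per_bin_fracI)
        result["trend_rho"], result["trend_p"] = float(rho), float(p)
    else:
        result["trend_rho"] = result["trend_p"] = float("nan")
    return result
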