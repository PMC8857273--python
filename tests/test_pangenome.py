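"""Conservation-subset assignment and target-set group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from silencerscope.genome_io import GeneModel, Replicon
from silencerscope.pangenome import (
    StrainGroups,
    assign_subsets,
    at_by_group,
    enrichment_tests,
    expression_by_group,
    recruitment_by_conservation,
)

GROUPS = StrainGroups(
    genus=frozenset(f"S{i:02d}" for i in range(1, 13)),
    species=frozenset(f"S{i:02d}" for i in range(1, 6)),
    close=frozenset(f"S{i:02d}" for i in range(1, 4)),
    focal="S01",
)


class TestAssignSubsets:
    def test_hierarchy_examples(self):
        clusters = {
            "gA": ("c1", GROUPS.genus),
            "gB": ("c2", GROUPS.species),
            "gC": ("c3", GROUPS.close),
            "gD": ("c4", frozenset({"S01"})),
            "gE": ("c5", GROUPS.close | {"S07"}),  # still not species core
        }
        out = assign_subsets(clusters, GROUPS, list(clusters) + ["gMissing"])
        assert out == {
            "gA": "I", "gB": "II", "gC": "III", "gD": "IV",
            "gE": "III", "gMissing": "IV",
        }

    def test_nesting_validated(self):
        with pytest.raises(ValueError):
            StrainGroups(
                genus=frozenset({"a"}), species=frozenset({"a", "b"}),
                close=frozenset({"a"}), focal="a",
            )

    def test_recovers_planted_labels_exactly(self, small_dataset):
        groups = small_dataset.ledger.config.strain_groups()
        got = assign_subsets(
            small_dataset.clusters, groups,
            [g.gene_id for g in small_dataset.genes],
        )
        planted = dict(
            zip(small_dataset.ledger.genes.gene_id, small_dataset.ledger.genes.subset)
        )
        assert got == planted


def hypergeom_two_sided(table):
    """Independent oracle: sum of all hypergeometric outcomes no more
    probable than the observed table."""
    (a, b), (c, d) = table
    n1, n2, k = a + b, c + d, a + c
    rv = stats.hypergeom(n1 + n2, n1, k)
    p_obs = rv.pmf(a)
    xs = np.arange(max(0, k - n2), min(k, n1) + 1)
    return float(rv.pmf(xs)[rv.pmf(xs) <= p_obs * (1 + 1e-7)].sum())


class TestEnrichment:
    def genes(self, n=400, n_rep=4):
        return [
            GeneModel(f"g{i}", f"rep{i % n_rep}", 1, 9, "+",
                      subset="I" if i % 3 else "IV")
            for i in range(n)
        ]

    def test_extreme_concentration_enriched(self):
        genes = self.genes()
        targets = {g.gene_id for g in genes if g.replicon_id == "rep0"}
        df = enrichment_tests(targets, genes, "replicon").set_index("stratum")
        assert df.loc["rep0", "direction"] == "enriched"
        assert df.loc["rep0", "p_value"] < 1e-10
        assert (df.drop("rep0").direction == "depleted").all()

    def test_fisher_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 50, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(hypergeom_two_sided([[a, b], [c, d]]),
                                      rel=1e-6)

    def test_row_swap_invariance(self):
        genes = self.genes()
        targets = {f"g{i}" for i in range(0, 400, 7)}
        df = enrichment_tests(targets, genes, "replicon")
        comp = enrichment_tests(
            {g.gene_id for g in genes} - targets, genes, "replicon"
        )
        for (_, r1), (_, r2) in zip(df.iterrows(), comp.iterrows()):
            assert r1.p_value == pytest.approx(r2.p_value)
            if r1.odds_ratio > 0 and np.isfinite(r1.odds_ratio):
                assert r1.odds_ratio == pytest.approx(
                    1 / r2.odds_ratio if r2.odds_ratio else np.inf
                )

    def test_uniform_null_false_positive_rate(self):
        rng = np.random.default_rng(1)
        genes = [
            GeneModel(f"g{i}", f"rep{i % 4}", 1, 9, "+") for i in range(2000)
        ]
        gene_ids = [g.gene_id for g in genes]
        hits = 0
        trials = 0
        for _ in range(100):
            targets = set(rng.choice(gene_ids, size=600, replace=False))
            df = enrichment_tests(targets, genes, "replicon")
            hits += int((df.p_value < 0.05).sum())
            trials += len(df)
        rate = hits / trials
        assert 0.01 <= rate <= 0.09


class TestAtByGroup:
    def test_identical_sequences_null(self):
        genome = {"r": Replicon("r", "ACGT" * 100)}
        genes = [
            GeneModel(f"g{i}", "r", 1, 40, "+", subset="I") for i in range(10)
        ]
        df = at_by_group(genes, genome, targets={"g0", "g1", "g2"})
        assert df.iloc[0].mean_target == pytest.approx(df.iloc[0].mean_nontarget)

    def test_subset_at_ordering_recovered(self, small_dataset):
        df = at_by_group(
            small_dataset.genes,
            small_dataset.genome,
            targets=set(),
            group_by="subset",
        ).set_index("stratum")
        means = df.mean_nontarget
        assert means["I"] < means["II"] < means["III"] < means["IV"]

    def test_group_mean_matches_naive_average(self, small_dataset):
        from silencerscope.pangenome import gene_at_percent

        genes = [g for g in small_dataset.genes if g.subset == "II"]
        naive = np.mean([gene_at_percent(g, small_dataset.genome) for g in genes])
        df = at_by_group(
            small_dataset.genes, small_dataset.genome, targets=set(),
            group_by="subset",
        ).set_index("stratum")
        assert df.loc["II", "mean_nontarget"] == pytest.approx(naive)


class TestExpression:
    def test_constant_expression_null(self):
        expr = pd.DataFrame(
            {"c1": [5.0] * 20}, index=[f"g{i}" for i in range(20)]
        )
        assignment = {f"g{i}": "I" for i in range(20)}
        out = expression_by_group(expr, assignment, targets={"g0", "g1", "g2"})
        assert (out["tests"].mean_diff.abs() < 1e-12).all()

    def test_unknown_condition_rejected(self):
        expr = pd.DataFrame({"c1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            expression_by_group(expr, {}, set(), mutant_vs_wt=("c1", "zz"))

    def test_planted_boost_and_mutant_shift_recovered(self, dataset):
        led = dataset.ledger.genes
        assignment = dict(zip(led.gene_id, led.subset))
        targets = set(led[led.is_target].gene_id)
        out = expression_by_group(
            dataset.expression, assignment, targets,
            mutant_vs_wt=("wild_type", "mucr_mutant"),
        )
        tests = out["tests"]
        # targets transcribed higher than non-targets in most subsets
        assert (tests.mean_diff > 0).mean() > 0.7
        mc = out["mutant_contrast"].iloc[0]
        assert mc.mean_mutant > mc.mean_wt
        assert mc.p_value < 0.01

    def test_subset_mean_ordering(self, dataset):
        led = dataset.ledger.genes
        assignment = dict(zip(led.gene_id, led.subset))
        out = expression_by_group(dataset.expression, assignment, set())
        g = out["groups"]
        sub = g[(g.condition == "wild_type") & (g.status == "nontarget")]
        means = sub.set_index("subset")["mean"]
        assert means["I"] > means["II"] > means["III"] > means["IV"]


class TestRecruitmentByConservation:
    def test_fractions_sum_to_one(self, dataset):
        from silencerscope.peaks import assign_targets, merge_peaks

        merged = merge_peaks([dataset.peak_records])
        assignments = assign_targets(merged, dataset.genes)
        led = dataset.ledger.genes
        subset_of = dict(zip(led.gene_id, led.subset))
        out = recruitment_by_conservation(merged, assignments, subset_of)
        frac_cols = [c for c in out["bins"].columns if c.startswith("frac_")]
        assert np.allclose(out["bins"][frac_cols].sum(axis=1), 1.0)

    def test_null_trend_near_zero(self):
        rng = np.random.default_rng(2)
        from silencerscope.peaks import MergedPeak, TargetAssignment

        peaks = [
            MergedPeak(f"p{i}", "r", 100 * i, [], {"FC": float(f)})
            for i, f in enumerate(rng.uniform(1, 20, 400))
        ]
        assignments = [
            TargetAssignment(f"g{i}", f"p{i}", 0) for i in range(400)
        ]
        subset_of = {
            f"g{i}": rng.choice(["I", "II", "III", "IV"]) for i in range(400)
        }
        out = recruitment_by_conservation(peaks, assignments, subset_of)
        assert abs(out["trend_rho"]) < 1.0  # defined
        assert out["trend_p"] > 0.01 or abs(out["trend_rho"]) < 0.9

    def test_planted_negative_association_recovered(self):
        # genus-core genes get weak peaks, strain-specific get strong ones
        rng = np.random.default_rng(3)
        from silencerscope.peaks import MergedPeak, TargetAssignment

        peaks, assignments, subset_of = [], [], {}
        for i in range(400):
            subset = rng.choice(["I", "II", "III", "IV"])
            base = {"I": 2.0, "II": 5.0, "III": 8.0, "IV": 14.0}[subset]
            fold = float(max(1.01, rng.normal(base, 2.0)))
            peaks.append(MergedPeak(f"p{i}", "r", 100 * i, [], {"FC": fold}))
            assignments.append(TargetAssignment(f"g{i}", f"p{i}", 0))
            subset_of[f"g{i}"] = subset
        out = recruitment_by_conservation(peaks, assignments, subset_of)
        assert out["trend_rho"] < 0
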