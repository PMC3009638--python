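"""Reporter-metabolite scoring, background calibration, subnetworks,
category summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import synflux as sf
from synflux.reporter import (
    DegenerateInputError,
    build_background,
    background_correct,
    category_summary,
    gene_zscores,
    metabolite_raw_score,
)


def dataset(p_by_gene, contrast="c1"):
    return sf.ExpressionDataset(pd.DataFrame({contrast: p_by_gene}))


class TestGeneZscores:
    def test_median_p_maps_to_zero(self):
        z = gene_zscores(dataset({"g1": 0.5}), "c1")
        assert z["g1"] == pytest.approx(0.0, abs=1e-12)

    def test_p_one_clamped_finite(self):
        z = gene_zscores(dataset({"g1": 1.0}), "c1")
        assert z["g1"] == pytest.approx(norm.ppf(1e-10))
        assert np.isfinite(z["g1"])

    def test_known_quantile(self):
        z = gene_zscores(dataset({"g1": 0.0228}), "c1")
        assert z["g1"] == pytest.approx(1.999, abs=1e-3)

    def test_antitone_in_p(self):
        ps = {f"g{i}": p for i, p in enumerate([0.001, 0.05, 0.2, 0.5, 0.9])}
        z = gene_zscores(dataset(ps), "c1")
        values = [z[f"g{i}"] for i in range(5)]
        assert values == sorted(values, reverse=True)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(sf.ModelError):
            dataset({"g1": 1.5})

    def test_missing_contrast_rejected(self):
        with pytest.raises(sf.ModelError):
            gene_zscores(dataset({"g1": 0.5}), "nope")

    def test_unmeasured_genes_skipped(self):
        ds = sf.ExpressionDataset(
            pd.DataFrame({"c1": {"g1": 0.5, "g2": np.nan}})
        )
        assert set(gene_zscores(ds, "c1")) == {"g1"}


class TestRawScore:
    def test_mean_of_neighbors(self):
        score, n = metabolite_raw_score({"a": 2.0, "b": 0.0}, {"a", "b"})
        assert (score, n) == (1.0, 2)

    def test_single_neighbor(self):
        assert metabolite_raw_score({"a": 1.3}, {"a"}) == (1.3, 1)

    def test_matches_independent_mean(self):
        rng = np.random.default_rng(0)
        z = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=5))}
        score, n = metabolite_raw_score(z, set(z))
        assert n == 5
        assert score == pytest.approx(sum(z.values()) / 5)

    def test_no_scored_neighbors_rejected(self):
        with pytest.raises(sf.ModelError):
            metabolite_raw_score({"a": 1.0}, {"b"})


class TestBackground:
    def test_raw_at_mean_corrects_to_zero(self):
        rng = np.random.default_rng(1)
        z = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=200))}
        bg = build_background(z, [3], seed=0)
        m, s = bg[3]
        assert background_correct(m, 3, bg) == pytest.approx(0.0, abs=1e-12)
        assert background_correct(m + s, 3, bg) == pytest.approx(1.0, abs=1e-12)

    def test_standard_normal_scores_scale_like_sqrt_n(self):
        # For standard-normal gene scores s_N ~ 1/sqrt(N), so a raw score
        # of 1 at N=4 corrects to ~2 (Monte-Carlo tolerance).
        rng = np.random.default_rng(2)
        z = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=5000))}
        bg = build_background(z, [4], n_samples=100_000, seed=3)
        assert background_correct(1.0, 4, bg) == pytest.approx(2.0, abs=0.05)

    def test_constant_scores_rejected(self):
        z = {f"g{i}": 0.0 for i in range(10)}
        with pytest.raises(DegenerateInputError):
            build_background(z, [2], seed=0)

    def test_unknown_size_rejected(self):
        rng = np.random.default_rng(3)
        z = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=50))}
        bg = build_background(z, [2], seed=0)
        with pytest.raises(sf.ModelError):
            bg[7]


class TestReporterPipeline:
    def test_planted_metabolite_ranks_first_in_most_seeds(self, toy):
        wins = 0
        for seed in range(20):
            data = sf.generate_expression_dataset(
                toy, ["g6p"], effect_alpha=0.1, seed=seed
            )
            table = sf.reporter_metabolites(toy, data, "contrast_1", seed=seed)
            wins += int(table.table.iloc[0].metabolite == "g6p")
        assert wins >= 18

    def test_null_scores_centered(self, toy):
        means = []
        for seed in range(20):
            data = sf.generate_expression_dataset(
                toy, [], effect_alpha=1.0, seed=seed
            )
            table = sf.reporter_metabolites(toy, data, "contrast_1", seed=seed)
            means.append(table.table.z_corrected.mean())
        assert abs(np.mean(means)) < 0.1

    def test_constant_pvalues_raise_degenerate_error(self, toy):
        data = sf.ExpressionDataset(
            pd.DataFrame({"c1": {g: 0.5 for g in toy.genes}})
        )
        with pytest.raises(DegenerateInputError):
            sf.reporter_metabolites(toy, data, "c1", seed=0)

    def test_fixed_seed_is_reproducible(self, toy):
        data = sf.generate_expression_dataset(toy, ["g6p"], seed=4)
        t1 = sf.reporter_metabolites(toy, data, "contrast_1", seed=4)
        t2 = sf.reporter_metabolites(toy, data, "contrast_1", seed=4)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_invariant_to_gene_ordering(self, toy):
        data = sf.generate_expression_dataset(toy, ["g6p"], seed=4)
        reordered = sf.ExpressionDataset(
            data.pvalues.sort_index(ascending=False)
        )
        t1 = sf.reporter_metabolites(toy, data, "contrast_1", seed=4)
        t2 = sf.reporter_metabolites(toy, reordered, "contrast_1", seed=4)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_cofactors_excluded_from_neighborhoods(self, toy):
        hoods = sf.metabolite_gene_neighborhoods(toy)
        assert "atp" not in hoods and "h2o" not in hoods
        assert "g6p" in hoods


class TestSubnetworkSearch:
    def test_isolated_high_gene_returned_as_singleton(self):
        mets = [sf.Metabolite("m1"), sf.Metabolite("m2")]
        rxns = [
            sf.Reaction("r1", {"m1": -1}, reversible=True, gpr=sf.parse_gpr("gHot")),
            sf.Reaction("r2", {"m2": -1}, reversible=True, gpr=sf.parse_gpr("gCold")),
        ]
        model = sf.MetabolicModel(mets, rxns, objective_reaction_id="r1")
        rng = np.random.default_rng(0)
        filler = {f"x{i}": float(rng.uniform(0.3, 0.9)) for i in range(40)}
        data = dataset({"gHot": 1e-6, "gCold": 0.9, **filler})
        # filler genes are not in the graph; gHot and gCold are isolated
        genes, _ = sf.coregulated_subnetwork_search(
            model, data, "c1", seed=0, n_permutations=5
        )
        assert genes == frozenset({"gHot"})

    def test_planted_chain_members_recovered_in_majority_of_seeds(self, toy):
        chain = {"glk", "pgi1", "pgi2", "pfkA", "zwf"}
        hits = {g: 0 for g in chain}
        for seed in range(20):
            data = sf.generate_expression_dataset(
                toy, ["g6p", "f6p"], effect_alpha=0.1, seed=seed
            )
            genes, _ = sf.coregulated_subnetwork_search(
                toy, data, "contrast_1", seed=seed
            )
            for g in genes & chain:
                hits[g] += 1
        recovered = [g for g, n in hits.items() if n > 10]
        assert len(recovered) >= 4

    def test_null_calibrated_score_stays_moderate(self, toy):
        scores = []
        for seed in range(20):
            data = sf.generate_expression_dataset(
                toy, [], effect_alpha=1.0, seed=seed
            )
            _, score = sf.coregulated_subnetwork_search(
                toy, data, "contrast_1", seed=seed
            )
            scores.append(score)
        assert max(scores) <= 3.0


class TestCategorySummary:
    def test_published_energy_metabolism_percent(self):
        cat_map = {f"g{i}": ("Energy Metabolism" if i < 128 else "Other")
                   for i in range(212)}
        df = category_summary([f"g{i}" for i in range(212)], cat_map)
        row = df[df.category == "Energy Metabolism"].iloc[0]
        assert (row["count"], row["percent"]) == (128, 60.38)

    def test_light_to_dark_percent(self):
        cat_map = {f"g{i}": ("Energy Metabolism" if i < 127 else "Other")
                   for i in range(206)}
        df = category_summary([f"g{i}" for i in range(206)], cat_map)
        assert df[df.category == "Energy Metabolism"].iloc[0]["percent"] == 61.65

    def test_zero_count_category_reports_zero_percent(self):
        cat_map = {"g1": "A", "g2": "B"}
        df = category_summary(["g1"], cat_map)
        assert df[df.category == "B"].iloc[0]["percent"] == 0.0

    def test_sorted_by_count_descending(self):
        cat_map = {"g1": "A", "g2": "B", "g3": "B", "g4": "Z"}
        df = category_summary(["g1", "g2", "g3", "g4"], cat_map)
        assert list(df.category) == ["B", "A", "Z"]
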