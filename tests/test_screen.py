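"""Screen scoring: dead-colony filter, plate normalization, Z-scores, hits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitocpr import screen
from mitocpr.simulate import ScreenSimConfig, simulate_screen


def _plate_rows(gene, plate, medium, sizes, replicate_start=1):
    return [
        {
            "gene_id": gene,
            "plate_id": plate,
            "row": 1,
            "col": 1,
            "replicate": replicate_start + i,
            "medium": medium,
            "size_px": float(s),
        }
        for i, s in enumerate(sizes)
    ]


class TestFilterSmallColonies:
    def _table(self):
        rows = []
        rows += _plate_rows("small", "p1", "permissive", [15, 17])
        rows += _plate_rows("small", "p1", "selective", [100, 100])
        rows += _plate_rows("boundary", "p1", "permissive", [20])
        rows += _plate_rows("boundary", "p1", "selective", [90])
        rows += _plate_rows("big", "p1", "permissive", [50, 60])
        rows += _plate_rows("big", "p1", "selective", [55, 65])
        rows += _plate_rows("orphan", "p1", "selective", [80])
        return pd.DataFrame(rows)

    def test_mean_below_threshold_excluded_from_both_media(self):
        surviving, excluded = screen.filter_small_colonies(self._table())
        assert "small" not in set(surviving["gene_id"])
        assert "small" in set(excluded["gene_id"])

    def test_exactly_20_retained_strict_inequality(self):
        surviving, _ = screen.filter_small_colonies(self._table())
        assert "boundary" in set(surviving["gene_id"])

    def test_no_control_growth_reason(self):
        _, excluded = screen.filter_small_colonies(self._table())
        reason = excluded.set_index("gene_id").loc["orphan", "reason"]
        assert reason == "no control growth"

    def test_all_large_is_identity(self):
        table = pd.DataFrame(
            _plate_rows("a", "p1", "permissive", [30, 40])
            + _plate_rows("a", "p1", "selective", [30, 40])
        )
        surviving, excluded = screen.filter_small_colonies(table)
        pd.testing.assert_frame_equal(surviving, table)
        assert excluded.empty


class TestNormalizePlates:
    def test_two_plate_arithmetic_oracle(self, toy_plate_table):
        # plate means 100 and 200, grand mean 150: factors 1.5 and 0.75
        norm = screen.normalize_plates(toy_plate_table)
        sel = norm[norm["medium"] == "selective"].set_index("gene_id")
        assert sel.loc["p1_g0", "size_norm"] == pytest.approx(80 * 1.5)
        assert sel.loc["p2_g1", "size_norm"] == pytest.approx(240 * 0.75)

    def test_plate_means_equal_grand_mean(self, toy_plate_table):
        norm = screen.normalize_plates(toy_plate_table)
        for medium, group in norm.groupby("medium"):
            grand = group["group_grand_mean"].iloc[0]
            plate_means = group.groupby("plate_id")["size_norm"].mean()
            assert np.allclose(plate_means, grand, rtol=1e-9)

    def test_single_plate_identity(self):
        table = pd.DataFrame(
            _plate_rows("a", "p1", "selective", [10, 30])
            + _plate_rows("b", "p1", "permissive", [20, 40])
        )
        norm = screen.normalize_plates(table)
        assert np.allclose(norm["size_norm"], norm["size_px"])

    def test_identical_plates_unchanged(self):
        rows = _plate_rows("a", "p1", "selective", [10, 30]) + _plate_rows(
            "b", "p2", "selective", [10, 30]
        )
        rows += _plate_rows("a", "p1", "permissive", [10]) + _plate_rows(
            "b", "p2", "permissive", [30]
        )
        norm = screen.normalize_plates(pd.DataFrame(rows))
        sel = norm[norm["medium"] == "selective"]
        assert np.allclose(sel["size_norm"], sel["size_px"])

    def test_scale_invariance_of_one_plate(self, toy_plate_table):
        # multiplying one plate by a constant changes nothing downstream
        # of normalization: Z-scores are identical
        scaled = toy_plate_table.copy()
        mask = scaled["plate_id"].str.startswith("p1")
        scaled.loc[mask, "size_px"] *= 7.0
        for medium in ("selective", "permissive"):
            a = screen.gene_zscores(screen.normalize_plates(toy_plate_table), medium)
            b = screen.gene_zscores(screen.normalize_plates(scaled), medium)
            assert np.allclose(a["mean_z"], b["mean_z"])

    def test_zero_mean_plate_rejected(self):
        table = pd.DataFrame(
            _plate_rows("a", "pz", "selective", [0, 0])
            + _plate_rows("b", "p1", "selective", [10])
        )
        with pytest.raises(ValueError, match="pz"):
            screen.normalize_plates(table)


class TestGeneZscores:
    def _norm(self, sizes, genes=None):
        genes = genes or [f"g{i}" for i in range(len(sizes))]
        rows = []
        for g, s in zip(genes, sizes):
            rows += _plate_rows(g, "p1", "selective", [s])
        return screen.normalize_plates(pd.DataFrame(rows))

    def test_hand_computed_z(self):
        # sizes {1,2,3}: sample SD 1, so gene with 3 has Z = +1
        z = screen.gene_zscores(self._norm([1, 2, 3]), "selective")
        assert z.loc["g2", "mean_z"] == pytest.approx(1.0)
        assert z.loc["g0", "mean_z"] == pytest.approx(-1.0)

    def test_population_mean_zero_sd_one(self):
        cfg = ScreenSimConfig(n_genes=300, seed=5)
        plates, _ = simulate_screen(cfg)
        norm = screen.normalize_plates(plates)
        for medium in ("selective", "permissive"):
            z = screen.gene_zscores(norm, medium)
            pooled = np.concatenate(z["replicate_zs"].to_numpy())
            assert abs(pooled.mean()) < 1e-9
            assert abs(pooled.std(ddof=1) - 1) < 1e-9

    def test_location_invariance(self):
        a = screen.gene_zscores(self._norm([5, 6, 9]), "selective")
        b = screen.gene_zscores(self._norm([105, 106, 109]), "selective")
        assert np.allclose(a["mean_z"], b["mean_z"])

    def test_gene_at_group_mean_scores_zero(self):
        z = screen.gene_zscores(self._norm([10, 20, 30]), "selective")
        assert z.loc["g1", "mean_z"] == pytest.approx(0.0)

    def test_degenerate_screen_rejected(self):
        with pytest.raises(screen.DegenerateScreenError):
            screen.gene_zscores(self._norm([7, 7, 7]), "selective")


class TestStoreyQvalues:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = screen.storey_qvalues(p, lam=0.5)
        # brute force: q_i = min over thresholds t >= p_i of pi0*m*t/#(p<=t)
        m = p.size
        pi0 = min(1.0, (p > 0.5).sum() / (m * 0.5))
        brute = np.array(
            [
                min(
                    pi0 * m * t / (p <= t).sum()
                    for t in p[p >= pi] # all candidate thresholds above
                )
                for pi in p
            ]
        )
        assert np.allclose(q, np.minimum(brute, 1.0), atol=1e-12)

    def test_monotone_in_p(self):
        p = np.array([0.001, 0.01, 0.2, 0.8, 0.9])
        q = screen.storey_qvalues(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()


class TestScoreHits:
    def test_equal_media_gene_not_hit(self):
        rows = []
        rng = np.random.default_rng(3)
        for i in range(40):
            sizes = rng.uniform(50, 150, size=2)
            for medium in ("selective", "permissive"):
                rows += _plate_rows(f"g{i}", "p1", medium, sizes)
        norm = screen.normalize_plates(pd.DataFrame(rows))
        hits = screen.score_hits(norm)
        table = hits.set_index("gene_id")
        assert np.allclose(table["z_diff"], 0.0, atol=1e-12)
        assert not table["is_hit"].any()

    def test_pvalue_oracle_equivalence_welch(self):
        """Welch p-values match scipy recomputed from raw Z-scores."""
        cfg = ScreenSimConfig(n_genes=10, n_replicates=2, seed=6)
        plates, _ = simulate_screen(cfg)
        norm = screen.normalize_plates(plates)
        hits = screen.score_hits(norm, test="welch")
        zs = screen.gene_zscores(norm, "selective")
        zp = screen.gene_zscores(norm, "permissive")
        for row in hits.itertuples():
            expected = stats.ttest_ind(
                zs.loc[row.gene_id, "replicate_zs"],
                zp.loc[row.gene_id, "replicate_zs"],
                equal_var=False,
                alternative="greater",
            ).pvalue
            assert row.p_value == pytest.approx(expected, abs=1e-12)

    def test_pvalue_oracle_equivalence_normal(self):
        cfg = ScreenSimConfig(n_genes=8, n_replicates=3, seed=7)
        plates, _ = simulate_screen(cfg)
        norm = screen.normalize_plates(plates)
        hits = screen.score_hits(norm, test="normal")
        zs = screen.gene_zscores(norm, "selective")
        zp = screen.gene_zscores(norm, "permissive")
        for row in hits.itertuples():
            diff = (
                zs.loc[row.gene_id, "replicate_zs"].mean()
                - zp.loc[row.gene_id, "replicate_zs"].mean()
            )
            expected = stats.norm.sf(diff / np.sqrt(1 / 3 + 1 / 3))
            assert row.p_value == pytest.approx(expected, abs=1e-12)

    def test_single_replicate_normal_tail_fallback(self):
        cfg = ScreenSimConfig(n_genes=20, n_replicates=1, seed=8)
        plates, _ = simulate_screen(cfg)
        norm = screen.normalize_plates(plates)
        hits = screen.score_hits(norm, test="welch")  # must fall back
        table = hits.set_index("gene_id")
        for gene, row in table.iterrows():
            expected = stats.norm.sf(row["z_diff"] / np.sqrt(2.0))
            assert row["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_hit_ranking_by_z_diff(self):
        cfg = ScreenSimConfig(
            n_genes=400, n_hits=5, hit_effect_sd_units=4.0, seed=9
        )
        plates, truth = simulate_screen(cfg)
        hits, _ = screen.run_screen(plates)
        flagged = hits[hits["is_hit"]]
        assert (flagged["rank"] == np.arange(1, len(flagged) + 1)).all()
        assert (np.diff(flagged["z_diff"]) <= 1e-12).all()

    def test_gene_permutation_invariance(self):
        cfg = ScreenSimConfig(n_genes=60, n_hits=3, hit_effect_sd_units=3, seed=10)
        plates, _ = simulate_screen(cfg)
        shuffled = plates.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a, _ = screen.run_screen(plates)
        b, _ = screen.run_screen(shuffled)
        merged = a.merge(b, on="gene_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["z_diff_a"], merged["z_diff_b"])
        assert (merged["is_hit_a"] == merged["is_hit_b"]).all()

    def test_monotonicity_in_planted_effect(self):
        """A larger planted effect never lowers that gene's z_diff (noiseless)."""
        z_diffs = []
        for effect in (1.0, 2.0, 4.0):
            cfg = ScreenSimConfig(
                n_genes=100, n_hits=1, hit_effect_sd_units=effect,
                plate_effect_sd=0.0, colony_noise_cv=1e-6,
                baseline_size_px=1e6, seed=12,
            )
            plates, truth = simulate_screen(cfg)
            hits, _ = screen.run_screen(plates)
            gene = truth[truth["is_hit"]]["gene_id"].iloc[0]
            z_diffs.append(
                hits.set_index("gene_id").loc[gene, "z_diff"]
            )
        assert z_diffs[0] < z_diffs[1] < z_diffs[2]

    def test_bh_used_below_storey_minimum(self):
        cfg = ScreenSimConfig(n_genes=30, seed=13)
        plates, _ = simulate_screen(cfg)
        norm = screen.normalize_plates(plates)
        from statsmodels.stats.multitest import multipletests

        hits = screen.score_hits(norm, fdr="storey")
        expected = multipletests(hits["p_value"].to_numpy(), method="fdr_bh")[1]
        assert np.allclose(hits["q_value"], expected)
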