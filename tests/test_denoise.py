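import math

import numpy as np
import pandas as pd
import pytest

from nbdep.denoise import rank_within_cell_line, remove_batch_effects, select_consistent_shrnas
from nbdep.simulate import SimConfig, generate_synthetic_screen

from conftest import flat_stability, make_screen


def _ols_residual_oracle(y, pools, stab):
    """Independent per-cell-line correction: OLS with dummy pools, subtract
    fitted pool deviations (sum-to-zero) and stability slope."""
    obs = np.isfinite(y)
    yv, pv, sv = y[obs], np.asarray(pools)[obs], np.asarray(stab)[obs]
    levels = sorted(set(pv))
    cols = [np.ones(len(yv))]
    if len(levels) > 1:
        for lev in levels[:-1]:
            cols.append((pv == lev).astype(float) - (pv == levels[-1]).astype(float))
    if np.ptp(sv) > 0:
        cols.append(sv - sv.mean())
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    fitted_batch = X[:, 1:] @ beta[1:]
    out = y.copy()
    out[obs] = yv - fitted_batch
    return out


class TestBatchRemoval:
    def test_no_estimable_terms_is_identity(self):
        mat = pd.DataFrame({"c1": [1.0, 2.0, 3.0]}, index=pd.Index(["s1", "s2", "s3"], name="shrna_id"))
        screen = make_screen(mat, pools=["poolA"] * 3, seeds=["ACGTACG"] * 3)
        with pytest.warns(UserWarning):
            out = remove_batch_effects(screen, flat_stability(screen))
        pd.testing.assert_frame_equal(out, mat)

    def test_injected_pool_offsets_removed_exactly(self):
        # flat baseline 1.0, two pools with offsets +2/-2, constant stability
        baseline = 1.0
        vals = [baseline + 2, baseline + 2, baseline + 2, baseline - 2, baseline - 2, baseline - 2]
        mat = pd.DataFrame({"c1": vals}, index=pd.Index([f"s{i}" for i in range(6)], name="shrna_id"))
        screen = make_screen(mat, pools=["poolA"] * 3 + ["poolB"] * 3, seeds=["ACGTACG"] * 6)
        out = remove_batch_effects(screen, flat_stability(screen))
        assert np.allclose(out["c1"].to_numpy(), baseline)

    def test_matches_per_cell_line_ols_oracle(self, synthetic_bundle):
        syn, screen, _, bundle = synthetic_bundle
        stab_map = syn.stability.stability_of
        stab = np.array([stab_map.get(s, stab_map.mean()) for s in screen.seed_of.loc[screen.logfc.index]])
        pools = screen.pool_of.loc[screen.logfc.index].to_numpy()
        for cl in screen.cell_lines[:5]:
            expected = _ols_residual_oracle(screen.logfc[cl].to_numpy(), pools, stab)
            got = bundle.corrected[cl].to_numpy()
            assert np.allclose(got, expected, atol=1e-8, equal_nan=True)

    def test_idempotent(self, synthetic_bundle):
        syn, screen, _, bundle = synthetic_bundle
        from nbdep.dataio import ScreenDataset

        twice_in = ScreenDataset(annotations=screen.annotations.copy(), logfc=bundle.corrected)
        twice = remove_batch_effects(twice_in, syn.stability)
        assert np.allclose(twice.to_numpy(), bundle.corrected.to_numpy(), atol=1e-8, equal_nan=True)

    def test_missingness_pattern_preserved(self, synthetic_bundle):
        _, screen, _, bundle = synthetic_bundle
        assert (np.isnan(bundle.corrected.to_numpy()) == np.isnan(screen.logfc.to_numpy())).all()

    def test_location_shift_leaves_ranks_unchanged(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame({"c1": rng.normal(size=8)}, index=pd.Index([f"s{i}" for i in range(8)], name="shrna_id"))
        screen = make_screen(mat, pools=["poolA"] * 4 + ["poolB"] * 4)
        shifted = make_screen(mat + 3.7, pools=["poolA"] * 4 + ["poolB"] * 4)
        r1 = rank_within_cell_line(remove_batch_effects(screen, flat_stability(screen)))
        r2 = rank_within_cell_line(remove_batch_effects(shifted, flat_stability(shifted)))
        pd.testing.assert_frame_equal(r1, r2)

    def test_recovers_generator_batch_parameters(self):
        # moment check: with 200 shRNAs per pool and tiny noise, correction
        # should shrink the pool-mean spread by an order of magnitude
        cfg = SimConfig(seed=21, n_genes=60, shrnas_per_gene=10, n_cell_lines=4,
                        residual_sd=0.1, gene_effect_sd=0.0, driver_fraction=0.0,
                        missing_logfc_rate=0.0, n_missing_abundance=0)
        syn = generate_synthetic_screen(cfg)
        screen = syn.screen
        corrected = remove_batch_effects(screen, syn.stability)
        pools = screen.pool_of
        raw_spread, corr_spread = [], []
        for cl in screen.cell_lines:
            raw_means = screen.logfc[cl].groupby(pools).mean()
            corr_means = corrected[cl].groupby(pools).mean()
            raw_spread.append(np.ptp(raw_means.to_numpy()))
            corr_spread.append(np.ptp(corr_means.to_numpy()))
        assert max(corr_spread) < 0.05 * max(raw_spread)


class TestRanking:
    def test_simple_column(self):
        mat = pd.DataFrame({"c1": [-3.0, -1.0, 0.5]}, index=pd.Index(["a", "b", "c"], name="shrna_id"))
        ranks = rank_within_cell_line(mat)
        assert list(ranks["c1"]) == [1.0, 2.0, 3.0]

    def test_missing_excluded_and_contiguous(self):
        mat = pd.DataFrame({"c1": [-1.0, np.nan, 2.0]}, index=pd.Index(["a", "b", "c"], name="shrna_id"))
        ranks = rank_within_cell_line(mat)
        assert ranks.loc["a", "c1"] == 1.0 and np.isnan(ranks.loc["b", "c1"]) and ranks.loc["c", "c1"] == 2.0

    def test_ties_break_by_shrna_id(self):
        mat = pd.DataFrame({"c1": [-1.0, -1.0, 0.0]}, index=pd.Index(["b", "a", "c"], name="shrna_id"))
        ranks = rank_within_cell_line(mat)
        assert ranks.loc["a", "c1"] == 1.0 and ranks.loc["b", "c1"] == 2.0 and ranks.loc["c", "c1"] == 3.0

    def test_observed_ranks_are_exact_permutations(self, synthetic_bundle):
        _, _, _, bundle = synthetic_bundle
        for cl in bundle.ranks.columns:
            col = bundle.ranks[cl].dropna().to_numpy()
            assert sorted(col) == list(range(1, len(col) + 1))

    def test_lower_rank_means_more_negative_corrected_value(self, synthetic_bundle):
        _, _, _, bundle = synthetic_bundle
        cl = bundle.ranks.columns[0]
        sub = pd.DataFrame({"rank": bundle.ranks[cl], "val": bundle.corrected[cl]}).dropna()
        ordered = sub.sort_values("rank")["val"].to_numpy()
        assert (np.diff(ordered) >= 0).all()


class TestConsistentSelection:
    def test_single_shrna_gene_retained(self):
        mat = pd.DataFrame({"c1": [1.0], "c2": [2.0]}, index=pd.Index(["s1"], name="shrna_id"))
        screen = make_screen(mat)
        sel = select_consistent_shrnas(rank_within_cell_line(mat), screen.gene_of)
        assert [s for s, _ in sel["g1"]] == ["s1"]

    def test_two_concordant_beat_one_reversed(self):
        # two identical rank profiles plus the reversed profile over 4 lines
        mat = pd.DataFrame(
            {
                "c1": [1.0, 1.1, 4.0],
                "c2": [2.0, 2.1, 3.0],
                "c3": [3.0, 3.1, 2.0],
                "c4": [4.0, 4.1, 1.0],
            },
            index=pd.Index(["s1", "s2", "s3"], name="shrna_id"),
        )
        screen = make_screen(mat, genes=["g1"] * 3)
        sel = select_consistent_shrnas(rank_within_cell_line(mat), screen.gene_of)
        kept = {s for s, _ in sel["g1"]}
        assert kept == {"s1", "s2"}  # ceil(3/2) = 2 most concordant

    def test_matches_brute_force_oracle_on_random_profiles(self, synthetic_bundle):
        _, screen, _, bundle = synthetic_bundle
        sel = bundle.consistent
        ranks = bundle.ranks
        gene_of = screen.gene_of
        for gene in list(sel)[:20]:
            shrnas = [s for s in ranks.index if gene_of[s] == gene and np.isfinite(ranks.loc[s]).any()]
            sub = ranks.loc[shrnas].to_numpy()
            mean_profile = np.nanmean(sub, axis=0)
            corrs = []
            for i, s in enumerate(shrnas):
                both = np.isfinite(sub[i]) & np.isfinite(mean_profile)
                if both.sum() < 3 or np.ptp(sub[i][both]) == 0 or np.ptp(mean_profile[both]) == 0:
                    corrs.append((s, -np.inf))
                else:
                    corrs.append((s, np.corrcoef(sub[i][both], mean_profile[both])[0, 1]))
            corrs.sort(key=lambda t: (-t[1], t[0]))
            expect = [s for s, _ in corrs[: math.ceil(len(shrnas) / 2)]]
            assert [s for s, _ in sel[gene]] == expect

    def test_selection_sizes(self, synthetic_bundle):
        _, screen, _, bundle = synthetic_bundle
        counts = screen.gene_of.loc[bundle.ranks.index].value_counts()
        for gene, pairs in bundle.consistent.items():
            n = counts[gene]
            assert len(pairs) == math.ceil(n / 2)
            assert 1 <= len(pairs) <= n


class TestEndToEndDenoising:
    def test_correction_improves_agreement_with_noise_free_signal(self):
        cfg = SimConfig(seed=31, n_genes=40, shrnas_per_gene=6, n_cell_lines=6,
                        residual_sd=0.3, pool_offsets=(1.5, -1.0, -0.5), stability_slope=0.4,
                        driver_fraction=0.0, missing_logfc_rate=0.0, n_missing_abundance=0)
        syn = generate_synthetic_screen(cfg)
        screen = syn.screen
        corrected = remove_batch_effects(screen, syn.stability)
        gene_signal = np.array([syn.truth["gene_effect"][g] for g in screen.gene_of.loc[screen.logfc.index]])
        from scipy.stats import spearmanr

        rho_raw = np.mean([spearmanr(screen.logfc[c], gene_signal).statistic for c in screen.cell_lines])
        rho_corr = np.mean([spearmanr(corrected[c], gene_signal).statistic for c in screen.cell_lines])
        assert rho_corr > rho_raw
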