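import numpy as np
import pandas as pd
import pytest


from nbdep.dataio import CancerTypeMap, CopyNumberTable, MutationTable
from nbdep.glmm import bh_adjust
from nbdep.screen import (
    ABLATION_VARIANTS,
    AnalysisBundle,
    run_ablation_variant,
    run_cancer_specific,
    run_pancancer,
)
from nbdep.screen import test_gene as gene_test  # alias keeps pytest from collecting it
from nbdep.simulate import SimConfig, generate_synthetic_screen

from conftest import flat_stability, make_screen


def _results_frame(results):
    return pd.DataFrame(
        [
            (r.gene, r.alteration_class, r.cancer_type, r.n_mutant, r.n_wildtype, r.beta, r.p_value, r.q_value, r.skipped_reason)
            for r in results
        ],
        columns=["gene", "class", "type", "nm", "nw", "beta", "p", "q", "skip"],
    )


class TestTestGene:
    def test_single_mutant_line_skipped_with_reason(self, synthetic_bundle):
        syn, _, _, bundle = synthetic_bundle
        gene = sorted(bundle.consistent)[0]
        lines = list(bundle.ranks.columns)
        from nbdep.alterations import TestGroups

        groups = TestGroups(gene=gene, alteration_class="missense", mutant=lines[:1], control=lines[1:], excluded=[])
        res = gene_test(gene, "missense", bundle.ranks, bundle.consistent, groups)
        assert res.skipped_reason == "insufficient mutant group"
        assert np.isnan(res.beta)

    def test_injected_depletion_detected_in_most_replicates(self, power_bundle):
        # stochastic power property of the generator: a strong driver should
        # reach p < 0.05 in nearly all subsampled replicates
        syn, bundle = power_bundle
        from nbdep.simulate import simulate_power

        gene = syn.truth["driver_genes"][0]
        rep = simulate_power(bundle, [gene], n_m_range=(10,), q_values=(1,), n_datasets=100, seed=17)
        assert rep.table["rejection_fraction"].iloc[0] >= 0.90

    def test_null_gene_rejection_near_nominal(self, null_bundle):
        syn, bundle = null_bundle
        from nbdep.alterations import build_test_groups
        from nbdep.simulate import simulate_type1

        genes = []
        for g in sorted(bundle.consistent):
            grp = build_test_groups(bundle.calls, g, "missense", list(bundle.ranks.columns))
            if len(grp.mutant) >= 8 and len(grp.control) >= 8:
                genes.append(g)
        rep = simulate_type1(bundle, genes[:8], n_datasets=240, alpha=0.05, seed=23)
        # binomial MC band around the nominal 5% level
        assert 0.02 <= rep.rejection_fraction <= 0.09


class TestPancancer:
    def test_recovers_injected_drivers(self, synthetic_bundle):
        syn, _, _, bundle = synthetic_bundle
        results = run_pancancer(bundle)
        frame = _results_frame(results)
        sig = frame[(frame["q"] < 0.05) & frame["skip"].eq("")]
        for gene in syn.truth["driver_genes"]:
            assert gene in set(sig[sig["class"] == "missense"]["gene"])

    def test_group_size_rule_enforced(self, synthetic_bundle):
        _, _, _, bundle = synthetic_bundle
        for r in run_pancancer(bundle):
            if r.tested:
                assert r.n_mutant >= 2 and r.n_wildtype >= 2

    def test_bh_recomputation_reproduces_q_values(self, synthetic_bundle):
        _, _, _, bundle = synthetic_bundle
        results = run_pancancer(bundle)
        for cls in ("missense", "non_missense", "amplification"):
            tested = [r for r in results if r.tested and r.alteration_class == cls]
            qs = bh_adjust([r.p_value for r in tested])
            assert np.allclose(qs, [r.q_value for r in tested], atol=1e-12)

    def test_repeated_runs_identical(self, synthetic_bundle):
        _, _, _, bundle = synthetic_bundle
        a = _results_frame(run_pancancer(bundle, classes=("missense",)))
        b = _results_frame(run_pancancer(bundle, classes=("missense",)))
        pd.testing.assert_frame_equal(a, b)

    def test_cell_line_order_invariance(self, synthetic_bundle):
        syn, screen, _, bundle = synthetic_bundle
        perm = list(bundle.ranks.columns)[::-1]
        shuffled = AnalysisBundle.from_inputs(
            screen.subset_cell_lines(perm), syn.stability, syn.mutations, syn.copynumber
        )
        a = _results_frame(run_pancancer(bundle, classes=("missense",)))
        b = _results_frame(run_pancancer(shuffled, classes=("missense",)))
        pd.testing.assert_frame_equal(a, b)


def _two_type_fixture():
    """16 lines in two cancer types; one gene depleted only in type-A mutants.

    The gene is mutated in 4 lines of each type but the viability shift is
    injected only in type A, so a cancer-specific run must call it in A and
    not in B.  A third type with 3 lines checks the minimum-size gate.
    """
    rng = np.random.default_rng(71)
    n_genes, n_sh = 10, 6
    lines = [f"A{i}" for i in range(8)] + [f"B{i}" for i in range(8)] + [f"C{i}" for i in range(3)]
    genes = [f"g{j}" for j in range(n_genes)]
    ids = [f"{g}_s{k}" for g in genes for k in range(n_sh)]
    base = rng.normal(0, 0.4, size=(len(ids), len(lines)))
    gene_idx = np.repeat(np.arange(n_genes), n_sh)
    mut_a = ["A0", "A1", "A2", "A3"]
    mut_b = ["B0", "B1", "B2", "B3"]
    for j, cl in enumerate(lines):
        if cl in mut_a:
            base[gene_idx == 0, j] -= 2.0  # depletion only in type-A mutants
    mat = pd.DataFrame(base, index=pd.Index(ids, name="shrna_id"), columns=lines)
    screen = make_screen(
        mat,
        genes=[genes[i] for i in gene_idx],
        pools=["poolA"] * len(ids),
        seeds=["ACGTACG"] * len(ids),
        abundance=[100.0] * len(ids),
    )
    # every gene gets mutant lines in both types so BH adjusts over a real
    # family; only g0 carries a viability shift (in its type-A mutants)
    mut_rows = [(genes[0], cl, "Missense_Mutation") for cl in mut_a + mut_b]
    for j in range(1, n_genes):
        for prefix in ("A", "B"):
            mut_rows += [
                (genes[j], f"{prefix}{j % 8}", "Missense_Mutation"),
                (genes[j], f"{prefix}{(j + 3) % 8}", "Missense_Mutation"),
            ]
    mut_rows += [(g, lines[0], "Silent") for g in genes]
    mutations = MutationTable(records=pd.DataFrame(mut_rows, columns=["gene", "cell_line", "variant_classification"]))
    cn = CopyNumberTable(
        gistic=pd.DataFrame(
            {"gene": np.repeat(genes, len(lines)), "cell_line": lines * n_genes, "gistic": 0}
        )
    )
    types = CancerTypeMap(
        type_of=pd.Series(
            ["type_A"] * 8 + ["type_B"] * 8 + ["type_C"] * 3,
            index=pd.Index(lines, name="cell_line"),
            name="cancer_type",
        )
    )
    bundle = AnalysisBundle.from_inputs(screen, flat_stability(screen), mutations, cn)
    return bundle, types


class TestCancerSpecific:
    @pytest.fixture(scope="class")
    def two_type(self):
        return _two_type_fixture()

    def test_small_type_excluded_entirely(self, two_type):
        bundle, types = two_type
        results = run_cancer_specific(bundle, types, min_lines=4, classes=("missense",))
        assert {r.cancer_type for r in results} == {"type_A", "type_B"}

    def test_type_restricted_driver_called_only_in_its_type(self, two_type):
        bundle, types = two_type
        results = run_cancer_specific(bundle, types, min_lines=4, classes=("missense",))
        by = {(r.cancer_type, r.gene): r for r in results}
        res_a, res_b = by[("type_A", "g0")], by[("type_B", "g0")]
        assert res_a.tested and res_b.tested
        assert res_a.q_value < 0.05
        assert res_b.q_value > 0.05

    def test_bh_within_type_and_class(self, two_type):
        bundle, types = two_type
        results = run_cancer_specific(bundle, types, min_lines=4, classes=("missense",))
        for ctype in ("type_A", "type_B"):
            tested = [r for r in results if r.tested and r.cancer_type == ctype]
            assert np.allclose(bh_adjust([r.p_value for r in tested]), [r.q_value for r in tested])


class TestAblation:
    def test_unknown_variant_rejected(self, synthetic_bundle):
        _, _, _, bundle = synthetic_bundle
        with pytest.raises(ValueError, match="unknown variant"):
            run_ablation_variant("nb_rank_none", bundle)

    def test_nb_rank_denoised_identical_to_main_pipeline(self, synthetic_bundle):
        _, _, _, bundle = synthetic_bundle
        a = _results_frame(run_ablation_variant("nb_rank_denoised", bundle, classes=("missense",)))
        b = _results_frame(run_pancancer(bundle, classes=("missense",)))
        pd.testing.assert_frame_equal(a, b)

    def test_no_batch_terms_makes_raw_and_denoised_lmm_agree(self):
        # one pool + constant stability: no estimable batch terms, so the
        # corrected matrix equals the raw matrix and the two LMM variants match
        cfg = SimConfig(
            seed=41, n_genes=12, shrnas_per_gene=4, n_cell_lines=10,
            pool_labels=("poolA",), pool_offsets=(0.0,), stability_sd=0.0,
            driver_fraction=0.1, mutant_fraction=0.4,
            n_missing_abundance=0, missing_logfc_rate=0.0,
        )
        syn = generate_synthetic_screen(cfg)
        with pytest.warns(UserWarning):  # both batch terms dropped as inestimable
            bundle = AnalysisBundle.from_inputs(syn.screen, syn.stability, syn.mutations, syn.copynumber)
        assert bundle.corrected.equals(bundle.screen.logfc)
        raw = run_ablation_variant("lmm_raw", bundle, classes=("missense",))
        den = run_ablation_variant("lmm_denoised", bundle, classes=("missense",))
        beta_raw = np.array([r.beta for r in raw if r.tested])
        beta_den = np.array([r.beta for r in den if r.tested])
        assert np.max(np.abs(beta_raw - beta_den)) < 1e-6

    def test_all_variants_produce_results(self, synthetic_bundle):
        _, _, _, bundle = synthetic_bundle
        for variant in ABLATION_VARIANTS:
            results = run_ablation_variant(variant, bundle, classes=("missense",))
            assert any(r.tested for r in results)
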