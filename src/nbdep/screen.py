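"""Screen-wide association testing: per-gene tests, pan-cancer and
cancer-specific runs, and the ablation variants that isolate the
contribution of denoising and ranking.

Every (gene, alteration class) with at least two mutant and two strictly
wild-type cell lines contributing observations is tested with the NB
random-intercept model on the gene's retained shRNA ranks; one-sided Wald
p-values are Benjamini-Hochberg adjusted within each alteration class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alterations import TESTED_CLASSES, AlterationCalls, build_test_groups, classify_gene_cell_alterations
from .dataio import (
    CancerTypeMap,
    CopyNumberTable,
    GeneTestResult,
    MutationTable,
    ScreenDataset,
    SeedStabilityTable,
)
from .denoise import rank_within_cell_line, remove_batch_effects, select_consistent_shrnas
from .glmm import GaussianMixedModel, NegativeBinomialMixedModel, bh_adjust, wald_one_sided_p

__all__ = [
    "AnalysisBundle",
    "ABLATION_VARIANTS",
    "test_gene",
    "run_pancancer",
    "run_cancer_specific",
    "run_ablation_variant",
]

ABLATION_VARIANTS = ("lmm_raw", "lmm_denoised", "nb_rank_raw", "nb_rank_denoised")

MIN_GROUP = 2


@dataclass
class AnalysisBundle:
    """Everything the per-gene test consumes, computed once per screen."""

    screen: ScreenDataset
    corrected: pd.DataFrame
    ranks: pd.DataFrame
    consistent: dict[str, list[tuple[str, float]]]
    calls: AlterationCalls

    @classmethod
    def from_inputs(
        cls,
        screen: ScreenDataset,
        seeds: SeedStabilityTable,
        mutations: MutationTable,
        cn: CopyNumberTable,
    ) -> "AnalysisBundle":
        """Run batch correction, ranking, consistency selection and alteration calling."""
        corrected = remove_batch_effects(screen, seeds)
        ranks = rank_within_cell_line(corrected)
        consistent = select_consistent_shrnas(ranks, screen.gene_of)
        calls = classify_gene_cell_alterations(mutations, cn)
        return cls(screen=screen, corrected=corrected, ranks=ranks, consistent=consistent, calls=calls)

    def subset_cell_lines(self, keep: list[str]) -> "AnalysisBundle":
        keep = [c for c in self.ranks.columns if c in set(keep)]
        return AnalysisBundle(
            screen=self.screen.subset_cell_lines(keep),
            corrected=self.corrected[keep],
            ranks=self.ranks[keep],
            consistent=self.consistent,
            calls=self.calls,
        )


def _assemble_observations(values: pd.DataFrame, shrnas: list[str], mutant_lines: list[str], control_lines: list[str]):
    """Stack one gene's retained-shRNA values over mutant + control lines.

    Returns (y, x, groups, n_mutant_lines, n_control_lines) after dropping
    missing entries; group counts reflect lines actually contributing >= 1
    observation.
    """
    lines = list(mutant_lines) + list(control_lines)
    is_mut = {c: 1.0 for c in mutant_lines}
    sub = values.loc[shrnas, lines]
    arr = sub.to_numpy()
    y, x, g = [], [], []
    for j, cl in enumerate(lines):
        col = arr[:, j]
        obs = np.isfinite(col)
        if not obs.any():
            continue
        y.extend(col[obs])
        x.extend([is_mut.get(cl, 0.0)] * int(obs.sum()))
        g.extend([cl] * int(obs.sum()))
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n_mut = len({c for c, xi in zip(g, x) if xi == 1.0})
    n_ctl = len({c for c, xi in zip(g, x) if xi == 0.0})
    return y, x, np.asarray(g, dtype=object), n_mut, n_ctl


def _fit_one(y, x, groups, family: str, n_quad: int):
    if family == "nb":
        model = NegativeBinomialMixedModel(y, x, groups)
        return model.fit(n_quad=n_quad)
    model = GaussianMixedModel(y, x, groups)
    return model.fit()


def test_gene(
    gene: str,
    cls: str,
    ranks: pd.DataFrame,
    consistent: dict,
    groups,
    n_quad: int = 1,
    family: str = "nb",
) -> GeneTestResult:
    """Test one (gene, alteration class) on the gene's retained shRNAs.

    Testable iff >= 2 mutant and >= 2 control cell lines each contribute at
    least one observed rank; otherwise the result is marked skipped with a
    reason and carries no estimates.
    """
    if gene not in consistent:
        return GeneTestResult(gene=gene, alteration_class=cls, skipped_reason="no shRNA data")
    shrnas = [s for s, _ in consistent[gene]]
    y, x, g, n_mut, n_ctl = _assemble_observations(ranks, shrnas, groups.mutant, groups.control)
    if n_mut < MIN_GROUP:
        return GeneTestResult(gene=gene, alteration_class=cls, n_mutant=n_mut, n_wildtype=n_ctl,
                              n_shrnas_used=len(shrnas), skipped_reason="insufficient mutant group")
    if n_ctl < MIN_GROUP:
        return GeneTestResult(gene=gene, alteration_class=cls, n_mutant=n_mut, n_wildtype=n_ctl,
                              n_shrnas_used=len(shrnas), skipped_reason="insufficient wild-type group")
    try:
        fit = _fit_one(y, x, g, family=family, n_quad=n_quad)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return GeneTestResult(gene=gene, alteration_class=cls, n_mutant=n_mut, n_wildtype=n_ctl,
                              n_shrnas_used=len(shrnas), skipped_reason=f"fit failed: {exc}")
    return GeneTestResult(
        gene=gene,
        alteration_class=cls,
        n_mutant=n_mut,
        n_wildtype=n_ctl,
        n_shrnas_used=len(shrnas),
        beta=fit.beta,
        se_beta=fit.se_beta,
        theta=fit.theta if fit.theta is not None else np.nan,
        sigma2=fit.sigma2,
        p_value=wald_one_sided_p(fit.beta, fit.se_beta),
        converged=fit.converged,
    )


def _adjust_within_class(results: list[GeneTestResult]) -> None:
    """BH-adjust p-values in place, separately per (cancer_type, class)."""
    strata: dict[tuple, list[GeneTestResult]] = {}
    for r in results:
        if r.tested and np.isfinite(r.p_value):
            strata.setdefault((r.cancer_type, r.alteration_class), []).append(r)
    for _, rs in strata.items():
        qs = bh_adjust([r.p_value for r in rs])
        for r, q in zip(rs, qs):
            r.q_value = float(q)


def _run_tests(
    bundle: AnalysisBundle,
    values: pd.DataFrame,
    consistent: dict,
    classes=TESTED_CLASSES,
    family: str = "nb",
    n_quad: int = 1,
    cancer_type: str = "",
) -> list[GeneTestResult]:
    cell_lines = list(values.columns)
    genes = sorted(set(bundle.screen.gene_of.loc[values.index.unique()]))
    results = []
    for cls in classes:
        for gene in genes:
            grp = build_test_groups(bundle.calls, gene, cls, cell_lines)
            res = test_gene(gene, cls, values, consistent, grp, n_quad=n_quad, family=family)
            res.cancer_type = cancer_type
            results.append(res)
    _adjust_within_class(results)
    results.sort(key=lambda r: (r.cancer_type, r.alteration_class, r.gene))
    return results


def run_pancancer(bundle: AnalysisBundle, classes=TESTED_CLASSES, n_quad: int = 1) -> list[GeneTestResult]:
    """Test every (gene, class) over all cell lines; BH within each class."""
    results = _run_tests(bundle, bundle.ranks, bundle.consistent, classes=classes, n_quad=n_quad)
    if not any(r.tested for r in results):
        warnings.warn("no testable (gene, class) combinations")
    return results


def run_cancer_specific(
    bundle: AnalysisBundle,
    types: CancerTypeMap,
    min_lines: int = 4,
    classes=TESTED_CLASSES,
    n_quad: int = 1,
) -> list[GeneTestResult]:
    """Per-cancer-type testing; types with fewer than ``min_lines`` screened
    cell lines (after preprocessing) are excluded entirely.  BH within each
    (type, class)."""
    by_type: dict[str, list[str]] = {}
    for cl in bundle.ranks.columns:
        if cl in types.type_of.index:
            by_type.setdefault(str(types.type_of[cl]), []).append(cl)
    results: list[GeneTestResult] = []
    for ctype in sorted(by_type):
        lines = by_type[ctype]
        if len(lines) < min_lines:
            continue
        sub = bundle.subset_cell_lines(lines)
        results.extend(
            _run_tests(sub, sub.ranks, sub.consistent, classes=classes, n_quad=n_quad, cancer_type=ctype)
        )
    return results


def run_ablation_variant(
    variant: str,
    bundle: AnalysisBundle,
    classes=TESTED_CLASSES,
    n_quad: int = 1,
) -> list[GeneTestResult]:
    """Run one of four model variants sharing grouping/selection/testing machinery.

    - ``lmm_raw``: Gaussian LMM on raw logFC;
    - ``lmm_denoised``: Gaussian LMM on batch-corrected logFC;
    - ``nb_rank_raw``: NB mixed model on ranks of raw logFC;
    - ``nb_rank_denoised``: NB mixed model on ranks of corrected logFC —
      identical to the main pipeline.

    Consistency selection always operates on the rank matrix matching the
    variant's response (raw-based variants select on ranks of raw logFC).
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {ABLATION_VARIANTS}")
    if variant == "nb_rank_denoised":
        return _run_tests(bundle, bundle.ranks, bundle.consistent, classes=classes, n_quad=n_quad)

    if variant in ("lmm_raw", "nb_rank_raw"):
        base = bundle.screen.logfc
        raw_ranks = rank_within_cell_line(base)
        consistent = select_consistent_shrnas(raw_ranks, bundle.screen.gene_of)
        if variant == "nb_rank_raw":
            return _run_tests(bundle, raw_ranks, consistent, classes=classes, family="nb", n_quad=n_quad)
        return _run_tests(bundle, base, consistent, classes=classes, family="gaussian")
    # lmm_denoised
    return _run_tests(bundle, bundle.corrected, bundle.consistent, classes=classes, family="gaussian")
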