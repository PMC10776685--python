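"""Synthetic pooled-screen generator and Monte-Carlo type-I-error / power protocols.

The generator emulates the structure of an shRNA dependency screen:

    logFC(s, c) = gene_effect(g(s))
                + driver_shift * mutant(g(s), c)
                + pool_offset(pool(s))
                + stability_slope * stability(seed(s))
                + cell_line_effect(c)
                + noise

with NB-distributed initial library abundances (some below the filter floor
and some missing, to exercise preprocessing), a generated 7-mer seed
stability table, and mutation / GISTIC tables consistent with the mutant
assignments.  Everything derives from a single integer seed; per-replicate
substreams make the Monte-Carlo reports exactly reproducible.

The type-I protocol assigns random pseudo-mutant / pseudo-wild-type labels
(sizes n_m ~ U{2..m}, n_w ~ U{2..w}) so the null holds by construction; the
power protocol subsamples n_m true mutant and n_w = q * n_m wild-type lines
per setting.  Both report the fraction of tests rejected at the raw p < alpha.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alterations import build_test_groups
from .dataio import (
    CancerTypeMap,
    CopyNumberTable,
    MutationTable,
    ScreenDataset,
    SeedStabilityTable,
)
from .glmm import NegativeBinomialMixedModel, wald_one_sided_p

__all__ = [
    "SimConfig",
    "SyntheticScreen",
    "SimReport",
    "generate_synthetic_screen",
    "simulate_type1",
    "simulate_power",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic screen (defaults are the desk scale)."""

    n_genes: int = 100
    shrnas_per_gene: int = 10
    n_cell_lines: int = 20
    pool_labels: tuple = ("poolA", "poolB", "BGPD")
    pool_offsets: tuple = (0.3, -0.1, -0.2)
    stability_slope: float = 0.1
    stability_mean: float = -7.0
    stability_sd: float = 1.5
    gene_effect_sd: float = 0.5
    cellline_sd: float = 0.3
    residual_sd: float = 0.8
    driver_effect: float = -1.0
    driver_fraction: float = 0.05
    mutant_fraction: float = 0.25
    max_null_mutants: int = 6
    passenger_silent_records: bool = True
    amp_rate: float = 0.02
    deep_del_rate: float = 0.01
    abundance_mean: float = 500.0
    abundance_shape: float = 2.0
    n_missing_abundance: int = 2
    missing_logfc_rate: float = 0.02
    n_hypermutated: int = 0
    hypermutated_records: int = 2000
    n_duplicate_shrnas: int = 0
    n_cancer_types: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("stability_sd", "gene_effect_sd", "cellline_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.driver_fraction <= 1:
            raise ValueError("driver_fraction must be in [0, 1]")
        if len(self.pool_labels) != len(self.pool_offsets):
            raise ValueError("pool_labels and pool_offsets must have equal length")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass
class SyntheticScreen:
    """Generated tables plus the ground truth they were generated from."""

    screen: ScreenDataset
    mutations: MutationTable
    copynumber: CopyNumberTable
    stability: SeedStabilityTable
    types: CancerTypeMap
    truth: dict = field(default_factory=dict)

    def as_tuple(self):
        return self.screen, self.mutations, self.copynumber, self.stability, self.types


@dataclass
class SimReport:
    """Monte-Carlo rejection summary; one row per setting plus pooled totals."""

    protocol: str
    table: pd.DataFrame
    pvalues: np.ndarray
    alpha: float
    seed: int

    @property
    def rejection_fraction(self) -> float:
        n = int(self.table["n_datasets"].sum())
        return float(self.table["n_rejected"].sum() / n) if n else float("nan")

    @property
    def mc_se(self) -> float:
        n = int(self.table["n_datasets"].sum())
        p = self.rejection_fraction
        return float(np.sqrt(p * (1 - p) / n)) if n else float("nan")


def generate_synthetic_screen(config: SimConfig) -> SyntheticScreen:
    """Draw one full synthetic screen bundle from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    G, S, L = config.n_genes, config.shrnas_per_gene, config.n_cell_lines
    genes = [f"G{g:04d}" for g in range(G)]
    lines = [f"CL{c:03d}" for c in range(L)]
    n_shrnas = G * S
    shrna_ids = [f"{genes[g]}_sh{s:02d}" for g in range(G) for s in range(S)]
    gene_of = np.repeat(np.arange(G), S)

    pools = rng.choice(len(config.pool_labels), size=n_shrnas)
    seeds7 = ["".join(row) for row in _BASES[rng.integers(0, 4, size=(n_shrnas, 7))]]
    uniq_seeds = sorted(set(seeds7))
    stab_vals = rng.normal(config.stability_mean, config.stability_sd, size=len(uniq_seeds))
    stability = SeedStabilityTable(
        stability_of=pd.Series(stab_vals, index=pd.Index(uniq_seeds, name="seed"), name="stability")
    )
    stab_of_shrna = stability.stability_of.loc[seeds7].to_numpy()

    # driver genes and mutant assignments
    n_drivers = int(round(config.driver_fraction * G))
    driver_idx = rng.choice(G, size=n_drivers, replace=False) if n_drivers else np.array([], dtype=int)
    is_driver = np.zeros(G, dtype=bool)
    is_driver[driver_idx] = True
    mutant = np.zeros((G, L), dtype=bool)
    for g in range(G):
        if is_driver[g]:
            n_mut = min(max(2, int(round(config.mutant_fraction * L))), L)
        else:
            n_mut = min(int(rng.integers(0, config.max_null_mutants + 1)), L)
        if n_mut:
            mutant[g, rng.choice(L, size=n_mut, replace=False)] = True

    gene_effect = rng.normal(0.0, config.gene_effect_sd, size=G)
    cell_effect = rng.normal(0.0, config.cellline_sd, size=L)
    noise = rng.normal(0.0, config.residual_sd, size=(n_shrnas, L))
    offsets = np.asarray(config.pool_offsets)

    logfc = (
        gene_effect[gene_of][:, None]
        + config.driver_effect * (is_driver[gene_of][:, None] & mutant[gene_of, :])
        + offsets[pools][:, None]
        + config.stability_slope * stab_of_shrna[:, None]
        + cell_effect[None, :]
        + noise
    )
    if config.missing_logfc_rate > 0:
        mask = rng.random(size=logfc.shape) < config.missing_logfc_rate
        logfc = np.where(mask, np.nan, logfc)

    # NB abundances: gamma-Poisson mixture with mean and shape from config
    lam = rng.gamma(config.abundance_shape, config.abundance_mean / config.abundance_shape, size=n_shrnas)
    abundance = rng.poisson(lam).astype(float)
    if config.n_missing_abundance:
        miss = rng.choice(n_shrnas, size=min(config.n_missing_abundance, n_shrnas), replace=False)
        abundance[miss] = np.nan

    annotations = pd.DataFrame(
        {
            "gene": [genes[g] for g in gene_of],
            "pool": [config.pool_labels[p] for p in pools],
            "seed": seeds7,
            "initial_abundance": abundance,
        },
        index=pd.Index(shrna_ids, name="shrna_id"),
    )
    logfc_df = pd.DataFrame(logfc, index=pd.Index(shrna_ids, name="shrna_id"), columns=lines)

    n_dup = 0
    if config.n_duplicate_shrnas:
        dup_ids = list(rng.choice(np.array(shrna_ids), size=config.n_duplicate_shrnas, replace=False))
        extra = logfc_df.loc[dup_ids] + rng.normal(0.0, 0.1, size=(len(dup_ids), L))
        logfc_df = pd.concat([logfc_df, extra])
        n_dup = len(dup_ids)

    # mutation records: missense for every mutant assignment, plus one
    # unclassified record per gene so every gene is profiled
    mut_rows = []
    for g in range(G):
        for c in np.flatnonzero(mutant[g]):
            mut_rows.append((genes[g], lines[c], "Missense_Mutation"))
        if config.passenger_silent_records:
            mut_rows.append((genes[g], lines[int(rng.integers(0, L))], "Silent"))
    # hypermutated lines get a large burden of non-flagging records
    hyper = list(rng.choice(L, size=config.n_hypermutated, replace=False)) if config.n_hypermutated else []
    for c in hyper:
        gsel = rng.integers(0, G, size=config.hypermutated_records)
        for g in gsel:
            mut_rows.append((genes[g], lines[c], "Silent"))
    mutations = MutationTable(records=pd.DataFrame(mut_rows, columns=["gene", "cell_line", "variant_classification"]))

    # GISTIC: every gene profiled in every line; sparse +-2 on non-driver genes
    gistic = np.zeros((G, L), dtype=int)
    nondriver = ~is_driver
    amp_mask = (rng.random(size=(G, L)) < config.amp_rate) & nondriver[:, None]
    del_mask = (rng.random(size=(G, L)) < config.deep_del_rate) & nondriver[:, None] & ~amp_mask
    gistic[amp_mask] = 2
    gistic[del_mask] = -2
    cn_frame = pd.DataFrame(
        {
            "gene": np.repeat(genes, L),
            "cell_line": np.tile(lines, G),
            "gistic": gistic.reshape(-1),
        }
    )
    copynumber = CopyNumberTable(gistic=cn_frame)

    type_labels = [f"type_{1 + (i % config.n_cancer_types)}" for i in range(L)]
    types = CancerTypeMap(type_of=pd.Series(type_labels, index=pd.Index(lines, name="cell_line"), name="cancer_type"))

    screen = ScreenDataset(annotations=annotations, logfc=logfc_df)

    truth = {
        "driver_genes": sorted(genes[g] for g in driver_idx),
        "mutant_lines": {genes[g]: [lines[c] for c in np.flatnonzero(mutant[g])] for g in range(G)},
        "gene_effect": dict(zip(genes, gene_effect)),
        "pool_offsets": dict(zip(config.pool_labels, config.pool_offsets)),
        "stability_slope": config.stability_slope,
        "hypermutated_lines": sorted(lines[c] for c in hyper),
        "n_shrnas_low_or_missing_abundance": int(np.sum(np.isnan(abundance) | (abundance < 50))),
        "n_duplicates": n_dup,
    }
    return SyntheticScreen(
        screen=screen, mutations=mutations, copynumber=copynumber, stability=stability, types=types, truth=truth
    )


# ------------------------------------------------------------ MC protocols


def _fit_gene_pvalue(ranks: pd.DataFrame, consistent: dict, gene: str, mut_lines, wt_lines, n_quad: int):
    """One NB mixed-model fit on a gene's retained shRNAs for given groups."""
    shrnas = [s for s, _ in consistent[gene]]
    sub = ranks.loc[shrnas, list(mut_lines) + list(wt_lines)]
    arr = sub.to_numpy()
    mutset = set(mut_lines)
    y, x, g = [], [], []
    for j, cl in enumerate(sub.columns):
        col = arr[:, j]
        obs = np.isfinite(col)
        if not obs.any():
            continue
        y.extend(col[obs])
        x.extend([1.0 if cl in mutset else 0.0] * int(obs.sum()))
        g.extend([cl] * int(obs.sum()))
    try:
        fit = NegativeBinomialMixedModel(np.asarray(y), np.asarray(x), np.asarray(g, dtype=object)).fit(n_quad=n_quad)
        return wald_one_sided_p(fit.beta, fit.se_beta)
    except (ValueError, np.linalg.LinAlgError):
        return None


def _gene_groups(bundle, gene: str, cls: str = "missense"):
    grp = build_test_groups(bundle.calls, gene, cls, list(bundle.ranks.columns))
    return grp.mutant, grp.control


def simulate_type1(
    bundle,
    genes: list[str],
    n_datasets: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    n_quad: int = 1,
    alteration_class: str = "missense",
) -> SimReport:
    """Estimate per-test type-I error by random pseudo-labelling.

    Replicates are distributed evenly across ``genes`` (remainder to the
    first genes).  Denoising, ranking and shRNA selection do not depend on
    the labels, so only the mixed-model fit is redone per replicate.
    """
    usable = []
    for gene in genes:
        mut, wt = _gene_groups(bundle, gene, alteration_class)
        if len(mut) < 2 or len(wt) < 2 or gene not in bundle.consistent:
            warnings.warn(f"gene {gene!r} skipped in type-I protocol (m={len(mut)}, w={len(wt)})")
            continue
        usable.append((gene, len(mut), len(wt)))
    if not usable:
        raise ValueError("no usable genes for the type-I protocol")

    all_lines = np.array(bundle.ranks.columns, dtype=object)
    per_gene = [n_datasets // len(usable)] * len(usable)
    for i in range(n_datasets % len(usable)):
        per_gene[i] += 1

    rows, pvals = [], []
    rep_counter = 0
    for (gene, m, w), n_rep in zip(usable, per_gene):
        n_rej = 0
        n_done = 0
        for _ in range(n_rep):
            rng = np.random.default_rng([seed, rep_counter])
            rep_counter += 1
            n_m = int(rng.integers(2, m + 1))
            pseudo_mut = rng.choice(all_lines, size=n_m, replace=False)
            remaining = np.array([c for c in all_lines if c not in set(pseudo_mut)], dtype=object)
            n_w = int(rng.integers(2, w + 1))
            n_w = min(n_w, len(remaining))
            pseudo_wt = rng.choice(remaining, size=n_w, replace=False)
            p = _fit_gene_pvalue(bundle.ranks, bundle.consistent, gene, pseudo_mut, pseudo_wt, n_quad)
            if p is None:
                continue
            pvals.append(p)
            n_done += 1
            if p < alpha:
                n_rej += 1
        frac = n_rej / n_done if n_done else float("nan")
        rows.append(
            {
                "gene": gene,
                "m": m,
                "w": w,
                "n_datasets": n_done,
                "n_rejected": n_rej,
                "rejection_fraction": frac,
                "mc_se": float(np.sqrt(frac * (1 - frac) / n_done)) if n_done else float("nan"),
            }
        )
    return SimReport(protocol="type1", table=pd.DataFrame(rows), pvalues=np.array(pvals), alpha=alpha, seed=seed)


def simulate_power(
    bundle,
    genes: list[str],
    n_m_range=range(2, 11),
    q_values=(1, 2, 3, 4),
    n_datasets: int = 800,
    alpha: float = 0.05,
    seed: int = 0,
    n_quad: int = 1,
    alteration_class: str = "missense",
) -> SimReport:
    """Estimate power by subsampling true mutant and wild-type lines.

    For each (gene, n_m, q) with n_w = q * n_m, ``n_datasets`` subsampled
    datasets are tested; settings a gene cannot support are skipped with a
    warning.
    """
    rows, pvals = [], []
    for gi, gene in enumerate(genes):
        mut, wt = _gene_groups(bundle, gene, alteration_class)
        if gene not in bundle.consistent:
            warnings.warn(f"gene {gene!r} has no shRNA data; skipped")
            continue
        mut = np.array(mut, dtype=object)
        wt = np.array(wt, dtype=object)
        for n_m, q in itertools.product(n_m_range, q_values):
            n_w = q * n_m
            if n_m > len(mut) or n_w > len(wt):
                warnings.warn(f"gene {gene!r}: setting n_m={n_m}, q={q} not supported (m={len(mut)}, w={len(wt)})")
                continue
            n_rej = 0
            n_done = 0
            for rep in range(n_datasets):
                rng = np.random.default_rng([seed, gi, n_m, q, rep])
                sub_m = rng.choice(mut, size=n_m, replace=False)
                sub_w = rng.choice(wt, size=n_w, replace=False)
                p = _fit_gene_pvalue(bundle.ranks, bundle.consistent, gene, sub_m, sub_w, n_quad)
                if p is None:
                    continue
                pvals.append(p)
                n_done += 1
                if p < alpha:
                    n_rej += 1
            frac = n_rej / n_done if n_done else float("nan")
            rows.append(
                {
                    "gene": gene,
                    "n_m": n_m,
                    "n_w": n_w,
                    "q": q,
                    "n_datasets": n_done,
                    "n_rejected": n_rej,
                    "rejection_fraction": frac,
                    "mc_se": float(np.sqrt(frac * (1 - frac) / n_done)) if n_done else float("nan"),
                }
            )
    return SimReport(protocol="power", table=pd.DataFrame(rows), pvalues=np.array(pvals), alpha=alpha, seed=seed)
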