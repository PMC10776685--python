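"""Batch-effect removal, within-cell-line ranking, and concordant-shRNA selection.

Two known batch effects of shRNA reagents are removed from the logFC values:
the library pool a hairpin was screened in, and the thermodynamic pairing
stability of its 7-mer seed (which predicts microRNA-like off-target
strength).  Both are attributes of the shRNA, so the correction is an
ordinary least-squares residualization fitted independently within each cell
line across its observed shRNAs, with a sum-to-zero pool encoding and a
centered stability covariate so the cell line's mean is preserved.

Corrected values are then ranked within each cell line (rank 1 = most
depleted), and for every gene the half of its shRNAs most concordant with
the gene's average rank profile is retained.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .dataio import ScreenDataset, SeedStabilityTable

__all__ = [
    "remove_batch_effects",
    "rank_within_cell_line",
    "select_consistent_shrnas",
]


def _stability_covariate(screen: ScreenDataset, seeds: SeedStabilityTable) -> np.ndarray:
    """Per-shRNA stability; seeds absent from the table get the table mean."""
    mean_stab = seeds.mean_stability
    vals = np.empty(len(screen.shrna_ids))
    stab = seeds.stability_of
    for j, shrna in enumerate(screen.shrna_ids):
        seed = screen.seed_of[shrna]
        if seed is not None and seed in stab.index:
            vals[j] = stab[seed]
        else:
            vals[j] = mean_stab
    return vals


def remove_batch_effects(screen: ScreenDataset, seeds: SeedStabilityTable) -> pd.DataFrame:
    """Residualize pool and seed-stability effects out of the logFC matrix.

    For each cell line c with observed shRNAs s the model
    ``y_s = alpha_c + delta_c[pool(s)] + gamma_c * (stab(s) - mean stab) + eps``
    is fitted by OLS (sum-to-zero pool deviations) and the fitted pool and
    stability terms are subtracted.  Cell lines whose observed shRNAs span a
    single pool lose the pool term; constant stability drops the stability
    term.  Missing entries stay missing; the operation is idempotent.
    """
    mat = screen.logfc
    if mat.index.has_duplicates:
        raise ValueError("collapse duplicate shRNA rows before batch correction")
    pools = screen.pool_of.loc[mat.index].to_numpy()
    stab_all = _stability_covariate(screen, seeds)
    stab_all = pd.Series(stab_all, index=screen.annotations.index).loc[mat.index].to_numpy()

    out = mat.copy()
    values = mat.to_numpy()
    for j, cl in enumerate(mat.columns):
        y = values[:, j]
        obs = np.isfinite(y)
        if obs.sum() < 2:
            continue
        yv = y[obs]
        pv = pools[obs]
        sv = stab_all[obs]

        cols = [np.ones(obs.sum())]
        levels = sorted(set(pv))
        use_pool = len(levels) > 1
        if not use_pool:
            warnings.warn(f"cell line {cl!r}: single pool among observed shRNAs; pool term dropped")
        use_stab = np.ptp(sv) > 0
        if not use_stab:
            warnings.warn(f"cell line {cl!r}: constant seed stability; stability term dropped")
        if not use_pool and not use_stab:
            continue

        if use_pool:
            # sum-to-zero encoding: last level's deviation = -(sum of others)
            for lev in levels[:-1]:
                col = np.where(pv == lev, 1.0, 0.0) - np.where(pv == levels[-1], 1.0, 0.0)
                cols.append(col)
        sbar = sv.mean()
        if use_stab:
            cols.append(sv - sbar)
        X = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(X, yv, rcond=None)

        batch = np.zeros(obs.sum())
        k = 1
        if use_pool:
            dev = dict(zip(levels[:-1], coef[1 : len(levels)]))
            dev[levels[-1]] = -sum(coef[1 : len(levels)])
            batch += np.array([dev[p] for p in pv])
            k = len(levels)
        if use_stab:
            batch += coef[k] * (sv - sbar)
        corrected = yv - batch
        col = y.copy()
        col[obs] = corrected
        out[cl] = col
    return out


def rank_within_cell_line(corrected: pd.DataFrame) -> pd.DataFrame:
    """Ascending integer ranks per cell line over observed entries.

    The most depleted (most negative) corrected logFC gets rank 1; missing
    entries stay missing and observed ranks are contiguous 1..n_observed.
    Ties are broken deterministically by shRNA ID lexicographic order.
    """
    ids = np.asarray(corrected.index, dtype=object)
    out = pd.DataFrame(np.nan, index=corrected.index, columns=corrected.columns)
    values = corrected.to_numpy()
    for j in range(values.shape[1]):
        y = values[:, j]
        obs = np.flatnonzero(np.isfinite(y))
        if obs.size == 0:
            continue
        order = obs[np.lexsort((ids[obs], y[obs]))]
        col = np.full(len(y), np.nan)
        col[order] = np.arange(1, obs.size + 1, dtype=float)
        out.iloc[:, j] = col
    return out


def _pearson_pairwise(a: np.ndarray, b: np.ndarray, min_pairs: int = 3) -> float:
    """Pearson r over indices where both vectors are observed; -inf if undefined."""
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < min_pairs:
        return -np.inf
    x, y = a[mask], b[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return -np.inf
    r = np.corrcoef(x, y)[0, 1]
    return float(r) if np.isfinite(r) else -np.inf


def select_consistent_shrnas(ranks: pd.DataFrame, gene_of: pd.Series) -> dict[str, list[tuple[str, float]]]:
    """Per gene, retain ceil(n/2) shRNAs most correlated with the mean rank profile.

    The mean profile is the per-cell-line average rank over all the gene's
    shRNAs that have at least one observed rank (the shRNA being scored is
    included in the average).  Correlations are pairwise-complete Pearson;
    undefined correlations (< 3 paired observations or zero variance) score
    -inf and are never selected ahead of defined ones.  Ties at the cutoff
    break by shRNA ID.  Returns ``{gene: [(shrna_id, r), ...]}`` in retained
    order.
    """
    gene_groups: dict[str, list[str]] = {}
    for shrna in ranks.index:
        gene_groups.setdefault(gene_of[shrna], []).append(shrna)

    out: dict[str, list[tuple[str, float]]] = {}
    rank_values = ranks.to_numpy()
    pos = {s: i for i, s in enumerate(ranks.index)}
    for gene, shrnas in gene_groups.items():
        with_data = [s for s in shrnas if np.isfinite(rank_values[pos[s]]).any()]
        if not with_data:
            continue
        n = len(with_data)
        if n == 1:
            out[gene] = [(with_data[0], float("nan"))]
            continue
        sub = np.vstack([rank_values[pos[s]] for s in with_data])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_profile = np.nanmean(sub, axis=0)
        corrs = []
        for i, s in enumerate(with_data):
            r = _pearson_pairwise(sub[i], mean_profile)
            if r == -np.inf:
                warnings.warn(f"gene {gene!r}: correlation undefined for shRNA {s!r}")
            corrs.append((s, r))
        n_keep = math.ceil(n / 2)
        corrs.sort(key=lambda t: (-t[1], t[0]))
        out[gene] = corrs[:n_keep]
    return out
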