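"""Screen preprocessing: cell-line, gene, and shRNA filters plus duplicate collapsing.

The four steps run in a fixed order:

1. drop hypermutated cell lines (mutation burden > mean + 3 sd over lines);
2. drop genes absent from either the mutation or the copy-number gene universe;
3. drop shRNAs whose initial library abundance is missing or below a floor
   (default 50, strictly less than);
4. collapse duplicated shRNA rows by averaging observed readouts (and the
   abundance) per cell line.

Re-running the pipeline on its own output is the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import CopyNumberTable, MutationTable, ScreenDataset

__all__ = [
    "PreprocessReport",
    "remove_hypermutated_cell_lines",
    "filter_genes_without_molecular_data",
    "filter_shrnas_by_abundance",
    "collapse_duplicate_measurements",
    "run_preprocess",
]

DEFAULT_MIN_ABUNDANCE = 50


@dataclass
class PreprocessReport:
    n_cell_lines_removed_hypermutated: int
    n_genes_removed_no_molecular_data: int
    n_shrnas_removed_abundance: int
    n_duplicates_collapsed: int
    n_shrnas_final: int
    n_genes_final: int
    n_cell_lines_final: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def remove_hypermutated_cell_lines(mutations: MutationTable, cell_lines: list[str]):
    """Split cell lines into (kept, removed) by mutation burden.

    A line is removed iff its record count exceeds mean + 3 sd (sample sd,
    n-1 denominator), computed once on the original burdens. Lines absent
    from the table have burden zero.
    """
    cell_lines = list(cell_lines)
    if len(cell_lines) < 2:
        warnings.warn("fewer than 2 cell lines: burden sd undefined, keeping all")
        return cell_lines, []
    counts = mutations.records["cell_line"].value_counts()
    burden = np.array([counts.get(c, 0) for c in cell_lines], dtype=float)
    thresh = burden.mean() + 3.0 * burden.std(ddof=1)
    removed = [c for c, b in zip(cell_lines, burden) if b > thresh]
    kept = [c for c in cell_lines if c not in set(removed)]
    return kept, removed


def filter_genes_without_molecular_data(
    screen: ScreenDataset, mutations: MutationTable, cn: CopyNumberTable
) -> ScreenDataset:
    """Keep a gene iff it is profiled in BOTH the mutation and copy-number tables.

    Presence means the gene appears in the table at all (a gene with GISTIC 0
    everywhere is still profiled); absence drops all the gene's shRNAs.
    """
    good = mutations.gene_universe & cn.gene_universe
    keep = screen.annotations.index[screen.annotations["gene"].isin(good)]
    if len(keep) == 0:
        warnings.warn("no gene has both mutation and copy-number data; dataset is empty")
    return screen.subset_shrnas(keep)


def filter_shrnas_by_abundance(screen: ScreenDataset, min_abundance: float = DEFAULT_MIN_ABUNDANCE) -> ScreenDataset:
    """Keep shRNAs whose initial abundance is present and >= ``min_abundance``."""
    ab = screen.initial_abundance_of
    keep = ab.index[ab.notna() & (ab >= min_abundance)]
    return screen.subset_shrnas(keep)


def collapse_duplicate_measurements(screen: ScreenDataset) -> tuple[ScreenDataset, int]:
    """Average replicated readouts per shRNA and cell line into one row.

    Missing readouts are excluded from each mean (all-missing stays missing).
    Duplicate rows must agree on gene/pool/seed; returns the collapsed dataset
    and the number of duplicate rows collapsed away.
    """
    mat = screen.logfc
    dup_mask = mat.index.duplicated(keep=False)
    n_collapsed = int(mat.index.duplicated(keep="first").sum())
    if n_collapsed == 0:
        return screen, 0
    for shrna in mat.index[dup_mask].unique():
        # annotations are unique by construction; duplicates only occur in the matrix
        if shrna not in screen.annotations.index:
            raise ValueError(f"duplicated shRNA {shrna!r} has no annotation row")
    collapsed = mat.groupby(level=0, sort=False).mean()
    collapsed = collapsed.loc[[s for s in dict.fromkeys(mat.index)]]
    out = ScreenDataset(annotations=screen.annotations.copy(), logfc=collapsed)
    return out, n_collapsed


def run_preprocess(
    screen: ScreenDataset,
    mutations: MutationTable,
    cn: CopyNumberTable,
    min_abundance: float = DEFAULT_MIN_ABUNDANCE,
) -> tuple[ScreenDataset, PreprocessReport]:
    """Apply the four preprocessing steps in order and account for every removal."""
    kept, removed = remove_hypermutated_cell_lines(mutations, screen.cell_lines)
    screen = screen.subset_cell_lines(kept)

    n_genes_before = len(set(screen.annotations["gene"]))
    screen = filter_genes_without_molecular_data(screen, mutations, cn)
    n_genes_removed = n_genes_before - len(set(screen.annotations["gene"]))

    n_shrnas_before = len(screen.annotations)
    screen = filter_shrnas_by_abundance(screen, min_abundance)
    n_shrnas_removed = n_shrnas_before - len(screen.annotations)

    screen, n_collapsed = collapse_duplicate_measurements(screen)

    report = PreprocessReport(
        n_cell_lines_removed_hypermutated=len(removed),
        n_genes_removed_no_molecular_data=n_genes_removed,
        n_shrnas_removed_abundance=n_shrnas_removed,
        n_duplicates_collapsed=n_collapsed,
        n_shrnas_final=len(screen.logfc),
        n_genes_final=len(set(screen.annotations.loc[screen.logfc.index.unique(), "gene"])) if len(screen.logfc) else 0,
        n_cell_lines_final=len(screen.cell_lines),
    )
    return screen, report
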