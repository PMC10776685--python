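"""Domain types and readers/writers for the tabular inputs and outputs.

All on-disk formats are plain TSV.  Missing values are written as ``NA``
and read back from either an empty field or ``NA``.  Identifiers (shRNA
IDs, gene symbols, cell-line names) are opaque strings; no gene-symbol
normalization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ScreenDataset",
    "SeedStabilityTable",
    "MutationTable",
    "CopyNumberTable",
    "CancerTypeMap",
    "GeneTestResult",
    "LoadError",
    "load_screen_dataset",
    "load_alteration_inputs",
    "load_seed_stability",
    "write_screen_dataset",
    "write_alteration_inputs",
    "write_seed_stability",
    "write_results_table",
    "read_results_table",
]

_NA_VALUES = ["", "NA"]
_SEED_ALPHABET = set("ACGT")

RESULT_COLUMNS = [
    "gene",
    "alteration_class",
    "n_mutant",
    "n_wildtype",
    "n_shrnas_used",
    "beta",
    "se_beta",
    "theta",
    "sigma2",
    "p_value",
    "q_value",
    "converged",
    "skipped_reason",
]


class LoadError(ValueError):
    """Raised when an input table violates its format contract."""


def _normalize_seed(seed):
    """Uppercase a seed and unify the RNA/DNA alphabet to T."""
    if seed is None or (isinstance(seed, float) and np.isnan(seed)):
        return None
    return str(seed).strip().upper().replace("U", "T")


@dataclass
class ScreenDataset:
    """shRNA annotations plus the logFC matrix over cell lines.

    ``annotations`` is indexed by shRNA ID with columns
    ``gene``, ``pool``, ``seed``, ``initial_abundance``;
    ``logfc`` is shRNA x cell line with NaN for missing readouts.
    ``logfc`` may carry duplicated shRNA rows straight after loading;
    preprocessing collapses them.
    """

    annotations: pd.DataFrame
    logfc: pd.DataFrame

    def __post_init__(self):
        self.validate()

    # -- dict-like accessors used throughout the pipeline ------------
    @property
    def shrna_ids(self) -> list[str]:
        return list(self.annotations.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.logfc.columns)

    @property
    def gene_of(self) -> pd.Series:
        return self.annotations["gene"]

    @property
    def pool_of(self) -> pd.Series:
        return self.annotations["pool"]

    @property
    def seed_of(self) -> pd.Series:
        return self.annotations["seed"]

    @property
    def initial_abundance_of(self) -> pd.Series:
        return self.annotations["initial_abundance"]

    @property
    def genes(self) -> list[str]:
        return sorted(self.annotations["gene"].unique())

    def validate(self) -> None:
        ann = self.annotations
        required = {"gene", "pool", "seed", "initial_abundance"}
        missing_cols = required - set(ann.columns)
        if missing_cols:
            raise LoadError(f"annotation table lacks columns {sorted(missing_cols)}")
        if ann.index.has_duplicates:
            dup = ann.index[ann.index.duplicated()][0]
            raise LoadError(f"duplicate shRNA id in annotations: {dup!r}")
        if self.logfc.columns.has_duplicates:
            dup = self.logfc.columns[self.logfc.columns.duplicated()][0]
            raise LoadError(f"duplicate cell line in logFC header: {dup!r}")
        unknown = self.logfc.index.difference(ann.index)
        if len(unknown):
            raise LoadError(f"shRNA {unknown[0]!r} in logFC matrix has no annotation row")
        for shrna, seed in ann["seed"].items():
            if seed is None or (isinstance(seed, float) and np.isnan(seed)):
                continue
            if len(seed) != 7 or not set(seed) <= _SEED_ALPHABET:
                raise LoadError(f"shRNA {shrna!r} has malformed 7-mer seed {seed!r}")

    def subset_shrnas(self, keep: Iterable[str]) -> "ScreenDataset":
        keep = [s for s in self.shrna_ids if s in set(keep)]
        return ScreenDataset(
            annotations=self.annotations.loc[keep].copy(),
            logfc=self.logfc.loc[self.logfc.index.isin(keep)].copy(),
        )

    def subset_cell_lines(self, keep: Iterable[str]) -> "ScreenDataset":
        keep = [c for c in self.cell_lines if c in set(keep)]
        return ScreenDataset(
            annotations=self.annotations.copy(),
            logfc=self.logfc[keep].copy(),
        )

    def __eq__(self, other):
        if not isinstance(other, ScreenDataset):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.annotations, other.annotations)
            pd.testing.assert_frame_equal(self.logfc, other.logfc)
        except AssertionError:
            return False
        return True


@dataclass
class SeedStabilityTable:
    """Map 7-mer seed -> thermodynamic pairing stability (energy units as supplied)."""

    stability_of: pd.Series

    def __post_init__(self):
        idx = self.stability_of.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise LoadError(f"duplicate seed in stability table: {dup!r}")
        if len(idx) > 4**7:
            raise LoadError("stability table has more entries than distinct 7-mers")
        for seed in idx:
            if len(seed) != 7 or not set(seed) <= _SEED_ALPHABET:
                raise LoadError(f"malformed seed in stability table: {seed!r}")

    @property
    def mean_stability(self) -> float:
        return float(self.stability_of.mean())

    def __eq__(self, other):
        if not isinstance(other, SeedStabilityTable):
            return NotImplemented
        return self.stability_of.equals(other.stability_of)


@dataclass
class MutationTable:
    """MAF-like minimal mutation records: (gene, cell_line, variant_classification)."""

    records: pd.DataFrame

    def __post_init__(self):
        required = {"gene", "cell_line", "variant_classification"}
        if not required <= set(self.records.columns):
            raise LoadError(f"mutation table lacks columns {sorted(required - set(self.records.columns))}")
        self.records = self.records.reset_index(drop=True)

    @property
    def gene_universe(self) -> set[str]:
        return set(self.records["gene"])

    def __len__(self):
        return len(self.records)

    def __eq__(self, other):
        if not isinstance(other, MutationTable):
            return NotImplemented
        return self.records.equals(other.records)


@dataclass
class CopyNumberTable:
    """GISTIC2 integer calls per (gene, cell line); values restricted to -2..2."""

    gistic: pd.DataFrame  # columns gene, cell_line, gistic

    def __post_init__(self):
        required = {"gene", "cell_line", "gistic"}
        if not required <= set(self.gistic.columns):
            raise LoadError(f"copy-number table lacks columns {sorted(required - set(self.gistic.columns))}")
        vals = self.gistic["gistic"]
        bad = ~vals.isin([-2, -1, 0, 1, 2])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise LoadError(f"GISTIC value {vals.iloc[row]!r} outside -2..2 at row {row}")
        dup = self.gistic.duplicated(subset=["gene", "cell_line"], keep=False)
        if dup.any():
            grp = self.gistic[dup].groupby(["gene", "cell_line"])["gistic"].nunique()
            conflicting = grp[grp > 1]
            if len(conflicting):
                g, c = conflicting.index[0]
                raise LoadError(f"conflicting GISTIC calls for gene {g!r} in cell line {c!r}")
            self.gistic = self.gistic.drop_duplicates(subset=["gene", "cell_line"])
        self.gistic = self.gistic.reset_index(drop=True)

    @property
    def gene_universe(self) -> set[str]:
        return set(self.gistic["gene"])

    def lookup(self) -> pd.Series:
        return self.gistic.set_index(["gene", "cell_line"])["gistic"]

    def __eq__(self, other):
        if not isinstance(other, CopyNumberTable):
            return NotImplemented
        return self.gistic.equals(other.gistic)


@dataclass
class CancerTypeMap:
    """Cell line -> cancer-type label (at most one label per line)."""

    type_of: pd.Series

    def __post_init__(self):
        if self.type_of.index.has_duplicates:
            dup = self.type_of.index[self.type_of.index.duplicated()][0]
            raise LoadError(f"cell line {dup!r} has more than one cancer-type label")

    def __eq__(self, other):
        if not isinstance(other, CancerTypeMap):
            return NotImplemented
        return self.type_of.equals(other.type_of)


@dataclass
class GeneTestResult:
    """One tested (gene, alteration class): effect estimate and inference."""

    gene: str
    alteration_class: str
    n_mutant: int = 0
    n_wildtype: int = 0
    n_shrnas_used: int = 0
    beta: float = np.nan
    se_beta: float = np.nan
    theta: float = np.nan
    sigma2: float = np.nan
    p_value: float = np.nan
    q_value: float = np.nan
    converged: bool = False
    skipped_reason: str = ""
    cancer_type: str = field(default="", compare=False)

    @property
    def tested(self) -> bool:
        return self.skipped_reason == ""

    @property
    def significant(self) -> bool:
        return self.tested and np.isfinite(self.q_value) and self.q_value < 0.05


# ---------------------------------------------------------------- readers


def load_screen_dataset(path_annotations, path_logfc) -> ScreenDataset:
    """Load annotations + logFC TSVs into a validated :class:`ScreenDataset`.

    Duplicate shRNA rows in the logFC table are preserved (collapsed later by
    preprocessing); duplicate annotation rows are an error.
    """
    ann = pd.read_csv(path_annotations, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    required = ["shrna_id", "gene", "pool", "seed", "initial_abundance"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise LoadError(f"annotation file {path_annotations} lacks columns {missing}")
    abund = pd.to_numeric(ann["initial_abundance"], errors="coerce")
    bad = abund.isna() & ann["initial_abundance"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise LoadError(
            f"non-numeric initial_abundance {ann['initial_abundance'].iloc[row]!r} at row {row} of {path_annotations}"
        )
    ann = ann.assign(
        initial_abundance=abund.astype(float),
        seed=[_normalize_seed(s) for s in ann["seed"]],
    )
    ann = ann[["shrna_id", "gene", "pool", "seed", "initial_abundance"]]
    if ann["shrna_id"].duplicated().any():
        # duplicated annotation rows are tolerated only when they agree
        key_cols = ["gene", "pool", "seed"]
        for shrna, grp in ann[ann["shrna_id"].duplicated(keep=False)].groupby("shrna_id"):
            if grp[key_cols].drop_duplicates().shape[0] > 1:
                raise LoadError(f"conflicting annotations across duplicate rows for shRNA {shrna!r}")
        # replicated library measurements: retain the average abundance
        mean_ab = ann.groupby("shrna_id", sort=False)["initial_abundance"].mean()
        ann = ann.drop_duplicates(subset=["shrna_id"], keep="first")
        ann = ann.assign(initial_abundance=mean_ab.loc[ann["shrna_id"]].to_numpy())
    ann = ann.set_index("shrna_id")

    mat = pd.read_csv(path_logfc, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if mat.columns[0] != "shrna_id":
        raise LoadError(f"logFC file {path_logfc}: first column must be 'shrna_id', got {mat.columns[0]!r}")
    mat = mat.set_index("shrna_id")
    for col in mat.columns:
        mat[col] = pd.to_numeric(mat[col], errors="raise")
    mat = mat.astype(float)
    return ScreenDataset(annotations=ann, logfc=mat)


def load_seed_stability(path) -> SeedStabilityTable:
    tab = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if not {"seed", "stability"} <= set(tab.columns):
        raise LoadError(f"stability file {path} must have columns [seed, stability]")
    seeds = [_normalize_seed(s) for s in tab["seed"]]
    return SeedStabilityTable(stability_of=pd.Series(tab["stability"].astype(float).to_numpy(), index=pd.Index(seeds, name="seed"), name="stability"))


def load_alteration_inputs(path_mut, path_cn, path_types):
    """Load mutation, GISTIC copy-number and cancer-type TSVs."""
    mut = pd.read_csv(path_mut, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if not {"gene", "cell_line", "variant_classification"} <= set(mut.columns):
        raise LoadError(f"mutation file {path_mut} must have columns [gene, cell_line, variant_classification]")
    mutations = MutationTable(records=mut[["gene", "cell_line", "variant_classification"]].astype(str))

    cn = pd.read_csv(path_cn, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if not {"gene", "cell_line", "gistic"} <= set(cn.columns):
        raise LoadError(f"copy-number file {path_cn} must have columns [gene, cell_line, gistic]")
    gvals = pd.to_numeric(cn["gistic"], errors="coerce")
    if gvals.isna().any():
        row = int(np.flatnonzero(gvals.isna().to_numpy())[0])
        raise LoadError(f"non-numeric GISTIC value at row {row} of {path_cn}")
    copynum = CopyNumberTable(gistic=cn.assign(gistic=gvals.astype(int))[["gene", "cell_line", "gistic"]])

    ty = pd.read_csv(path_types, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if not {"cell_line", "cancer_type"} <= set(ty.columns):
        raise LoadError(f"cancer-type file {path_types} must have columns [cell_line, cancer_type]")
    types = CancerTypeMap(type_of=ty.set_index("cell_line")["cancer_type"].astype(str))
    return mutations, copynum, types


# ---------------------------------------------------------------- writers


def write_screen_dataset(screen: ScreenDataset, path_annotations, path_logfc) -> None:
    ann = screen.annotations.reset_index()
    if "shrna_id" not in ann.columns:
        ann = ann.rename(columns={ann.columns[0]: "shrna_id"})
    ann.to_csv(path_annotations, sep="\t", index=False, na_rep="NA")
    screen.logfc.rename_axis("shrna_id").reset_index().to_csv(path_logfc, sep="\t", index=False, na_rep="NA")


def write_seed_stability(table: SeedStabilityTable, path) -> None:
    table.stability_of.rename_axis("seed").reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


def write_alteration_inputs(mutations: MutationTable, cn: CopyNumberTable, types: CancerTypeMap, path_mut, path_cn, path_types) -> None:
    mutations.records.to_csv(path_mut, sep="\t", index=False, na_rep="NA")
    cn.gistic.to_csv(path_cn, sep="\t", index=False, na_rep="NA")
    types.type_of.rename("cancer_type").rename_axis("cell_line").reset_index().to_csv(path_types, sep="\t", index=False, na_rep="NA")


def write_results_table(results: list[GeneTestResult], path) -> None:
    """Write results as TSV, one row per (gene, alteration class), sorted."""
    rows = []
    for r in sorted(results, key=lambda r: (r.gene, r.alteration_class)):
        rows.append({c: getattr(r, c) for c in RESULT_COLUMNS})
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_results_table(path) -> list[GeneTestResult]:
    frame = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    out = []
    for _, row in frame.iterrows():
        out.append(
            GeneTestResult(
                gene=str(row["gene"]),
                alteration_class=str(row["alteration_class"]),
                n_mutant=int(row["n_mutant"]),
                n_wildtype=int(row["n_wildtype"]),
                n_shrnas_used=int(row["n_shrnas_used"]),
                beta=float(row["beta"]) if pd.notna(row["beta"]) else np.nan,
                se_beta=float(row["se_beta"]) if pd.notna(row["se_beta"]) else np.nan,
                theta=float(row["theta"]) if pd.notna(row["theta"]) else np.nan,
                sigma2=float(row["sigma2"]) if pd.notna(row["sigma2"]) else np.nan,
                p_value=float(row["p_value"]) if pd.notna(row["p_value"]) else np.nan,
                q_value=float(row["q_value"]) if pd.notna(row["q_value"]) else np.nan,
                converged=bool(row["converged"]),
                skipped_reason="" if pd.isna(row["skipped_reason"]) else str(row["skipped_reason"]),
            )
        )
    return out
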