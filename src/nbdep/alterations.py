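"""Classify (gene, cell line) pairs into alteration classes and build test groups.

Three alteration classes are tested for self-dependency: missense mutation,
non-missense mutation (truncating / structural coding changes), and
copy-number amplification (GISTIC2 call of 2).  Deep deletion (GISTIC2 -2)
is never tested but removes a line from wild-type status.  A gene is
wild-type in a cell line iff it carries none of the four.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .dataio import CopyNumberTable, MutationTable

__all__ = [
    "AlterationCalls",
    "TestGroups",
    "TESTED_CLASSES",
    "DEFAULT_CLASS_ALIASES",
    "classify_gene_cell_alterations",
    "build_test_groups",
]

logger = logging.getLogger(__name__)

TESTED_CLASSES = ("missense", "non_missense", "amplification")
FLAGS = ("missense", "non_missense", "amplification", "deep_deletion")

_NON_MISSENSE_CANONICAL = {
    "start codon deletion",
    "stop codon deletion",
    "start codon insertion",
    "stop codon insertion",
    "frameshift deletion",
    "frameshift insertion",
    "in-frame deletion",
    "in-frame insertion",
    "nonsense mutation",
    "splice site",
}

# MAF dialects differ; map normalized DepMap/GDC-style strings onto the
# canonical categories. Users can extend via the classify() alias argument.
DEFAULT_CLASS_ALIASES = {
    "frame shift del": "frameshift deletion",
    "frame shift ins": "frameshift insertion",
    "in frame del": "in-frame deletion",
    "in frame ins": "in-frame insertion",
    "in frame deletion": "in-frame deletion",
    "in frame insertion": "in-frame insertion",
    "nonsense": "nonsense mutation",
    "splice site snp": "splice site",
    "splice site del": "splice site",
    "splice site ins": "splice site",
    "start codon del": "start codon deletion",
    "start codon ins": "start codon insertion",
    "stop codon del": "stop codon deletion",
    "stop codon ins": "stop codon insertion",
    "missense": "missense mutation",
}


def _normalize_classification(s: str) -> str:
    return str(s).strip().lower().replace("_", " ").replace("-", " ").replace("in frame", "in-frame")


@dataclass
class AlterationCalls:
    """Multi-hot alteration flags per (gene, cell line).

    ``flags`` is a boolean DataFrame indexed by (gene, cell_line) with one
    column per flag.  Pairs absent from the index carry no flag, hence are
    wild-type.  ``unrecognized`` tallies classification strings that mapped
    to no category.
    """

    flags: pd.DataFrame
    unrecognized: dict[str, int] = field(default_factory=dict)

    def flag(self, gene: str, cell_line: str, cls: str) -> bool:
        try:
            return bool(self.flags.loc[(gene, cell_line), cls])
        except KeyError:
            return False

    def is_wild_type(self, gene: str, cell_line: str) -> bool:
        try:
            row = self.flags.loc[(gene, cell_line)]
        except KeyError:
            return True
        return not bool(row.any())

    def genes(self) -> list[str]:
        return sorted(self.flags.index.get_level_values("gene").unique())


@dataclass
class TestGroups:
    """Mutant / strictly-wild-type / excluded cell lines for one (gene, class)."""

    gene: str
    alteration_class: str
    mutant: list[str]
    control: list[str]
    excluded: list[str]

    @property
    def testable(self) -> bool:
        return len(self.mutant) >= 2 and len(self.control) >= 2


def classify_gene_cell_alterations(
    mutations: MutationTable,
    cn: CopyNumberTable,
    aliases: dict[str, str] | None = None,
) -> AlterationCalls:
    """Derive the four alteration flags for every profiled (gene, cell line).

    Classification strings are matched case-insensitively with underscores,
    hyphens and spacing unified; unrecognized strings create no flag and are
    tallied.  The result is a pure function of the two tables (row order
    never matters).
    """
    alias = {_normalize_classification(k): v for k, v in DEFAULT_CLASS_ALIASES.items()}
    if aliases:
        alias.update({_normalize_classification(k): _normalize_classification(v) for k, v in aliases.items()})

    rows: dict[tuple[str, str], dict[str, bool]] = {}
    unrecognized: dict[str, int] = {}

    def cell(gene, line):
        return rows.setdefault((gene, line), {f: False for f in FLAGS})

    for gene, line, raw in mutations.records[["gene", "cell_line", "variant_classification"]].itertuples(index=False):
        norm = _normalize_classification(raw)
        norm = alias.get(norm, norm)
        if norm == "missense mutation":
            cell(gene, line)["missense"] = True
        elif norm in _NON_MISSENSE_CANONICAL:
            cell(gene, line)["non_missense"] = True
        else:
            unrecognized[str(raw)] = unrecognized.get(str(raw), 0) + 1

    for gene, line, g in cn.gistic[["gene", "cell_line", "gistic"]].itertuples(index=False):
        if g == 2:
            cell(gene, line)["amplification"] = True
        elif g == -2:
            cell(gene, line)["deep_deletion"] = True

    if unrecognized:
        logger.info("ignored %d unrecognized classification strings: %s", sum(unrecognized.values()), unrecognized)

    if rows:
        idx = pd.MultiIndex.from_tuples(sorted(rows), names=["gene", "cell_line"])
        flags = pd.DataFrame([rows[k] for k in sorted(rows)], index=idx, columns=list(FLAGS))
    else:
        idx = pd.MultiIndex.from_arrays([[], []], names=["gene", "cell_line"])
        flags = pd.DataFrame(columns=list(FLAGS), index=idx, dtype=bool)
    return AlterationCalls(flags=flags, unrecognized=unrecognized)


def build_test_groups(
    calls: AlterationCalls,
    gene: str,
    cls: str,
    cell_lines: list[str],
) -> TestGroups:
    """Partition screened cell lines into mutant / control / excluded for one class.

    mutant = lines where the class flag is set; control = strictly wild-type
    lines; lines carrying only other alteration classes are excluded from
    both.  Deep deletion is only ever an exclusion criterion.
    """
    if cls not in TESTED_CLASSES:
        raise ValueError(f"alteration class must be one of {TESTED_CLASSES}, got {cls!r}")
    mutant, control, excluded = [], [], []
    for line in cell_lines:
        if calls.flag(gene, line, cls):
            mutant.append(line)
        elif calls.is_wild_type(gene, line):
            control.append(line)
        else:
            excluded.append(line)
    return TestGroups(gene=gene, alteration_class=cls, mutant=mutant, control=control, excluded=excluded)
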