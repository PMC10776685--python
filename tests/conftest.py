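import numpy as np
import pandas as pd
import pytest

from nbdep.dataio import ScreenDataset, SeedStabilityTable
from nbdep.preprocess import run_preprocess
from nbdep.screen import AnalysisBundle
from nbdep.simulate import SimConfig, generate_synthetic_screen


def make_screen(logfc: pd.DataFrame, genes=None, pools=None, seeds=None, abundance=None) -> ScreenDataset:
    """Assemble a small ScreenDataset around a hand-written logFC frame."""
    ids = list(dict.fromkeys(logfc.index))
    n = len(ids)
    base_seeds = ["ACGTACG", "CCGTACG", "GCGTACG", "TCGTACG", "AAGTACG", "CAGTACG",
                  "GAGTACG", "TAGTACG", "ACTTACG", "CCTTACG", "GCTTACG", "TCTTACG"]
    ann = pd.DataFrame(
        {
            "gene": genes if genes is not None else ["g1"] * n,
            "pool": pools if pools is not None else ["poolA"] * n,
            "seed": seeds if seeds is not None else base_seeds[:n],
            "initial_abundance": abundance if abundance is not None else [100.0] * n,
        },
        index=pd.Index(ids, name="shrna_id"),
    )
    return ScreenDataset(annotations=ann, logfc=logfc)


def flat_stability(screen: ScreenDataset, value: float = 0.0) -> SeedStabilityTable:
    seeds = sorted({s for s in screen.seed_of if s is not None})
    return SeedStabilityTable(
        stability_of=pd.Series([value] * len(seeds), index=pd.Index(seeds, name="seed"), name="stability")
    )


@pytest.fixture(scope="session")
def synthetic_screen():
    """The seeded desk-scale screen with injected filter violations and drivers."""
    cfg = SimConfig(seed=11, n_hypermutated=1, n_duplicate_shrnas=3)
    return generate_synthetic_screen(cfg)


@pytest.fixture(scope="session")
def synthetic_bundle(synthetic_screen):
    syn = synthetic_screen
    screen, report = run_preprocess(syn.screen, syn.mutations, syn.copynumber)
    bundle = AnalysisBundle.from_inputs(screen, syn.stability, syn.mutations, syn.copynumber)
    return syn, screen, report, bundle


@pytest.fixture(scope="session")
def null_bundle():
    """A screen with no injected drivers and paper-style mutant group sizes."""
    cfg = SimConfig(seed=202, n_genes=60, n_cell_lines=30, driver_fraction=0.0, max_null_mutants=15)
    syn = generate_synthetic_screen(cfg)
    screen, _ = run_preprocess(syn.screen, syn.mutations, syn.copynumber)
    bundle = AnalysisBundle.from_inputs(screen, syn.stability, syn.mutations, syn.copynumber)
    return syn, bundle


@pytest.fixture(scope="session")
def power_bundle():
    """A screen with strongly depleted drivers and enough lines for power grids."""
    cfg = SimConfig(seed=303, n_genes=60, n_cell_lines=60, driver_fraction=0.05, mutant_fraction=0.2)
    syn = generate_synthetic_screen(cfg)
    screen, _ = run_preprocess(syn.screen, syn.mutations, syn.copynumber)
    bundle = AnalysisBundle.from_inputs(screen, syn.stability, syn.mutations, syn.copynumber)
    return syn, bundle
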