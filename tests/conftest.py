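"""Shared fixtures: tiny hand-built libraries/tables and simulated screens."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from isletscreen import (
    GuideCountTable,
    LibraryDesign,
    SimulationConfig,
    simulate_screen,
)


def make_library(n_genes=2, guides_per_gene=2, n_nt=3, n_intergenic=1) -> LibraryDesign:
    """Deterministic miniature library with readable ids and spacers."""
    rng = np.random.default_rng(12345)
    bases = np.array(list("ACGT"))
    n = n_genes * guides_per_gene + n_nt + n_intergenic
    spacers = ["".join(bases[rng.integers(0, 4, 20)]) for _ in range(n)]
    assert len(set(spacers)) == n
    rows = []
    k = 0
    for g in range(n_genes):
        for j in range(guides_per_gene):
            rows.append((f"GENE{g + 1}_sg{j + 1}", spacers[k], f"GENE{g + 1}", "targeting"))
            k += 1
    for i in range(n_nt):
        rows.append((f"NT_{i + 1}", spacers[k], pd.NA, "non_targeting"))
        k += 1
    for i in range(n_intergenic):
        rows.append((f"IG_{i + 1}", spacers[k], pd.NA, "intergenic"))
        k += 1
    return LibraryDesign(
        pd.DataFrame(rows, columns=["guide_id", "spacer", "gene", "class"])
    )


def make_table(counts: dict[str, list[int]], guide_ids: list[str]) -> GuideCountTable:
    """Count table from a dict sample_id -> column; condition from the name."""
    samples = pd.DataFrame(
        {
            "sample_id": list(counts),
            "condition": ["hPi" if s.startswith("hPi") else "control" for s in counts],
            "mouse_id": [f"m{i + 1}" for i in range(len(counts))],
        }
    )
    return GuideCountTable(pd.DataFrame(counts, index=pd.Index(guide_ids)), samples)


@pytest.fixture
def tiny_library() -> LibraryDesign:
    return make_library()


@pytest.fixture(scope="session")
def null_screen():
    """A neutral (theta = 1) simulated screen at reduced scale.

    200 genes x 4 guides + 60 NT + 20 intergenic, 6 mice per arm, with the
    default global rejection r = 0.5 acting in the hPi arm only.
    """
    config = SimulationConfig(
        n_genes=200,
        n_nt=60,
        n_intergenic=20,
        n_cells=200_000,
        bottleneck=80_000,
        depth=500_000.0,
        seed=20_240_101,
    )
    return simulate_screen(config)
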