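import numpy as np
import pytest

import pathperm as pp


@pytest.fixture(scope="session")
def small_panel() -> pp.ReferencePanel:
    """A modest multi-chromosome panel with an X chromosome."""
    cfg = pp.PanelConfig(
        n_haplotypes=600,
        n_chromosomes=8,
        blocks_per_chromosome=12,
        block_size_range=(2, 6),
        singleton_fraction=0.5,
        within_block_r2=0.9,
        seed=101,
    )
    return pp.generate_reference_panel(cfg)


@pytest.fixture(scope="session")
def small_blocks(small_panel):
    return pp.panel_blocks(small_panel, threshold=0.8)


@pytest.fixture(scope="session")
def small_world(small_panel, small_blocks):
    """Panel + annotations + pathway + two null cohorts, analysis-ready."""
    annotations, pathway = pp.generate_annotations(
        small_panel,
        pathway_spec=pp.PathwaySpec(
            name="toy_pathway", n_genes=6, n_x_genes=1,
            snps_per_gene=(4, 8), flank=10_000,
        ),
        seed=202,
    )
    cohorts = [
        pp.generate_cohort(
            small_panel,
            pp.CohortConfig(name=f"study{i}", n_cases=150, n_controls=150, seed=300 + i),
        )
        for i in range(2)
    ]
    ctx = pp.AnalysisContext(
        panel=small_panel, blocks=small_blocks,
        annotations=annotations, pathway=pathway,
    )
    return ctx, cohorts
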