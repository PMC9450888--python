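import numpy as np
import pytest

from exmfoci.simulate import SimulationConfig, generate_nucleus_scene, generate_structure_scene

#: Detection settings matched to the simulator's post-expansion PSF
#: (axial sigma 300 nm, lateral 100 nm; LoG blob radius = sigma * sqrt(3)).
DETECT_RADIUS_NM = (520.0, 180.0, 180.0)
QUALITY_THRESHOLD = 25.0
LINK_RADIUS_NM = 1500.0
SEARCH_RADIUS_NM = 2000.0


@pytest.fixture(scope="session")
def nucleus_scene():
    """One default mid-S-phase nucleus, pre and post ~4x expansion."""
    cfg = SimulationConfig(seed=3)
    pre, post, truth = generate_nucleus_scene(cfg)
    return cfg, pre, post, truth


@pytest.fixture(scope="session")
def structure_scene():
    """Flat post-expansion scene with 5 structures of each class (1-5)."""
    grid, truth = generate_structure_scene({c: 5 for c in range(1, 6)}, seed=1)
    return grid, truth


def detect_and_classify(grid, site="brca1", partners=("53bp1",), rules=None):
    """Shared helper: full detection -> clustering -> assembly -> labels."""
    from exmfoci.spots import (
        assemble_structures,
        classify_structure,
        cluster_site_spots,
        detect_spots,
        two_channel_rules,
    )

    rules = rules or two_channel_rules(site, partners[0])
    dets = {
        ch: detect_spots(grid.channel(ch), DETECT_RADIUS_NM, QUALITY_THRESHOLD)
        for ch in (site, *partners)
    }
    site_pos = dets[site][["z", "y", "x"]].to_numpy()
    labels, cores = cluster_site_spots(site_pos, LINK_RADIUS_NM)
    structures = assemble_structures(
        site_pos, labels, cores,
        {ch: dets[ch][["z", "y", "x"]].to_numpy() for ch in partners},
        SEARCH_RADIUS_NM, site_channel=site,
    )
    for s in structures:
        classify_structure(s, rules)
    return dets, structures
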