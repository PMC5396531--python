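import numpy as np
import pytest

from connectolapse.io import Region, RegionAtlas
from connectolapse.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_atlas() -> RegionAtlas:
    """8 cortical regions (2 modules per hemisphere) + 2 striatal regions."""
    regions = []
    rid = 0
    for hemi in ("L", "R"):
        for m in (1, 2):
            for k in range(2):
                regions.append(Region(rid, f"ctx_{hemi}_m{m}_{k:02d}", hemi, "cortical"))
                rid += 1
    regions.append(Region(rid, "caudate_L", "L", "striatal"))
    regions.append(Region(rid + 1, "caudate_R", "R", "striatal"))
    return RegionAtlas(tuple(regions))


@pytest.fixture(scope="session")
def small_partition(small_atlas) -> dict[int, int]:
    """Hemisphere-pure 4-module partition matching the small atlas layout."""
    part = {}
    for r in small_atlas.regions:
        if r.tissue_class != "cortical":
            continue
        hemi, module = r.name.split("_")[1], int(r.name.split("_")[2][1:])
        part[r.region_id] = module + (0 if hemi == "L" else 2)
    return part


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small simulated longitudinal cohort shared across tests (12 + 12 subjects)."""
    cfg = SimulationConfig(
        n_controls=12, n_preHD=12, modules_per_hemisphere=2, cortical_per_module=3,
        n_striatal=2, seed=11,
    )
    dataset, truth = generate_cohort(cfg)
    return dataset, truth
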