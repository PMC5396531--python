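"""Connection subtype classification and aggregation.

Given a cortical module partition, every region pair falls into one of four
analysed subtypes — cortico-striatal (striatal x cortical), interhemispheric
(cortical modules in different hemispheres), intrahemispheric (different
modules, same hemisphere) or intramodular (same module) — or is excluded
(striatal x striatal pairs, which the analysis never examines).

Subtype-level "connections" aggregate region pairs: the strength of a
subtype connection is the sum of the weights of its member pairs.  Left and
right striatal regions are pooled into a single striatum seed set, so a
partition with m_L + m_R cortical modules yields m_L + m_R cortico-striatal
connections, m_L * m_R interhemispheric, C(m_L,2) + C(m_R,2)
intrahemispheric and m_L + m_R intramodular connections.

Also provided: the voxel-connectivity-profile (VCP) thresholding and
volume-normalization rule as a standalone numeric operation on pre-computed
per-voxel streamline fractions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from connectolapse.io import LongDataset, RegionAtlas

STRIATUM = "STRIATUM"


class SubtypeLabel(str, enum.Enum):
    CORTICO_STRIATAL = "cortico_striatal"
    INTERHEMISPHERIC = "interhemispheric"
    INTRAHEMISPHERIC = "intrahemispheric"
    INTRAMODULAR = "intramodular"
    EXCLUDED = "excluded"


#: the four analysed subtypes, ordered from longest to shortest expected path
ANALYSED_SUBTYPES = (
    SubtypeLabel.CORTICO_STRIATAL,
    SubtypeLabel.INTERHEMISPHERIC,
    SubtypeLabel.INTRAHEMISPHERIC,
    SubtypeLabel.INTRAMODULAR,
)


@dataclass(frozen=True)
class SubtypeConnection:
    """A subtype-level connection aggregating a disjoint set of region pairs."""

    subtype: SubtypeLabel
    endpoints: tuple  # (module_id|STRIATUM, module_id|STRIATUM)
    member_pairs: tuple[tuple[int, int], ...]

    @property
    def name(self) -> str:
        a, b = self.endpoints
        return f"{self.subtype.value}:{a}-{b}"


def classify_pair(
    i: int, j: int, atlas: RegionAtlas, partition: Mapping[int, int]
) -> SubtypeLabel:
    """Classify the unordered region pair (i, j); symmetric in i and j."""
    if i == j:
        raise ValueError("a region pair needs two distinct regions")
    for r in (i, j):
        if not 0 <= r < atlas.n:
            raise KeyError(f"unknown region id {r}")
    ci, cj = atlas.is_cortical(i), atlas.is_cortical(j)
    if not ci and not cj:
        return SubtypeLabel.EXCLUDED
    if ci != cj:
        return SubtypeLabel.CORTICO_STRIATAL
    mi, mj = partition[i], partition[j]
    if mi == mj:
        return SubtypeLabel.INTRAMODULAR
    if atlas.hemisphere_of(i) == atlas.hemisphere_of(j):
        return SubtypeLabel.INTRAHEMISPHERIC
    return SubtypeLabel.INTERHEMISPHERIC


def enumerate_subtype_connections(
    atlas: RegionAtlas, partition: Mapping[int, int]
) -> list[SubtypeConnection]:
    """All subtype-level connections; their member pairs partition the pair set.

    Module hemisphere is inherited from the member regions; modules are
    required to be hemisphere-pure (planted and consensus partitions are run
    per the cortical matrix, and empirically stay within hemisphere; a
    module straddling hemispheres would make "intrahemispheric" ill-posed).
    """
    module_regions: dict[int, list[int]] = {}
    for rid in atlas.cortical_ids:
        module_regions.setdefault(partition[int(rid)], []).append(int(rid))
    module_hemi: dict[int, str] = {}
    for m, rids in module_regions.items():
        hemis = {atlas.hemisphere_of(r) for r in rids}
        if len(hemis) != 1:
            raise ValueError(f"module {m} spans hemispheres {sorted(hemis)}")
        module_hemi[m] = hemis.pop()

    striatal = [int(r) for r in atlas.striatal_ids]
    connections: list[SubtypeConnection] = []

    # intramodular: one connection per module
    for m in sorted(module_regions):
        pairs = tuple(combinations(sorted(module_regions[m]), 2))
        connections.append(SubtypeConnection(SubtypeLabel.INTRAMODULAR, (m, m), pairs))

    # between-module cortical connections
    for ma, mb in combinations(sorted(module_regions), 2):
        pairs = tuple(
            (min(a, b), max(a, b))
            for a in module_regions[ma]
            for b in module_regions[mb]
        )
        label = (
            SubtypeLabel.INTRAHEMISPHERIC
            if module_hemi[ma] == module_hemi[mb]
            else SubtypeLabel.INTERHEMISPHERIC
        )
        connections.append(SubtypeConnection(label, (ma, mb), pairs))

    # cortico-striatal: striatum pooled across hemispheres, one per module
    if striatal:
        for m in sorted(module_regions):
            pairs = tuple(
                (min(s, c), max(s, c)) for s in striatal for c in module_regions[m]
            )
            connections.append(
                SubtypeConnection(SubtypeLabel.CORTICO_STRIATAL, (STRIATUM, m), pairs)
            )
    return connections


def aggregate_strength(W: np.ndarray, connection: SubtypeConnection) -> float:
    """Sum of connection weights over the member region pairs."""
    if not connection.member_pairs:
        return 0.0
    idx = np.asarray(connection.member_pairs)
    return float(W[idx[:, 0], idx[:, 1]].sum())


def subtype_strength_table(
    dataset: LongDataset, connections: Sequence[SubtypeConnection]
) -> pd.DataFrame:
    """Long table of aggregated strengths: subject, visit, connection, subtype, strength."""
    rows = []
    for obs in dataset.observations:
        for conn in connections:
            rows.append(
                {
                    "subject": obs.subject_id,
                    "visit": obs.visit,
                    "connection": conn.name,
                    "subtype": conn.subtype.value,
                    "strength": aggregate_strength(obs.W, conn),
                }
            )
    return pd.DataFrame(rows)


def count_connection_level_pairs(atlas: RegionAtlas) -> int:
    """Number of analysed region pairs: C(n_cortical, 2) + n_striatal * n_cortical."""
    n_c = len(atlas.cortical_ids)
    n_s = len(atlas.striatal_ids)
    return comb(n_c, 2) + n_s * n_c


def analysed_pairs(atlas: RegionAtlas) -> list[tuple[int, int]]:
    """All cortical-cortical and striatal-cortical pairs (i < j), atlas order."""
    cort = set(int(r) for r in atlas.cortical_ids)
    pairs = []
    for i, j in combinations(range(atlas.n), 2):
        if i in cort or j in cort:
            pairs.append((i, j))
    return pairs


def vcp_normalize(
    voxel_fractions: Iterable[float],
    vol_seed: float,
    vol_target: float,
    threshold: float = 0.01,
) -> float:
    """Voxel-connectivity-profile strength for one striatal-cortical target.

    A seed voxel counts as connected when at least ``threshold`` (default 1%)
    of its streamlines reach the target — the bound is inclusive.  The voxel
    count is normalized by the summed seed and target volumes (mm^3), giving
    a connected volume per unit ROI volume.
    """
    if vol_seed <= 0 or vol_target <= 0:
        raise ValueError("ROI volumes must be positive")
    frac = np.asarray(list(voxel_fractions), dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("voxel fractions must lie in [0, 1]")
    n_connected = int((frac >= threshold).sum())
    return n_connected / (vol_seed + vol_target)
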