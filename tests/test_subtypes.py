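"""Connection subtype classification, enumeration combinatorics and the VCP
threshold/normalization rule."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectolapse.io import Region, RegionAtlas
from connectolapse.subtypes import (
    SubtypeLabel,
    aggregate_strength,
    analysed_pairs,
    classify_pair,
    count_connection_level_pairs,
    enumerate_subtype_connections,
    vcp_normalize,
)


def _atlas(n_left, n_right, striatal=2):
    regions, rid = [], 0
    for hemi, n in (("L", n_left), ("R", n_right)):
        for k in range(n):
            regions.append(Region(rid, f"c{hemi}{k}", hemi, "cortical"))
            rid += 1
    for s in range(striatal):
        regions.append(Region(rid, f"str{s}", "L" if s % 2 == 0 else "R", "striatal"))
        rid += 1
    return RegionAtlas(tuple(regions))


def _partition(atlas, modules_left, modules_right):
    """Split each hemisphere's cortical regions into the given module count."""
    part = {}
    next_module = 1
    for hemi, m in (("L", modules_left), ("R", modules_right)):
        ids = [r.region_id for r in atlas.regions if r.hemisphere == hemi and r.tissue_class == "cortical"]
        chunks = np.array_split(ids, m)
        for chunk in chunks:
            for rid in chunk:
                part[int(rid)] = next_module
            next_module += 1
    return part


class TestClassifyPair:
    def test_striatal_cortical_is_cortico_striatal(self, small_atlas, small_partition):
        striatal = int(small_atlas.striatal_ids[0])
        for cortical in small_atlas.cortical_ids:
            assert classify_pair(striatal, int(cortical), small_atlas, small_partition) is SubtypeLabel.CORTICO_STRIATAL

    def test_same_module_is_intramodular(self, small_atlas, small_partition):
        assert classify_pair(0, 1, small_atlas, small_partition) is SubtypeLabel.INTRAMODULAR

    def test_striatal_striatal_excluded(self, small_atlas, small_partition):
        a, b = (int(x) for x in small_atlas.striatal_ids[:2])
        assert classify_pair(a, b, small_atlas, small_partition) is SubtypeLabel.EXCLUDED

    def test_hemisphere_split(self, small_atlas, small_partition):
        # regions 0 (L module 1) vs 2 (L module 2) vs 4 (R module 3)
        assert classify_pair(0, 2, small_atlas, small_partition) is SubtypeLabel.INTRAHEMISPHERIC
        assert classify_pair(0, 4, small_atlas, small_partition) is SubtypeLabel.INTERHEMISPHERIC

    @settings(max_examples=50, derandomize=True)
    @given(i=st.integers(0, 9), j=st.integers(0, 9))
    def test_symmetric_in_arguments(self, small_atlas, small_partition, i, j):
        if i == j:
            return
        assert classify_pair(i, j, small_atlas, small_partition) == classify_pair(
            j, i, small_atlas, small_partition
        )

    def test_errors(self, small_atlas, small_partition):
        with pytest.raises(ValueError):
            classify_pair(1, 1, small_atlas, small_partition)
        with pytest.raises(KeyError):
            classify_pair(0, 99, small_atlas, small_partition)


def _counts(connections):
    out = {}
    for c in connections:
        out[c.subtype] = out.get(c.subtype, 0) + 1
    return out


class TestEnumeration:
    def test_three_modules_per_hemisphere(self):
        atlas = _atlas(6, 6, striatal=4)
        part = _partition(atlas, 3, 3)
        counts = _counts(enumerate_subtype_connections(atlas, part))
        assert counts[SubtypeLabel.CORTICO_STRIATAL] == 6
        assert counts[SubtypeLabel.INTERHEMISPHERIC] == 9
        assert counts[SubtypeLabel.INTRAHEMISPHERIC] == 6
        assert counts[SubtypeLabel.INTRAMODULAR] == 6

    def test_one_module_per_hemisphere_no_striatum(self):
        atlas = _atlas(3, 3, striatal=0)
        part = _partition(atlas, 1, 1)
        counts = _counts(enumerate_subtype_connections(atlas, part))
        assert counts.get(SubtypeLabel.CORTICO_STRIATAL, 0) == 0
        assert counts[SubtypeLabel.INTERHEMISPHERIC] == 1
        assert counts.get(SubtypeLabel.INTRAHEMISPHERIC, 0) == 0
        assert counts[SubtypeLabel.INTRAMODULAR] == 2

    def test_asymmetric_module_counts_vs_pair_enumeration(self):
        atlas = _atlas(8, 8, striatal=4)
        part = _partition(atlas, 2, 4)
        connections = enumerate_subtype_connections(atlas, part)
        counts = _counts(connections)
        assert counts[SubtypeLabel.INTERHEMISPHERIC] == 8
        assert counts[SubtypeLabel.INTRAHEMISPHERIC] == 1 + 6
        assert counts[SubtypeLabel.INTRAMODULAR] == 6
        assert counts[SubtypeLabel.CORTICO_STRIATAL] == 6
        # exhaustive oracle: every analysed pair appears in exactly one connection
        seen = {}
        for conn in connections:
            for pair in conn.member_pairs:
                assert pair not in seen
                seen[pair] = conn.subtype
        expected_pairs = set(analysed_pairs(atlas))
        assert set(seen) == expected_pairs
        for (i, j), subtype in seen.items():
            assert classify_pair(i, j, atlas, part) is subtype

    def test_hemisphere_straddling_module_rejected(self, small_atlas):
        bad = {int(r): 1 for r in small_atlas.cortical_ids}  # one module spanning L and R
        with pytest.raises(ValueError, match="spans hemispheres"):
            enumerate_subtype_connections(small_atlas, bad)


class TestAggregation:
    def test_sum_of_member_weights(self, small_atlas, small_partition):
        connections = enumerate_subtype_connections(small_atlas, small_partition)
        conn = next(c for c in connections if len(c.member_pairs) >= 3)
        n = small_atlas.n
        W = np.zeros((n, n))
        for w, (i, j) in zip((1.0, 2.0, 3.0), conn.member_pairs[:3]):
            W[i, j] = W[j, i] = w
        assert aggregate_strength(W, conn) == 6.0
        assert aggregate_strength(np.zeros((n, n)), conn) == 0.0

    def test_matches_naive_double_loop_and_conserves_total(self, small_atlas, small_partition):
        rng = np.random.default_rng(5)
        n = small_atlas.n
        A = rng.random((n, n))
        W = np.triu(A, 1) + np.triu(A, 1).T
        connections = enumerate_subtype_connections(small_atlas, small_partition)
        total = 0.0
        for conn in connections:
            expected = sum(W[i][j] for (i, j) in conn.member_pairs)
            assert aggregate_strength(W, conn) == pytest.approx(expected)
            total += expected
        included = sum(W[i, j] for (i, j) in analysed_pairs(small_atlas))
        assert total == pytest.approx(included)


class TestPairCounts:
    @pytest.mark.parametrize("n_c,n_s,expected", [(70, 4, 2695), (2, 0, 1), (5, 2, 20)])
    def test_count_formula(self, n_c, n_s, expected):
        atlas = _atlas(n_c // 2, n_c - n_c // 2, striatal=n_s)
        assert count_connection_level_pairs(atlas) == expected
        # enumeration oracle
        cort = set(int(r) for r in atlas.cortical_ids)
        n_pairs = sum(
            1 for i, j in combinations(range(atlas.n), 2) if i in cort or j in cort
        )
        assert n_pairs == expected


class TestVcpNormalize:
    def test_one_percent_rule(self):
        assert vcp_normalize([0.5, 0.005, 0.02], 100, 300) == pytest.approx(2 / 400)

    def test_all_below_threshold(self):
        assert vcp_normalize([0.001, 0.009], 50, 50) == 0.0

    def test_boundary_is_inclusive(self):
        assert vcp_normalize([0.01], 100, 100) == pytest.approx(1 / 200)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="volumes"):
            vcp_normalize([0.5], 0, 100)
        with pytest.raises(ValueError, match="fractions"):
            vcp_normalize([1.5], 100, 100)
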