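"""Cubical persistence: combinatorics, known fixtures, oracle agreement."""

import numpy as np
import pytest

from fibrintda import PersistenceDiagram, build_filtration, compute_persistence

from _oracles import flood_fill_components, reduction_persistence


def diagram_equals(d: PersistenceDiagram, oracle: dict, atol=1e-12) -> bool:
    for dim in (0, 1):
        mine = np.array(sorted(map(tuple, d.points(dim)))).reshape(-1, 2)
        ref = np.array(sorted(oracle[dim])).reshape(-1, 2)
        if mine.shape != ref.shape or not np.allclose(mine, ref, atol=atol):
            return False
    return True


@pytest.mark.parametrize("h,w", [(1, 1), (2, 2), (1, 5), (3, 4), (5, 5)])
def test_filtration_cell_counts(h, w, rng):
    filt = build_filtration(rng.random((h, w)))
    assert filt.n_vertices == h * w
    assert filt.n_edges == h * (w - 1) + w * (h - 1)
    assert filt.n_squares == (h - 1) * (w - 1)


def test_filtration_sorted_and_face_consistent(rng):
    filt = build_filtration(rng.random((4, 4)))
    keys = list(zip(filt.values, filt.cell_dims))
    assert keys == sorted(keys)
    for k, faces in enumerate(filt.boundary):
        for f in faces:
            assert f < k  # faces precede cofaces
            assert filt.values[f] <= filt.values[k]


def test_square_value_is_max_of_pixels():
    img = np.array([[0.1, 0.7], [0.3, 0.2]])
    filt = build_filtration(img)
    sq = filt.values[filt.cell_dims == 2]
    assert sq.shape == (1,) and sq[0] == 0.7


def test_constant_image_single_component():
    d = compute_persistence(np.full((6, 6), 0.3))
    assert d.count(0) == 1 and d.count(1) == 0
    assert d.points(0)[0] == pytest.approx([0.3, 1.0])


def test_ring_fixture_component_and_hole(ring_image):
    d = compute_persistence(ring_image)
    assert d.count(0) == 1 and d.count(1) == 1
    assert tuple(d.points(0)[0]) == (0.2, 1.0)
    assert tuple(d.points(1)[0]) == (0.2, 0.9)


def test_inverted_orientation_matches_manual_inversion(rng):
    img = rng.random((7, 7))
    d1 = compute_persistence(img, "sublevel_inverted")
    d2 = compute_persistence(1.0 - img, "sublevel")
    assert diagram_equals(d1, {0: list(map(tuple, d2.points(0))), 1: list(map(tuple, d2.points(1)))})


def test_drop_essential_flag(rng):
    img = rng.random((6, 6))
    full = compute_persistence(img)
    no_ess = compute_persistence(img, keep_essential=False)
    assert full.count(0) == no_ess.count(0) + 1
    assert 1.0 in full.deaths and (no_ess.deaths < 1.0).all() or no_ess.count(0) == 0


def test_matches_reduction_oracle_with_ties(rng):
    """Quantized images force plateaus and ties; diagrams must still agree."""
    for _ in range(30):
        h, w = rng.integers(2, 7, 2)
        img = np.round(rng.random((h, w)) * 4) / 4.0
        d = compute_persistence(img)
        assert diagram_equals(d, reduction_persistence(img))


def test_betti0_matches_flood_fill_at_levels(rng):
    img = rng.random((12, 12))
    d = compute_persistence(img)
    pts = d.points(0)
    for t in np.linspace(0.05, 0.95, 7):
        alive = int(np.sum((pts[:, 0] <= t) & (t < pts[:, 1])))
        assert alive == flood_fill_components(img <= t, connectivity=4)


def test_zero_class_births_count_local_minimum_plateaus(rng):
    """Each 0-class is born at a distinct local-minimum plateau."""
    for _ in range(20):
        img = np.round(rng.random((6, 6)) * 3) / 3.0
        d = compute_persistence(img)
        # enumerate plateaus: connected regions of equal value whose 4-neighbors
        # are all strictly larger
        h, w = img.shape
        seen = np.zeros((h, w), bool)
        plateaus = 0
        for si in range(h):
            for sj in range(w):
                if seen[si, sj]:
                    continue
                v = img[si, sj]
                stack, region, is_min = [(si, sj)], [(si, sj)], True
                seen[si, sj] = True
                while stack:
                    i, j = stack.pop()
                    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                        ni, nj = i + di, j + dj
                        if not (0 <= ni < h and 0 <= nj < w):
                            continue
                        if img[ni, nj] == v and not seen[ni, nj]:
                            seen[ni, nj] = True
                            stack.append((ni, nj))
                            region.append((ni, nj))
                        elif img[ni, nj] < v:
                            is_min = False
                if is_min:
                    plateaus += 1
        assert d.count(0) == plateaus


def test_stability_under_bounded_perturbation(rng):
    """Bottleneck stability: amplitude-delta noise moves no matched point by
    more than delta in the infinity norm."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching

    delta = 0.05
    for _ in range(10):
        img = rng.uniform(0.2, 0.8, (6, 6))
        noisy = img + rng.uniform(-delta, delta, img.shape)
        for dim in (0, 1):
            a = compute_persistence(img).points(dim)
            b = compute_persistence(noisy).points(dim)
            na, nb = len(a), len(b)
            n = na + nb
            if n == 0:
                continue
            # feasibility of a perfect matching at cost <= delta
            rows, cols = [], []
            for i in range(na):
                for j in range(nb):
                    if np.abs(a[i] - b[j]).max() <= delta + 1e-9:
                        rows.append(i), cols.append(j)
                if (a[i, 1] - a[i, 0]) / 2 <= delta + 1e-9:
                    for j in range(nb, n):
                        rows.append(i), cols.append(j)
            for i in range(na, n):
                for j in range(nb):
                    if (b[j, 1] - b[j, 0]) / 2 <= delta + 1e-9:
                        rows.append(i), cols.append(j)
                for j in range(nb, n):
                    rows.append(i), cols.append(j)
            graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
            match = maximum_bipartite_matching(graph, perm_type="column")
            assert (match >= 0).all(), "no delta-matching found"


def test_diagram_serialization_roundtrip(rng):
    img = np.round(rng.random((8, 8)), 2)
    d = compute_persistence(img)
    import io

    buf = io.StringIO()
    d.to_csv(buf)
    buf.seek(0)
    d2 = PersistenceDiagram.from_csv(buf)
    assert diagram_equals(d2, {0: list(map(tuple, d.points(0))), 1: list(map(tuple, d.points(1)))})
    d3 = PersistenceDiagram.from_json(d.to_json())
    assert len(d3) == len(d)


def test_multiplicity_grouping_preserves_total():
    d = PersistenceDiagram([0.1, 0.1, 0.2], [0.5, 0.5, 0.6], [0, 0, 1])
    g = d.grouped()
    assert g["multiplicity"].sum() == 3
    assert g.loc[(g.birth == 0.1) & (g.dim == 0), "multiplicity"].item() == 2
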