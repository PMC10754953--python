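"""Morphology and texture features: analytic values and enumeration oracles."""

import numpy as np
import pytest

from vemseg.features import (circular_variance, fenestrated_pct, glcm_3d, haralick,
                             pattern_spectrum, per_cell_report,
                             proximity_to_membrane, solidity, sphericity,
                             sphericity_of, szm, szm_features)


def _sphere(r, pad=4):
    n = 2 * (r + pad) + 1
    g = np.mgrid[:n, :n, :n] - (r + pad)
    return (g ** 2).sum(axis=0) <= r * r


# ---------------------------------------------------------------------------
# morphology

def test_solidity_convex_and_carved_shapes():
    assert solidity(_sphere(15)) >= 0.95
    cube = np.zeros((24, 24, 24), bool)
    cube[2:22, 2:22, 2:22] = True
    carved = cube.copy()
    carved[12:22, 12:22, 12:22] = False  # corner octant removed
    assert solidity(carved) == pytest.approx(7 / 8, abs=0.03)
    # analytic hull of an L covering 3 quadrants: box minus the corner
    # triangle, V/V_hull = 3/3.5 = 6/7
    L = np.zeros((24, 24, 24), bool)
    L[2:22, 2:22, 2:12] = True
    L[2:22, 2:12, 12:22] = True
    assert solidity(L) == pytest.approx(6 / 7, abs=0.03)


def test_solidity_degenerate_raises():
    flat = np.zeros((5, 5, 5), bool)
    flat[2, 2, 1:4] = True  # collinear voxels: no 3D hull
    with pytest.raises(ValueError):
        solidity(flat)


def test_sphericity_closed_forms():
    r = 10.0
    assert sphericity(4 / 3 * np.pi * r ** 3, 4 * np.pi * r ** 2) == pytest.approx(1.0)
    a = 7.0
    assert sphericity(a ** 3, 6 * a ** 2) == pytest.approx((np.pi / 6) ** (1 / 3), rel=1e-12)
    with pytest.raises(ValueError):
        sphericity(0.0, 1.0)


def test_sphericity_of_voxelized_sphere():
    assert sphericity_of(_sphere(20)) == pytest.approx(1.0, abs=0.05)


def test_circular_variance_sphere_ellipsoid_and_scale():
    assert circular_variance(_sphere(15)) <= 0.01
    g = np.mgrid[:81, :41, :41].astype(float)
    ell = ((g[0] - 40) / 30) ** 2 + ((g[1] - 20) / 10) ** 2 + ((g[2] - 20) / 10) ** 2 <= 1
    # 3:1 ellipsoid: brute-force surface-voxel oracle, regression-locked
    from scipy import ndimage as ndi

    surf = np.argwhere(ell & ~ndi.binary_erosion(ell)).astype(float)
    c = np.argwhere(ell).mean(axis=0)
    rr = np.linalg.norm(surf - c, axis=1)
    expect = float(((rr - rr.mean()) ** 2).sum() / (len(rr) * rr.mean() ** 2))
    assert circular_variance(ell) == pytest.approx(expect, rel=1e-9)
    assert expect > 0.05
    # scale invariance from the mean-radius normalization
    assert abs(circular_variance(_sphere(10)) - circular_variance(_sphere(20))) < 0.005


def test_fenestration_analytic_and_open_dent():
    solid = _sphere(12)
    assert fenestrated_pct(solid) == 0.0
    hollowed = _sphere(20) & ~_sphere(10, pad=14)
    assert fenestrated_pct(hollowed) == pytest.approx(12.5, abs=1.0)
    dented = _sphere(12).copy()
    dented[:14, 12:20, 12:20] = False  # open channel from outside: not a cavity
    assert fenestrated_pct(dented) == 0.0


def test_proximity_limits_and_midpoint():
    nucleus = _sphere(30, pad=3)
    nol = np.zeros_like(nucleus)
    c = nucleus.shape[0] // 2
    g = np.mgrid[:nucleus.shape[0], :nucleus.shape[1], :nucleus.shape[2]]
    nol[((g - c) ** 2).sum(axis=0) <= 8 ** 2] = True
    assert proximity_to_membrane(nucleus, nol) == pytest.approx(0.0, abs=1e-9)
    # displaced so that d_cc == d_s: halfway to the surface
    off = np.zeros_like(nucleus)
    off[((g[0] - c - 15) ** 2 + (g[1] - c) ** 2 + (g[2] - c) ** 2) <= 4 ** 2] = True
    d_cc = 15.0
    surf_pts = np.argwhere(nucleus & ~_erode(nucleus)).astype(float)
    cen = np.array([c + 15.0, c, c])
    d_s = np.linalg.norm(surf_pts - cen, axis=1).min()
    expect = d_cc / (d_cc + d_s)
    assert proximity_to_membrane(nucleus, off) == pytest.approx(expect, abs=1e-6)
    assert expect == pytest.approx(0.5, abs=0.02)
    # nucleolus centered on the surface -> d_s = 0 -> 1
    edge = np.zeros_like(nucleus)
    edge[((g[0] - c - 30) ** 2 + (g[1] - c) ** 2 + (g[2] - c) ** 2) <= 3 ** 2] = True
    with pytest.warns(UserWarning):
        assert proximity_to_membrane(nucleus, edge) > 0.9


def _erode(m):
    from scipy import ndimage as ndi

    return ndi.binary_erosion(m)


# ---------------------------------------------------------------------------
# texture

def _brute_glcm(vol, mask, n_levels):
    """Oracle: explicit loop over every voxel pair at the 26 unit offsets."""
    from vemseg.features import _quantize

    q = _quantize(vol, mask, n_levels)
    counts = np.zeros((n_levels, n_levels))
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)]
    Z, H, W = vol.shape
    for z in range(Z):
        for y in range(H):
            for x in range(W):
                if q[z, y, x] == 0:
                    continue
                for dz, dy, dx in offs:
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if 0 <= zz < Z and 0 <= yy < H and 0 <= xx < W and q[zz, yy, xx] > 0:
                        counts[q[z, y, x] - 1, q[zz, yy, xx] - 1] += 1
    return counts / counts.sum()


def test_glcm_matches_pair_enumeration_oracle():
    rng = np.random.default_rng(0)
    vol = rng.integers(0, 255, size=(5, 5, 5)).astype(np.uint8)
    mask = rng.random((5, 5, 5)) > 0.2
    g = glcm_3d(vol, mask, n_levels=4)
    assert np.allclose(g.p, _brute_glcm(vol, mask, 4))
    assert g.p.sum() == pytest.approx(1.0)
    assert np.allclose(g.p, g.p.T)


def test_glcm_checkerboard_features_equal_oracle():
    g3 = np.indices((4, 4, 4)).sum(axis=0) % 2
    vol = (g3 * 255).astype(np.uint8)
    mask = np.ones((4, 4, 4), bool)
    g = glcm_3d(vol, mask, n_levels=2)
    p = _brute_glcm(vol, mask, 2)
    got = haralick(g)
    i = np.arange(1, 3)
    I, J = np.meshgrid(i, i, indexing="ij")
    assert got["homogeneity"] == pytest.approx((p / (1 + (I - J) ** 2)).sum())
    assert got["contrast"] == pytest.approx(((I - J) ** 2 * p).sum())
    mu = (i * p.sum(axis=1)).sum()
    assert got["variance"] == pytest.approx((((I - mu) ** 2) * p).sum())


def test_constant_volume_diagonal_glcm():
    vol = np.full((8, 8, 8), 7, np.uint8)
    mask = np.ones((8, 8, 8), bool)
    with pytest.warns(UserWarning):
        h = haralick(glcm_3d(vol, mask, 32))
    assert h["homogeneity"] == 1.0
    assert h["contrast"] == 0.0
    assert h["correlation"] == 0.0


def test_glcm_invariant_to_constant_intensity_shift():
    rng = np.random.default_rng(1)
    vol = rng.integers(10, 200, size=(6, 6, 6)).astype(np.int32)
    mask = np.ones(vol.shape, bool)
    a = haralick(glcm_3d(vol, mask, 8))
    b = haralick(glcm_3d(vol + 30, mask, 8))
    for k in a:
        assert a[k] == pytest.approx(b[k])


def test_szm_hand_enumerated_zones():
    vol = np.zeros((4, 4, 4), np.uint8)
    vol[0, 0, :2] = 255        # zone: level hi, size 2
    vol[2:4, 2:4, 2:4] = 255   # zone: level hi, size 8
    mask = np.ones((4, 4, 4), bool)
    m = szm(vol, mask, n_levels=2)
    # background level: one 26-connected zone of the remaining 54 voxels
    assert m.n_zones == 3
    assert m.P[0, 53] == 1     # level 1, size 54
    assert m.P[1, 1] == 1      # level 2, size 2
    assert m.P[1, 7] == 1      # level 2, size 8
    f = szm_features(m)
    assert f["zone_percentage"] == pytest.approx(3 / 64)
    # printed reading: sum P(i,j)*i^2 over the zone count
    assert f["szhge"] == pytest.approx((1 * 1 + 2 * 4) / 3)
    assert szm_features(m, variant="standard")["szhge"] == pytest.approx(
        (1 / 54 ** 2 + 4 / 2 ** 2 + 4 / 8 ** 2) / 3)


def test_szm_degenerate_cases_and_mass_conservation():
    vol = np.arange(27, dtype=np.uint8).reshape(3, 3, 3)
    mask = np.ones((3, 3, 3), bool)
    m = szm(vol, mask, n_levels=27)
    assert szm_features(m)["zone_percentage"] == pytest.approx(1.0)  # all distinct
    const = szm(np.zeros((3, 3, 3), np.uint8), mask, n_levels=8)
    assert szm_features(const)["zone_percentage"] == pytest.approx(1 / 27)
    rng = np.random.default_rng(2)
    r = rng.integers(0, 255, (6, 6, 6)).astype(np.uint8)
    m2 = szm(r, np.ones(r.shape, bool), 4)
    j = np.arange(1, m2.P.shape[1] + 1)
    assert (m2.P * j).sum() == m2.n_voxels  # Σ_i Σ_j j·P(i,j) = N


def test_pattern_spectrum_peak_at_structure_radius():
    img = np.zeros((40, 40, 40))
    g = np.mgrid[:40, :40, :40]
    for c in [(10, 10, 10), (10, 28, 28), (28, 10, 28), (28, 28, 10)]:
        img[((g[0] - c[0]) ** 2 + (g[1] - c[1]) ** 2 + (g[2] - c[2]) ** 2) <= 25] = 200.0
    ps = pattern_spectrum(img, np.ones(img.shape, bool), n_max=8)
    pos = {n: p for n, p in zip(ps.ns, ps.ps) if n >= 1}
    peak = max(pos, key=pos.get)
    assert abs(peak - 5) <= 1
    assert (ps.ps >= 0).all()
    assert sum(p for n, p in zip(ps.ns, ps.ps) if n >= 0) <= 1 + 1e-9


def test_pattern_spectrum_single_bright_voxel():
    img = np.zeros((9, 9, 9))
    img[4, 4, 4] = 10.0
    ps = pattern_spectrum(img, np.ones(img.shape, bool), n_max=3)
    mass = {n: p for n, p in zip(ps.ns, ps.ps)}
    assert mass[0] == pytest.approx(1.0)


def test_pattern_spectrum_zero_sum_raises():
    with pytest.raises(ValueError):
        pattern_spectrum(np.zeros((8, 8, 8)), np.ones((8, 8, 8), bool), n_max=2)


def test_morphology_rotation_and_translation_invariance():
    base = _sphere(9) & ~_sphere(4, pad=9)  # hollow shell, nontrivial shape
    base[3:9, 3:9, 3:9] = False
    for k in range(1, 4):
        rot = np.rot90(base, k=k, axes=(0, 1))
        assert solidity(rot) == pytest.approx(solidity(base), rel=1e-9)
        assert circular_variance(rot) == pytest.approx(circular_variance(base), rel=1e-9)
        assert fenestrated_pct(rot) == pytest.approx(fenestrated_pct(base), rel=1e-9)


# ---------------------------------------------------------------------------
# reporting

def test_per_cell_report_matches_phantom_bookkeeping(phantom_small):
    _, stack, truth = phantom_small
    df = per_cell_report(truth.cell_labels, truth.organelle_labels, stack.voxels,
                         voxel_size_nm=6.0)
    cells = df[df["class"] == "cell"].set_index("cell_id")
    for cid, want in truth.nucleoli_per_nucleus.items():
        assert cells.loc[cid, "nucleoli_count"] == want
    mito_truth = {}
    for inst, cid in truth.organelle_parent["mitochondrion"].items():
        mito_truth[cid] = mito_truth.get(cid, 0) + 1
    for cid, want in mito_truth.items():
        assert cells.loc[cid, "mitochondrion_count"] == want
    # nucleus volume fraction equals the direct voxel ratio
    for cid in cells.index:
        v_nuc = int((truth.organelle_labels["nucleus"] == cid).sum())
        v_cell = int((truth.cell_labels == cid).sum())
        assert cells.loc[cid, "nucleus_volume_fraction"] == pytest.approx(v_nuc / v_cell)


def test_per_cell_report_orphan_organelle_goes_to_background():
    cells = np.zeros((20, 20, 20), np.uint16)
    cells[4:12, 4:12, 4:12] = 1
    org = np.zeros_like(cells)
    org[15:18, 15:18, 15:18] = 1  # outside every cell
    df = per_cell_report(cells, {"mitochondrion": org}, np.zeros(cells.shape, np.uint8))
    orphan = df[(df["class"] == "mitochondrion")].iloc[0]
    assert orphan["cell_id"] == 0
    bg = df[df["class"] == "background"]
    assert len(bg) == 1 and bg.iloc[0]["mitochondrion_count"] == 1
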