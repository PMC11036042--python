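"""The index chain C, N, D, E, V, R -> ERI: hand-computed values, closed
forms, monotonicity, and equivalence with a straight-line transcription."""

import numpy as np
import pytest

from lerisk import (
    LandCoverRaster,
    build_grid,
    compute_risk_grid,
    label_patches,
    vulnerability_scores,
)
from lerisk.risk_index import (
    disturbance,
    dominance,
    fragmentation,
    isolation,
    loss,
)

from conftest import random_raster


class TestComponents:
    def test_fragmentation_quotient(self):
        assert fragmentation(2, 8.0) == pytest.approx(0.25)
        assert fragmentation(1, 6.25) == pytest.approx(0.16)
        assert fragmentation(4, 8.0) == pytest.approx(2 * fragmentation(2, 8.0))

    def test_fragmentation_zero_area_rejected(self):
        with pytest.raises(ValueError):
            fragmentation(1, 0.0)

    def test_isolation_hand_values(self):
        assert isolation(1, 6.25, 6.25) == pytest.approx(0.2)
        assert isolation(2, 8.0, 100.0) == pytest.approx((100 / 16) * np.sqrt(0.02), rel=1e-6)

    def test_isolation_monotone_in_patch_count(self):
        vals = [isolation(n, 8.0, 100.0) for n in range(1, 6)]
        assert np.all(np.diff(vals) > 0)

    def test_dominance_single_class_upper_bound(self):
        assert dominance(1, 10.0, 6.25, 1, 10.0, 6.25) == pytest.approx(1.0)

    def test_dominance_hand_value(self):
        # relative perimeter 0.3, relative count 0.2, relative area 0.1
        assert dominance(2, 3.0, 1.0, 10, 10.0, 10.0) == pytest.approx(0.175)

    def test_dominance_sums_to_one_over_classes(self):
        p = np.array([3.0, 7.0])
        n = np.array([2, 8])
        a = np.array([4.0, 6.0])
        d = dominance(n, p, a, n.sum(), p.sum(), a.sum())
        assert d.sum() == pytest.approx(1.0)

    def test_disturbance_defaults_and_degenerate_weights(self):
        assert disturbance(0.16, 0.2, 1.0) == pytest.approx(0.34)
        assert disturbance(1.0, 1.0, 1.0, (0.2, 0.5, 0.3)) == pytest.approx(1.0)
        assert disturbance(0.7, 9.0, 9.0, (1.0, 0.0, 0.0)) == pytest.approx(0.7)

    def test_disturbance_invalid_weights(self):
        with pytest.raises(ValueError):
            disturbance(1.0, 1.0, 1.0, (0.5, 0.3, 0.3))

    def test_loss_product(self):
        assert loss(0.34, 1 / 3) == pytest.approx(0.11333333, rel=1e-6)
        assert loss(7.0, 0.0) == 0.0


class TestVulnerability:
    def test_default_scores(self):
        v = vulnerability_scores()
        assert v["wasteland"] == pytest.approx(5 / 15)
        assert v["cropland"] == pytest.approx(1 / 15)
        assert v["water"] == pytest.approx(4 / 15)
        assert sum(v.values()) == pytest.approx(1.0)

    def test_ordering_follows_arid_land_sensitivity(self):
        v = vulnerability_scores()
        assert v["wasteland"] > v["water"] > v["grassland"] > v["impervious"] > v["cropland"]

    def test_duplicate_ranks_rejected(self):
        with pytest.raises(ValueError):
            vulnerability_scores({"a": 1, "b": 1, "c": 3})


def eri_transcription(raster, grid, weights=(0.5, 0.3, 0.2)):
    """Straight-line independent transcription of the index chain.

    Recomputes everything from the raw raster with plain loops: per cell,
    per class — patch count (scipy label only), area, perimeter — then
    C, N, D, E, V, R and the area-weighted ERI.
    """
    from scipy import ndimage

    v_score = {"wasteland": 5 / 15, "water": 4 / 15, "grassland": 3 / 15,
               "impervious": 2 / 15, "cropland": 1 / 15}
    a_w, b_w, c_w = weights
    px_area = raster.pixel_area_km2
    px_len = raster.cell_size / 1000.0
    out = {}
    for cid in grid.cells["cell_id"]:
        in_cell = grid.cell_index == cid
        stats = {}
        for code in np.unique(raster.values[in_cell & raster.valid]):
            mask = in_cell & (raster.values == code)
            _, n = ndimage.label(mask, structure=np.ones((3, 3)))
            area = mask.sum() * px_area
            pm = np.pad(mask, 1)
            per = ((pm[1:, :] != pm[:-1, :]).sum() + (pm[:, 1:] != pm[:, :-1]).sum()) * px_len
            stats[raster.class_map[int(code)]] = (n, area, per)
        A = sum(s[1] for s in stats.values())
        N_tot = sum(s[0] for s in stats.values())
        P_tot = sum(s[2] for s in stats.values())
        eri = 0.0
        for name, (n, area, per) in stats.items():
            C = n / area
            N = A / (2 * area) * np.sqrt(n / A)
            D = (per / P_tot + n / N_tot) / 4 + (area / A) / 2
            E = a_w * C + b_w * N + c_w * D
            eri += (area / A) * E * v_score[name]
        out[cid] = eri
    return out


class TestEri:
    def test_single_class_cell_chain(self, uniform_raster, uniform_grid):
        pt = label_patches(uniform_raster, uniform_grid)
        rg = compute_risk_grid(pt, uniform_grid)
        np.testing.assert_allclose(rg.cells["eri"], 0.34 / 3, rtol=1e-12)

    @pytest.mark.parametrize("code", [1, 2, 3, 4, 5])
    def test_single_class_closed_form(self, code):
        r = LandCoverRaster(np.full((25, 25), code, dtype=np.int32), 100.0, (0.0, 2500.0))
        grid = build_grid(r, 2500.0)
        rg = compute_risk_grid(label_patches(r, grid), grid)
        A = 6.25
        v = vulnerability_scores()[r.class_map[code]]
        expected = v * (0.5 / A + 0.3 * 0.5 / np.sqrt(A) + 0.2)
        assert rg.cells["eri"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_splitting_patch_increases_eri(self):
        one = np.full((10, 10), 5, dtype=np.int32)
        two = one.copy()
        # replace with two disjoint wasteland patches separated by grassland,
        # grass area identical in a control with contiguous wasteland
        two[:, 4:6] = 3
        ctrl = one.copy()
        ctrl[:, 8:10] = 3
        r_split = LandCoverRaster(two, 100.0, (0.0, 1000.0))
        r_ctrl = LandCoverRaster(ctrl, 100.0, (0.0, 1000.0))
        grid = build_grid(r_split, 1000.0)
        e_split = compute_risk_grid(label_patches(r_split, grid, 4), grid).cells["eri"].iloc[0]
        e_ctrl = compute_risk_grid(label_patches(r_ctrl, grid, 4), grid).cells["eri"].iloc[0]
        assert e_split > e_ctrl

    def test_linearity_in_weights(self):
        r = random_raster((20, 20), codes=(1, 3, 5), seed=5)
        grid = build_grid(r, 10_000.0)
        pt = label_patches(r, grid)
        w1, w2 = (0.5, 0.3, 0.2), (0.2, 0.3, 0.5)
        e1 = compute_risk_grid(pt, grid, weights=w1).cells["eri"].iloc[0]
        e2 = compute_risk_grid(pt, grid, weights=w2).cells["eri"].iloc[0]
        mid = tuple((a + b) / 2 for a, b in zip(w1, w2))
        e_mid = compute_risk_grid(pt, grid, weights=mid).cells["eri"].iloc[0]
        assert e_mid == pytest.approx((e1 + e2) / 2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_cells(self, seed):
        r = random_raster((20, 20), codes=(1, 2, 3, 4, 5), seed=seed)
        grid = build_grid(r, 5_000.0)  # 2x2 cells
        rg = compute_risk_grid(label_patches(r, grid), grid)
        oracle = eri_transcription(r, grid)
        for cid, eri in zip(rg.cells["cell_id"], rg.cells["eri"]):
            assert eri == pytest.approx(oracle[cid], rel=1e-12)

    def test_scale_covariance(self):
        # same lattice, all lengths doubled: C/4, N/2 per class
        r1 = random_raster((20, 20), codes=(3, 5), seed=2, cell_size=100.0)
        r2 = LandCoverRaster(r1.values.copy(), 200.0, (0.0, 4000.0))
        g1, g2 = build_grid(r1, 2000.0), build_grid(r2, 4000.0)
        rg1 = compute_risk_grid(label_patches(r1, g1), g1)
        rg2 = compute_risk_grid(label_patches(r2, g2), g2)
        m1 = rg1.per_class.set_index("class_code")
        m2 = rg2.per_class.set_index("class_code")
        np.testing.assert_allclose(m2["C_i"], m1["C_i"] / 4, rtol=1e-12)
        np.testing.assert_allclose(m2["N_i"], m1["N_i"] / 2, rtol=1e-12)
        np.testing.assert_allclose(m2["D_i"], m1["D_i"], rtol=1e-12)

    def test_stored_components_recompose_eri(self, small_scenario):
        _, raster, _ = small_scenario
        grid = build_grid(raster, 2500.0)
        rg = compute_risk_grid(label_patches(raster, grid), grid)
        recomposed = (
            rg.per_class.assign(t=rg.per_class["area_share"] * rg.per_class["R_i"])
            .groupby("cell_id")["t"]
            .sum()
        )
        cells = rg.cells.set_index("cell_id")["eri"]
        np.testing.assert_allclose(recomposed, cells.loc[recomposed.index], rtol=1e-12)
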