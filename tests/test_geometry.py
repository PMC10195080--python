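"""Sector assignment and single-frame arbor metrics against independent oracles."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull, Delaunay
from scipy.spatial.transform import Rotation

from arbordyn.errors import ArbordynError, DegeneratePointError
from arbordyn.geometry import (
    DIRECTIONS,
    DirectionFrame,
    assign_sector,
    assign_sectors,
    cable_metrics,
    canonical_frame,
    core_overlap,
    count_terminal_branches,
    exploring_volume,
    mass_center,
)

from conftest import frame_from_rows, random_tree_frame


def oracle_sector(point, dframe):
    """Independent atan2-based angular binning."""
    v = np.asarray(point, float) - dframe.origin
    theta = np.degrees(np.arctan2(v @ dframe.axis_dm, v @ dframe.axis_dl)) % 360.0
    if theta >= 315 or theta < 45:
        return "DL"
    if theta < 135:
        return "DM"
    if theta < 225:
        return "VM"
    return "VL"


class TestAssignSector:
    def test_on_axis_points(self):
        df = canonical_frame()
        assert assign_sector(df.origin + df.axis_dl, df) == "DL"
        assert assign_sector(df.origin + df.axis_dm, df) == "DM"
        assert assign_sector(df.origin - df.axis_dl, df) == "VM"
        assert assign_sector(df.origin - df.axis_dm, df) == "VL"

    def test_half_open_boundaries(self):
        df = canonical_frame()
        # 45°: u == w > 0 belongs to DM; 315°: u == -w > 0 belongs to DL
        assert assign_sector([1.0, 1.0, 0.0], df) == "DM"
        assert assign_sector([1.0, -1.0, 0.0], df) == "DL"
        assert assign_sector([-1.0, 1.0, 0.0], df) == "VM"
        assert assign_sector([-1.0, -1.0, 0.0], df) == "VL"

    def test_degenerate_point_raises(self):
        df = canonical_frame()
        with pytest.raises(DegeneratePointError):
            assign_sector(df.origin + 1e-12 * df.axis_dl, df)
        # purely anterior offsets also project onto the origin
        with pytest.raises(DegeneratePointError):
            assign_sector(df.origin + df.axis_anterior, df)

    def test_matches_angle_oracle_on_random_points(self, rng):
        df = DirectionFrame.from_vectors(
            rng.normal(size=3), rng.normal(size=3), rng.normal(size=3)
        )
        pts = df.origin + rng.normal(scale=20.0, size=(1000, 3))
        labels = assign_sectors(pts, df)
        for p, lab in zip(pts, labels):
            assert lab == oracle_sector(p, df)

    def test_rotation_consistency(self, rng):
        df = canonical_frame()
        pts = rng.normal(scale=10.0, size=(200, 3))
        before = assign_sectors(pts, df)
        rot = Rotation.random(random_state=7).as_matrix()
        df_rot = DirectionFrame(df.origin, rot @ df.axis_dl, rot @ df.axis_dm)
        after = assign_sectors(pts @ rot.T, df_rot)
        assert list(before) == list(after)

    def test_sectors_partition_the_circle(self):
        df = canonical_frame()
        thetas = np.arange(0.0, 360.0, 0.5)
        pts = np.stack(
            [np.cos(np.radians(thetas)), np.sin(np.radians(thetas)), np.zeros_like(thetas)],
            axis=1,
        )
        labels = assign_sectors(pts, df)
        # every point gets exactly one label, 90° per sector
        counts = {d: int((labels == d).sum()) for d in DIRECTIONS}
        assert sum(counts.values()) == len(thetas)
        assert all(c == 180 for c in counts.values())


class TestCableMetrics:
    def test_cylinder_closed_form(self):
        frame = frame_from_rows(
            [(1, 1, 0, 0, 0, 1.0, -1), (2, 3, 3, 0, 0, 1.0, 1)]
        )
        m = cable_metrics(frame)
        assert m.length == pytest.approx(3.0)
        assert m.volume == pytest.approx(3 * np.pi)

    def test_three_four_five_chain(self):
        frame = frame_from_rows(
            [
                (1, 1, 0, 0, 0, 1, -1),
                (2, 3, 3, 0, 0, 1, 1),
                (3, 3, 3, 4, 0, 1, 2),
            ]
        )
        assert cable_metrics(frame).length == pytest.approx(7.0)

    def test_matches_edgewise_oracle(self, rng):
        frame = random_tree_frame(rng, 40)
        m = cable_metrics(frame, exclude_axon=False)
        idx = frame.node_index()
        L = V = 0.0
        for row in frame.nodes.itertuples(index=False):
            if row.parent_id == -1:
                continue
            p = idx.loc[row.parent_id]
            ell = float(
                np.linalg.norm(
                    np.array([row.x, row.y, row.z]) - np.array([p.x, p.y, p.z])
                )
            )
            ra, rb = float(p.radius), float(row.radius)
            L += ell
            V += np.pi / 3.0 * ell * (ra * ra + ra * rb + rb * rb)
        assert m.length == pytest.approx(L)
        assert m.volume == pytest.approx(V)

    def test_additive_over_disjoint_subsets(self, rng):
        frame = random_tree_frame(rng, 30)
        edges = frame.edges()
        total = cable_metrics(frame, exclude_axon=False).length
        assert edges["length"].sum() == pytest.approx(total)


class TestExploringVolume:
    def test_unit_tetrahedron(self):
        frame = frame_from_rows(
            [
                (1, 1, 0, 0, 0, 0.1, -1),
                (2, 3, 1, 0, 0, 0.1, 1),
                (3, 3, 0, 1, 0, 0.1, 1),
                (4, 3, 0, 0, 1, 0.1, 1),
            ]
        )
        assert exploring_volume(frame, exclude_axon=False) == pytest.approx(1 / 6)

    def test_collinear_returns_zero_with_warning(self):
        frame = frame_from_rows(
            [(1, 1, 0, 0, 0, 1, -1)]
            + [(i, 3, float(i), 0, 0, 1, i - 1) for i in range(2, 7)]
        )
        with pytest.warns(UserWarning):
            assert exploring_volume(frame, exclude_axon=False) == 0.0

    def test_matches_delaunay_oracle(self, rng):
        frame = random_tree_frame(rng, 200)
        vol = exploring_volume(frame, exclude_axon=False)
        pts = frame.positions()
        tri = Delaunay(pts)
        simplices = pts[tri.simplices]
        d = simplices[:, 1:] - simplices[:, :1]
        oracle = float(np.abs(np.linalg.det(d)).sum() / 6.0)
        assert vol == pytest.approx(oracle, rel=1e-9)

    def test_monotone_under_adding_points(self, rng):
        frame = random_tree_frame(rng, 50)
        sub = frame.nodes.iloc[:20]
        small = ConvexHull(sub[["x", "y", "z"]].to_numpy()).volume
        assert exploring_volume(frame, exclude_axon=False) >= small - 1e-12


class TestTerminalCountAndMassCenter:
    def test_unbranched_cable_has_one_terminal(self):
        frame = frame_from_rows(
            [(1, 1, 0, 0, 0, 1, -1)]
            + [(i, 3, float(i), 0, 0, 1, i - 1) for i in range(2, 6)]
        )
        assert count_terminal_branches(frame) == 1

    def test_depth_two_binary_tree_has_four(self):
        rows = [(1, 1, 0, 0, 0, 1, -1), (2, 3, 1, 1, 0, 1, 1), (3, 3, 1, -1, 0, 1, 1)]
        rows += [(4, 3, 2, 2, 0, 1, 2), (5, 3, 2, 0, 0, 1, 2)]
        rows += [(6, 3, 2, -2, 0, 1, 3), (7, 3, 2, 0, 1, 1, 3)]
        assert count_terminal_branches(frame_from_rows(rows)) == 4

    def test_count_matches_degree_scan(self, rng):
        frame = random_tree_frame(rng, 60)
        deg = {int(i): 0 for i in frame.nodes["node_id"]}
        for c, p in zip(frame.nodes["node_id"], frame.nodes["parent_id"]):
            if p != -1:
                deg[int(c)] += 1
                deg[int(p)] += 1
        oracle = sum(1 for i, d in deg.items() if d == 1 and i != frame.soma_id)
        assert count_terminal_branches(frame, exclude_axon=False) == oracle

    def test_mass_center_symmetry_and_single_edge(self):
        sym = frame_from_rows(
            [
                (1, 1, -2, 0, 0, 0.5, -1),
                (2, 3, -1, 0, 0, 0.5, 1),
                (3, 1, 1, 0, 0, 0.5, 2),  # bridging edge crosses the origin
                (4, 3, 2, 0, 0, 0.5, 3),
            ]
        )
        np.testing.assert_allclose(
            mass_center(sym, exclude_axon=False), [0, 0, 0], atol=1e-12
        )
        one = frame_from_rows([(1, 1, 0, 0, 0, 0.5, -1), (2, 3, 2, 0, 0, 0.5, 1)])
        np.testing.assert_allclose(mass_center(one, exclude_axon=False), [1, 0, 0])

    def test_mass_center_matches_weighted_mean_oracle(self, rng):
        frame = random_tree_frame(rng, 40)
        got = mass_center(frame, exclude_axon=False)
        idx = frame.node_index()
        acc = np.zeros(3)
        wsum = 0.0
        for row in frame.nodes.itertuples(index=False):
            if row.parent_id == -1:
                continue
            p = idx.loc[row.parent_id]
            a = np.array([p.x, p.y, p.z])
            b = np.array([row.x, row.y, row.z])
            ell = np.linalg.norm(b - a)
            w = np.pi / 3 * ell * (p.radius**2 + p.radius * row.radius + row.radius**2)
            acc += w * (a + b) / 2
            wsum += w
        np.testing.assert_allclose(got, acc / wsum, rtol=1e-9)

    def test_mass_center_empty_subset_errors(self, rng):
        frame = random_tree_frame(rng, 10)
        with pytest.raises(ArbordynError):
            mass_center(frame, subset=[], exclude_axon=False)


class TestCoreOverlap:
    def _bar(self, x0):
        return frame_from_rows(
            [(1, 1, x0, 0, 0, 0.3, -1)]
            + [(i, 3, x0 + (i - 1) * 1.0, 0, 0, 0.3, i - 1) for i in range(2, 12)]
        )

    def test_identical_arbors_overlap_fully(self):
        assert core_overlap(self._bar(0.0), self._bar(0.0), voxel=1.0) == 1.0

    def test_disjoint_arbors_do_not_overlap(self):
        assert core_overlap(self._bar(0.0), self._bar(100.0), voxel=1.0) == 0.0

    def test_translated_copy_matches_voxel_oracle(self):
        a, b = self._bar(0.0), self._bar(5.0)
        got = core_overlap(a, b, voxel=1.0, density_quantile=0.9)

        def voxels(frame):
            # brute-force: deposit fine samples of each edge
            out = {}
            for e in frame.edges().itertuples():
                pa = np.array([e.ax, e.ay, e.az])
                pb = np.array([e.bx, e.by, e.bz])
                n = 200
                for f in (np.arange(n) + 0.5) / n:
                    key = tuple(np.floor(pa + f * (pb - pa)).astype(int))
                    out[key] = out.get(key, 0.0) + e.length / n
            total = sum(out.values())
            core, acc = set(), 0.0
            for k, v in sorted(out.items(), key=lambda kv: (-kv[1], kv[0])):
                core.add(k)
                acc += v
                if acc >= 0.9 * total - 1e-12:
                    break
            return core

        ca, cb = voxels(a), voxels(b)
        assert got == pytest.approx(len(ca & cb) / min(len(ca), len(cb)))
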