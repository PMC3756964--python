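"""CAPRI metrics, hit calling, clustering, overlap classes, landscapes."""

import numpy as np
import pytest

import replidock as rd
from replidock.metrics_analysis import OverlapRegion, _site_coords
from replidock.model_io import CentroidModel


class TestCapriMetrics:
    def test_reference_against_itself(self, toy):
        m = rd.capri_metrics(toy.model, toy.native_pose, toy.native_pose)
        assert m.I_rms == pytest.approx(0.0, abs=1e-5)
        assert m.L_rms == pytest.approx(0.0, abs=1e-9)
        assert m.f_nat == 1.0
        assert m.f_non_nat == 0.0

    def test_rigid_100A_shift(self, toy):
        shifted = toy.native_pose.translated(np.array([100.0, 0.0, 0.0]))
        m = rd.capri_metrics(toy.model, shifted, toy.native_pose)
        assert m.f_nat == 0.0
        assert m.L_rms == pytest.approx(100.0, abs=1e-6)

    def test_three_residue_toy_hand_enumeration(self):
        """3+3 residue complex with hand-countable contacts and RMSDs."""
        def res(x, z):
            p = np.array([x, 0.0, z])
            return np.tile(p, (4, 1)), p

        xs = [0.0, 6.0, 12.0]
        bb, cent = zip(*[res(x, 0.0) for x in xs], *[res(x, 4.0) for x in xs])
        model = CentroidModel(
            backbone=np.array(bb),
            centroid=np.array(cent),
            restype=np.array(["ALA"] * 6),
            partner=np.array(["A"] * 3 + ["B"] * 3),
            chain=np.array(["R"] * 3 + ["L"] * 3),
            resnum=np.array([1, 2, 3, 1, 2, 3]),
        )
        native = rd.RigidPose.identity()
        # native contacts (<5 Å): only the vertical pairs (i, i), distance 4
        decoy = native.translated(np.array([6.0, 0.0, 0.0]))
        # decoy contacts: ligand i sits over receptor i+1 -> pairs (1,0), (2,1)
        m = rd.capri_metrics(model, decoy, native)
        assert m.f_nat == pytest.approx(0.0)
        assert m.f_non_nat == pytest.approx(1.0)
        assert m.L_rms == pytest.approx(6.0, abs=1e-9)
        # all six residues are interface residues (any site < 10 Å cross);
        # independent oracle: minimize the superposed RMSD numerically over
        # a rotation vector + translation, instead of the closed-form Kabsch
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        ref_pts = _site_coords(model, native)[:, :4, :].reshape(-1, 3)
        dec_pts = _site_coords(model, decoy)[:, :4, :].reshape(-1, 3)

        def rmsd_of(params):
            Rm = Rotation.from_rotvec(params[:3]).as_matrix()
            moved = dec_pts @ Rm.T + params[3:]
            return np.sqrt(np.mean(np.sum((moved - ref_pts) ** 2, axis=1)))

        starts = [
            np.zeros(6),
            np.array([0, 0.5, 0, -3, 0, 0.0]),
            np.array([0, -0.5, 0, -3, 0, 1.0]),
        ]
        best = min(
            minimize(
                rmsd_of, x0, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 50_000,
                         "maxfev": 50_000},
            ).fun
            for x0 in starts
        )
        assert m.I_rms == pytest.approx(best, abs=1e-5)
        assert m.I_rms <= best + 1e-9  # Kabsch result is never worse

    def test_native_contact_denominator_flag(self, toy):
        near = toy.native_pose.translated(np.array([1.0, 0.0, 0.0]))
        capri = rd.capri_metrics(toy.model, near, toy.native_pose)
        alt = rd.capri_metrics(
            toy.model, near, toy.native_pose, fnonnat_native_denominator=True
        )
        assert capri.f_non_nat <= 1.0
        assert alt.f_nat == capri.f_nat

    def test_invariance_under_common_rigid_transform(self, toy, rng):
        from scipy.spatial.transform import Rotation

        decoy = toy.native_pose.translated(np.array([2.0, 1.0, 3.0]))
        m0 = rd.capri_metrics(toy.model, decoy, toy.native_pose)
        R = Rotation.random(random_state=3).as_matrix()
        moved = toy.model.transformed(R, np.array([5.0, -8.0, 2.0]))
        # same poses re-expressed in the moved frame leave all metrics fixed
        from replidock.rigid_geometry import RigidPose, quat_multiply, quat_normalize
        from scipy.spatial.transform import Rotation as Rot

        def requat(M):
            q = Rot.from_matrix(M).as_quat()
            return np.array([q[3], q[0], q[1], q[2]])

        def reframe(pose):
            q = quat_normalize(
                quat_multiply(quat_multiply(requat(R), pose.quat), requat(R.T))
            )
            t = R @ pose.translation
            return RigidPose(quat=q, translation=t)

        m1 = rd.capri_metrics(moved, reframe(decoy), reframe(toy.native_pose))
        assert m1.I_rms == pytest.approx(m0.I_rms, abs=1e-6)
        assert m1.L_rms == pytest.approx(m0.L_rms, abs=1e-6)
        assert m1.f_nat == m0.f_nat
        assert m1.f_non_nat == m0.f_non_nat

    def test_i_rms_monotone_along_linear_displacement(self, toy):
        values = [
            rd.capri_metrics(
                toy.model,
                toy.native_pose.translated(np.array([0.0, 0.0, 2.0 * i])),
                toy.native_pose,
            ).I_rms
            for i in range(6)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(values, values[1:]))

    def test_non_complex_reference_rejected(self, toy):
        apart = toy.native_pose.translated(np.array([0.0, 0.0, 300.0]))
        with pytest.raises(rd.ValidationError):
            rd.capri_metrics(toy.model, toy.native_pose, apart)


class TestCallHits:
    def test_fixture_fraction_exact(self, toy, decoy_fixture):
        frac, flags, i_rms = rd.call_hits(decoy_fixture, toy.model, toy.native_pose)
        assert frac == 0.10
        assert flags[:10].all() and not flags[10:].any()

    def test_all_native_and_all_far(self, toy):
        near = rd.make_decoy_fixture(toy, 5, 0, seed=1)
        far = rd.make_decoy_fixture(toy, 0, 5, seed=1)
        assert rd.call_hits(near, toy.model, toy.native_pose)[0] == 1.0
        assert rd.call_hits(far, toy.model, toy.native_pose)[0] == 0.0

    def test_threshold_straddling_matches_direct_count(self, toy, decoy_fixture):
        _, _, i_rms = rd.call_hits(decoy_fixture, toy.model, toy.native_pose)
        for threshold in (0.5, 2.5, 20.0):
            frac, _, _ = rd.call_hits(
                decoy_fixture, toy.model, toy.native_pose, threshold=threshold
            )
            assert frac == (i_rms <= threshold).mean()


class TestClustering:
    def test_bimodal_fixture_yields_two_clusters(self, toy, decoy_fixture):
        clusters = rd.cluster_decoys(decoy_fixture, toy.model, rmsd_cutoff=5.0)
        assert len(clusters) == 2
        assert clusters[0].size == 90 and clusters[1].size == 10
        # brute-force connected components over the pairwise-RMSD graph
        from scipy.sparse.csgraph import connected_components

        from replidock.metrics_analysis import ligand_rmsd_matrix

        d = ligand_rmsd_matrix(decoy_fixture.poses(), toy.model)
        n_comp, labels = connected_components(d <= 5.0, directed=False)
        assert n_comp == 2
        member_sets = [set(c.members) for c in clusters]
        for comp in range(n_comp):
            assert set(np.nonzero(labels == comp)[0].tolist()) in member_sets

    def test_identical_decoys_form_single_cluster(self, toy):
        table = rd.make_decoy_fixture(toy, 0, 20, seed=5)
        clusters = rd.cluster_decoys(table, toy.model)
        assert len(clusters) == 1 and clusters[0].size == 20

    def test_representative_is_lowest_energy_member(self, toy, decoy_fixture):
        energies = decoy_fixture.df["total"].to_numpy()
        for cl in rd.cluster_decoys(decoy_fixture, toy.model):
            assert cl.representative_energy == min(energies[m] for m in cl.members)

    def test_partition_property(self, toy, decoy_fixture):
        clusters = rd.cluster_decoys(decoy_fixture, toy.model, top_n=50)
        all_members = [m for c in clusters for m in c.members]
        assert len(all_members) == len(set(all_members)) == 50


class TestOverlapClassification:
    def test_empty_overlap_is_none(self):
        out = rd.classify_native_overlap(
            energies=[10.0, 12.0], i_rms=[30.0, 40.0],
            reference_energies=np.arange(20.0), reference_i_rms=np.ones(20),
        )
        assert out.category == "none" and out.n == 0

    def test_reference_against_itself_is_dense(self, rng):
        e = rng.normal(size=80)
        i = np.abs(rng.normal(size=80))
        out = rd.classify_native_overlap(e, i, e, i)
        # by percentile construction at least 25% of the reference lies in
        # its own region
        assert out.n >= 20
        assert out.category == "dense"

    def test_single_decoy_is_magic_point(self):
        ref_e = np.arange(20.0)
        ref_i = np.linspace(0.5, 4.0, 20)
        out = rd.classify_native_overlap([0.0], [0.5], ref_e, ref_i)
        assert out.category == "magic_points" and out.n == 1

    def test_category_boundaries(self):
        ref_e = np.arange(100.0)
        ref_i = np.linspace(0.1, 10.0, 100)
        region = OverlapRegion.from_reference(ref_e, ref_i)
        inside_e = region.energy_ceiling - 1.0
        inside_i = region.i_rms_ceiling - 0.1

        def classify(n):
            return rd.classify_native_overlap(
                [inside_e] * n, [inside_i] * n, ref_e, ref_i
            ).category

        assert classify(2) == "magic_points"
        assert classify(3) == "sporadic"
        assert classify(9) == "sporadic"
        assert classify(10) == "dense"

    def test_monotone_under_decoy_addition(self, rng):
        ref_e = rng.normal(size=50)
        ref_i = np.abs(rng.normal(size=50))
        e = list(rng.normal(size=30))
        i = list(np.abs(rng.normal(size=30)))
        prev = 0
        for stop in range(1, 31):
            out = rd.classify_native_overlap(e[:stop], i[:stop], ref_e, ref_i)
            assert out.n >= prev
            prev = out.n


class TestLandscapeMap:
    def test_single_pose_occupies_single_cell(self, toy):
        from replidock.model_io import DecoyTable
        from replidock.samplers import DecoyRecord

        pose = toy.native_pose.translated(np.array([12.0, 5.0, 25.0]))
        e = rd.total_interchain_cen(toy.model, pose)
        table = DecoyTable.from_records(
            [
                DecoyRecord(pose=pose, energies=e, level=0, step=i, traj=0, capped=False)
                for i in range(25)
            ]
        )
        pop, emin = rd.landscape_map(table, toy.model)
        assert pop.sum() == 25
        assert (pop > 0).sum() == 1
        occupied = pop > 0
        assert np.isfinite(emin[occupied]).all()
        assert np.isnan(emin[~occupied]).all()

    def test_population_conservation(self, toy, decoy_fixture):
        pop, _ = rd.landscape_map(decoy_fixture, toy.model, n_theta=10, n_phi=20)
        assert pop.sum() == len(decoy_fixture)

    def test_cell_minimum_matches_brute_force(self, toy, decoy_fixture):
        n_theta, n_phi = 6, 8
        pop, emin = rd.landscape_map(
            decoy_fixture, toy.model, n_theta=n_theta, n_phi=n_phi
        )
        energies = decoy_fixture.df["total"].to_numpy()
        cells = {}
        for row, pose in enumerate(decoy_fixture.poses()):
            v = pose.mobile_center_position(toy.model.mobile_center) - toy.model.com_A
            r = np.linalg.norm(v)
            theta = np.arccos(np.clip(v[2] / r, -1, 1))
            phi = np.arctan2(v[1], v[0])
            it = min(int(theta / np.pi * n_theta), n_theta - 1)
            ip = min(int((phi + np.pi) / (2 * np.pi) * n_phi), n_phi - 1)
            cells.setdefault((it, ip), []).append(energies[row])
        for (it, ip), vals in cells.items():
            assert emin[it, ip] == pytest.approx(min(vals))


class TestEnergyNormalization:
    def test_closed_form_single_ensemble(self):
        energies = -np.arange(20.0)  # 0, -1, ..., -19
        df = rd.normalize_energy_percentiles(
            {"a": energies}, percentiles=(0.0, 5.0)
        )
        # max is 0 -> no shift; mean of 10 lowest = -14.5; min -> -19/14.5
        assert df.loc["a", "p0"] == pytest.approx(-19.0 / 14.5)

    def test_scale_invariance(self, rng):
        e = rng.normal(size=50)
        d1 = rd.normalize_energy_percentiles({"a": e})
        d2 = rd.normalize_energy_percentiles({"a": 2.0 * e})
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)

    def test_degenerate_ensemble_rejected(self):
        with pytest.raises(rd.ValidationError):
            rd.normalize_energy_percentiles({"a": np.zeros(15)})

    def test_short_ensemble_rejected(self):
        with pytest.raises(rd.ValidationError):
            rd.normalize_energy_percentiles({"a": np.arange(5.0)})

    def test_shift_uses_global_maximum_across_methods(self):
        a = -np.arange(20.0)
        b = -np.arange(20.0) + 5.0  # max of the pool is 5
        df = rd.normalize_energy_percentiles({"a": a, "b": b}, percentiles=(0.0,))
        pooled_shifted = np.concatenate([a - 5.0, b - 5.0])
        divisor = abs(np.sort(pooled_shifted)[:10].mean())
        assert df.loc["a", "p0"] == pytest.approx((a.min() - 5.0) / divisor)
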