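"""Coordination statistics, inclusion bookkeeping, clustering and plane
geometry on labelled trajectories."""

import numpy as np
import pytest

from calixtherm import mdcoord, synthgen
from calixtherm.mdcoord import (
    EMPTY,
    HEAD_IN,
    TAIL_IN,
    Frame,
    InclusionTimeline,
    LabeledTrajectory,
    build_coordination_matrix,
    classify_inclusion,
    coordination_series,
    count_exchanges,
    fit_plane,
    geometry_report,
    pca_cluster_representatives,
)
from calixtherm.reference_data import GEOMETRY_DISTANCES


def single_frame_traj(donor_distance=2.5, nphen_distance=None):
    """Hand-built one-frame complex with donors at a prescribed distance."""
    nphen_distance = donor_distance if nphen_distance is None else nphen_distance
    elements, roles, mols, coords = ["Ca"], ["cation"], ["CAT"], [[0.0, 0.0, 0.0]]
    for k in range(4):
        ang = np.pi / 2 * k
        elements.append("O"); roles.append("O_ether"); mols.append("LIG")
        coords.append([donor_distance * np.cos(ang), donor_distance * np.sin(ang), 0.0])
    for sgn in (1, -1):
        elements.append("O"); roles.append("O_carbonyl"); mols.append("LIG")
        coords.append([0.0, 0.0, sgn * donor_distance])
        elements.append("C"); roles.append("other"); mols.append("LIG")
        coords.append([0.0, 0.0, sgn * (donor_distance + 1.23)])
    for sgn in (1, -1):
        elements.append("N"); roles.append("N_phen"); mols.append("LIG")
        coords.append([sgn * nphen_distance / np.sqrt(2), sgn * nphen_distance / np.sqrt(2), 0.0])
    return LabeledTrajectory(elements, roles, mols, [Frame(np.array(coords))])


def rigid_motion(coords, seed=0):
    rng = np.random.default_rng(seed)
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return coords @ q.T + rng.uniform(-5, 5, 3)


class TestCoordinationSeries:
    def test_counts_with_all_donors_in_shell(self):
        out = coordination_series(single_frame_traj(2.5))
        assert out["mean"] == {"O_ether": 4.0, "O_carbonyl": 2.0, "N_phen": 2.0}

    def test_counts_zero_beyond_cutoff(self):
        out = coordination_series(single_frame_traj(3.5))
        assert out["mean"] == {"O_ether": 0.0, "O_carbonyl": 0.0, "N_phen": 0.0}

    def test_partial_phenanthridine_contact_fraction(self):
        rng = np.random.default_rng(8)
        n = 1000
        contact = rng.random(n) < 0.3
        sched = [(EMPTY, None)] * n
        traj, _ = synthgen.gen_trajectory(sched, jitter_sd=0.02, seed=8,
                                          nphen_contact=list(contact))
        out = coordination_series(traj)
        expected = 2.0 * contact.mean()
        assert out["mean"]["N_phen"] == pytest.approx(expected, abs=1e-12)
        assert 0.0 < out["se"]["N_phen"] < 0.2

    def test_missing_role_rejected(self):
        traj = single_frame_traj()
        with pytest.raises(ValueError):
            coordination_series(traj, {"solvent_head": 3.0})


class TestInclusion:
    def test_head_orientation_rule(self):
        sched = [(HEAD_IN, "A")] * 3
        traj, _ = synthgen.gen_trajectory(sched, jitter_sd=0.0)
        tl = classify_inclusion(traj)
        assert tl.states == [HEAD_IN] * 3
        assert tl.occupants == ["A"] * 3

    def test_empty_cavity(self):
        traj, _ = synthgen.gen_trajectory([(EMPTY, None)] * 4, jitter_sd=0.0)
        tl = classify_inclusion(traj)
        assert tl.states == [EMPTY] * 4
        assert tl.fractions()[EMPTY] == 1.0

    def test_fractions_recovered_from_known_schedule(self):
        sched = [(HEAD_IN, "A")] * 70 + [(TAIL_IN, "A")] * 20 + [(EMPTY, None)] * 10
        traj, _ = synthgen.gen_trajectory(sched, jitter_sd=0.05, seed=1)
        fr = classify_inclusion(traj).fractions()
        assert fr == {EMPTY: 0.10, HEAD_IN: 0.70, TAIL_IN: 0.20}

    def test_exchange_counting_rules(self):
        tl = InclusionTimeline([HEAD_IN] * 100 + [HEAD_IN] * 100, ["A"] * 100 + ["B"] * 100)
        assert count_exchanges(tl) == (2, 1)
        tl2 = InclusionTimeline([HEAD_IN, EMPTY, HEAD_IN], ["A", None, "A"])
        assert count_exchanges(tl2) == (1, 0)

    def test_random_schedule_exchanges_match_brute_force(self):
        rng = np.random.default_rng(77)
        mols = ["A", "B", "C"]
        sched = []
        for _ in range(300):
            if rng.random() < 0.2:
                sched.append((EMPTY, None))
            else:
                sched.append((HEAD_IN if rng.random() < 0.6 else TAIL_IN, mols[rng.integers(3)]))
        traj, truth = synthgen.gen_trajectory(sched, jitter_sd=0.03, seed=7)
        tl = classify_inclusion(traj)
        # brute-force rescan oracle over the known schedule
        occ = [o for _, o in sched if o is not None]
        expected_ex = sum(1 for a, b in zip(occ, occ[1:]) if a != b)
        distinct, exchanges = count_exchanges(tl)
        assert exchanges == expected_ex == truth.exchanges
        assert distinct == len(set(occ))


class TestCoordinationMatrix:
    def test_hand_placed_geometry(self):
        traj = single_frame_traj(2.5)
        cm = build_coordination_matrix(traj)
        assert cm.values.shape == (1, 10)
        row = dict(zip(cm.labels, cm.values[0]))
        for lab in cm.labels[:8]:
            assert row[lab] == pytest.approx(2.5, abs=1e-12)
        # cation, O and C are collinear with C outermost: the C=O bond and
        # the C->cation direction coincide, so the angle at C is 0
        assert row["angle(carbonyl1)"] == pytest.approx(0.0, abs=1e-9)
        assert row["angle(carbonyl2)"] == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_frame_gives_identical_rows(self):
        base = single_frame_traj(2.4)
        traj = LabeledTrajectory(
            base.elements, base.roles, base.mol_ids,
            [Frame(base.frames[0].coords.copy()), Frame(base.frames[0].coords.copy())],
        )
        cm = build_coordination_matrix(traj)
        np.testing.assert_array_equal(cm.values[0], cm.values[1])

    def test_rigid_motion_invariance(self):
        sched = [(HEAD_IN, "A")] * 5
        traj, _ = synthgen.gen_trajectory(sched, jitter_sd=0.05, seed=3)
        cm = build_coordination_matrix(traj)
        moved = LabeledTrajectory(
            traj.elements, traj.roles, traj.mol_ids,
            [Frame(rigid_motion(fr.coords, seed=i)) for i, fr in enumerate(traj.frames)],
        )
        cm2 = build_coordination_matrix(moved)
        np.testing.assert_allclose(cm2.values, cm.values, atol=1e-10)


class TestPCACluster:
    def test_identical_rows_collapse_to_single_cluster(self):
        cm = mdcoord.CoordinationMatrix(np.ones((12, 4)), ["a", "b", "c", "d"])
        out = pca_cluster_representatives(cm)
        assert out["k"] == 1
        assert out["representatives"] == [0]
        assert out["populations"] == [12]

    def test_two_blobs_found_with_correct_representatives(self):
        rng = np.random.default_rng(10)
        blob1 = rng.normal(0.0, 0.05, (40, 6))
        blob2 = rng.normal(3.0, 0.05, (20, 6))
        cm = mdcoord.CoordinationMatrix(np.vstack([blob1, blob2]), [f"c{i}" for i in range(6)])
        out = pca_cluster_representatives(cm, range(1, 7), seed=0)
        assert out["k"] == 2
        assert out["populations"] == [40, 20]
        assert out["representatives"][0] < 40 <= out["representatives"][1]

    def test_scores_preserve_distances_of_rank2_data(self):
        rng = np.random.default_rng(11)
        basis = rng.normal(size=(2, 8))
        weights = rng.normal(size=(30, 2))
        cm = mdcoord.CoordinationMatrix(weights @ basis, [f"c{i}" for i in range(8)])
        scores = mdcoord.pca_scores(cm, 2)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(scores), pdist(cm.values), atol=1e-8)


class TestPlaneFit:
    def test_square_in_xy_plane(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
        pf = fit_plane(pts)
        assert abs(pf.normal[2]) == pytest.approx(1.0, abs=1e-14)
        assert pf.rms == pytest.approx(0.0, abs=1e-14)
        assert pf.distance(np.array([0.0, 0.0, 0.678])) == pytest.approx(0.678, abs=1e-12)

    def test_rotated_coplanar_points_have_zero_rms(self):
        rng = np.random.default_rng(4)
        pts = np.column_stack([rng.uniform(-2, 2, (12, 2)), np.zeros(12)])
        moved = rigid_motion(pts, seed=5)
        assert fit_plane(moved).rms < 1e-12

    def test_noisy_plane_normal_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        true_normal = np.array([0.3, -0.4, 0.866])
        true_normal /= np.linalg.norm(true_normal)
        u = np.cross(true_normal, [0, 0, 1.0]); u /= np.linalg.norm(u)
        v = np.cross(true_normal, u)
        ab = rng.uniform(-3, 3, (40, 2))
        pts = ab @ np.vstack([u, v]) + rng.normal(0, 0.01, (40, 1)) * true_normal
        pf = fit_plane(pts)

        # coarse-to-fine brute-force search over unit normals
        def ssq(n):
            c = pts - pts.mean(axis=0)
            return float(np.sum((c @ n) ** 2))

        best, best_val = None, np.inf
        theta_c, phi_c, width = np.pi / 4, 0.0, np.pi
        # center the first pass on the full sphere
        for _ in range(6):
            for th in np.linspace(max(theta_c - width, 0), min(theta_c + width, np.pi), 25):
                for ph in np.linspace(phi_c - width, phi_c + width, 25):
                    n = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
                    val = ssq(n)
                    if val < best_val:
                        best, best_val, th_b, ph_b = n, val, th, ph
            theta_c, phi_c = th_b, ph_b
            width /= 5
        cosang = abs(float(best @ pf.normal))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 0.5
        assert np.degrees(np.arccos(abs(float(pf.normal @ true_normal)))) < 0.5

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], float)
        with pytest.raises(ValueError, match="collinear"):
            fit_plane(pts)


class TestGeometryReport:
    def test_axial_distances(self):
        # ether square at z=0, cation/solvent on the axis: distances are
        # plain coordinate differences
        traj, _ = synthgen.gen_trajectory([(HEAD_IN, "A")], jitter_sd=0.0)
        rep = geometry_report(traj, frame=0, solvent_mol="A")
        # generator geometry: cation 0.8 below the plane; head 2.8 from the
        # cation along the axis; tail 4.3; solvent COM mass-weighted N/C
        assert rep["plane_cation"] == pytest.approx(0.8, abs=1e-12)
        from calixtherm.mdcoord import ATOM_MASSES

        m_n, m_c = ATOM_MASSES["N"], ATOM_MASSES["C"]
        com_z = (m_n * 2.0 + m_c * 3.5) / (m_n + m_c)
        assert rep["plane_solvent"] == pytest.approx(com_z, abs=1e-12)
        assert rep["cation_solvent"] == pytest.approx(com_z + 0.8, abs=1e-12)
        assert rep["triangle_ok"]

    def test_random_geometry_matches_brute_force_and_triangle(self):
        traj, _ = synthgen.gen_trajectory([(TAIL_IN, "B")] * 3, jitter_sd=0.1, seed=9)
        rep = geometry_report(traj, frame=2, solvent_mol="B")
        fr = traj.frames[2]
        ether = fr.coords[traj.indices("O_ether")]
        pf = fit_plane(ether)
        cat = fr.coords[traj.cation_index()]
        assert rep["plane_cation"] == pytest.approx(abs(float((cat - pf.centroid) @ pf.normal)), rel=1e-12)
        assert abs(rep["plane_solvent"] - rep["plane_cation"]) <= rep["cation_solvent"] + 1e-12

    def test_missing_solvent_rejected(self):
        traj, _ = synthgen.gen_trajectory([(EMPTY, None)], jitter_sd=0.0)
        with pytest.raises(ValueError, match="not present"):
            geometry_report(traj, solvent_mol="ZZ")

    def test_published_distance_table_satisfies_triangle_inequality(self):
        for cation, forms in GEOMETRY_DISTANCES.items():
            for form, d in forms.items():
                if "plane_solvent" in d:
                    assert abs(d["plane_solvent"] - d["plane_cation"]) <= d["cation_solvent"], (
                        cation, form,
                    )
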