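"""Titration profiles, MS coefficient, aggregation, RMSD and reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttmd.analysis import (
    TitrationProfile,
    aggregate_replicates,
    contact_frequency_report,
    export_report,
    ms_coefficient,
    rank_poses,
    rmsd_series,
    titration_profile,
)
from ttmd.geometry import superpose_kabsch
from ttmd.titration import DEFAULT_RAMP, run_titration

from conftest import make_backend


@pytest.fixture(scope="module")
def stable_run():
    backend = make_backend(5000.0)
    return run_titration(
        backend.model, backend.reference_frame, DEFAULT_RAMP, backend,
        seed=0, stride_ps=1000.0,
    )


@pytest.fixture(scope="module")
def weak_run():
    backend = make_backend(100.0)
    return run_titration(
        backend.model, backend.reference_frame, DEFAULT_RAMP, backend,
        seed=0, stride_ps=1000.0,
    )


class TestTitrationProfile:
    def test_full_ramp_profile(self, stable_run):
        profile = titration_profile(stable_run)
        assert len(profile.points) == 16
        assert profile.anchor == (300.0, -1.0)

    def test_terminated_profile_ends_at_zero(self, weak_run):
        profile = titration_profile(weak_run)
        assert profile.points[-1][1] == 0.0

    def test_temperatures_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            TitrationProfile(points=[(310.0, -0.5), (310.0, -0.4)], anchor=(300.0, -1.0))

    def test_anchor_must_be_minus_one(self):
        with pytest.raises(ValueError):
            TitrationProfile(points=[(310.0, -0.5)], anchor=(300.0, 0.0))


class TestMsCoefficient:
    def test_fully_retained_gives_zero(self):
        points = [(300.0 + 10 * i, -1.0) for i in range(16)]
        profile = TitrationProfile(points=points, anchor=(300.0, -1.0))
        assert ms_coefficient(profile, DEFAULT_RAMP).ms == 0.0

    def test_first_window_loss_gives_one(self):
        profile = TitrationProfile(points=[(300.0, 0.0)], anchor=(300.0, -1.0))
        result = ms_coefficient(profile, DEFAULT_RAMP)
        assert result.ms == 1.0
        assert result.t_end_used == 300.0

    def test_full_ramp_partial_retention(self):
        points = [(300.0 + 10 * i, -1.0) for i in range(15)] + [(450.0, -0.25)]
        profile = TitrationProfile(points=points, anchor=(300.0, -1.0))
        result = ms_coefficient(profile, DEFAULT_RAMP)
        assert result.ms == pytest.approx(0.75 / 15)
        assert result.normalization == 15
        assert result.raw_slope_per_K == pytest.approx(0.75 / 150.0)

    def test_termination_mid_ramp(self):
        points = [(300.0, -0.9), (310.0, -0.4), (320.0, 0.0)]
        profile = TitrationProfile(points=points, anchor=(300.0, -1.0))
        result = ms_coefficient(profile, DEFAULT_RAMP)
        assert result.ms == pytest.approx(1.0 / 2)

    def test_ms_bounds_on_runs(self, stable_run, weak_run):
        for run in (stable_run, weak_run):
            ms = ms_coefficient(titration_profile(run), DEFAULT_RAMP).ms
            assert 0.0 <= ms <= 1.0
        assert ms_coefficient(titration_profile(stable_run), DEFAULT_RAMP).ms == 0.0

    def test_earlier_loss_never_scores_lower(self):
        """A pose losing its interactions colder is never ranked more stable."""
        for seed in range(20):
            cold = make_backend(320.0)
            hot = make_backend(420.0)
            run_cold = run_titration(
                cold.model, cold.reference_frame, DEFAULT_RAMP, cold,
                seed=seed, stride_ps=1000.0,
            )
            run_hot = run_titration(
                hot.model, hot.reference_frame, DEFAULT_RAMP, hot,
                seed=seed, stride_ps=1000.0,
            )
            ms_cold = ms_coefficient(titration_profile(run_cold), DEFAULT_RAMP).ms
            ms_hot = ms_coefficient(titration_profile(run_hot), DEFAULT_RAMP).ms
            assert ms_cold >= ms_hot


class TestAggregateReplicates:
    def test_drop_extremes(self):
        rep = aggregate_replicates([0.10, 0.20, 0.30, 0.40, 0.90])
        assert sorted(rep.retained) == [0.20, 0.30, 0.40]
        assert rep.aggregated_ms == pytest.approx(0.30)

    def test_identical_values(self):
        rep = aggregate_replicates([0.4] * 5)
        assert rep.aggregated_ms == pytest.approx(0.4)

    def test_tie_drops_one_instance_each(self):
        rep = aggregate_replicates([0.1, 0.1, 0.2, 0.3, 0.3])
        assert sorted(rep.retained) == [0.1, 0.2, 0.3]
        assert rep.aggregated_ms == pytest.approx(0.2)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            aggregate_replicates([0.1, 0.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=5, max_size=5))
    @settings(deadline=None, max_examples=200)
    def test_matches_sort_slice_mean_oracle(self, values):
        rep = aggregate_replicates(values)
        expected = float(np.mean(sorted(values)[1:-1]))
        assert rep.aggregated_ms == pytest.approx(expected, abs=1e-12)
        assert len(rep.retained) == 3


class TestRankPoses:
    def test_ascending_order(self):
        reps = {
            "p2": aggregate_replicates([0.3] * 5),
            "p1": aggregate_replicates([0.05] * 5),
            "p3": aggregate_replicates([0.41] * 5),
        }
        reports = rank_poses(reps)
        assert [p.pose_id for p in reports] == ["p1", "p2", "p3"]
        assert [p.rank for p in reports] == [1, 2, 3]

    def test_single_pose(self):
        reports = rank_poses({"only": aggregate_replicates([0.2] * 5)})
        assert reports[0].rank == 1

    def test_tie_flagged_and_lexicographic(self):
        reps = {
            "b": aggregate_replicates([0.3] * 5),
            "a": aggregate_replicates([0.3] * 5),
        }
        reports = rank_poses(reps)
        assert [p.pose_id for p in reports] == ["a", "b"]
        assert all(p.tied for p in reports)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_poses({})


class TestSuperposeKabsch:
    def test_identity(self, rng):
        coords = rng.normal(size=(10, 3))
        _, _, fitted = superpose_kabsch(coords, coords)
        assert fitted == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_removed(self, rng):
        from scipy.spatial.transform import Rotation

        coords = rng.normal(size=(10, 3))
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = coords @ R.T + np.array([5.0, -3.0, 1.0])
        Rf, t, fitted = superpose_kabsch(moved, coords)
        assert fitted == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(Rf) == pytest.approx(1.0, abs=1e-9)

    def test_single_displaced_atom_closed_form(self):
        target = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]], dtype=float)
        mobile = target.copy()
        mobile[3, 2] += 2.0  # displaced by 2 Å
        from ttmd.geometry import rmsd

        # unfitted RMSD of a single 2 Å displacement over N=4 atoms: 2/√4
        assert rmsd(mobile, target) == pytest.approx(1.0)

    def test_degenerate_subset_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            superpose_kabsch(line, line + 1.0)


class TestRmsdSeries:
    def test_identical_frames_zero(self, stable_run):
        # intact synthetic frames only jitter below 0.2 Å
        table = rmsd_series(stable_run)
        assert (table["backbone_rmsd"] < 0.01).all()
        assert (table["ligand_rmsd"] < 0.25).all()

    def test_pure_ligand_translation(self):
        backend = make_backend(5000.0)
        run = run_titration(
            backend.model, backend.reference_frame, DEFAULT_RAMP, backend,
            seed=0, stride_ps=5000.0,
        )
        ref = backend.reference_frame
        for w in run.windows:
            for f in w.frames:
                f.coords_ligand = ref.coords_ligand + np.array([0.0, 0.0, 3.0])
                f.coords_protein = ref.coords_protein
        table = rmsd_series(run, ref)
        assert table["ligand_rmsd"].values == pytest.approx(3.0, abs=1e-9)
        assert table["backbone_rmsd"].values == pytest.approx(0.0, abs=1e-9)

    def test_global_rigid_motion_invariant(self):
        from scipy.spatial.transform import Rotation

        backend = make_backend(5000.0)
        run = run_titration(
            backend.model, backend.reference_frame, DEFAULT_RAMP, backend,
            seed=0, stride_ps=5000.0,
        )
        ref = backend.reference_frame
        R = Rotation.from_euler("z", 1.0).as_matrix()
        for w in run.windows:
            for f in w.frames:
                f.coords_protein = ref.coords_protein @ R.T + 7.0
                f.coords_ligand = ref.coords_ligand @ R.T + 7.0
        table = rmsd_series(run, ref)
        assert table["backbone_rmsd"].values == pytest.approx(0.0, abs=1e-9)
        assert table["ligand_rmsd"].values == pytest.approx(0.0, abs=1e-9)


class TestContactReport:
    def test_contacted_residues_reported(self, stable_run):
        table = contact_frequency_report(stable_run)
        assert len(table) <= 25
        assert len(table) >= 4  # the four interaction-site residues
        assert (table["frequency"] <= 1.0).all()
        assert (table["frequency"] > 0.0).all()

    def test_intermittent_contact_frequency(self):
        backend = make_backend(5000.0)
        run = run_titration(
            backend.model, backend.reference_frame,
            DEFAULT_RAMP, backend, seed=0, stride_ps=5000.0,
        )
        frames = list(run.iter_frames())
        # displace the ligand in exactly half the frames
        for f in frames[: len(frames) // 2]:
            f.coords_ligand = f.coords_ligand + np.array([0.0, -50.0, 0.0])
        table = contact_frequency_report(run)
        assert table["frequency"].values == pytest.approx(0.5, abs=1e-9)

    def test_cap_at_top_n(self, stable_run):
        table = contact_frequency_report(stable_run, top_n=2)
        assert len(table) == 2

    def test_invalid_cutoff(self, stable_run):
        with pytest.raises(ValueError):
            contact_frequency_report(stable_run, cutoff=-1.0)


class TestExportReport:
    def test_files_written_and_roundtrip(self, tmp_path, stable_run):
        import pandas as pd

        profile = titration_profile(stable_run)
        ms = ms_coefficient(profile, DEFAULT_RAMP)
        reports = rank_poses({"pose1": aggregate_replicates([ms.ms] * 5)})
        written = export_report(
            {"pose1": stable_run}, {"pose1": profile}, reports, tmp_path
        )
        for key in (
            "titration_profile_plot", "titration_profile_csv",
            "contact_frequency_plot", "contact_frequency_csv",
            "timeseries_plot", "timeseries_csv",
            "pose_ranking_csv", "pose_ranking_json",
        ):
            assert key in written
            assert (tmp_path / written[key].split("/")[-1]).exists()

        back = pd.read_csv(written["titration_profile_csv"])
        assert list(back["temperature_K"]) == [t for t, _ in profile.points]
        assert back["mean_ifpcs"].values == pytest.approx(
            [m for _, m in profile.points]
        )

    def test_deterministic_csv_content(self, tmp_path, stable_run):
        profile = titration_profile(stable_run)
        a, b = tmp_path / "a", tmp_path / "b"
        export_report({"p": stable_run}, {"p": profile}, [], a)
        export_report({"p": stable_run}, {"p": profile}, [], b)
        assert (a / "titration_profile.csv").read_text() == (
            b / "titration_profile.csv"
        ).read_text()
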