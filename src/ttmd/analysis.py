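"""Titration profiles, the MS coefficient, replicate aggregation and reports.

The titration profile of a run is the sequence of (window temperature,
window-mean IFP_CS) points, anchored at the equilibrated native state
(t_start, −1).  The MS coefficient is the slope of the straight line from
that anchor to the final completed window,

    MS = (meanIFP_CS(T_end) − (−1)) / (T_end − T_start),

with the temperature axis measured in ramp-increment units and capped at 1,
so MS spans [0, 1]: 0 means the native binding mode survived the full ramp
untouched, 1 means it was completely lost within the first window.  The
raw per-kelvin slope is reported alongside.  Five replicate runs are
aggregated by discarding the single highest and lowest MS and averaging
the remaining three; poses rank by ascending aggregated MS (lower = more
persistent binding mode).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .complex_model import ComplexModel, Frame
from .geometry import rmsd, superpose_kabsch
from .titration import TemperatureRamp, TitrationRun

__all__ = [
    "TitrationProfile",
    "MSResult",
    "ReplicateSet",
    "PoseReport",
    "titration_profile",
    "ms_coefficient",
    "aggregate_replicates",
    "rank_poses",
    "superpose_kabsch",
    "rmsd_series",
    "contact_frequency_report",
    "export_report",
]


@dataclass
class TitrationProfile:
    """(temperature, mean IFP_CS) points of one run, plus the anchor state."""

    points: list  # [(temperature K, mean_ifpcs), ...] strictly increasing T
    anchor: tuple  # (t_start, -1.0)

    def __post_init__(self):
        temps = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("profile temperatures must be strictly increasing")
        if self.anchor[1] != -1.0:
            raise ValueError("anchor mean is −1 by definition")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["temperature_K", "mean_ifpcs"])


@dataclass
class MSResult:
    """MS coefficient of one titration run."""

    ms: float
    t_end_used: float
    mean_ifpcs_at_end: float
    normalization: int  # temperature span in ramp increments (>= 1)
    raw_slope_per_K: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.ms <= 1.0:
            raise ValueError(f"MS out of range: {self.ms}")


@dataclass
class ReplicateSet:
    """Trimmed-mean aggregation of replicate MS values (drop one max, one min)."""

    ms_values: list
    retained: list
    aggregated_ms: float


@dataclass
class PoseReport:
    pose_id: str
    aggregated_ms: float
    replicate_ms: list
    rank: int
    ligand_rmsd: float | None = None
    tied: bool = False


def titration_profile(run: TitrationRun) -> TitrationProfile:
    """Profile of a run: anchor plus one point per completed window."""
    if not run.windows:
        raise ValueError("run has no windows")
    return TitrationProfile(
        points=[(w.temperature, w.mean_ifpcs) for w in run.windows],
        anchor=(run.ramp.t_start, -1.0),
    )


def ms_coefficient(profile: TitrationProfile, ramp: TemperatureRamp) -> MSResult:
    """Slope from the anchor to the final window, in ramp-increment units.

    A termination within the very first window (T_end = T_start, window
    mean 0) yields the maximum MS of 1; a run that keeps mean IFP_CS at −1
    through the full ramp yields 0.
    """
    if not profile.points:
        raise ValueError("empty titration profile")
    t_end, mean_end = profile.points[-1]
    t_start = profile.anchor[0]
    if t_end < t_start or t_end > ramp.t_end + 1e-9:
        raise ValueError("profile temperatures do not match the ramp")
    n_inc = max(1, int(round((t_end - t_start) / ramp.increment)))
    ms = min(1.0, (mean_end + 1.0) / n_inc)
    raw = (mean_end + 1.0) / (t_end - t_start) if t_end > t_start else None
    return MSResult(
        ms=ms,
        t_end_used=t_end,
        mean_ifpcs_at_end=mean_end,
        normalization=n_inc,
        raw_slope_per_K=raw,
    )


def aggregate_replicates(ms_values) -> ReplicateSet:
    """Drop exactly one maximum and one minimum, average the rest.

    With the default five replicates this retains three values.  Ties drop
    a single instance each.
    """
    values = [float(v) for v in ms_values]
    if len(values) < 3:
        raise ValueError("need at least 3 replicate MS values")
    retained = list(values)
    retained.remove(max(retained))
    retained.remove(min(retained))
    return ReplicateSet(
        ms_values=values,
        retained=retained,
        aggregated_ms=float(np.mean(retained)),
    )


def rank_poses(replicates: dict) -> list:
    """Order poses by ascending aggregated MS; ties break by pose id."""
    if not replicates:
        raise ValueError("no poses to rank")
    items = sorted(replicates.items(), key=lambda kv: (kv[1].aggregated_ms, kv[0]))
    ms_counts = {}
    for _, rep in items:
        ms_counts[rep.aggregated_ms] = ms_counts.get(rep.aggregated_ms, 0) + 1
    return [
        PoseReport(
            pose_id=pid,
            aggregated_ms=rep.aggregated_ms,
            replicate_ms=rep.ms_values,
            rank=i + 1,
            tied=ms_counts[rep.aggregated_ms] > 1,
        )
        for i, (pid, rep) in enumerate(items)
    ]


def _backbone_subset(model: ComplexModel) -> np.ndarray:
    names = {"N", "CA", "C", "O"}
    idx = [i for i, a in enumerate(model.protein_atoms)
           if a.name.upper() in names and not a.is_metal]
    if len(idx) < 3:
        raise ValueError("model lacks the backbone atoms (N, CA, C, O) needed for fitting")
    return np.array(idx, dtype=int)


def rmsd_series(run: TitrationRun, reference: Frame | None = None) -> pd.DataFrame:
    """Backbone-fitted per-frame backbone and ligand RMSD (Å).

    Each frame is superposed onto the reference on protein backbone atoms
    (N, CA, C, O); the ligand heavy-atom RMSD is then computed in that frame
    without refitting, so it reports genuine ligand motion relative to the
    protein.  No ligand symmetry correction is applied.
    """
    model = run.model
    if model is None:
        raise ValueError("run carries no model")
    reference = reference or run.reference_frame
    reference.check_congruent(model)
    bb = _backbone_subset(model)
    lig_heavy = np.array([i for i, a in enumerate(model.ligand_atoms) if a.is_heavy], dtype=int)

    rows = []
    for frame in run.iter_frames():
        R, t, bb_rmsd = superpose_kabsch(
            frame.coords_protein, reference.coords_protein, subset=bb
        )
        lig_fitted = frame.coords_ligand[lig_heavy] @ R.T + t
        rows.append(
            {
                "frame": frame.index,
                "time_ps": frame.time,
                "temperature_K": frame.temperature_set,
                "backbone_rmsd": bb_rmsd,
                "ligand_rmsd": rmsd(lig_fitted, reference.coords_ligand[lig_heavy]),
            }
        )
    return pd.DataFrame(rows)


def contact_frequency_report(
    run: TitrationRun, cutoff: float = 4.5, top_n: int = 25
) -> pd.DataFrame:
    """Residues most frequently contacted by the ligand across the run.

    A residue is in contact in a frame when any of its heavy atoms lies
    within ``cutoff`` Å of any ligand heavy atom; residues are ranked by the
    fraction of frames in contact (ties broken by residue order) and the
    table is capped at ``top_n`` rows.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    model = run.model
    if model is None:
        raise ValueError("run carries no model")
    res_index = model.residue_index
    p_heavy = [(i, res_index[a.residue_key]) for i, a in enumerate(model.protein_atoms)
               if a.is_heavy]
    l_heavy = [i for i, a in enumerate(model.ligand_atoms) if a.is_heavy]
    p_rows = np.array([i for i, _ in p_heavy])
    p_res = np.array([ri for _, ri in p_heavy])

    counts = np.zeros(model.r, dtype=int)
    n_frames = 0
    for frame in run.iter_frames():
        n_frames += 1
        d = np.linalg.norm(
            frame.coords_protein[p_rows, None, :] - frame.coords_ligand[None, l_heavy, :],
            axis=-1,
        )
        touched = np.unique(p_res[(d <= cutoff).any(axis=1)])
        counts[touched] += 1
    if n_frames == 0:
        raise ValueError("run has no frames")

    freq = counts / n_frames
    order = sorted(range(model.r), key=lambda i: (-freq[i], i))
    rows = [
        {
            "residue": "{}{}{}:{}".format(*model.residue_order[i]),
            "residue_index": i,
            "frequency": freq[i],
            "n_frames_in_contact": int(counts[i]),
        }
        for i in order
        if counts[i] > 0
    ]
    return pd.DataFrame(rows[:top_n])


# --------------------------------------------------------------------------
# report export


def export_report(runs, profiles, pose_reports, output_dir) -> dict:
    """Write the analysis plots and tables for a set of runs.

    Emits the titration-profile plot/CSV, the contact-frequency plot/CSV,
    the RMSD + IFP_CS time-series plot/CSV and the pose-ranking table
    (CSV + JSON).  Data files are deterministic (no timestamps).  Returns a
    manifest of written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    # titration profiles
    prof_rows = []
    fig, ax = plt.subplots(figsize=(6, 4))
    for run_id, profile in profiles.items():
        temps = [profile.anchor[0]] + [t for t, _ in profile.points]
        means = [profile.anchor[1]] + [m for _, m in profile.points]
        ax.plot(temps, means, marker="o", label=str(run_id))
        prof_rows.extend(
            {"run": run_id, "temperature_K": t, "mean_ifpcs": m}
            for t, m in profile.points
        )
    ax.set_xlabel("temperature (K)")
    ax.set_ylabel("window mean IFP_CS")
    ax.set_title("Titration profile")
    ax.legend(fontsize=7)
    fig.tight_layout()
    written["titration_profile_plot"] = str(out / "titration_profile.png")
    fig.savefig(written["titration_profile_plot"], dpi=120)
    plt.close(fig)
    written["titration_profile_csv"] = str(out / "titration_profile.csv")
    pd.DataFrame(prof_rows).to_csv(written["titration_profile_csv"], index=False)

    # contact frequencies and RMSD/IFP_CS time series (per run)
    contact_frames, series_frames = [], []
    for run_id, run in runs.items():
        contacts = contact_frequency_report(run)
        contacts.insert(0, "run", run_id)
        contact_frames.append(contacts)
        series = rmsd_series(run)
        series.insert(0, "run", run_id)
        series["ifp_cs"] = [s.ifp_cs for w in run.windows for s in w.frame_scores]
        series_frames.append(series)
    contacts_all = pd.concat(contact_frames, ignore_index=True)
    series_all = pd.concat(series_frames, ignore_index=True)
    written["contact_frequency_csv"] = str(out / "contact_frequency.csv")
    contacts_all.to_csv(written["contact_frequency_csv"], index=False)
    written["timeseries_csv"] = str(out / "rmsd_ifpcs_timeseries.csv")
    series_all.to_csv(written["timeseries_csv"], index=False)

    fig, ax = plt.subplots(figsize=(6, 4))
    first = contact_frames[0]
    ax.barh(first["residue"][::-1], first["frequency"][::-1])
    ax.set_xlabel("fraction of frames in contact (≤ 4.5 Å)")
    ax.set_title("Most contacted residues")
    fig.tight_layout()
    written["contact_frequency_plot"] = str(out / "contact_frequency.png")
    fig.savefig(written["contact_frequency_plot"], dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    for run_id, group in series_all.groupby("run"):
        axes[0].plot(group["time_ps"], group["ligand_rmsd"], label=f"{run_id} ligand")
        axes[0].plot(group["time_ps"], group["backbone_rmsd"], ls="--",
                     label=f"{run_id} backbone")
        axes[1].plot(group["time_ps"], group["ifp_cs"], label=str(run_id))
    axes[0].set_ylabel("RMSD (Å)")
    axes[0].legend(fontsize=6)
    axes[1].set_ylabel("IFP_CS")
    axes[1].set_xlabel("time (ps)")
    fig.tight_layout()
    written["timeseries_plot"] = str(out / "rmsd_ifpcs_timeseries.png")
    fig.savefig(written["timeseries_plot"], dpi=120)
    plt.close(fig)

    # pose ranking
    if pose_reports:
        ranking = pd.DataFrame(
            [
                {
                    "rank": p.rank,
                    "pose_id": p.pose_id,
                    "aggregated_ms": p.aggregated_ms,
                    "replicate_ms": ";".join(f"{v:.6f}" for v in p.replicate_ms),
                    "tied": p.tied,
                }
                for p in pose_reports
            ]
        )
        written["pose_ranking_csv"] = str(out / "pose_ranking.csv")
        ranking.to_csv(written["pose_ranking_csv"], index=False)
        written["pose_ranking_json"] = str(out / "pose_ranking.json")
        with open(written["pose_ranking_json"], "w") as fh:
            json.dump(
                [
                    {
                        "pose_id": p.pose_id,
                        "aggregated_ms": p.aggregated_ms,
                        "replicate_ms": p.replicate_ms,
                        "rank": p.rank,
                        "ligand_rmsd": p.ligand_rmsd,
                        "tied": p.tied,
                    }
                    for p in pose_reports
                ],
                fh,
                indent=2,
            )
    return written
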