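"""Model/Results interface over the full simulation pipeline.

:class:`SubtalarLigamentModel` holds a cohort of specimens plus the motion
and tunnel protocols; :meth:`~SubtalarLigamentModel.fit` runs axis
estimation, tunnel generation, intrusion classification, strain simulation
and cohort aggregation, returning a
:class:`LigamentReconstructionResults` with the tables, the selected optimal
combinations and a text ``summary()``.

Typical use::

    from subtalarsim import SubtalarLigamentModel

    model = SubtalarLigamentModel.from_synthetic_cohort(n_specimens=10, seed=7)
    res = model.fit()
    print(res.summary())
    best = res.selection.top.iloc[0]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import strain as strain_mod
from . import tunnels as tunnels_mod
from .errors import ConfigError
from .geometry import (
    RotationAxis,
    estimate_subtalar_axis,
    estimate_talocrural_axis,
    make_vertical_axis,
)
from .motion import (
    INTERNAL_EXTERNAL,
    INVERSION_EVERSION,
    MotionProtocol,
    check_protocol_clearance,
)
from .strain import CohortSummary, SelectionCriteria, SelectionResult
from .synthetic import SyntheticSpecimen, default_cohort_specs, generate_cohort
from .tunnels import ArticularSurface, orientation_label


@dataclass
class SpecimenFit:
    """Per-specimen intermediate products kept for provenance."""

    specimen_id: str
    subtalar_axis: RotationAxis
    talocrural_axis: RotationAxis
    vertical_axis: RotationAxis
    anchors: tunnels_mod.EntryExitAnchors
    talar_exits: list
    calcaneal_exits: list
    impingement: list = field(default_factory=list)


class SubtalarLigamentModel:
    """Kinematic model of candidate talocalcaneal ligament reconstructions.

    Parameters
    ----------
    specimens
        Cohort of specimens (synthetic or imported); left-sided specimens
        are mirrored into the canonical right-foot frame.
    inversion_max, inversion_step, rotation_max, rotation_step
        Motion protocol angles in degrees (defaults: 9 and 3 for both
        motions, i.e. 7 positions each).
    criteria
        Selection criteria; defaults to talar >=90% / calcaneal >=70%
        extraarticular, objective at maximal internal rotation, top 4.
    use_true_axes
        Use the specimens' stored ground-truth axes instead of estimating
        them from landmarks (synthetic specimens only; used for validation).
    """

    def __init__(
        self,
        specimens: list[SyntheticSpecimen],
        *,
        inversion_max: float = 9.0,
        inversion_step: float = 3.0,
        rotation_max: float = 9.0,
        rotation_step: float = 3.0,
        criteria: SelectionCriteria | None = None,
        use_true_axes: bool = False,
    ):
        if not specimens:
            raise ConfigError("model needs at least one specimen")
        self.specimens = [s.canonical() for s in specimens]
        self.inversion_max = inversion_max
        self.inversion_step = inversion_step
        self.rotation_max = rotation_max
        self.rotation_step = rotation_step
        self.criteria = criteria or SelectionCriteria()
        self.use_true_axes = use_true_axes

    @classmethod
    def from_synthetic_cohort(
        cls, n_specimens: int = 10, seed: int = 0, landmark_noise_sd: float = 0.1, **kwargs
    ) -> "SubtalarLigamentModel":
        """Build the model on a freshly generated synthetic cohort."""
        specs = default_cohort_specs(n=n_specimens, seed=seed, landmark_noise_sd=landmark_noise_sd)
        return cls(generate_cohort(specs), **kwargs)

    # -- fitting ----------------------------------------------------------

    def _fit_specimen(self, sp: SyntheticSpecimen, check_impingement: bool) -> tuple:
        if self.use_true_axes:
            subtalar = sp.true_subtalar_axis
            talocrural = sp.true_talocrural_axis
        else:
            subtalar = estimate_subtalar_axis(sp.landmarks)
            talocrural = estimate_talocrural_axis(sp.landmarks)
        vertical = make_vertical_axis(talocrural)

        protocols = [
            MotionProtocol(INVERSION_EVERSION, subtalar, self.inversion_max, self.inversion_step),
            MotionProtocol(INTERNAL_EXTERNAL, vertical, self.rotation_max, self.rotation_step),
        ]

        anchors = tunnels_mod.compute_entry_points(sp.talus, sp.calcaneus, subtalar)
        frame_t = tunnels_mod.build_deviation_frame(
            anchors.talar_entry, subtalar, talocrural, toward_other_bone=-1
        )
        frame_c = tunnels_mod.build_deviation_frame(
            anchors.calcaneal_entry, subtalar, talocrural, toward_other_bone=+1
        )
        exits_t = tunnels_mod.generate_exit_points(sp.talus, frame_t, "talus", anchors)
        exits_c = tunnels_mod.generate_exit_points(sp.calcaneus, frame_c, "calcaneus", anchors)

        art_t = ArticularSurface(sp.talus)
        art_c = ArticularSurface(sp.calcaneus)
        for e in exits_t:
            if not e.missed:
                tunnels_mod.classify_intrusion(e, art_t)
        for e in exits_c:
            if not e.missed:
                tunnels_mod.classify_intrusion(e, art_c)

        impingement = (
            check_protocol_clearance(sp.talus, sp.calcaneus, protocols)
            if check_impingement
            else []
        )
        fitres = SpecimenFit(
            specimen_id=sp.specimen_id,
            subtalar_axis=subtalar,
            talocrural_axis=talocrural,
            vertical_axis=vertical,
            anchors=anchors,
            talar_exits=exits_t,
            calcaneal_exits=exits_c,
            impingement=impingement,
        )
        long_df = strain_mod.specimen_length_table(exits_t, exits_c, protocols)
        long_df.insert(0, "specimen_id", sp.specimen_id)
        return fitres, long_df

    def fit(self, check_impingement: bool = True) -> "LigamentReconstructionResults":
        """Run the full pipeline over the cohort."""
        fits, long_frames, exit_rows = [], [], []
        for sp in self.specimens:
            fitres, long_df = self._fit_specimen(sp, check_impingement)
            fits.append(fitres)
            long_frames.append(long_df)
            for e in fitres.talar_exits + fitres.calcaneal_exits:
                exit_rows.append(
                    {
                        "specimen_id": sp.specimen_id,
                        "bone": e.bone,
                        "plane": e.plane if e.plane else "axis",
                        "theta": e.theta,
                        "orientation": orientation_label(e.plane, e.theta),
                        "x": np.nan if e.missed else e.point[0],
                        "y": np.nan if e.missed else e.point[1],
                        "z": np.nan if e.missed else e.point[2],
                        "face_index": e.face_index,
                        "intrusion": e.intrusion,
                        "dist_to_axis_mm": e.distance_to_axis_on_surface,
                        "missed": e.missed,
                    }
                )
        long_table = pd.concat(long_frames, ignore_index=True)
        exit_table = pd.DataFrame(exit_rows)
        summary = strain_mod.aggregate_cohort(long_table, exit_table)
        selection = strain_mod.filter_and_rank(summary, self.criteria)
        return LigamentReconstructionResults(
            model=self,
            specimen_fits=fits,
            long_table=long_table,
            exit_table=exit_table,
            cohort=summary,
            selection=selection,
        )


@dataclass
class LigamentReconstructionResults:
    """Fitted results: tables, cohort summary and ranked tunnel candidates."""

    model: SubtalarLigamentModel
    specimen_fits: list[SpecimenFit]
    long_table: pd.DataFrame
    exit_table: pd.DataFrame
    cohort: CohortSummary
    selection: SelectionResult

    # -- derived quantities ------------------------------------------------

    @property
    def n_combinations(self) -> int:
        return int(self.cohort.combos.shape[0])

    def mean_neutral_length(self) -> float:
        """Cohort mean neutral ligament length over all combinations (mm)."""
        return float(self.cohort.combos["mean_L0_mm"].mean())

    def opposite_selection(self, criteria: SelectionCriteria | None = None) -> SelectionResult:
        """Selection for the external-rotation objective under relaxed
        intrusion thresholds."""
        return strain_mod.opposite_direction_analysis(self.cohort, criteria)

    def impingement_table(self) -> pd.DataFrame:
        rows = []
        for f in self.specimen_fits:
            for rep in f.impingement:
                rows.append({"specimen_id": f.specimen_id, **rep.to_dict()})
        return pd.DataFrame(rows)

    def profile(self, talar_plane, talar_theta, calc_plane, calc_theta) -> pd.DataFrame:
        """Cohort mean/CI profile of one combination across both motions."""
        pp = self.cohort.per_position
        sel = pp[
            (pp["talar_plane"] == talar_plane)
            & (pp["talar_theta"] == talar_theta)
            & (pp["calc_plane"] == calc_plane)
            & (pp["calc_theta"] == calc_theta)
        ]
        return sel.sort_values(["motion", "alpha_deg"]).reset_index(drop=True)

    def plot_profile(self, talar_plane, talar_theta, calc_plane, calc_theta, ax=None):
        """Error-bar plot (mean +- 95% CI) of delta across both motions."""
        import matplotlib.pyplot as plt

        prof = self.profile(talar_plane, talar_theta, calc_plane, calc_theta)
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for motion, marker in ((INVERSION_EVERSION, "o"), (INTERNAL_EXTERNAL, "s")):
            sub = prof[prof["motion"] == motion]
            ax.errorbar(
                sub["alpha_deg"],
                sub["mean_delta_mm"],
                yerr=sub["ci95_halfwidth_mm"],
                marker=marker,
                capsize=3,
                label=motion.replace("_", "/"),
            )
        ax.axhline(0.0, color="0.6", lw=0.8)
        ax.set_xlabel("position α (deg)")
        ax.set_ylabel("length variation Δ (mm)")
        ax.set_title(
            f"talar {orientation_label(None if talar_plane == 'axis' else talar_plane, talar_theta)}"
            f" / calcaneal {orientation_label(None if calc_plane == 'axis' else calc_plane, calc_theta)}"
        )
        ax.legend()
        return ax

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary in the spirit of a statsmodels results table."""
        n_spec = self.cohort.n_specimens
        n_pos = self.long_table.groupby("motion")["alpha_deg"].nunique()
        lines = [
            "Subtalar ligament reconstruction - kinematic simulation",
            "=" * 60,
            f"specimens:                 {n_spec}",
            f"tunnel combinations:       {self.n_combinations}",
            f"positions (inv/eversion):  {int(n_pos.get(INVERSION_EVERSION, 0))}",
            f"positions (int/external):  {int(n_pos.get(INTERNAL_EXTERNAL, 0))}",
            f"mean neutral length L0:    {self.mean_neutral_length():.2f} mm",
            "",
            "selection criteria: talar extraarticular >= "
            f"{self.selection.criteria.talar_extraarticular_min:.0%}, "
            "calcaneal >= "
            f"{self.selection.criteria.calcaneal_extraarticular_min:.0%}",
            f"combinations passing:      {self.selection.report['n_passing']}",
            "",
        ]
        if len(self.selection.top):
            lines.append(
                f"top {len(self.selection.top)} combinations "
                "(Δ at maximal internal rotation; inversion/eversion excursion):"
            )
            for _, row in self.selection.top.iterrows():
                t_lab = orientation_label(
                    None if row["talar_plane"] == "axis" else row["talar_plane"],
                    row["talar_theta"],
                )
                c_lab = orientation_label(
                    None if row["calc_plane"] == "axis" else row["calc_plane"],
                    row["calc_theta"],
                )
                lines.append(
                    f"  {int(row['rank']):2d}. talar {t_lab:>15s} | calcaneal {c_lab:>15s}"
                    f" | Δ_IR {row['objective_delta_mm']:+.3f} mm"
                    f" ({row['objective_delta_mm'] / row['mean_L0_mm'] * 100:+.1f}% of L0)"
                    f" | iso {row['isometry_score_mm']:.4f} mm"
                )
        else:
            lines.append("no combination passed the intrusion filters")
        imp = self.impingement_table()
        if len(imp):
            n_contact = int(imp["contact"].sum())
            lines.append("")
            lines.append(
                f"impingement: {n_contact}/{len(imp)} checked positions report bone contact"
            )
        return "\n".join(lines)
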