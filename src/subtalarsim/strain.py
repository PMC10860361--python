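"""Ligament length-variation profiles, cohort aggregation and tunnel
selection.

The candidate ligament is the straight segment between a talar and a
calcaneal exit point.  Its length at a motion position alpha is the
Euclidean distance after rigidly rotating the talar exit with the talus
(the calcaneal exit stays fixed), and the reported quantity is the length
variation

    delta(alpha) = L(alpha) - L(0)        [mm, and as percent of L(0)]

computed at all seven positions of each motion.  A near-isometric
reconstruction has |delta| ~ 0 across inversion/eversion; a reconstruction
that resists internal talar rotation has large positive delta at maximal
internal rotation.

Cohort aggregation produces, per tunnel combination and position, the mean,
SD and t-based 95% CI of delta across specimens, plus per-ray extraarticular
frequencies (fraction of specimens whose exit lies off the articular
facets).  Selection keeps combinations whose talar ray is extraarticular in
at least 90% and calcaneal ray in at least 70% of specimens, then ranks by
highest mean lengthening at maximal internal rotation with the lowest
inversion/eversion excursion as tie-breaker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError
from .geometry import rotate_about_axis, rotation_matrix
from .motion import (
    INTERNAL_EXTERNAL,
    INVERSION_EVERSION,
    MotionPosition,
    MotionProtocol,
    enumerate_positions,
)
from .tunnels import ExitPoint, LigamentCombination

COMBO_KEYS = ["talar_plane", "talar_theta", "calc_plane", "calc_theta"]


# ---------------------------------------------------------------------------
# Per-combination kinematics
# ---------------------------------------------------------------------------


def ligament_length(comb: LigamentCombination, position: MotionPosition) -> float:
    """Ligament length at one motion position: the talar exit rotates with
    the talus about the position's axis, the calcaneal exit stays fixed."""
    p = rotate_about_axis(comb.talar_exit.point, position.axis, position.angle)
    return float(np.linalg.norm(p - comb.calcaneal_exit.point))


@dataclass
class StrainProfile:
    """Length and length-variation of one combination across both motions."""

    combination: LigamentCombination
    table: pd.DataFrame  # columns: motion, alpha_deg, L_mm, delta_mm, pct

    @property
    def neutral_length(self) -> float:
        return self.combination.neutral_length


def strain_profile(comb: LigamentCombination, protocols: list[MotionProtocol]) -> StrainProfile:
    """Profile of one combination over all positions of both protocols.

    delta(0) is exactly zero by construction (the neutral length is
    subtracted from itself, not recomputed through the rotation path).
    """
    if comb.neutral_length <= 1e-9:
        raise DegenerateInputError("degenerate combination: neutral length ~ 0")
    rows = []
    l0 = comb.neutral_length
    for proto in protocols:
        for pos in enumerate_positions(proto):
            length = l0 if pos.angle == 0.0 else ligament_length(comb, pos)
            delta = 0.0 if pos.angle == 0.0 else length - l0
            rows.append(
                {
                    "motion": proto.motion_type,
                    "alpha_deg": pos.angle,
                    "L_mm": length,
                    "delta_mm": delta,
                    "pct": delta / l0 * 100.0,
                }
            )
    return StrainProfile(combination=comb, table=pd.DataFrame(rows))


def specimen_length_table(
    talar_exits: list[ExitPoint],
    calcaneal_exits: list[ExitPoint],
    protocols: list[MotionProtocol],
) -> pd.DataFrame:
    """Vectorised long-format table of L and delta for every talar x
    calcaneal exit pairing at every position of both motions.

    Missed exits are excluded (their combinations are simply absent); the
    neutral row of each motion has delta exactly zero.
    """
    t_ok = [e for e in talar_exits if not e.missed]
    c_ok = [e for e in calcaneal_exits if not e.missed]
    tp = np.array([e.point for e in t_ok])  # (nt, 3)
    cp = np.array([e.point for e in c_ok])  # (nc, 3)
    l0 = np.linalg.norm(tp[:, None, :] - cp[None, :, :], axis=-1)  # (nt, nc)
    if np.any(l0 <= 1e-9):
        raise DegenerateInputError("coincident talar and calcaneal exits (L0 ~ 0)")

    frames = []
    t_meta = pd.DataFrame(
        {
            "talar_plane": [e.plane if e.plane else "axis" for e in t_ok],
            "talar_theta": [e.theta for e in t_ok],
        }
    )
    c_meta = pd.DataFrame(
        {
            "calc_plane": [e.plane if e.plane else "axis" for e in c_ok],
            "calc_theta": [e.theta for e in c_ok],
        }
    )
    # index grids for the (nt, nc) combination matrix
    ti, ci = np.meshgrid(np.arange(len(t_ok)), np.arange(len(c_ok)), indexing="ij")
    base = pd.DataFrame(
        {
            "talar_plane": t_meta["talar_plane"].to_numpy()[ti.ravel()],
            "talar_theta": t_meta["talar_theta"].to_numpy()[ti.ravel()],
            "calc_plane": c_meta["calc_plane"].to_numpy()[ci.ravel()],
            "calc_theta": c_meta["calc_theta"].to_numpy()[ci.ravel()],
            "L0_mm": l0.ravel(),
        }
    )
    for proto in protocols:
        axis = proto.axis
        for pos in enumerate_positions(proto):
            if pos.angle == 0.0:
                lengths = l0
            else:
                rot = rotation_matrix(axis.direction, pos.angle)
                tp_rot = (tp - axis.point) @ rot.T + axis.point
                lengths = np.linalg.norm(tp_rot[:, None, :] - cp[None, :, :], axis=-1)
            df = base.copy()
            df["motion"] = proto.motion_type
            df["alpha_deg"] = pos.angle
            df["L_mm"] = lengths.ravel()
            df["delta_mm"] = 0.0 if pos.angle == 0.0 else (lengths - l0).ravel()
            df["pct"] = df["delta_mm"] / df["L0_mm"] * 100.0
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Per-combination aggregates across specimens.

    ``per_position``: mean/SD/95% CI of delta at each (motion, alpha);
    ``ray_freq``: per (bone, plane, theta) extraarticular frequency;
    ``combos``: one row per combination with neutral length, frequencies and
    the number of specimens contributing.
    """

    per_position: pd.DataFrame
    ray_freq: pd.DataFrame
    combos: pd.DataFrame
    n_specimens: int
    ci_available: bool = True


def _t_ci_halfwidth(sd: np.ndarray, n: int, level: float = 0.95) -> np.ndarray:
    if n < 2:
        return np.full_like(np.asarray(sd, float), np.nan)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return tcrit * sd / np.sqrt(n)


def aggregate_cohort(
    long_df: pd.DataFrame, exit_df: pd.DataFrame, ci_level: float = 0.95
) -> CohortSummary:
    """Aggregate per-specimen results across the cohort.

    ``long_df``: concatenated specimen_length_table outputs with a
    ``specimen_id`` column; ``exit_df``: one row per (specimen, bone, ray)
    with an ``intrusion`` column.  With a single specimen, means are
    reported and SD/CI are flagged unavailable (NaN).
    """
    n = long_df["specimen_id"].nunique()
    keys = COMBO_KEYS + ["motion", "alpha_deg"]
    grp = long_df.groupby(keys, sort=True)["delta_mm"]
    per_pos = grp.agg(mean_delta_mm="mean", sd_delta_mm="std", n_specimens="count").reset_index()
    per_pos["ci95_halfwidth_mm"] = _t_ci_halfwidth(
        per_pos["sd_delta_mm"].to_numpy(), n, ci_level
    )
    per_pos["ci_low_mm"] = per_pos["mean_delta_mm"] - per_pos["ci95_halfwidth_mm"]
    per_pos["ci_high_mm"] = per_pos["mean_delta_mm"] + per_pos["ci95_halfwidth_mm"]

    ex = exit_df[~exit_df["missed"]].copy()
    ex["extra"] = (ex["intrusion"] == "extraarticular").astype(float)
    ray_freq = (
        ex.groupby(["bone", "plane", "theta"], sort=True)["extra"]
        .agg(extraarticular_freq="mean", n_specimens="count")
        .reset_index()
    )

    combo_grp = long_df[long_df["alpha_deg"] == 0.0].groupby(COMBO_KEYS, sort=True)
    combos = combo_grp.agg(
        mean_L0_mm=("L0_mm", "mean"), n_specimens=("specimen_id", "nunique")
    ).reset_index()
    freq_t = ray_freq[ray_freq["bone"] == "talus"].rename(
        columns={
            "plane": "talar_plane",
            "theta": "talar_theta",
            "extraarticular_freq": "talar_extraarticular_freq",
        }
    )[["talar_plane", "talar_theta", "talar_extraarticular_freq"]]
    freq_c = ray_freq[ray_freq["bone"] == "calcaneus"].rename(
        columns={
            "plane": "calc_plane",
            "theta": "calc_theta",
            "extraarticular_freq": "calc_extraarticular_freq",
        }
    )[["calc_plane", "calc_theta", "calc_extraarticular_freq"]]
    combos = combos.merge(freq_t, on=["talar_plane", "talar_theta"], how="left")
    combos = combos.merge(freq_c, on=["calc_plane", "calc_theta"], how="left")
    # combinations absent for some specimens (per-ray misses)
    combos["miss_count"] = n - combos["n_specimens"]
    return CohortSummary(
        per_position=per_pos,
        ray_freq=ray_freq,
        combos=combos,
        n_specimens=n,
        ci_available=n >= 2,
    )


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionCriteria:
    """Filtering and ranking rules for the optimal reconstruction.

    The objective is the mean length variation at the maximal angle of the
    internal/external motion: ``objective_direction=+1`` targets internal
    rotation (resisting the subluxation of progressive collapsing foot
    deformity), ``-1`` targets external rotation.  The isometry score is the
    largest |mean delta| over all inversion/eversion positions; smaller is
    closer to isometric.
    """

    talar_extraarticular_min: float = 0.90
    calcaneal_extraarticular_min: float = 0.70
    objective_direction: int = +1
    top_k: int = 4

    def __post_init__(self):
        # thresholds above 1 are allowed and simply select nothing
        if self.talar_extraarticular_min <= 0.0:
            raise ValueError("talar threshold must be > 0")
        if self.calcaneal_extraarticular_min <= 0.0:
            raise ValueError("calcaneal threshold must be > 0")
        if self.objective_direction not in (+1, -1):
            raise ValueError("objective_direction must be +1 or -1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class SelectionResult:
    """Ranked candidates plus a report of the filtering stage."""

    ranked: pd.DataFrame  # all passing combinations, best first
    top: pd.DataFrame  # head(top_k)
    criteria: SelectionCriteria
    report: dict = field(default_factory=dict)


def _combo_objective_table(summary: CohortSummary, objective_direction: int) -> pd.DataFrame:
    """Per-combination objective and isometry columns."""
    pp = summary.per_position
    ie = pp[pp["motion"] == INVERSION_EVERSION]
    iso = (
        ie.assign(absd=ie["mean_delta_mm"].abs())
        .groupby(COMBO_KEYS, sort=True)["absd"]
        .max()
        .rename("isometry_score_mm")
        .reset_index()
    )
    ir = pp[pp["motion"] == INTERNAL_EXTERNAL]
    target_alpha = ir["alpha_deg"].max() if objective_direction > 0 else ir["alpha_deg"].min()
    obj = (
        ir[ir["alpha_deg"] == target_alpha][COMBO_KEYS + ["mean_delta_mm", "sd_delta_mm"]]
        .rename(columns={"mean_delta_mm": "objective_delta_mm", "sd_delta_mm": "objective_sd_mm"})
        .copy()
    )
    obj["objective_alpha_deg"] = target_alpha
    out = summary.combos.merge(obj, on=COMBO_KEYS).merge(iso, on=COMBO_KEYS)
    return out


def filter_and_rank(summary: CohortSummary, criteria: SelectionCriteria) -> SelectionResult:
    """Keep combinations meeting both extraarticular-frequency thresholds and
    rank them lexicographically: descending mean delta at the objective
    position, then ascending isometry score, then a deterministic
    (talar plane, theta, calcaneal plane, theta) tie-break."""
    table = _combo_objective_table(summary, criteria.objective_direction)
    eps = 1e-12
    passing = table[
        (table["talar_extraarticular_freq"] >= criteria.talar_extraarticular_min - eps)
        & (table["calc_extraarticular_freq"] >= criteria.calcaneal_extraarticular_min - eps)
    ].copy()
    report = {
        "n_combinations": int(len(table)),
        "n_passing": int(len(passing)),
        "talar_extraarticular_min": criteria.talar_extraarticular_min,
        "calcaneal_extraarticular_min": criteria.calcaneal_extraarticular_min,
        "objective_direction": criteria.objective_direction,
    }
    if passing.empty:
        report["message"] = (
            "no combination meets both extraarticular-frequency thresholds; "
            "consider relaxing them"
        )
        return SelectionResult(
            ranked=passing, top=passing, criteria=criteria, report=report
        )
    passing["_obj"] = -passing["objective_delta_mm"]
    ranked = passing.sort_values(
        by=["_obj", "isometry_score_mm"] + COMBO_KEYS,
        kind="mergesort",  # stable: deterministic lexicographic tie-break
    ).drop(columns="_obj")
    ranked = ranked.reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return SelectionResult(
        ranked=ranked, top=ranked.head(criteria.top_k).copy(), criteria=criteria, report=report
    )


def opposite_direction_analysis(
    summary: CohortSummary, criteria: SelectionCriteria | None = None
) -> SelectionResult:
    """Selection targeting lengthening in maximal EXTERNAL rotation under
    relaxed intrusion thresholds (an articular intrusion of up to 40% of
    specimens tolerated on either bone)."""
    if criteria is None:
        criteria = SelectionCriteria(
            talar_extraarticular_min=0.60,
            calcaneal_extraarticular_min=0.60,
            objective_direction=-1,
        )
    else:
        criteria = replace(criteria, objective_direction=-1)
    return filter_and_rank(summary, criteria)
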