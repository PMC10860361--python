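"""Strain profiles, cohort aggregation and selection ranking."""

import numpy as np
import pandas as pd
import pytest

from subtalarsim import (
    DegenerateInputError,
    INTERNAL_EXTERNAL,
    INVERSION_EVERSION,
    MotionProtocol,
    RotationAxis,
    SelectionCriteria,
    aggregate_cohort,
    filter_and_rank,
    ligament_length,
    opposite_direction_analysis,
    strain_profile,
)
from subtalarsim.motion import enumerate_positions
from subtalarsim.strain import COMBO_KEYS, CohortSummary
from subtalarsim.tunnels import ExitPoint, TunnelRay, make_combination

Z_AXIS = RotationAxis([0.0, 0.0, 0.0], [0.0, 0.0, 1.0])


def _exit(bone, point, plane="medial_lateral", theta=2.0):
    return ExitPoint(
        bone=bone, ray=TunnelRay(bone=bone, plane=plane, theta=theta), point=np.asarray(point, float)
    )


def _protocols(axis_ie=Z_AXIS, axis_ir=Z_AXIS):
    return [
        MotionProtocol(INVERSION_EVERSION, axis_ie),
        MotionProtocol(INTERNAL_EXTERNAL, axis_ir),
    ]


class TestLigamentLength:
    def test_closed_form_chord_length(self):
        # talar exit (10,0,5), calcaneal (10,0,-5), z axis, alpha=9:
        # L = sqrt(100 + 200 (1 - cos 9 deg))
        comb = make_combination(_exit("talus", [10, 0, 5]), _exit("calcaneus", [10, 0, -5]))
        pos = [p for p in enumerate_positions(_protocols()[1]) if p.angle == 9][0]
        expected = np.sqrt(100.0 + 200.0 * (1.0 - np.cos(np.deg2rad(9.0))))
        got = ligament_length(comb, pos)
        assert got == pytest.approx(expected, abs=1e-9)
        # frozen from the closed form: sqrt(100 + 200 (1 - cos 9 deg)) - 10
        assert got - comb.neutral_length == pytest.approx(0.1223679, abs=1e-6)

    def test_exit_on_axis_is_isometric(self):
        comb = make_combination(_exit("talus", [0, 0, 7]), _exit("calcaneus", [3, 2, -5]))
        for pos in enumerate_positions(_protocols()[0]):
            assert ligament_length(comb, pos) == pytest.approx(comb.neutral_length, abs=1e-9)

    def test_alpha_symmetry_in_axis_plane(self):
        # both exits in the xz plane (containing the z axis): L(a) = L(-a)
        comb = make_combination(_exit("talus", [6, 0, 4]), _exit("calcaneus", [9, 0, -3]))
        proto = _protocols()[0]
        for a in (3, 6, 9):
            pos_p = [p for p in enumerate_positions(proto) if p.angle == a][0]
            pos_m = [p for p in enumerate_positions(proto) if p.angle == -a][0]
            assert ligament_length(comb, pos_p) == pytest.approx(
                ligament_length(comb, pos_m), abs=1e-9
            )


class TestStrainProfile:
    def test_profile_covers_both_motions(self):
        comb = make_combination(_exit("talus", [10, 0, 5]), _exit("calcaneus", [8, 1, -5]))
        prof = strain_profile(comb, _protocols())
        assert len(prof.table) == 14
        assert (prof.table.groupby("motion")["alpha_deg"].count() == 7).all()
        neutral = prof.table[prof.table["alpha_deg"] == 0.0]
        assert (neutral["delta_mm"] == 0.0).all()

    def test_degenerate_combination_rejected(self):
        with pytest.raises(DegenerateInputError):
            make_combination(_exit("talus", [1, 1, 1]), _exit("calcaneus", [1, 1, 1]))

    def test_baseline_combination_isometric_in_inversion_eversion(self, fit3):
        # both baseline exits lie on the (estimated) subtalar axis: the
        # inversion/eversion profile is flat to numerical precision
        lt = fit3.long_table
        base = lt[
            (lt["talar_plane"] == "axis")
            & (lt["calc_plane"] == "axis")
            & (lt["motion"] == INVERSION_EVERSION)
        ]
        assert len(base) > 0
        assert base["delta_mm"].abs().max() < 1e-9


class TestAggregation:
    def _toy_inputs(self):
        rows = []
        for sid, d in (("A", 0.2), ("B", 0.4)):
            for alpha in (-9.0, 0.0, 9.0):
                for motion in (INVERSION_EVERSION, INTERNAL_EXTERNAL):
                    rows.append(
                        {
                            "specimen_id": sid,
                            "talar_plane": "axis",
                            "talar_theta": 0.0,
                            "calc_plane": "axis",
                            "calc_theta": 0.0,
                            "motion": motion,
                            "alpha_deg": alpha,
                            "L_mm": 10.0,
                            "L0_mm": 10.0,
                            "delta_mm": 0.0 if alpha == 0 else d * np.sign(alpha),
                            "pct": 0.0,
                        }
                    )
        long_df = pd.DataFrame(rows)
        exit_df = pd.DataFrame(
            [
                {"specimen_id": s, "bone": b, "plane": "axis", "theta": 0.0,
                 "intrusion": i, "missed": False}
                for s, b, i in (
                    ("A", "talus", "extraarticular"),
                    ("B", "talus", "extraarticular"),
                    ("A", "calcaneus", "extraarticular"),
                    ("B", "calcaneus", "intraarticular"),
                )
            ]
        )
        return long_df, exit_df

    def test_mean_sd_and_ci(self):
        long_df, exit_df = self._toy_inputs()
        summary = aggregate_cohort(long_df, exit_df)
        row = summary.per_position[
            (summary.per_position["alpha_deg"] == 9.0)
            & (summary.per_position["motion"] == INTERNAL_EXTERNAL)
        ].iloc[0]
        assert row["mean_delta_mm"] == pytest.approx(0.3)
        assert row["sd_delta_mm"] == pytest.approx(np.sqrt(((0.2 - 0.3) ** 2 + (0.4 - 0.3) ** 2)), abs=1e-12)
        assert row["sd_delta_mm"] == pytest.approx(0.1414213562, abs=1e-9)
        assert row["ci_low_mm"] <= row["mean_delta_mm"] <= row["ci_high_mm"]

    def test_extraarticular_frequency(self):
        long_df, exit_df = self._toy_inputs()
        summary = aggregate_cohort(long_df, exit_df)
        combo = summary.combos.iloc[0]
        assert combo["talar_extraarticular_freq"] == 1.0
        assert combo["calc_extraarticular_freq"] == 0.5

    def test_single_specimen_has_no_ci(self):
        long_df, exit_df = self._toy_inputs()
        one = long_df[long_df["specimen_id"] == "A"]
        summary = aggregate_cohort(one, exit_df[exit_df["specimen_id"] == "A"])
        assert not summary.ci_available
        assert summary.per_position["ci95_halfwidth_mm"].isna().all()

    def test_nine_of_ten_passes_talar_threshold(self):
        assert 0.9 >= SelectionCriteria().talar_extraarticular_min


def _random_summary(rng, n_rays=5):
    """Small synthetic cohort summary with random deltas and frequencies."""
    planes = ["axis", "medial_lateral", "proximal_distal"]
    rays = [("axis", 0.0)] + [
        (p, t) for p in planes[1:] for t in (-4.0, 2.0)
    ]
    rays = rays[:n_rays]
    combos, per_rows = [], []
    for tp, tt in rays:
        for cp, ct in rays:
            tf = rng.choice([0.6, 0.8, 0.9, 1.0])
            cf = rng.choice([0.5, 0.7, 0.9, 1.0])
            combos.append(
                {
                    "talar_plane": tp, "talar_theta": tt,
                    "calc_plane": cp, "calc_theta": ct,
                    "mean_L0_mm": 10.0, "n_specimens": 3, "miss_count": 0,
                    "talar_extraarticular_freq": tf,
                    "calc_extraarticular_freq": cf,
                }
            )
            for motion in (INVERSION_EVERSION, INTERNAL_EXTERNAL):
                for alpha in (-9.0, -6.0, -3.0, 0.0, 3.0, 6.0, 9.0):
                    per_rows.append(
                        {
                            "talar_plane": tp, "talar_theta": tt,
                            "calc_plane": cp, "calc_theta": ct,
                            "motion": motion, "alpha_deg": alpha,
                            "mean_delta_mm": 0.0 if alpha == 0 else round(float(rng.normal(0, 0.3)), 6),
                            "sd_delta_mm": 0.05, "n_specimens": 3,
                            "ci95_halfwidth_mm": 0.1,
                            "ci_low_mm": 0.0, "ci_high_mm": 0.0,
                        }
                    )
    return CohortSummary(
        per_position=pd.DataFrame(per_rows),
        ray_freq=pd.DataFrame(),
        combos=pd.DataFrame(combos),
        n_specimens=3,
    )


def _brute_force_rank(summary, criteria):
    """Independent oracle: explicit python-level lexicographic sort."""
    pp = summary.per_position
    rows = []
    for _, c in summary.combos.iterrows():
        key = tuple(c[k] for k in COMBO_KEYS)
        sub = pp[(pp[COMBO_KEYS] == pd.Series(dict(zip(COMBO_KEYS, key)))).all(axis=1)]
        ir = sub[sub["motion"] == INTERNAL_EXTERNAL]
        alpha = ir["alpha_deg"].max() if criteria.objective_direction > 0 else ir["alpha_deg"].min()
        obj = float(ir[ir["alpha_deg"] == alpha]["mean_delta_mm"].iloc[0])
        iso = float(sub[sub["motion"] == INVERSION_EVERSION]["mean_delta_mm"].abs().max())
        if (
            c["talar_extraarticular_freq"] >= criteria.talar_extraarticular_min - 1e-12
            and c["calc_extraarticular_freq"] >= criteria.calcaneal_extraarticular_min - 1e-12
        ):
            rows.append((-obj, iso) + key)
    return [r[2:] for r in sorted(rows)]


class TestSelection:
    def test_matches_brute_force_oracle(self, rng):
        summary = _random_summary(rng)
        criteria = SelectionCriteria(
            talar_extraarticular_min=0.8, calcaneal_extraarticular_min=0.7, top_k=4
        )
        sel = filter_and_rank(summary, criteria)
        got = [tuple(r[k] for k in COMBO_KEYS) for _, r in sel.ranked.iterrows()]
        assert got == _brute_force_rank(summary, criteria)
        assert len(sel.top) == min(4, len(got))

    def test_unique_best_ranks_first(self, rng):
        summary = _random_summary(rng)
        pp = summary.per_position
        target = (pp["motion"] == INTERNAL_EXTERNAL) & (pp["alpha_deg"] == 9.0)
        best = ("medial_lateral", 2.0, "proximal_distal", -4.0)
        mask = target & (
            (pp[COMBO_KEYS] == pd.Series(dict(zip(COMBO_KEYS, best)))).all(axis=1)
        )
        pp.loc[mask, "mean_delta_mm"] = 99.0
        summary.combos.loc[:, ["talar_extraarticular_freq", "calc_extraarticular_freq"]] = 1.0
        sel = filter_and_rank(summary, SelectionCriteria())
        assert tuple(sel.ranked.iloc[0][k] for k in COMBO_KEYS) == best

    def test_overstrict_thresholds_give_empty_result_with_report(self, rng):
        summary = _random_summary(rng)
        sel = filter_and_rank(
            summary,
            SelectionCriteria(talar_extraarticular_min=1.01, calcaneal_extraarticular_min=1.01),
        )
        assert sel.ranked.empty and sel.top.empty
        assert "message" in sel.report
        assert sel.report["n_passing"] == 0

    def test_relaxing_thresholds_never_shrinks_pool(self, rng):
        summary = _random_summary(rng)
        strict = filter_and_rank(
            summary, SelectionCriteria(talar_extraarticular_min=0.9, calcaneal_extraarticular_min=0.7)
        )
        relaxed = filter_and_rank(
            summary, SelectionCriteria(talar_extraarticular_min=0.6, calcaneal_extraarticular_min=0.5)
        )
        strict_set = {tuple(r[k] for k in COMBO_KEYS) for _, r in strict.ranked.iterrows()}
        relaxed_set = {tuple(r[k] for k in COMBO_KEYS) for _, r in relaxed.ranked.iterrows()}
        assert strict_set <= relaxed_set

    def test_external_objective_mirrors_on_symmetric_summary(self, rng):
        # construct a sign-symmetric cohort: delta(+alpha) for calc theta +t
        # equals delta(-alpha) for calc theta -t; the external-rotation
        # winner must mirror the internal winner's calcaneal deviation sense
        summary = _random_summary(rng)
        pp = summary.per_position
        ie = pp["motion"] == INTERNAL_EXTERNAL
        pp.loc[ie, "mean_delta_mm"] = (
            np.sign(pp.loc[ie, "calc_theta"]) * pp.loc[ie, "alpha_deg"] * 0.05
        )
        summary.combos.loc[:, ["talar_extraarticular_freq", "calc_extraarticular_freq"]] = 1.0
        internal = filter_and_rank(summary, SelectionCriteria())
        external = opposite_direction_analysis(summary)
        best_int = internal.ranked.iloc[0]
        best_ext = external.ranked.iloc[0]
        assert np.sign(best_int["calc_theta"]) == -np.sign(best_ext["calc_theta"])
        assert best_ext["objective_delta_mm"] == pytest.approx(
            best_int["objective_delta_mm"], abs=1e-12
        )

    def test_full_cohort_ranked_equals_brute_force(self, fit3):
        criteria = SelectionCriteria(
            talar_extraarticular_min=0.5, calcaneal_extraarticular_min=0.5, top_k=4
        )
        sel = filter_and_rank(fit3.cohort, criteria)
        got = [tuple(r[k] for k in COMBO_KEYS) for _, r in sel.ranked.iterrows()]
        assert got == _brute_force_rank(fit3.cohort, criteria)
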