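"""Specimen and results IO, run configuration and the pipeline entry point.

Per-specimen artifacts: bone meshes as STL (binary) or PLY, plus a JSON
sidecar carrying landmarks, articular face labels, ground-truth axes and
generation metadata.  Pipeline outputs: CSV tables (exit points, long-format
strain results, cohort summary), JSON reports (selection, impingement) and a
machine-readable run manifest.  Identical config + seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import __version__
from .errors import ConfigError, DataError, GeometryError
from .geometry import LandmarkSet, RotationAxis, SurfaceMesh
from .model import LigamentReconstructionResults, SubtalarLigamentModel
from .strain import SelectionCriteria
from .synthetic import SyntheticSpecimen, default_cohort_specs, generate_cohort

#: CSV float precision: 6 significant digits (well beyond 0.01 mm reporting)
CSV_FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# Specimen round trip
# ---------------------------------------------------------------------------


def save_specimen(sp: SyntheticSpecimen, directory, mesh_format: str = "stl") -> Path:
    """Write a specimen's meshes plus a JSON sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if mesh_format not in ("stl", "ply"):
        raise ConfigError(f"unsupported mesh format {mesh_format!r}")
    paths = {}
    for name, mesh in (("talus", sp.talus), ("calcaneus", sp.calcaneus)):
        fn = directory / f"{sp.specimen_id}_{name}.{mesh_format}"
        mesh.as_trimesh().export(fn)
        paths[name] = fn.name
    sidecar = {
        "specimen_id": sp.specimen_id,
        "side": sp.side,
        "units": "mm",
        "meshes": paths,
        "face_labels": {
            "talus": sp.talus.face_labels.tolist() if sp.talus.face_labels is not None else None,
            "calcaneus": sp.calcaneus.face_labels.tolist()
            if sp.calcaneus.face_labels is not None
            else None,
        },
        "landmarks": {
            "groups": {k: v.tolist() for k, v in sp.landmarks.groups.items()},
            "points": {k: v.tolist() for k, v in sp.landmarks.points.items()},
        },
        "true_axes": {
            "subtalar": sp.true_subtalar_axis.to_dict(),
            "talocrural": sp.true_talocrural_axis.to_dict(),
            "vertical": sp.true_vertical_axis.to_dict(),
        },
        "meta": {"clearance": sp.meta.get("clearance")},
    }
    out = directory / f"{sp.specimen_id}.json"
    out.write_text(json.dumps(sidecar, sort_keys=True, indent=1))
    return out


def load_specimen(sidecar_path) -> SyntheticSpecimen:
    """Read a specimen from its sidecar + mesh files and validate it.

    Meshes must be watertight; missing facet labels raise (the intrusion
    stage cannot run without them).  The specimen is returned as stored;
    use ``.canonical()`` to mirror left feet into the right-foot frame.
    """
    sidecar_path = Path(sidecar_path)
    try:
        sc = json.loads(sidecar_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise DataError(f"cannot read sidecar {sidecar_path}: {exc}") from exc
    for key in ("specimen_id", "side", "meshes", "landmarks", "true_axes"):
        if key not in sc:
            raise DataError(f"sidecar {sidecar_path} is missing field {key!r}")
    groups = sc["landmarks"].get("groups", {})
    for grp in (LandmarkSet.CALCANEAL, LandmarkSet.NAVICULAR):
        if grp not in groups:
            raise DataError(f"sidecar landmark group {grp!r} is missing")
    meshes = {}
    for name in ("talus", "calcaneus"):
        fn = sidecar_path.parent / sc["meshes"][name]
        if not fn.exists():
            raise DataError(f"mesh file {fn} not found")
        tm = trimesh.load(fn, force="mesh", process=False)
        # STL is an unindexed triangle soup: merge duplicate vertices (face
        # order is preserved, so per-face labels stay aligned)
        tm.merge_vertices()
        labels = sc.get("face_labels", {}).get(name)
        mesh = SurfaceMesh.from_trimesh(
            tm,
            face_labels=None if labels is None else np.asarray(labels),
            side=sc["side"],
            name=name,
        )
        if not mesh.is_watertight:
            raise GeometryError(f"imported {name} mesh is not watertight")
        meshes[name] = mesh
    lm = LandmarkSet(
        groups={k: np.asarray(v) for k, v in groups.items()},
        points={k: np.asarray(v) for k, v in sc["landmarks"].get("points", {}).items()},
    )
    return SyntheticSpecimen(
        specimen_id=sc["specimen_id"],
        side=sc["side"],
        talus=meshes["talus"],
        calcaneus=meshes["calcaneus"],
        landmarks=lm,
        true_subtalar_axis=RotationAxis.from_dict(sc["true_axes"]["subtalar"]),
        true_talocrural_axis=RotationAxis.from_dict(sc["true_axes"]["talocrural"]),
        true_vertical_axis=RotationAxis.from_dict(sc["true_axes"]["vertical"]),
        meta=sc.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    n_specimens: int = 10
    seed: int = 0
    landmark_noise_sd: float = 0.1
    mesh_dir: str | None = None  # load specimens from sidecars instead of generating
    inversion_max: float = 9.0
    inversion_step: float = 3.0
    rotation_max: float = 9.0
    rotation_step: float = 3.0
    talar_extraarticular_min: float = 0.90
    calcaneal_extraarticular_min: float = 0.70
    top_k: int = 4
    check_impingement: bool = True
    output_dir: str = "results"

    def validate(self) -> None:
        for max_a, step in (
            (self.inversion_max, self.inversion_step),
            (self.rotation_max, self.rotation_step),
        ):
            if max_a <= 0 or step <= 0:
                raise ConfigError("motion angles must be positive")
            if abs(max_a / step - round(max_a / step)) > 1e-9:
                raise ConfigError(f"max angle {max_a} not divisible by step {step}")
        if self.n_specimens < 1:
            raise ConfigError("n_specimens must be >= 1")
        if self.mesh_dir is not None and not Path(self.mesh_dir).is_dir():
            raise ConfigError(f"mesh_dir {self.mesh_dir} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def criteria(self) -> SelectionCriteria:
        return SelectionCriteria(
            talar_extraarticular_min=self.talar_extraarticular_min,
            calcaneal_extraarticular_min=self.calcaneal_extraarticular_min,
            top_k=self.top_k,
        )

    def scientific_params(self) -> dict:
        """Config fields that determine the results (excludes output_dir)."""
        d = asdict(self)
        d.pop("output_dir")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.scientific_params(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_cohort(config: RunConfig) -> list[SyntheticSpecimen]:
    if config.mesh_dir is not None:
        sidecars = sorted(Path(config.mesh_dir).glob("*.json"))
        sidecars = [p for p in sidecars if p.name != "cohort_manifest.json"]
        if not sidecars:
            raise DataError(f"no specimen sidecars found in {config.mesh_dir}")
        return [load_specimen(p) for p in sidecars]
    specs = default_cohort_specs(
        n=config.n_specimens, seed=config.seed, landmark_noise_sd=config.landmark_noise_sd
    )
    return generate_cohort(specs)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> LigamentReconstructionResults:
    """Execute synth/import -> axes -> tunnels -> simulate -> aggregate ->
    select and write all outputs under ``config.output_dir``."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = _load_cohort(config)
    model = SubtalarLigamentModel(
        cohort,
        inversion_max=config.inversion_max,
        inversion_step=config.inversion_step,
        rotation_max=config.rotation_max,
        rotation_step=config.rotation_step,
        criteria=config.criteria(),
    )
    res = model.fit(check_impingement=config.check_impingement)

    _write_csv(res.exit_table, outdir / "exit_points.csv")
    _write_csv(res.long_table, outdir / "strain_long.csv")
    _write_csv(res.cohort.per_position, outdir / "cohort_summary.csv")
    _write_csv(res.cohort.ray_freq, outdir / "ray_frequencies.csv")
    _write_csv(res.cohort.combos, outdir / "combinations.csv")
    if len(res.selection.ranked):
        _write_csv(res.selection.ranked, outdir / "selection_ranked.csv")

    selection_report = {
        "criteria": asdict(res.selection.criteria),
        "report": res.selection.report,
        "top": json.loads(res.selection.top.to_json(orient="records")),
    }
    (outdir / "selection.json").write_text(
        json.dumps(selection_report, sort_keys=True, indent=1)
    )
    imp = res.impingement_table()
    (outdir / "impingement.json").write_text(
        json.dumps(
            json.loads(imp.to_json(orient="records")) if len(imp) else [],
            sort_keys=True,
            indent=1,
        )
    )
    manifest = {
        "software": "subtalarsim",
        "version": __version__,
        "config": config.scientific_params(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_specimens": len(cohort),
        "n_combinations": res.n_combinations,
        "n_positions": {
            motion: int(n)
            for motion, n in res.long_table.groupby("motion")["alpha_deg"].nunique().items()
        },
        "n_evaluations": int(len(res.long_table)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return res


def synthesize_cohort_to_dir(config: RunConfig, directory, mesh_format: str = "stl") -> list[Path]:
    """Generate the synthetic cohort and write per-specimen artifacts plus a
    cohort manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort = _load_cohort(config)
    paths = [save_specimen(sp, directory, mesh_format=mesh_format) for sp in cohort]
    manifest = {
        "n_specimens": len(cohort),
        "seed": config.seed,
        "specimens": [p.name for p in paths],
    }
    (directory / "cohort_manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return paths
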