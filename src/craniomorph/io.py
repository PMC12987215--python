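"""Readers/writers and the end-to-end pipeline runner.

On-disk formats: cloud CSV (one row per vertex), PLY point export,
feature-table CSV, YAML run configuration and JSON results.  The CSV
dialect is fixed: comma separator, dot decimal, UTF-8, mandatory header.
"""

from __future__ import annotations

import hashlib
import json
import logging
import struct
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from craniomorph import __version__
from craniomorph.augment import NoiseSpec, ScalePlan, augment_cohort
from craniomorph.cloud import N_SLOTS, HeadCloud, slot_role
from craniomorph.descriptors import DESCRIPTOR_COLUMNS, build_feature_table
from craniomorph.errors import CloudSchemaError, ConfigError, CraniomorphError
from craniomorph.headgen import CohortPlan, generate_cohort
from craniomorph.mlsuite import RATIO_PRESETS, run_experiment_matrix

logger = logging.getLogger("craniomorph")

CLOUD_CSV_COLUMNS = [
    "cloud_id",
    "base_id",
    "class_label",
    "marker_slot",
    "role",
    "vertex_index",
    "x_mm",
    "y_mm",
    "z_mm",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one, keyed by stage name."""
    key = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([int(global_seed), key]).generate_state(1)[0])


# ---------------------------------------------------------------------------
# Cloud CSV
# ---------------------------------------------------------------------------


def write_cloud_csv(clouds: Sequence[HeadCloud], path: str | Path) -> None:
    """One row per vertex of every present marker."""
    records = []
    for cloud in clouds:
        for slot in range(1, N_SLOTS + 1):
            if not cloud.present[slot - 1]:
                continue
            verts = cloud.marker_vertices(slot)
            for vi in range(4):
                records.append(
                    (
                        cloud.cloud_id,
                        cloud.base_id,
                        cloud.class_label,
                        slot,
                        slot_role(slot),
                        vi,
                        verts[vi, 0],
                        verts[vi, 1],
                        verts[vi, 2],
                    )
                )
    df = pd.DataFrame.from_records(records, columns=CLOUD_CSV_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_cloud_csv(path: str | Path) -> list[HeadCloud]:
    """Reconstruct clouds from the vertex CSV; validates the schema on load."""
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise CloudSchemaError(f"no clouds in {path}: {exc}") from exc
    missing_cols = set(CLOUD_CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise CloudSchemaError(f"{path}: missing columns {sorted(missing_cols)}")
    if df.empty:
        raise CloudSchemaError(f"no clouds in {path}")

    bad = df[~df["marker_slot"].between(1, N_SLOTS)]
    if not bad.empty:
        line = int(bad.index[0]) + 2  # header + 1-based
        raise CloudSchemaError(f"{path}:{line}: marker_slot outside 1..{N_SLOTS}")

    clouds = []
    for cloud_id, group in df.groupby("cloud_id", sort=False):
        vertices = np.full((N_SLOTS, 4, 3), np.nan)
        present = np.zeros(N_SLOTS, dtype=bool)
        for slot, marker in group.groupby("marker_slot"):
            if len(marker) != 4 or sorted(marker["vertex_index"]) != [0, 1, 2, 3]:
                raise CloudSchemaError(
                    f"{path}: cloud {cloud_id!r} marker slot {slot} has "
                    f"{len(marker)} vertices, expected 4"
                )
            ordered = marker.sort_values("vertex_index")
            vertices[slot - 1] = ordered[["x_mm", "y_mm", "z_mm"]].to_numpy()
            present[slot - 1] = True
        first = group.iloc[0]
        clouds.append(
            HeadCloud(
                cloud_id=str(cloud_id),
                base_id=str(first["base_id"]),
                class_label=str(first["class_label"]),
                vertices=vertices,
                present=present,
                provenance="loaded",
            )
        )
    return clouds


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------


def _slot_colour(slot: int) -> tuple[int, int, int]:
    # deterministic hue per slot; reference stickers get fixed colours
    role = slot_role(slot)
    if role == "ref_front":
        return (255, 165, 0)
    if role == "ref_left":
        return (0, 200, 0)
    if role == "ref_right":
        return (200, 0, 0)
    h = zlib.crc32(str(slot).encode())
    return (64 + h % 192, 64 + (h >> 8) % 192, 64 + (h >> 16) % 192)


def write_ply(cloud: HeadCloud, path: str | Path) -> None:
    """Binary little-endian PLY: float32 xyz + uchar rgb per vertex."""
    n = cloud.n_vertices
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"comment craniomorph {__version__} cloud_id={cloud.cloud_id}\n"
        f"element vertex {n}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        for slot in range(1, N_SLOTS + 1):
            if not cloud.present[slot - 1]:
                continue
            r, g, b = _slot_colour(slot)
            for v in cloud.marker_vertices(slot):
                fh.write(struct.pack("<fffBBB", v[0], v[1], v[2], r, g, b))


def read_ply_vertices(path: str | Path) -> np.ndarray:
    """Read back the xyz coordinates of a PLY written by :func:`write_ply`."""
    with open(path, "rb") as fh:
        data = fh.read()
    head, _, body = data.partition(b"end_header\n")
    header = head.decode("ascii")
    if "format binary_little_endian 1.0" not in header:
        raise CraniomorphError(f"{path}: not a binary little-endian PLY")
    n = int(next(l.split()[-1] for l in header.splitlines() if l.startswith("element vertex")))
    out = np.empty((n, 3), dtype=np.float32)
    rec = struct.Struct("<fffBBB")
    for i in range(n):
        x, y, z, *_ = rec.unpack_from(body, i * rec.size)
        out[i] = (x, y, z)
    return out


# ---------------------------------------------------------------------------
# Feature table CSV
# ---------------------------------------------------------------------------


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, encoding="utf-8")


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = set(["cloud_id", "base_id", "label_code"] + DESCRIPTOR_COLUMNS) - set(df.columns)
    if missing:
        raise CraniomorphError(f"{path}: missing feature columns {sorted(missing)[:5]}")
    if "split" not in df.columns:
        df["split"] = "unassigned"
    return df


def write_manifest(clouds: Sequence[HeadCloud], path: str | Path) -> None:
    """Augmentation provenance manifest (cloud_id, base_id, factor, mode, noise_seed)."""
    rows = []
    for c in clouds:
        prov = c.provenance
        if hasattr(prov, "factor"):
            rows.append(
                {
                    "cloud_id": c.cloud_id,
                    "base_id": c.base_id,
                    "factor": prov.factor,
                    "mode": prov.mode.value,
                    "noise_seed": prov.noise_seed,
                }
            )
        else:
            rows.append(
                {
                    "cloud_id": c.cloud_id,
                    "base_id": c.base_id,
                    "factor": 1.0,
                    "mode": "",
                    "noise_seed": -1,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Full pipeline configuration; one global seed drives every stage."""

    out_dir: Path
    seed: int = 0
    cohort: CohortPlan = None  # type: ignore[assignment]
    scale: ScalePlan = None  # type: ignore[assignment]
    noise: NoiseSpec = None  # type: ignore[assignment]
    ratio_presets: dict = field(default_factory=lambda: dict(RATIO_PRESETS))
    eval_seeds: tuple[int, ...] = (0,)
    group_level: str = "sample"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.cohort is None:
            self.cohort = CohortPlan(seed=stage_seed(self.seed, "generate"))
        if self.scale is None:
            self.scale = ScalePlan(seed=stage_seed(self.seed, "scale"))
        if self.noise is None:
            self.noise = NoiseSpec(seed=stage_seed(self.seed, "noise"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"configuration file not found: {path}")
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        seed = int(raw.get("seed", 0))
        out_dir = raw.get("out_dir", "craniomorph-run")
        kwargs: dict = {"out_dir": out_dir, "seed": seed}
        if "cohort" in raw:
            c = raw["cohort"]
            kwargs["cohort"] = CohortPlan(
                class_counts=c.get("class_counts", None) or CohortPlan().class_counts,
                dropout_histogram={
                    k: {int(dk): dv for dk, dv in v.items()}
                    for k, v in c["dropout_histogram"].items()
                }
                if "dropout_histogram" in c
                else CohortPlan().dropout_histogram,
                seed=c.get("seed", stage_seed(seed, "generate")),
            )
        if "scale" in raw:
            s = dict(raw["scale"])
            s.setdefault("seed", stage_seed(seed, "scale"))
            kwargs["scale"] = ScalePlan(**s)
        if "noise" in raw:
            n = dict(raw["noise"])
            n.setdefault("seed", stage_seed(seed, "noise"))
            kwargs["noise"] = NoiseSpec(**n)
        if "eval_seeds" in raw:
            kwargs["eval_seeds"] = tuple(raw["eval_seeds"])
        if "group_level" in raw:
            kwargs["group_level"] = raw["group_level"]
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "cohort": {
                    "class_counts": dict(self.cohort.class_counts),
                    "dropout": {k: dict(v) for k, v in self.cohort.dropout_histogram.items()},
                    "seed": self.cohort.seed,
                },
                "scale": asdict(self.scale),
                "noise": asdict(self.noise),
                "eval_seeds": list(self.eval_seeds),
                "group_level": self.group_level,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """generate -> augment -> features -> train -> report.

    Writes all artifacts under ``config.out_dir`` and returns a summary
    dict with paths and headline counts.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stamp = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    summary: dict = dict(stamp)

    def _stage(name: str):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    try:
        t = _stage("generate")
        bases = generate_cohort(config.cohort)
        write_cloud_csv(bases, out / "bases.csv")
        summary["n_bases"] = len(bases)
        logger.info("generate: %d base clouds in %.1fs", len(bases), time.perf_counter() - t)
    except Exception as exc:
        raise CraniomorphError(f"stage generate failed: {exc}") from exc

    try:
        t = _stage("augment")
        augmented = augment_cohort(bases, config.scale, config.noise)
        write_manifest(augmented, out / "manifest.csv")
        summary["n_augmented"] = len(augmented)
        logger.info("augment: %d clouds in %.1fs", len(augmented), time.perf_counter() - t)
    except Exception as exc:
        raise CraniomorphError(f"stage augment failed: {exc}") from exc

    try:
        t = _stage("features")
        table = build_feature_table(augmented)
        write_feature_csv(table, out / "features.csv")
        summary["n_rows"] = len(table)
        summary["n_descriptor_columns"] = len(DESCRIPTOR_COLUMNS)
        logger.info("features: %d rows in %.1fs", len(table), time.perf_counter() - t)
    except Exception as exc:
        raise CraniomorphError(f"stage features failed: {exc}") from exc

    try:
        t = _stage("train")
        report = run_experiment_matrix(
            table, seeds=config.eval_seeds, group_level=config.group_level
        )
        logger.info("train: %d results in %.1fs", len(report["results"]), time.perf_counter() - t)
    except Exception as exc:
        raise CraniomorphError(f"stage train failed: {exc}") from exc

    try:
        metrics = report["metrics"]
        timing = report["timing"]
        metrics.to_csv(out / "metrics.csv", index=False)
        timing.to_csv(out / "timing.csv", index=False)
        results_json = {
            **stamp,
            "metrics": metrics.to_dict(orient="records"),
            "timing": timing.to_dict(orient="records"),
        }
        with open(out / "results.json", "w", encoding="utf-8") as fh:
            json.dump(results_json, fh, indent=2)
        with open(out / "report.md", "w", encoding="utf-8") as fh:
            fh.write(render_report(metrics, timing, stamp))
        summary["n_report_cells"] = len(metrics) * 2
    except Exception as exc:
        raise CraniomorphError(f"stage report failed: {exc}") from exc

    with open(out / "run.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def render_report(metrics: pd.DataFrame, timing: pd.DataFrame, stamp: dict) -> str:
    """Markdown report mirroring the metric-grid row layout."""
    lines = [
        "# craniomorph benchmark report",
        "",
        f"- config hash: `{stamp.get('config_hash', '?')}`",
        f"- seed: {stamp.get('seed', '?')}",
        f"- package version: {stamp.get('version', '?')}",
        "",
        "## Precision / recall / F1 (macro)",
        "",
        "| Ratios | Model | P(high) | R(high) | F1(high) | P(low) | R(low) | F1(low) |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for _, r in metrics.iterrows():
        lines.append(
            f"| {r['ratios']} | {r['model']} "
            f"| {r['precision_high']:.2f} | {r['recall_high']:.2f} | {r['f1_high']:.2f} "
            f"| {r['precision_low']:.2f} | {r['recall_low']:.2f} | {r['f1_low']:.2f} |"
        )
    lines += ["", "## Timing (fit + predict seconds)", "", "| Ratios | Model | high | low |", "|---|---|---|---|"]
    for _, r in timing.iterrows():
        lines.append(
            f"| {r['ratios']} | {r['model']} | {r['seconds_high']:.2f} | {r['seconds_low']:.2f} |"
        )
    return "\n".join(lines) + "\n"
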