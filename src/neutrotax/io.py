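"""File formats and pipeline configuration.

Track CSV dialect (shared by simulated and measured tracks so either feeds
the same downstream analysis): UTF-8, '.' decimal, header line
``track_id,frame,time_s,x_um,y_um,condition`` preceded by ``#`` comment
lines, one of which records the gradient axis.  Image stacks are multi-page
16-bit TIFF.  Pipeline configuration is a flat ``key = value`` text file
whose keys mirror :class:`PipelineConfig`; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .gradient import ChannelGeometry
from .simulate import AssayConfig, SyntheticCohort, Track

__all__ = [
    "PipelineConfig",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_stack",
    "read_stack",
    "write_cohort_manifest",
    "write_summary_tsv",
]

TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_um", "y_um", "condition"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with documented defaults.

    Distances are µm, times s, speeds µm/s; pixel→µm conversion happens at
    detection and nowhere else.
    """

    channel_width: float = 350.0
    channel_height: float = 100.0
    frame_interval: float = 10.0
    n_frames: int = 120
    pixel_size: float = 1.0
    field_length: float = 1000.0
    gradient_axis_x: float = 0.0
    gradient_axis_y: float = -1.0
    max_displacement: float | None = None  # default derived from speed law
    max_gap: int = 0
    min_track_length: int = 10
    min_area: float = 20.0
    morphology_frame: int = -1
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "results"

    def assay_config(self) -> AssayConfig:
        return AssayConfig(
            geometry=ChannelGeometry(width=self.channel_width, height=self.channel_height),
            frame_interval=self.frame_interval,
            n_frames=self.n_frames,
            pixel_size=self.pixel_size,
            gradient_axis=(self.gradient_axis_x, self.gradient_axis_y),
            field_length=self.field_length,
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file; unknown keys rejected."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            ftype = known[key].type
            if value.lower() in ("none", "na"):
                kwargs[key] = None
            elif "int" in str(ftype):
                kwargs[key] = int(value)
            elif "float" in str(ftype):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_tracks_csv(tracks: list[Track], path, gradient_axis=(0.0, -1.0)) -> None:
    """Write tracks in the shared CSV dialect with a gradient-axis header."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        ax = np.asarray(gradient_axis, dtype=float)
        fh.write(f"# gradient_axis = {ax[0]:g},{ax[1]:g}\n")
        fh.write(",".join(TRACK_COLUMNS) + "\n")
        for tr in tracks:
            for f, (t, (x, y)) in enumerate(zip(tr.t, tr.xy)):
                fh.write(
                    f"{tr.track_id},{f},{t:.6g},{x:.6f},{y:.6f},{tr.condition_label}\n"
                )


def read_tracks_csv(path) -> tuple[list[Track], np.ndarray]:
    """Read the track CSV dialect; returns (tracks, gradient_axis).

    A malformed data row raises with its line number.
    """
    path = Path(path)
    axis = np.array([0.0, -1.0])
    rows: dict[int, list[tuple[int, float, float, float, str]]] = {}
    header_seen = False
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "gradient_axis" in line and "=" in line:
                    vals = line.split("=", 1)[1].split(",")
                    axis = np.array([float(v) for v in vals])
                continue
            if not header_seen:
                if [c.strip() for c in line.split(",")] != TRACK_COLUMNS:
                    raise ValueError(f"{path}:{lineno}: bad header {line!r}")
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != len(TRACK_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(TRACK_COLUMNS)} fields, got {len(parts)}"
                )
            try:
                tid = int(parts[0])
                frame = int(parts[1])
                t = float(parts[2])
                x, y = float(parts[3]), float(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            rows.setdefault(tid, []).append((frame, t, x, y, parts[5]))
    if not header_seen:
        raise ValueError(f"{path}: missing header line")
    if not rows:
        raise ValueError(f"{path}: no track rows (header-only file)")
    tracks = []
    for tid in sorted(rows):
        entries = sorted(rows[tid])
        tracks.append(
            Track(
                track_id=tid,
                t=np.array([e[1] for e in entries]),
                xy=np.array([[e[2], e[3]] for e in entries]),
                condition_label=entries[0][4],
            )
        )
    return tracks, axis


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (T, H, W) array as a multi-page 16-bit TIFF."""
    tifffile.imwrite(path, np.asarray(stack).astype(np.uint16), photometric="minisblack")


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr if arr.ndim == 3 else arr[None]


def write_cohort_manifest(cohort: SyntheticCohort, path) -> pd.DataFrame:
    """Write the per-subject manifest (clinical columns + ground truths)."""
    rows = []
    for s in cohort.subjects:
        rows.append(
            dict(
                subject_id=s.subject_id,
                group=s.group,
                age=s.age,
                sex=s.sex,
                FVC_L=s.fvc_l,
                FEV1_L=s.fev1_l,
                FEV1_FVC_pct=s.fev1_fvc_pct,
                potency=s.potency,
                target_ci=s.target_ci,
                kappa_true=s.kappa_true,
                mean_speed_true=s.mean_speed_true,
                n_tracks=len(s.tracks),
            )
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, na_rep="NA", float_format="%.6g")
    return df


def write_summary_tsv(rows: list[dict], path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
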