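"""Plain-text I/O: waveform/contour/map CSV formats and study directories.

Formats
-------
* Waveform CSV: two columns ``time_s,value`` with a header; a JSON sidecar
  ``<name>.json`` may carry ``r_wave_times_s``, ``kind``, ``rr_s`` and
  ``site_position_m`` for multi-cycle recordings.
* Contour CSV: columns ``slice_id,phase_id,point_index,x_mm,y_mm``.
* Velocity maps: one CSV matrix per frame in a directory plus a
  ``header.json`` with component, pixel spacing, phase times and VENC.
* Study directory: ``manifest.json`` + per-subject subdirectories +
  ``truth.csv`` (written by ``aortapwv simulate``, consumed by
  ``aortapwv reproduce-study``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortConfig, SubjectData, SubjectTruth
from .errors import ManifestError
from .geometry import LumenContour, VelocityMapSeries
from .waveforms import MultiCycleRecording, SampledWaveform

__all__ = [
    "read_waveform_csv",
    "write_waveform_csv",
    "read_recording",
    "read_contours_csv",
    "write_contours_csv",
    "read_velocity_maps",
    "write_velocity_maps",
    "write_study",
    "load_study",
    "read_tidy_methods_csv",
]

_FLOAT_FMT = "%.12g"


def write_waveform_csv(
    path: str | Path,
    waveform: SampledWaveform,
    *,
    r_wave_times_s: Sequence[float] | None = None,
    site_position_m: float | None = None,
) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": waveform.times, "value": waveform.values})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = {"kind": waveform.kind, "rr_s": waveform.rr_s}
    if r_wave_times_s is not None:
        sidecar["r_wave_times_s"] = list(map(float, r_wave_times_s))
    if site_position_m is not None:
        sidecar["site_position_m"] = float(site_position_m)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, sort_keys=True)
        fh.write("\n")


def _read_sidecar(path: Path) -> dict:
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            return json.load(fh)
    return {}


def read_waveform_csv(
    path: str | Path, *, kind: str | None = None, rr_s: float | None = None
) -> SampledWaveform:
    """Read a ``time_s,value`` CSV (sidecar supplies kind/rr when present)."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ManifestError(f"{path}: expected columns time_s,value")
    side = _read_sidecar(path)
    kind = kind or side.get("kind")
    rr_s = rr_s or side.get("rr_s")
    if kind is None or rr_s is None:
        raise ManifestError(f"{path}: waveform kind/rr_s not given and no sidecar")
    t = df["time_s"].to_numpy()
    dt = float(np.mean(np.diff(t)))
    return SampledWaveform(
        start_time_s=float(t[0]),
        sample_interval_s=dt,
        values=df["value"].to_numpy(),
        kind=kind,
        rr_s=float(rr_s),
    )


def read_recording(path: str | Path) -> MultiCycleRecording:
    """Read a multi-cycle recording: waveform CSV + sidecar with triggers."""
    path = Path(path)
    side = _read_sidecar(path)
    if "r_wave_times_s" not in side:
        raise ManifestError(f"{path}: sidecar with r_wave_times_s required")
    wf = read_waveform_csv(path)
    return MultiCycleRecording(
        waveform=wf,
        r_wave_times_s=np.asarray(side["r_wave_times_s"], dtype=float),
        site_position_m=float(side.get("site_position_m", 0.0)),
    )


def write_contours_csv(path: str | Path, contours: Sequence[LumenContour]) -> None:
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.polygon):
            rows.append(
                {
                    "slice_id": c.slice_id,
                    "phase_id": c.phase_id,
                    "point_index": i,
                    "x_mm": x,
                    "y_mm": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_contours_csv(path: str | Path) -> list[LumenContour]:
    df = pd.read_csv(path)
    needed = {"slice_id", "phase_id", "point_index", "x_mm", "y_mm"}
    if not needed <= set(df.columns):
        raise ManifestError(f"{path}: expected columns {sorted(needed)}")
    out = []
    for (sl, ph), grp in df.groupby(["slice_id", "phase_id"], sort=True):
        grp = grp.sort_values("point_index")
        out.append(
            LumenContour(
                slice_id=int(sl),
                phase_id=int(ph),
                polygon=grp[["x_mm", "y_mm"]].to_numpy(),
            )
        )
    return out


def write_velocity_maps(dir_path: str | Path, maps: VelocityMapSeries) -> None:
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    header = {
        "component": maps.component,
        "pixel_spacing_mm": list(maps.pixel_spacing_mm),
        "phase_times_s": [float(t) for t in maps.phase_times_s],
        "venc_m_per_s": maps.venc_m_per_s,
    }
    with open(d / "header.json", "w") as fh:
        json.dump(header, fh, sort_keys=True)
        fh.write("\n")
    for k in range(maps.n_phases):
        np.savetxt(d / f"frame_{k:03d}.csv", maps.frames[k], fmt=_FLOAT_FMT, delimiter=",")


def read_velocity_maps(dir_path: str | Path) -> VelocityMapSeries:
    d = Path(dir_path)
    header_path = d / "header.json"
    if not header_path.exists():
        raise ManifestError(f"{d}: missing header.json")
    with open(header_path) as fh:
        header = json.load(fh)
    files = sorted(d.glob("frame_*.csv"))
    if not files:
        raise ManifestError(f"{d}: no frame CSVs")
    frames = np.stack([np.loadtxt(f, delimiter=",") for f in files])
    return VelocityMapSeries(
        component=header["component"],
        frames=frames,
        pixel_spacing_mm=tuple(header["pixel_spacing_mm"]),
        phase_times_s=np.asarray(header["phase_times_s"], dtype=float),
        venc_m_per_s=float(header["venc_m_per_s"]),
    )


# ---------------------------------------------------------------------------
# study directories


def write_study(dir_path: str | Path, cohort: Cohort, *, cfg_hash: str) -> None:
    """Write a simulated study directory (manifest, streams, truth table)."""
    root = Path(dir_path)
    root.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    manifest: dict = {
        "schema": "aortapwv-study/1",
        "seed": cfg.seed,
        "config_hash": cfg_hash,
        "site1_m": cfg.site1_m,
        "site2_m": cfg.site2_m,
        "pullback_step_m": cfg.pullback_step_m,
        "rho": cfg.rho,
        "subjects": [],
    }
    for s in cohort.subjects:
        sdir = root / s.subject_id
        sdir.mkdir(exist_ok=True)
        entry: dict = {
            "id": s.subject_id,
            "rr_s": s.rr_s,
            "cuff_pp_mmHg": s.cuff_pp_mmHg,
            "pullback": [],
            "tp": [],
        }
        for i, rec in enumerate(s.pullback):
            rel = f"{s.subject_id}/pullback_{i:02d}.csv"
            write_waveform_csv(
                root / rel,
                rec.waveform,
                r_wave_times_s=rec.r_wave_times_s,
                site_position_m=rec.site_position_m,
            )
            entry["pullback"].append(
                {"file": rel, "site_position_m": rec.site_position_m}
            )
        chord_rows = []
        for pos, curve in zip(s.chord_positions_m, s.chord_curves):
            for t, v in zip(curve.times, curve.values):
                chord_rows.append(
                    {"arc_position_m": pos, "time_s": t, "velocity_m_per_s": v}
                )
        rel = f"{s.subject_id}/chords.csv"
        pd.DataFrame(chord_rows).to_csv(root / rel, index=False, float_format=_FLOAT_FMT)
        entry["chords"] = rel
        for name, pos, curve in zip(
            ("tp_site1", "tp_site2"), s.tp_positions_m, s.tp_curves
        ):
            rel = f"{s.subject_id}/{name}.csv"
            write_waveform_csv(root / rel, curve, site_position_m=pos)
            entry["tp"].append({"file": rel, "site_position_m": pos})
        rel = f"{s.subject_id}/area.csv"
        write_waveform_csv(root / rel, s.area_curve)
        entry["area"] = rel
        manifest["subjects"].append(entry)
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    cohort.truth_table().to_csv(root / "truth.csv", index=False, float_format=_FLOAT_FMT)


def load_study(dir_path: str | Path) -> tuple[list[SubjectData], dict]:
    """Load a study directory; returns (subjects, manifest).

    A subject with a missing stream raises :class:`ManifestError` mentioning
    the stream; callers may drop such subjects.
    """
    root = Path(dir_path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise ManifestError(f"{root}: missing manifest.json")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    subjects = []
    for entry in manifest["subjects"]:
        sid = entry["id"]
        try:
            pullback = []
            for rec in entry["pullback"]:
                f = root / rec["file"]
                if not f.exists():
                    raise ManifestError(f"{sid}: missing {rec['file']}")
                pullback.append(read_recording(f))
            chords_file = root / entry["chords"]
            if not chords_file.exists():
                raise ManifestError(f"{sid}: missing {entry['chords']}")
            cdf = pd.read_csv(chords_file)
            rr = float(entry["rr_s"])
            positions = np.sort(cdf["arc_position_m"].unique())
            curves = []
            for pos in positions:
                grp = cdf[cdf["arc_position_m"] == pos].sort_values("time_s")
                t = grp["time_s"].to_numpy()
                curves.append(
                    SampledWaveform(
                        start_time_s=float(t[0]),
                        sample_interval_s=float(np.mean(np.diff(t))),
                        values=grp["velocity_m_per_s"].to_numpy(),
                        kind="velocity",
                        rr_s=rr,
                    )
                )
            tp_curves = []
            tp_positions = []
            for rec in entry["tp"]:
                f = root / rec["file"]
                if not f.exists():
                    raise ManifestError(f"{sid}: missing {rec['file']}")
                tp_curves.append(read_waveform_csv(f))
                tp_positions.append(float(rec["site_position_m"]))
            area_file = root / entry["area"]
            if not area_file.exists():
                raise ManifestError(f"{sid}: missing {entry['area']}")
            area = read_waveform_csv(area_file)
        except ManifestError:
            raise
        subjects.append(
            SubjectData(
                subject_id=sid,
                rr_s=rr,
                pullback=tuple(pullback),
                chord_positions_m=positions,
                chord_curves=tuple(curves),
                tp_positions_m=(tp_positions[0], tp_positions[1]),
                tp_curves=(tp_curves[0], tp_curves[1]),
                area_curve=area,
                cuff_pp_mmHg=float(entry["cuff_pp_mmHg"]),
                truth=None,
            )
        )
    return subjects, manifest


def read_tidy_methods_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy ``subject,method,value`` table for agreement analysis."""
    df = pd.read_csv(path)
    if not {"subject", "method", "value"} <= set(df.columns):
        raise ManifestError(f"{path}: expected columns subject,method,value")
    return df
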