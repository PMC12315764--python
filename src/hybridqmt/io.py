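"""File formats: schedule CSV, fingerprint CSV/NIfTI, parameter maps, config.

Conventions: SI units inside arrays (seconds, rad, 1/s); NIfTI volumes are
written float32 with the input affine passed through untouched (identity
for synthetic phantoms); CSV/JSON keep full precision.  All writers produce
files the corresponding readers round-trip bit-stably (float32 precision
for NIfTI volumes).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .spin_model import RFPulse, SequenceSchedule

SCHEDULE_COLUMNS = ("alpha_rad", "TRF_s", "TR_s")


def write_schedule_csv(path, schedule: SequenceSchedule) -> None:
    """Schedule CSV: '# key=value' metadata lines, then one row per repetition."""
    path = Path(path)
    lines = [f"# name={schedule.name}",
             f"# omega_z_rad_s={schedule.omega_z!r}",
             f"# b1_scale={schedule.b1_scale!r}",
             f"# phase_alternation={int(schedule.phase_alternation)}"]
    if schedule.inversion is not None:
        lines += [f"# inversion_alpha_rad={schedule.inversion.alpha!r}",
                  f"# inversion_TRF_s={schedule.inversion.TRF!r}"]
    lines.append(",".join(SCHEDULE_COLUMNS))
    for a, trf, tr in zip(schedule.alpha, schedule.TRF, schedule.TR):
        lines.append(f"{float(a)!r},{float(trf)!r},{float(tr)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_schedule_csv(path) -> SequenceSchedule:
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    header = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
            continue
        if header is None:
            header = [c.strip() for c in line.split(",")]
            missing = set(SCHEDULE_COLUMNS) - set(header)
            if missing:
                raise ValueError(f"schedule CSV missing columns {sorted(missing)}")
            continue
        rows.append([float(v) for v in line.split(",")])
    if header is None or not rows:
        raise ValueError(f"no schedule data in {path}")
    arr = np.asarray(rows)
    col = {c: arr[:, header.index(c)] for c in SCHEDULE_COLUMNS}
    inversion = None
    if "inversion_alpha_rad" in meta:
        inversion = RFPulse(alpha=float(meta["inversion_alpha_rad"]),
                            TRF=float(meta.get("inversion_TRF_s", 500e-6)))
    return SequenceSchedule(
        alpha=col["alpha_rad"], TRF=col["TRF_s"], TR=col["TR_s"],
        inversion=inversion,
        omega_z=float(meta.get("omega_z_rad_s", 0.0)),
        b1_scale=float(meta.get("b1_scale", 1.0)),
        phase_alternation=bool(int(meta.get("phase_alternation", 1))),
        name=meta.get("name", path.stem))


def write_fingerprint_csv(path, fingerprint: np.ndarray) -> None:
    s = np.asarray(fingerprint)
    pd.DataFrame({"t_index": np.arange(s.size), "real": s.real,
                  "imag": s.imag}).to_csv(path, index=False)


def read_fingerprint_csv(path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("t_index", "real", "imag"):
        if c not in df.columns:
            raise ValueError(f"fingerprint CSV missing column {c!r}")
    df = df.sort_values("t_index")
    return df["real"].to_numpy() + 1j * df["imag"].to_numpy()


def write_complex_nifti(path, data: np.ndarray, affine=None) -> None:
    """Complex 4-D series as a 4-D NIfTI with real/imag volumes interleaved
    along the last axis (two volumes per timepoint)."""
    data = np.asarray(data)
    if affine is None:
        affine = np.eye(4)
    out = np.empty(data.shape[:3] + (2 * data.shape[3],), np.float32)
    out[..., 0::2] = data.real
    out[..., 1::2] = data.imag
    nib.save(nib.Nifti1Image(out, affine), str(path))


def read_complex_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, np.float32)
    if arr.ndim != 4 or arr.shape[3] % 2:
        raise ValueError(f"{path}: expected 4-D NIfTI with interleaved real/imag volumes")
    data = arr[..., 0::2].astype(np.float64) + 1j * arr[..., 1::2].astype(np.float64)
    return data, img.affine


def write_map_nifti(path, volume: np.ndarray, affine=None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float32), affine), str(path))


def read_map_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, np.float32).astype(np.float64), img.affine


def load_config(path) -> dict:
    """YAML pipeline config; raises with the offending key on bad values."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return cfg


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_default) + "\n")
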