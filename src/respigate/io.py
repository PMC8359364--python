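"""File formats: signal TSV, phase TSV, NIfTI phantoms, CSV tables, YAML config.

Respiratory traces travel as two-column TSV (time_s, amplitude) with a
``# modality:`` header line; phase series add bin and accepted columns.
Phantom volumes are NIfTI-1 with the generating spec in a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from respigate.signal_types import PhaseSeries, RespiratorySignal
from respigate.synthetic import PhantomSpec, PhantomVolume


def write_signal_tsv(signal: RespiratorySignal, path: str | Path) -> None:
    path = Path(path)
    header = (f"# modality: {signal.modality}\n"
              f"# fs: {signal.fs}\n"
              f"# subject_id: {signal.subject_id}\n"
              "time_s\tamplitude\n")
    body = "\n".join(f"{t:.6f}\t{y:.9g}" for t, y in zip(signal.t, signal.y))
    path.write_text(header + body + "\n")


def read_signal_tsv(path: str | Path, fs: float | None = None) -> RespiratorySignal:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("#").partition(":")
            meta[key.strip()] = val.strip()
            continue
        if line.startswith("time_s"):
            continue
        t_str, y_str = line.split("\t")
        rows.append((float(t_str), float(y_str)))
    if not rows:
        raise ValueError(f"no samples in {path}")
    t, y = map(np.asarray, zip(*rows))
    if fs is None:
        fs = float(meta.get("fs", 0)) or 1.0 / np.median(np.diff(t))
    return RespiratorySignal(t=t, y=y, fs=fs,
                             modality=meta.get("modality", "camera"),
                             subject_id=meta.get("subject_id", ""))


def write_phase_tsv(phase: PhaseSeries, amplitude: np.ndarray | None,
                    path: str | Path) -> None:
    path = Path(path)
    amp = amplitude if amplitude is not None else np.full(len(phase), np.nan)
    header = (f"# modality: {phase.modality}\n"
              f"# fs: {phase.fs}\n"
              f"# accept_range: {phase.accept_range[0]}:{phase.accept_range[1]}\n"
              "time_s\tamplitude\tbin\taccepted\n")
    body = "\n".join(
        f"{t:.6f}\t{a:.9g}\t{b}\t{int(acc)}"
        for t, a, b, acc in zip(phase.t, amp, phase.bin, phase.accepted)
    )
    path.write_text(header + body + "\n")


def read_phase_tsv(path: str | Path) -> PhaseSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    t, b, acc = [], [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("#").partition(":")
            meta[key.strip()] = val.strip()
            continue
        if line.startswith("time_s"):
            continue
        parts = line.split("\t")
        t.append(float(parts[0]))
        b.append(int(parts[2]))
        acc.append(bool(int(parts[3])))
    fs = float(meta.get("fs", 0)) or 1.0 / np.median(np.diff(np.asarray(t)))
    lo, _, hi = meta.get("accept_range", "41:100").partition(":")
    return PhaseSeries(t=np.asarray(t), bin=np.asarray(b),
                       accepted=np.asarray(acc), fs=fs,
                       accept_range=(int(lo), int(hi)),
                       modality=meta.get("modality", "camera"))


def write_phantom_nifti(volume: PhantomVolume, path: str | Path) -> None:
    """NIfTI-1 volume plus a ``.json`` sidecar holding the ground truth."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine=np.eye(4))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    spec_dict = dataclasses.asdict(volume.spec)
    spec_dict["shape"] = list(spec_dict["shape"])
    sidecar.write_text(json.dumps(spec_dict, indent=2) + "\n")


def read_phantom_nifti(path: str | Path) -> PhantomVolume:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        d["shape"] = tuple(d["shape"])
        spec = PhantomSpec(**d)
    else:
        spec = PhantomSpec(shape=tuple(data.shape))
    return PhantomVolume(data=data, spec=spec)


def read_condition_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.columns[0].lower() in ("item", "item_id"):
        df = df.set_index(df.columns[0])
    return df


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise ValueError("config must contain a top-level 'seed' key")
    return cfg


__all__ = [
    "write_signal_tsv", "read_signal_tsv", "write_phase_tsv", "read_phase_tsv",
    "write_phantom_nifti", "read_phantom_nifti", "read_condition_csv",
    "read_ratings_csv", "load_config",
]
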