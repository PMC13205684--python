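"""Persistence: HDF5 for radar cubes and motion tensors (complex stored
as stacked float pairs, config as a JSON attribute), CSV for ECG
waveforms (one column per lead, header row carrying the sampling rate).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .frontend import MotionTensor
from .world import ECGRecord, Grid, RadarConfig, RadarCube, Rhythm


def save_radar_cube(cube: RadarCube, path: str | Path, group: str = "/") -> None:
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        if "samples" in g:
            del g["samples"], g["t_slow"]
        g.create_dataset(
            "samples",
            data=np.stack([cube.samples.real, cube.samples.imag]).astype(np.float32),
            compression="gzip",
        )
        g.create_dataset("t_slow", data=cube.t_slow_s)
        cfg = cube.config_ref
        g.attrs["config"] = json.dumps(
            {
                "carrier_hz": cfg.carrier_hz,
                "bandwidth_hz": cfg.bandwidth_hz,
                "n_pairs": cfg.n_pairs,
                "pair_positions": cfg.pair_positions.tolist(),
                "n_fast": cfg.n_fast,
                "chirp_rate_hz": cfg.chirp_rate_hz,
                "noise_sigma": cfg.noise_sigma,
            }
        )


def load_radar_cube(path: str | Path, group: str = "/") -> RadarCube:
    with h5py.File(path, "r") as f:
        g = f[group]
        d = json.loads(g.attrs["config"])
        d["pair_positions"] = np.array(d["pair_positions"])
        cfg = RadarConfig(**d)
        ri = g["samples"][()]
        return RadarCube(
            samples=(ri[0] + 1j * ri[1]).astype(np.complex64),
            config_ref=cfg,
            t_slow_s=g["t_slow"][()],
        )


def save_motion_tensor(mt: MotionTensor, path: str | Path, group: str = "/") -> None:
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        if "values" in g:
            del g["values"]
        g.create_dataset("values", data=mt.values.astype(np.float32), compression="gzip")
        g.attrs["config"] = json.dumps(
            {
                "fs_hz": mt.fs_hz,
                "subject_id": mt.subject_id,
                "grid_shape": list(mt.grid.shape),
                "grid_coords": mt.grid.coords.tolist(),
            }
        )


def load_motion_tensor(path: str | Path, group: str = "/") -> MotionTensor:
    with h5py.File(path, "r") as f:
        g = f[group]
        d = json.loads(g.attrs["config"])
        grid = Grid(coords=np.array(d["grid_coords"]), shape=tuple(d["grid_shape"]))
        return MotionTensor(
            values=g["values"][()],
            grid=grid,
            fs_hz=d["fs_hz"],
            subject_id=d["subject_id"],
        )


def write_ecg_csv(record: ECGRecord, path: str | Path) -> None:
    """CSV fallback format: '# fs_hz=...' comment, then one column per lead."""
    path = Path(path)
    header = ",".join(record.lead_names)
    label = record.labels.value if record.labels else ""
    with open(path, "w") as f:
        f.write(f"# fs_hz={record.fs_hz} label={label}\n")
        f.write(header + "\n")
        np.savetxt(f, record.waveform.T, delimiter=",", fmt="%.6f")


def read_ecg_csv(path: str | Path) -> ECGRecord:
    path = Path(path)
    with open(path) as f:
        meta = f.readline().strip().lstrip("#").split()
        kv = dict(item.split("=", 1) for item in meta if "=" in item)
        lead_names = f.readline().strip().split(",")
        data = np.loadtxt(f, delimiter=",", ndmin=2)
    label = kv.get("label", "")
    return ECGRecord(
        waveform=data.T,
        fs_hz=float(kv["fs_hz"]),
        lead_names=lead_names,
        labels=Rhythm(label) if label else None,
    )
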