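"""Plain-text readers/writers: TRC markers, force-plate CSV, JSON sidecars.

A trial on disk is a directory containing ``markers.trc``, ``forces.csv``
(time, Fx/Fy/Fz and CoP x/y/z per plate) and ``meta.json`` (anthropometry);
synthetic trials add a ``truth.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data.trial import Anthropometry, TrialRecording

__all__ = [
    "write_trc",
    "read_trc",
    "write_forces_csv",
    "read_forces_csv",
    "write_trial",
    "read_trial",
    "write_json",
]

_PLATE_SIDES = ("left", "right")


def write_trc(path, markers: dict[str, np.ndarray], rate_hz: float, t0: float = 0.0) -> None:
    """Write markers in the (text) TRC motion-trajectory format."""
    names = list(markers)
    n = next(iter(markers.values())).shape[0]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate_hz:g}\t{rate_hz:g}\t{n}\t{len(names)}\tm\t{rate_hz:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\n")
        fh.write(
            "\t\t"
            + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names)))
            + "\n"
        )
        for i in range(n):
            t = t0 + i / rate_hz
            row = [f"{i+1}", f"{t:.6f}"]
            for name in names:
                row.extend(f"{v:.8f}" for v in markers[name][i])
            fh.write("\t".join(row) + "\n")


def read_trc(path) -> tuple[dict[str, np.ndarray], float, float]:
    """Read a TRC file -> (markers, rate_hz, t0)."""
    lines = Path(path).read_text().splitlines()
    meta = lines[2].split("\t")
    rate = float(meta[0])
    names = [s for s in lines[3].split("\t")[2:] if s]
    data = np.array(
        [[float(v) for v in ln.split("\t")[1:]] for ln in lines[5:] if ln.strip()]
    )
    t0 = data[0, 0]
    markers = {
        name: data[:, 1 + 3 * i : 4 + 3 * i] for i, name in enumerate(names)
    }
    return markers, rate, t0


def write_forces_csv(
    path,
    plate_forces: dict[str, np.ndarray],
    plate_cops: dict[str, np.ndarray],
    rate_hz: float,
    t0: float = 0.0,
) -> None:
    n = next(iter(plate_forces.values())).shape[0]
    cols = {"time": t0 + np.arange(n) / rate_hz}
    for side in _PLATE_SIDES:
        for k, ax in enumerate("xyz"):
            cols[f"f{ax}_{side}"] = plate_forces[side][:, k]
        for k, ax in enumerate("xyz"):
            cols[f"cop{ax}_{side}"] = plate_cops[side][:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")


def read_forces_csv(path) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], float, float]:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    rate = 1.0 / np.mean(np.diff(t))
    forces, cops = {}, {}
    for side in _PLATE_SIDES:
        forces[side] = df[[f"f{ax}_{side}" for ax in "xyz"]].to_numpy()
        cops[side] = df[[f"cop{ax}_{side}" for ax in "xyz"]].to_numpy()
    return forces, cops, float(round(rate, 6)), float(t[0])


class _ArrayEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return super().default(obj)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(
        json.dumps(payload, cls=_ArrayEncoder, sort_keys=True, indent=1) + "\n"
    )


def write_trial(directory, recording: TrialRecording, truth=None) -> None:
    """Write one trial (markers.trc + forces.csv + meta.json [+ truth.json])."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_trc(directory / "markers.trc", recording.markers, recording.marker_rate_hz, recording.t0)
    write_forces_csv(
        directory / "forces.csv",
        recording.plate_forces,
        recording.plate_cops,
        recording.force_rate_hz,
        recording.t0,
    )
    write_json(
        directory / "meta.json",
        {
            "height_m": recording.anthropometry.height_m,
            "mass_kg": recording.anthropometry.mass_kg,
        },
    )
    if truth is not None:
        payload = {
            "contact_time_s": truth.contact_time_s,
            "jump_height_m": truth.jump_height_m,
            "rsi": truth.rsi,
            "t_contact": truth.t_contact,
            "t_com_min": truth.t_com_min,
            "t_takeoff": truth.t_takeoff,
            "t_landing": truth.t_landing,
            "body_mass_kg": truth.body_mass_kg,
            "rom_truth": {
                ph: {j: v for j, v in d.items()} for ph, d in truth.rom_truth.items()
            },
            "angles_at_gc": dict(truth.angles_at_gc),
        }
        write_json(directory / "truth.json", payload)


def read_trial(directory) -> TrialRecording:
    directory = Path(directory)
    markers, m_rate, t0 = read_trc(directory / "markers.trc")
    forces, cops, f_rate, _ = read_forces_csv(directory / "forces.csv")
    meta = json.loads((directory / "meta.json").read_text())
    return TrialRecording(
        markers=markers,
        marker_rate_hz=m_rate,
        plate_forces=forces,
        plate_cops=cops,
        force_rate_hz=f_rate,
        anthropometry=Anthropometry(meta["height_m"], meta["mass_kg"]),
        t0=t0,
    )
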