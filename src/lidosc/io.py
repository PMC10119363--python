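"""Readers and writers for the on-disk formats.

Sessions travel as HDF5 (/signals wires x samples, /fs, /channel_map) or as
flat int16 binary plus a YAML channel-map config; keypoints as CSV in the
common pose-estimation dialect (3-row header: scorer / bodyparts / coords);
AIM scores as tidy CSV; ground truth as JSON; analysis configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .preprocess import ChannelMap, LFPSession


def write_session_h5(path, session: LFPSession) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=session.signals, compression="gzip")
        f.create_dataset("fs", data=float(session.fs_hz))
        cm = f.create_group("channel_map")
        wires = session.wire_ids
        cm.create_dataset("wire_id", data=np.array(wires, dtype=np.int64))
        info = [session.channel_map.wires[w] for w in wires]
        cm.create_dataset("structure", data=[i.structure.encode() for i in info])
        cm.create_dataset("hemisphere", data=[i.hemisphere.encode() for i in info])
        cm.create_dataset("bundle", data=np.array([i.bundle for i in info], dtype=np.int64))
        if session.excluded_wires:
            f.create_dataset("excluded", data=np.array(sorted(session.excluded_wires), dtype=np.int64))


def read_session_h5(path) -> LFPSession:
    with h5py.File(path, "r") as f:
        signals = f["signals"][...]
        fs = float(f["fs"][()])
        cm = f["channel_map"]
        records = list(
            zip(
                cm["wire_id"][...],
                [s.decode() for s in cm["structure"][...]],
                [s.decode() for s in cm["hemisphere"][...]],
                cm["bundle"][...],
            )
        )
        excluded = set(int(w) for w in f["excluded"][...]) if "excluded" in f else set()
    return LFPSession(
        signals=signals,
        fs_hz=fs,
        channel_map=ChannelMap.from_records(records),
        wire_ids=[int(w) for w, *_ in records],
        excluded_wires=excluded,
    )


def read_flat_binary(path, config_path) -> LFPSession:
    """Flat int16 binary (wire-major interleaved) + YAML channel map.

    The YAML config must define fs_hz, gain_uv_per_bit, and wires: a list of
    {wire_id, structure, hemisphere, bundle} in file order.
    """
    cfg = yaml.safe_load(Path(config_path).read_text())
    wires = cfg["wires"]
    n_wires = len(wires)
    raw = np.fromfile(path, dtype=np.int16)
    n_samples = len(raw) // n_wires
    signals = raw[: n_samples * n_wires].reshape(n_samples, n_wires).T.astype(float)
    signals *= float(cfg["gain_uv_per_bit"])
    records = [(w["wire_id"], w["structure"], w["hemisphere"], w["bundle"]) for w in wires]
    return LFPSession(
        signals=signals,
        fs_hz=float(cfg["fs_hz"]),
        channel_map=ChannelMap.from_records(records),
        wire_ids=[int(w["wire_id"]) for w in wires],
    )


def write_keypoints_csv(path, table: pd.DataFrame) -> None:
    """Pose-estimation dialect: 3 header rows (scorer, bodyparts, coords)."""
    table.to_csv(path, index=True, index_label="frame")


def read_keypoints_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    df.columns.names = ["scorer", "bodyparts", "coords"]
    return df.astype(float)


def write_aim_csv(path, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, index=False)


def read_aim_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth_json(path, truth) -> None:
    def _clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {str(k): _clean(x) for k, x in v.items()}
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    payload = {k: _clean(v) for k, v in vars(truth).items() if v is not None}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_yaml_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
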