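"""Serialization: keyed binary array containers, CSV mirrors, checkpoints.

The binary container is a compressed ``.npz`` with keys ``values``, ``fps``
and ``region_labels`` (plus ``bands`` / band-spec metadata for multi-band
stacks); round-trips are bit-exact.  CSV is the human-readable interchange
format with one row per (frame, region).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import BandSpec, MultiBandStack
from .srrn import MFFNet, SRRNConfig
from .stmap import RGBRegionSeries, SpatioTemporalMap

__all__ = [
    "save_series", "load_series", "save_map", "load_map",
    "series_to_csv", "series_from_csv", "save_stack", "load_stack",
    "save_checkpoint", "load_checkpoint", "save_bvp_csv", "load_bvp_csv",
]


def save_series(path, series: RGBRegionSeries) -> None:
    np.savez_compressed(path, values=series.values, fps=series.fps,
                        region_labels=np.array(series.region_labels))


def load_series(path) -> RGBRegionSeries:
    with np.load(path, allow_pickle=False) as f:
        return RGBRegionSeries(
            values=f["values"], fps=float(f["fps"]),
            region_labels=tuple(str(x) for x in f["region_labels"]))


def save_map(path, stmap: SpatioTemporalMap) -> None:
    np.savez_compressed(path, values=stmap.values, fps=stmap.fps,
                        normalized=stmap.normalized,
                        region_labels=np.array(stmap.region_labels))


def load_map(path) -> SpatioTemporalMap:
    with np.load(path, allow_pickle=False) as f:
        return SpatioTemporalMap(
            values=f["values"], fps=float(f["fps"]),
            normalized=bool(f["normalized"]),
            region_labels=tuple(str(x) for x in f["region_labels"]))


_CH = {"rgb": ("R", "G", "B"), "yuv": ("Y", "U", "V")}


def series_to_csv(path, values: np.ndarray, colorspace: str = "rgb") -> None:
    """T x I x 3 array -> long CSV (frame, region, R|Y, G|U, B|V)."""
    T, I, _ = values.shape
    frames = np.repeat(np.arange(T), I)
    regions = np.tile(np.arange(I), T)
    flat = values.reshape(T * I, 3)
    cols = _CH[colorspace]
    df = pd.DataFrame({"frame": frames, "region": regions,
                       cols[0]: flat[:, 0], cols[1]: flat[:, 1],
                       cols[2]: flat[:, 2]})
    df.to_csv(path, index=False)


def series_from_csv(path, fps: float = 30.0,
                    colorspace: str = "rgb") -> np.ndarray:
    df = pd.read_csv(path)
    cols = _CH[colorspace]
    T = df["frame"].nunique()
    I = df["region"].nunique()
    df = df.sort_values(["frame", "region"])
    return df[list(cols)].to_numpy(dtype=np.float64).reshape(T, I, 3)


def save_stack(path, stack: MultiBandStack) -> None:
    np.savez_compressed(
        path, bands=stack.values,
        band_edges=np.array(stack.band_spec.bands),
        fps=stack.band_spec.fps)


def load_stack(path) -> MultiBandStack:
    with np.load(path, allow_pickle=False) as f:
        edges = tuple((float(lo), float(hi)) for lo, hi in f["band_edges"])
        return MultiBandStack(
            values=f["bands"],
            band_spec=BandSpec(bands=edges, fps=float(f["fps"])))


def save_checkpoint(path, model: MFFNet) -> None:
    """Weights + embedded config in one npz file."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        model.cfg.to_json().encode(), dtype=np.uint8)
    np.savez_compressed(path, **state)


def load_checkpoint(path) -> MFFNet:
    with np.load(path, allow_pickle=False) as f:
        cfg = SRRNConfig.from_json(bytes(f["__config__"]).decode())
        model = MFFNet(cfg)
        state = {k: f[k] for k in f.files if k != "__config__"}
    model.load_state_dict(state)
    model.eval()
    return model


def save_bvp_csv(path, values: np.ndarray) -> None:
    pd.DataFrame({"frame": np.arange(len(values)),
                  "bvp_value": values}).to_csv(path, index=False)


def load_bvp_csv(path) -> np.ndarray:
    return pd.read_csv(path)["bvp_value"].to_numpy(dtype=np.float64)
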