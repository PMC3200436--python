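"""HDF5 session container.

Layout of the hierarchical store::

    /version                 format version tag
    /data                    trials x channels x samples
    /time_ms, /fs, /units
    /layout/{channel_ids, positions_3d, channel_type}
    /trials/<column>         tidy per-trial metadata table
    /images/<name>/...       optional scalp-image volumes
    /provenance              append-only JSON records, one per operation

Writing then reading a session is the identity on all arrays and
metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .containers import EpochedData
from .layout import SensorLayout
from .scalp_map import ScalpImage

__all__ = ["Session", "write_session", "read_session", "FORMAT_VERSION"]

FORMAT_VERSION = 1
_STR = h5py.string_dtype(encoding="utf-8")


@dataclass
class Session:
    epochs: EpochedData
    images: dict[str, ScalpImage]


def write_session(
    epochs: EpochedData,
    path: str,
    images: dict[str, ScalpImage] | None = None,
) -> None:
    """Serialize an epoched session (and optional image volumes) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("version", data=FORMAT_VERSION)
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time_ms", data=epochs.time_ms)
        f.create_dataset("fs", data=float(epochs.fs))
        f.create_dataset("units", data=epochs.units, dtype=_STR)
        lay = f.create_group("layout")
        lay.create_dataset(
            "channel_ids", data=list(epochs.layout.channel_ids), dtype=_STR
        )
        lay.create_dataset("positions_3d", data=epochs.layout.positions_3d)
        lay.create_dataset("channel_type", data=epochs.layout.channel_type, dtype=_STR)
        tr = f.create_group("trials")
        tr.attrs["columns"] = json.dumps(list(map(str, epochs.trials.columns)))
        for col in epochs.trials.columns:
            vals = epochs.trials[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                tr.create_dataset(col, data=[str(v) for v in vals], dtype=_STR)
            else:
                tr.create_dataset(col, data=vals)
        f.create_dataset(
            "provenance",
            data=[json.dumps(rec) for rec in epochs.provenance],
            dtype=_STR,
        )
        if images:
            img_grp = f.create_group("images")
            for name, im in images.items():
                g = img_grp.create_group(name)
                g.create_dataset("values", data=im.values)
                g.create_dataset("x_mm", data=im.x_mm)
                g.create_dataset("y_mm", data=im.y_mm)
                g.create_dataset("time_ms", data=im.time_ms)
                g.create_dataset("validity_mask", data=im.validity_mask)
                g.create_dataset("pixel_mm", data=float(im.pixel_mm))


def read_session(path: str) -> Session:
    """Load a session container written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        if "version" not in f:
            raise ValueError("not a session container: /version is absent")
        version = int(f["version"][()])
        if version != FORMAT_VERSION:
            raise ValueError(
                f"unsupported container version {version}; this reader "
                f"supports version {FORMAT_VERSION} — re-export the session "
                "with a matching writer"
            )
        for key in ("data", "time_ms", "fs", "layout"):
            if key not in f:
                raise ValueError(f"malformed container: /{key} is absent")
        if "trials" not in f:
            raise ValueError("malformed container: trials table absent")
        layout = SensorLayout(
            tuple(s.decode() for s in f["layout/channel_ids"][()]),
            f["layout/positions_3d"][()],
            f["layout/channel_type"][()].decode(),
        )
        tr = f["trials"]
        col_order = json.loads(tr.attrs.get("columns", "null")) or list(tr.keys())
        trials = pd.DataFrame(
            {
                col: (
                    [v.decode() for v in tr[col][()]]
                    if tr[col].dtype.kind == "O"
                    else tr[col][()]
                )
                for col in col_order
            }
        )
        provenance = [json.loads(s.decode()) for s in f["provenance"][()]]
        epochs = EpochedData(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            time_ms=f["time_ms"][()],
            trials=trials,
            layout=layout,
            units=f["units"][()].decode(),
            provenance=provenance,
        )
        images: dict[str, ScalpImage] = {}
        if "images" in f:
            for name, g in f["images"].items():
                images[name] = ScalpImage(
                    values=g["values"][()],
                    x_mm=g["x_mm"][()],
                    y_mm=g["y_mm"][()],
                    time_ms=g["time_ms"][()],
                    validity_mask=g["validity_mask"][()].astype(bool),
                    pixel_mm=float(g["pixel_mm"][()]),
                )
    return Session(epochs=epochs, images=images)
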