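"""Condition-average scalp-image volumes for one preprocessed session.

Averages trials per (valence, outcome probability) cell, flattens the
sensor array (azimuthal-equidistant projection), rasterizes onto the
64 x 64 (3 mm) grid, smooths at FWHM 8 mm/8 ms, masks to 100-600 ms, and
stores the eight volumes back into the container under /images.
"""

import argparse
from pathlib import Path

import numpy as np

from axiomerf.config import PipelineConfig
from axiomerf.io import read_session, write_session
from axiomerf.pipeline import condition_volumes
from axiomerf.scalp_map import SensorRasterizer


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("session", nargs="?",
                    default="results/session_sub00_preproc.h5")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    epochs = read_session(args.session).epochs
    cfg = PipelineConfig()
    rast = SensorRasterizer(epochs.layout, cfg.map.grid_n, cfg.map.pixel_mm)
    vols = condition_volumes(epochs, cfg, rast)

    images = {f"{val}_P{p:g}": vol for (val, p), vol in vols.items()}
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / (Path(args.session).stem + "_images.h5")
    write_session(epochs, str(path), images=images)

    any_vol = next(iter(vols.values()))
    print(f"wrote {path}")
    print(f"{len(vols)} volumes of {any_vol.values.shape[0]}x"
          f"{any_vol.values.shape[1]} pixels x {any_vol.time_ms.size} frames "
          f"({any_vol.time_ms[0]:g}-{any_vol.time_ms[-1]:g} ms)")
    print(f"valid pixels inside sensor hull: {any_vol.validity_mask.sum()}")
    for name, vol in sorted(images.items()):
        peak = np.nanmax(np.abs(vol.values))
        print(f"  {name}: peak |amplitude| {peak:.3e}")


if __name__ == "__main__":
    main()
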