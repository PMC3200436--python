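"""Preprocess a stored session: filter, downsample, baseline, reject, SSP.

Applies the canonical order (0.5-30 Hz zero-phase Butterworth, 600->200 Hz,
pre-outcome baseline, 1.5e-10 T amplitude rejection, 4-component blink SSP)
and reports what each step removed.
"""

import argparse
from pathlib import Path

from axiomerf.config import PipelineConfig
from axiomerf.io import read_session, write_session
from axiomerf.pipeline import preprocess_subject


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("session", nargs="?", default="results/session_sub00.h5")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    epochs = read_session(args.session).epochs
    n0 = epochs.n_trials
    cfg = PipelineConfig()
    epochs = preprocess_subject(epochs, cfg)

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / (Path(args.session).stem + "_preproc.h5")
    write_session(epochs, str(path))

    print(f"wrote {path}")
    print(f"kept {epochs.n_trials}/{n0} trials at {epochs.fs:g} Hz")
    for rec in epochs.provenance:
        print(f"  {rec['operation']}: "
              + ", ".join(f"{k}={v}" for k, v in rec["params"].items()
                          if k not in ("components",)))


if __name__ == "__main__":
    main()
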