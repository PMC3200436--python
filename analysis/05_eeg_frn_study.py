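"""Electrode-level FRN study on the concurrent-EEG pattern.

Simulates the EEG cohort in which both valence signals scale positively
with outcome probability while the loss-minus-win difference wave still
shrinks with probability (a classical FRN).  Runs mastoid re-referencing,
2-30 Hz filtering, robust averaging, the 200-300 ms window ANOVA with the
axiom battery (expected: axiom-2 violation), and the 0-600 ms FRN
difference-wave analysis (expected: significant probability effect and
linear trend).  Writes tables under results/eeg/.
"""

import argparse
import json
import warnings
from pathlib import Path

from axiomerf.config import eeg_frn_config
from axiomerf.pipeline import run_frn_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--subjects", type=int, default=17)
    ap.add_argument("--out-dir", default="results/eeg")
    args = ap.parse_args()

    cfg = eeg_frn_config(seed=args.seed, n_subjects=args.subjects)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_frn_study(cfg)

    rep = res["axiom_report"]
    frn = res["frn"]
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res["means"].to_csv(out / "condition_means.tsv", sep="\t", index=False)
    frn.table.to_csv(out / "frn.tsv", sep="\t", index=False)
    (out / "axioms.json").write_text(json.dumps({
        "axiom_report": {
            "overall": rep.overall,
            "axiom2_pass": rep.axiom2_pass,
            "sign_opposition": rep.sign_opposition,
            "win_slope": rep.win_slope,
            "loss_slope": rep.loss_slope,
        },
        "frn_probability_effect": frn.probability_effect,
        "frn_linear_trend": frn.linear_trend,
        "window_anova": {
            k: res["anova"][k] for k in ("valence", "probability", "interaction")
        },
    }, indent=2, default=str))

    print(f"axiom battery at Cz (200-300 ms window): overall = {rep.overall}")
    print(f"  win slope {rep.win_slope:+.3e} V/P, "
          f"loss slope {rep.loss_slope:+.3e} V/P "
          f"(sign opposition: {rep.sign_opposition})")
    print(f"FRN (loss - win minimum, 0-600 ms):")
    print(f"  probability main effect F({frn.probability_effect['df'][0]},"
          f"{frn.probability_effect['df'][1]}) = "
          f"{frn.probability_effect['F']:.2f}, p = "
          f"{frn.probability_effect['p']:.2g}")
    print(f"  linear trend F({frn.linear_trend['df'][0]},"
          f"{frn.linear_trend['df'][1]}) = {frn.linear_trend['F']:.2f}, "
          f"p = {frn.linear_trend['p']:.2g}")
    print(f"tables written to {args.out_dir}/")


if __name__ == "__main__":
    main()
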