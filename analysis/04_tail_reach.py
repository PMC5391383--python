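#!/usr/bin/env python
"""Maximum tail reach per frame, quartile summaries and the Welch comparison.

The reach statistic anchors at the P43 α-carbon and takes the farthest
N-terminal α-carbon per frame.  Writes the per-frame series, the box
summaries (whose Q1/Q3 become the chromatin shell radii), a box plot, and
the Welch test of inactive vs active mean reach.
"""

import json
import sys
from dataclasses import asdict
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import build_ensembles, parse_args

from tailscope.reach import reach_series, summarize_reach, welch_test


def main():
    args = parse_args(__doc__)
    out = args.outdir / "reach"
    out.mkdir(exist_ok=True)
    ensembles = build_ensembles(args.seed, args.n_frames)
    series, summaries = {}, {}
    for name, traj in ensembles.items():
        r = reach_series(traj, anchor_res=43)
        r.to_frame(dt=traj.dt).to_csv(out / f"{name}_reach.csv", index=False)
        series[name] = r
        summaries[name] = summarize_reach(r)
        s = summaries[name]
        print(f"{name}: Q1 {s.q1:.1f}  median {s.median:.1f}  Q3 {s.q3:.1f} Å")

    w = welch_test(series["inactive"], series["active"])
    print(f"Welch inactive vs active: t = {w.t:.1f}, df = {w.df:.0f}, p = {w.p:.3g}; "
          f"mean difference {w.mean_diff:.1f} Å (95% CI {w.ci_low:.1f}..{w.ci_high:.1f})")
    print("inactive-like tail significantly longer:", w.p < 0.05 and w.mean_diff > 0)
    (out / "summary.json").write_text(json.dumps(
        {"summaries": {k: asdict(v) for k, v in summaries.items()},
         "welch_inactive_vs_active": asdict(w)}, indent=2) + "\n")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.boxplot([series[k].values for k in ("active", "inactive")],
                   tick_labels=["active", "inactive"])
        ax.set_ylabel("maximum tail reach (Å)")
        fig.tight_layout()
        fig.savefig(out / "reach_boxplot.png", dpi=120)
        print(f"figure -> {out / 'reach_boxplot.png'}")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
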