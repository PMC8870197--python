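#!/usr/bin/env python
"""Optional helper: plot choices and weight trajectories from a stored trace.

Usage:  python scripts/plot_trace.py RUN_DIR [--out plot.png]

Requires matplotlib (not a package dependency).
"""

import argparse
from pathlib import Path

from cgbg.io import read_trace


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("trace_dir", type=Path)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    trials, weights, provenance = read_trace(args.trace_dir)

    fig, (ax_w, ax_b) = plt.subplots(
        2, 1, figsize=(8, 6), sharex=True, height_ratios=[3, 1]
    )
    for (layer, source, target), grp in weights.groupby(["layer", "source", "target"]):
        ax_w.plot(grp["trial"], grp["value"], label=f"in{source}->{target}", lw=1)
    ax_w.set_ylabel("weight")
    ax_w.legend(fontsize=6, ncol=3, frameon=False)

    ax_b.scatter(trials["trial"], trials["chosen"], c=trials["rewarded"], cmap="RdYlGn",
                 vmin=0, vmax=1, s=15)
    ax_b.set_xlabel("trial")
    ax_b.set_ylabel("chosen")
    ax_b.set_yticks(sorted(set(trials["pair_first"]) | set(trials["pair_second"])))

    fig.suptitle(f"seed {provenance['seed']}")
    out = args.out or args.trace_dir / "trace.png"
    fig.savefig(out, dpi=150, bbox_inches="tight")
    print(out)


if __name__ == "__main__":
    main()
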