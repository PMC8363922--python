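#!/usr/bin/env python
"""Stain-pair consistency analysis of the scored study.

Builds the six stain-set pairs (two intra-laboratory, four
inter-laboratory), computes per-pair Spearman rho for every method and the
grouping summaries, correlates each method with the stain-free reference
on E1, and draws the per-method boxplot of pair correlations.  Outputs
under results/report/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from psrquant import pipeline
from psrquant.stats import read_score_table, report_frames, write_report

SCORES = Path("results/study/scores.csv")
OUT = Path("results/report")


def main() -> None:
    scores = read_score_table(SCORES)
    report = pipeline.analyze_scores(scores)
    pairs_path, summary_path = write_report(report, OUT)
    pairs, summary = report_frames(report)
    print(f"wrote {pairs_path} and {summary_path}")
    print(summary.round(3).to_string(index=False))

    order = [m for m in ("HSB", "PIXCLF_i", "PIXCLF_c1", "PIXCLF_c2", "GROUND_TRUTH")
             if m in set(pairs["method"])]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot(
        [pairs[pairs["method"] == m]["rho"].dropna() for m in order],
        tick_labels=order,
    )
    ax.set_ylabel("Spearman rho across stain-set pairs")
    ax.set_ylim(-0.1, 1.05)
    ax.axhline(1.0, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(OUT / "pair_rho_boxplot.png", dpi=150)
    print(f"wrote {OUT / 'pair_rho_boxplot.png'}")


if __name__ == "__main__":
    main()
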