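"""Descriptive statistics of the classified modes.

Tabulates mode frequencies, runs the mode x log2FC-bin contingency
analysis with standard Pearson residuals, scores silhouettes of the
log2FC triples grouped by assigned mode, and reprints the percent-increase
arithmetic for the published per-contrast regulated-transcript counts.
Writes tables under results/summary/.
"""

import json
from pathlib import Path

import numpy as np

from stressmodes.pattern_classifier import ModeAssignment
from stressmodes.summaries import (
    DEFAULT_BIN_EDGES,
    contingency_analysis,
    mode_frequencies,
    pct_increase,
    silhouette_scores,
)
from stressmodes.tables_io import read_assignments

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "summary"


def main() -> None:
    df = read_assignments(ROOT / "classification" / "assignments.tsv")
    assignments = [
        ModeAssignment(**{k: row[k] for k in (
            "feature_id", "mode", "f_st", "f_wl", "f_swl",
            "additive_expectation", "d_st", "d_wl", "d_sum", "rule_path")})
        for _, row in df.iterrows()
    ]

    OUT.mkdir(parents=True, exist_ok=True)

    freq = mode_frequencies(assignments, include_na=True)
    freq.to_frame().to_csv(OUT / "mode_frequencies.tsv", sep="\t", index=False)
    print(f"mode frequencies over {freq.total} classified features:")
    for mode, pct in freq.percentages.items():
        print(f"  {mode:>13}: {freq.counts[mode]:3d}  ({pct:5.2f}%)")

    cont = contingency_analysis(assignments, DEFAULT_BIN_EDGES)
    cont.observed.to_csv(OUT / "contingency_observed.tsv", sep="\t")
    cont.residuals.to_csv(OUT / "contingency_residuals.tsv", sep="\t")
    print(f"mode x log2FC-bin contingency: chi2 = {cont.chi2:.2f}, "
          f"dof = {cont.dof}")
    peak = np.unravel_index(
        np.abs(cont.residuals.to_numpy()).argmax(), cont.residuals.shape)
    print(f"largest |Pearson residual| = "
          f"{cont.residuals.iat[peak[0], peak[1]]:+.2f} at "
          f"({cont.residuals.index[peak[0]]}, {cont.residuals.columns[peak[1]]})")

    # silhouette of the log2FC triples grouped by assigned mode: how
    # geometrically separated the modes are in (f_st, f_wl, f_swl) space
    modes = df["mode"].to_numpy()
    keep = modes != "non_assigned"
    points = df.loc[keep, ["f_st", "f_wl", "f_swl"]].to_numpy()
    scores, by_mode = silhouette_scores(points, modes[keep])
    by_mode.rename("mean_silhouette").to_csv(OUT / "silhouette_by_mode.tsv", sep="\t")
    print("mean silhouette of log2FC triples by mode "
          f"(overall {scores.mean():+.3f}):")
    for mode, s in by_mode.items():
        print(f"  {mode:>13}: {s:+.3f}")

    pct = {
        "swl_over_wl": pct_increase(14053, 4111),
        "swl_over_st": pct_increase(14053, 2670),
    }
    print(f"percent increase of SWL-regulated transcripts (published counts): "
          f"{pct['swl_over_wl']}% over WL, {pct['swl_over_st']}% over ST")

    (OUT / "summary.json").write_text(json.dumps({
        "total_classified": freq.total,
        "mode_percent": freq.percentages,
        "chi2": cont.chi2,
        "dof": cont.dof,
        "mean_silhouette": float(scores.mean()),
        "pct_increase": pct,
    }, indent=2))


if __name__ == "__main__":
    main()
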