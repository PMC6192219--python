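#!/usr/bin/env python
"""Stage 4 — the robustness evaluation.

From the stage-3 age estimates and stage-2 betas: cross-platform agreement
per preprocessing method, the reduced-clock (missing-probe) experiment,
pairwise preprocessing comparisons of both age-acceleration measures,
probe-wise cross-platform correlations, technical-replicate concordance and
the SNP identity check.  Tables land in results/report/, summary figures in
results/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from epiclockbench import io as eio
from epiclockbench.clock import reduce_clock
from epiclockbench.core import snp_identity_check
from epiclockbench.evaluation import (
    AgeEstimateSet,
    compare_estimates,
    compare_methods,
    probewise_platform_correlation,
    replicate_concordance,
)
from epiclockbench.preprocessing import PREPROCESSORS

ROOT = Path(__file__).resolve().parents[1] / "results"
REPORT = ROOT / "report"
FIGS = ROOT / "figures"


def main() -> None:
    REPORT.mkdir(parents=True, exist_ok=True)
    FIGS.mkdir(parents=True, exist_ok=True)
    estimates = AgeEstimateSet(pd.read_csv(ROOT / "age_estimates.csv"))
    pan = [c for c in estimates.table["clock"].unique() if "pan" in c][0]
    sheet_b = eio.load_sample_sheet(ROOT / "data" / "sample_sheet_B.csv")
    subjects = [s for s in estimates.table["sample_id"].unique() if not s.endswith("_rep")]

    # cross-platform agreement
    xp_rows = []
    for method in PREPROCESSORS:
        a = estimates.condition("A", method, pan)["dnam_age"]
        b = estimates.condition("B", method, pan)["dnam_age"].reindex(subjects).dropna()
        common = a.index.intersection(b.index)
        stats_ = compare_estimates(a.loc[common], b.loc[common])
        xp_rows.append({"preprocessing": method, **stats_})
        print(f"cross-platform [{method:8s}]: r={stats_['r']:.3f}, "
              f"median |diff|={stats_['median_abs_diff']:.2f} y")
    pd.DataFrame(xp_rows).to_csv(REPORT / "cross_platform.tsv", sep="\t", index=False)

    # reduced-clock experiment on platform A raw betas
    clock = eio.load_clock(ROOT / "data" / "ground_truth" / "clock_pan_tissue.csv")
    absent = [
        line for line in (ROOT / "data" / "ground_truth" / "platform_b_absent.txt")
        .read_text().splitlines() if line in set(clock.cpgs)
    ]
    beta_a = eio.load_beta(ROOT / "betas" / "beta_A_raw.tsv")
    exp = reduce_clock(beta_a, clock, absent, calibrate=True)
    print(f"reduced clock ({len(clock.cpgs)} vs {len(clock.cpgs) - len(absent)} CpGs): "
          f"r = {exp.r:.4f}")
    pd.DataFrame({"full": exp.full, "reduced": exp.reduced}).to_csv(
        REPORT / "reduced_clock_estimates.tsv", sep="\t"
    )

    # preprocessing-method comparisons of the two acceleration measures
    subject_est = AgeEstimateSet(
        estimates.table[estimates.table["sample_id"].isin(subjects)].copy()
    )
    for metric in ("difference", "residual", "dnam_age"):
        cmp_ = compare_methods(subject_est, metric=metric, platform="B", clock=pan)
        cmp_.to_csv(REPORT / f"method_comparison_{metric}.tsv", sep="\t", index=False)
    diff = pd.read_csv(REPORT / "method_comparison_difference.tsv", sep="\t")
    resid = pd.read_csv(REPORT / "method_comparison_residual.tsv", sep="\t")
    print(f"acceleration difference: median |delta| up to "
          f"{diff['median_abs_diff'].max():.2f} y across method pairs")
    print(f"acceleration residual:   median |delta| up to "
          f"{resid['median_abs_diff'].max():.2f} y (offset-robust measure)")

    # probe-wise cross-platform correlation at the common clock CpGs
    beta_b = eio.load_beta(ROOT / "betas" / "beta_B_raw.tsv")
    common_clock = [c for c in clock.cpgs if c in beta_b.index]
    table, summary = probewise_platform_correlation(beta_a, beta_b[subjects],
                                                    probes=common_clock)
    table.to_csv(REPORT / "probewise_correlation.tsv", sep="\t", index=False)
    print(f"probe-wise: {summary['n_defined']} defined r values, "
          f"range-vs-r correlation = {summary['range_vs_r_correlation']:.2f}")

    # technical replicate concordance
    rep = replicate_concordance(
        AgeEstimateSet(estimates.table[estimates.table["platform"] == "B"].copy()),
        sheet_b.replicate_groups(),
    )
    rep.to_csv(REPORT / "replicate_concordance.tsv", sep="\t", index=False)
    med = rep[(rep["pair"] == "<median>") & (rep["clock"] == pan)]
    for _, row in med.iterrows():
        print(f"replicate median |delta age| [{row['preprocessing']:8s}]: "
              f"{row['abs_diff']:.2f} y")

    # SNP identity across platforms
    pairing, _ = snp_identity_check(
        beta_a, beta_b[subjects],
        [p for p in beta_a.index if p.startswith("rs_")],
    )
    pairing.to_csv(REPORT / "snp_pairing.tsv", sep="\t", index=False)
    frac = (pairing["best_match_b"] == pairing["sample_a"]).mean()
    print(f"SNP identity: correct best match for {frac:.0%} of samples")

    _figures(estimates, pan, subjects, med, exp)
    print(f"report tables in {REPORT}, figures in {FIGS}")


def _figures(estimates, pan, subjects, med, exp) -> None:
    # cross-platform scatter per preprocessing method
    fig, axes = plt.subplots(1, 4, figsize=(16, 4), sharex=True, sharey=True)
    for ax, method in zip(axes, PREPROCESSORS):
        a = estimates.condition("A", method, pan)["dnam_age"]
        b = estimates.condition("B", method, pan)["dnam_age"].reindex(a.index)
        ax.scatter(a, b, s=8, alpha=0.6)
        lims = [min(a.min(), b.min()), max(a.max(), b.max())]
        ax.plot(lims, lims, "k--", lw=0.8)
        slope, icpt = np.polyfit(a, b, 1)
        ax.plot(lims, [icpt + slope * x for x in lims], "r-", lw=1)
        ax.set_title(method)
        ax.set_xlabel("platform A DNAm age (y)")
    axes[0].set_ylabel("platform B DNAm age (y)")
    fig.tight_layout()
    fig.savefig(FIGS / "cross_platform_scatter.png", dpi=120)
    plt.close(fig)

    # acceleration difference vs residual box plots
    wide = estimates.table[
        (estimates.table["platform"] == "B")
        & (estimates.table["clock"] == pan)
        & (estimates.table["sample_id"].isin(subjects))
    ].pivot(index="sample_id", columns="preprocessing", values="dnam_age")
    chrono = estimates.table.drop_duplicates("sample_id").set_index("sample_id")[
        "chronological_age"].loc[wide.index]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    methods = list(wide.columns)
    ax1.boxplot([wide[m] - chrono for m in methods], tick_labels=methods)
    ax1.set_title("acceleration difference")
    ax1.set_ylabel("years")
    resids = []
    for m in methods:
        slope, icpt = np.polyfit(chrono, wide[m], 1)
        resids.append(wide[m] - (icpt + slope * chrono))
    ax2.boxplot(resids, tick_labels=methods)
    ax2.set_title("acceleration residual")
    fig.tight_layout()
    fig.savefig(FIGS / "acceleration_boxplots.png", dpi=120)
    plt.close(fig)

    # full vs reduced clock
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(exp.full, exp.reduced, s=8, alpha=0.6)
    lims = [exp.full.min(), exp.full.max()]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel("full-clock DNAm age (y)")
    ax.set_ylabel("reduced-clock DNAm age (y)")
    ax.set_title(f"r = {exp.r:.4f}")
    fig.tight_layout()
    fig.savefig(FIGS / "reduced_clock.png", dpi=120)
    plt.close(fig)


if __name__ == "__main__":
    main()
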