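"""Comparison layer: the statistics behind the benchmark's figures.

* cross-condition agreement of DNAm-age estimates (Pearson r, R^2, p,
  median absolute difference),
* the two epigenetic age-acceleration measures — the raw difference
  (DNAm age - chronological age) and the residual from regressing DNAm age
  on chronological age — whose contrasting sensitivity to preprocessing
  shifts is the benchmark's central point,
* pairwise preprocessing-method comparisons (paired test with Holm
  adjustment, Kendall rank concordance),
* probe-wise cross-platform correlations of log betas with the beta-range
  association,
* technical-replicate concordance (median absolute DNAm-age difference
  per replicate pair).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import EpiclockError

__all__ = [
    "AgeEstimateSet",
    "EvaluationReport",
    "compare_estimates",
    "acceleration_difference",
    "acceleration_residual",
    "kendall_tau",
    "compare_methods",
    "probewise_platform_correlation",
    "replicate_concordance",
]

CONDITION_KEYS = ["platform", "preprocessing", "clock"]


@dataclass
class AgeEstimateSet:
    """Long table of DNAm-age estimates across experimental conditions.

    One row per (sample, platform, preprocessing, clock) with columns
    ``sample_id, platform, preprocessing, clock, dnam_age,
    chronological_age``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "platform", "preprocessing", "clock", "dnam_age",
                    "chronological_age"}
        missing = required - set(self.table.columns)
        if missing:
            raise EpiclockError(f"age estimate table missing columns {sorted(missing)}")
        key = ["sample_id", *CONDITION_KEYS]
        if self.table.duplicated(subset=key).any():
            raise EpiclockError("duplicate (sample, platform, preprocessing, clock) rows")

    def condition(self, platform: str, preprocessing: str, clock: str) -> pd.DataFrame:
        mask = (
            (self.table["platform"] == platform)
            & (self.table["preprocessing"] == preprocessing)
            & (self.table["clock"] == clock)
        )
        return self.table.loc[mask].set_index("sample_id")

    def conditions(self) -> list[tuple[str, str, str]]:
        return sorted(
            self.table[CONDITION_KEYS].drop_duplicates().itertuples(index=False, name=None)
        )


@dataclass
class EvaluationReport:
    """Bundle of evaluation tables; every statistic carries the n it used."""

    cross_platform: pd.DataFrame | None = None
    chronological: pd.DataFrame | None = None
    method_comparison: dict[str, pd.DataFrame] = field(default_factory=dict)
    kendall_tau_matrix: pd.DataFrame | None = None
    probewise: pd.DataFrame | None = None
    probewise_summary: dict | None = None
    replicate: pd.DataFrame | None = None
    reduced_clock: pd.DataFrame | None = None
    snp_pairing: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        out: dict[str, pd.DataFrame] = {}
        for name in (
            "cross_platform", "chronological", "kendall_tau_matrix",
            "probewise", "replicate", "reduced_clock", "snp_pairing",
        ):
            val = getattr(self, name)
            if val is not None:
                out[name] = val
        for metric, table in self.method_comparison.items():
            out[f"method_comparison_{metric}"] = table
        return out


# ---------------------------------------------------------------------------
# pairwise estimate agreement
# ---------------------------------------------------------------------------


def compare_estimates(x, y) -> dict:
    """Pearson r (with two-sided p), R^2 and median absolute difference.

    Symmetric in its arguments.  With zero variance in either vector the
    correlation is undefined and reported as NaN rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise EpiclockError("paired vectors differ in length")
    if x.size < 3:
        raise EpiclockError("need at least 3 paired observations")
    out = {"n": int(x.size), "median_abs_diff": float(np.median(np.abs(x - y)))}
    if x.std() == 0 or y.std() == 0:
        out.update(r=np.nan, r2=np.nan, p=np.nan, defined=False)
        return out
    res = stats.pearsonr(x, y)
    out.update(r=float(res.statistic), r2=float(res.statistic) ** 2,
               p=float(res.pvalue), defined=True)
    return out


# ---------------------------------------------------------------------------
# age acceleration
# ---------------------------------------------------------------------------


def acceleration_difference(dnam, chrono) -> np.ndarray:
    """Epigenetic age acceleration as the raw difference, in years."""
    dnam = np.asarray(dnam, dtype=float)
    chrono = np.asarray(chrono, dtype=float)
    if dnam.shape != chrono.shape:
        raise EpiclockError("dnam and chronological age vectors differ in length")
    return dnam - chrono


def acceleration_residual(dnam, chrono) -> np.ndarray:
    """Epigenetic age acceleration as OLS residuals of DNAm age on age.

    An intercept is included, so residuals sum to zero and are invariant
    to any constant shift of the DNAm-age estimates — the property that
    makes this the preprocessing-robust acceleration measure.
    """
    dnam = np.asarray(dnam, dtype=float)
    chrono = np.asarray(chrono, dtype=float)
    if dnam.shape != chrono.shape:
        raise EpiclockError("dnam and chronological age vectors differ in length")
    if dnam.size < 3:
        raise EpiclockError("need at least 3 samples for the residual measure")
    if np.ptp(chrono) == 0:
        raise EpiclockError("chronological age is constant; residual measure undefined")
    slope, intercept = np.polyfit(chrono, dnam, 1)
    return dnam - (intercept + slope * chrono)


# ---------------------------------------------------------------------------
# rank concordance & method comparison
# ---------------------------------------------------------------------------


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall rank correlation (tau-b) with its two-sided p-value."""
    res = stats.kendalltau(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(res.statistic), float(res.pvalue)


_METRICS = ("difference", "residual", "dnam_age")


def compare_methods(
    estimates: AgeEstimateSet,
    metric: str = "difference",
    platform: str | None = None,
    clock: str | None = None,
    test: str = "t",
) -> pd.DataFrame:
    """Pairwise preprocessing-method comparison of an acceleration metric.

    For every pair of preprocessing conditions (same platform and clock):
    median absolute per-sample difference of the metric, a paired
    two-sided test (t by default, Wilcoxon signed-rank as alternative)
    with Holm multiplicity adjustment across pairs, and the Kendall tau of
    sample rankings.
    """
    if metric not in _METRICS:
        raise EpiclockError(f"metric must be one of {_METRICS}")
    table = estimates.table
    if platform is not None:
        table = table[table["platform"] == platform]
    if clock is not None:
        table = table[table["clock"] == clock]
    rows = []
    for (plat, clk), block in table.groupby(["platform", "clock"]):
        wide = block.pivot(index="sample_id", columns="preprocessing", values="dnam_age")
        chrono = block.drop_duplicates("sample_id").set_index("sample_id")["chronological_age"]
        chrono = chrono.loc[wide.index]
        if wide.isna().any().any():
            missing = wide.index[wide.isna().any(axis=1)].tolist()
            raise EpiclockError(f"samples missing under some condition: {missing[:5]}")
        values = {}
        for method in wide.columns:
            if metric == "difference":
                values[method] = acceleration_difference(wide[method], chrono)
            elif metric == "residual":
                values[method] = acceleration_residual(wide[method], chrono)
            else:
                values[method] = wide[method].to_numpy(dtype=float)
        for m1, m2 in itertools.combinations(sorted(wide.columns), 2):
            v1, v2 = values[m1], values[m2]
            delta = v1 - v2
            scale = max(1.0, float(np.max(np.abs(v1))), float(np.max(np.abs(v2))))
            if np.max(np.abs(delta)) < 1e-8 * scale:
                # numerically identical metrics; avoid t-tests on float residue
                p = 1.0
            elif test == "t":
                p = float(stats.ttest_rel(v1, v2).pvalue)
            elif test == "wilcoxon":
                p = float(stats.wilcoxon(v1, v2).pvalue)
            else:
                raise EpiclockError("test must be 't' or 'wilcoxon'")
            tau, tau_p = kendall_tau(v1, v2)
            rows.append(
                {
                    "platform": plat,
                    "clock": clk,
                    "method_1": m1,
                    "method_2": m2,
                    "metric": metric,
                    "n": len(delta),
                    "median_abs_diff": float(np.median(np.abs(delta))),
                    "mean_diff": float(np.mean(delta)),
                    "p_raw": p,
                    "kendall_tau": tau,
                    "kendall_p": tau_p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = np.nan
        for _, idx in out.groupby(["platform", "clock"]).groups.items():
            praw = out.loc[idx, "p_raw"].to_numpy()
            out.loc[idx, "p_adj"] = multipletests(praw, method="holm")[1]
    return out


# ---------------------------------------------------------------------------
# probe-wise platform correlation
# ---------------------------------------------------------------------------


def probewise_platform_correlation(
    beta_a: pd.DataFrame,
    beta_b: pd.DataFrame,
    probes=None,
    log_floor: float = 1e-6,
) -> tuple[pd.DataFrame, dict]:
    """Per-probe cross-platform correlation of log betas, with beta range.

    For each probe shared by both matrices (restricted to ``probes`` if
    given), the Pearson r of log-transformed betas across paired samples
    is computed, along with the probe's beta range (max - min of raw betas
    pooled over both platforms).  The summary reports the correlation
    between beta range and r over defined probes, and how many probes fall
    in the r <= 0.2, r > 0.5 and r > 0.8 bins.
    """
    common_samples = beta_a.columns.intersection(beta_b.columns)
    if len(common_samples) < 3:
        raise EpiclockError("need >= 3 paired samples for probe-wise correlation")
    if probes is None:
        probes = beta_a.index.intersection(beta_b.index)
    else:
        probes = pd.Index(probes)
        absent = probes.difference(beta_a.index).union(probes.difference(beta_b.index))
        if len(absent):
            warnings.warn(f"{len(absent)} requested probes absent from a matrix", stacklevel=2)
            probes = probes.difference(absent)
    xa = beta_a.loc[probes, common_samples].to_numpy(dtype=float)
    xb = beta_b.loc[probes, common_samples].to_numpy(dtype=float)
    la = np.log(np.clip(xa, log_floor, None))
    lb = np.log(np.clip(xb, log_floor, None))
    rows = []
    for i, probe in enumerate(probes):
        rng_beta = float(np.nanmax(np.concatenate([xa[i], xb[i]]))
                         - np.nanmin(np.concatenate([xa[i], xb[i]])))
        if np.nanstd(la[i]) == 0 or np.nanstd(lb[i]) == 0:
            rows.append((probe, np.nan, rng_beta, False, len(common_samples)))
            continue
        r = float(stats.pearsonr(la[i], lb[i]).statistic)
        rows.append((probe, r, rng_beta, True, len(common_samples)))
    table = pd.DataFrame(rows, columns=["probe_id", "r", "beta_range", "defined", "n_samples"])
    defined = table[table["defined"]]
    summary = {
        "n_probes": len(table),
        "n_defined": int(len(defined)),
        "n_undefined": int(len(table) - len(defined)),
        "n_r_le_0.2": int((defined["r"] <= 0.2).sum()),
        "n_r_gt_0.5": int((defined["r"] > 0.5).sum()),
        "n_r_gt_0.8": int((defined["r"] > 0.8).sum()),
        "range_vs_r_correlation": (
            float(stats.pearsonr(defined["beta_range"], defined["r"]).statistic)
            if len(defined) >= 3 and defined["beta_range"].std() > 0 and defined["r"].std() > 0
            else np.nan
        ),
    }
    return table, summary


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------


def replicate_concordance(
    estimates: AgeEstimateSet, replicate_groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Absolute DNAm-age difference within technical-replicate pairs.

    Returns one row per replicate pair per condition, plus per-condition
    ``median`` rows (pair label ``<median>``) with the median absolute
    difference — the benchmark's replicate-error statistic.
    """
    rows = []
    for plat, prep, clk in estimates.conditions():
        cond = estimates.condition(plat, prep, clk)["dnam_age"]
        diffs = []
        for group, members in replicate_groups.items():
            present = [m for m in members if m in cond.index]
            if len(present) < 2:
                warnings.warn(f"replicate group {group} has < 2 members with estimates; skipped",
                              stacklevel=2)
                continue
            for s1, s2 in itertools.combinations(present, 2):
                d = float(abs(cond[s1] - cond[s2]))
                diffs.append(d)
                rows.append(
                    {"platform": plat, "preprocessing": prep, "clock": clk,
                     "pair": f"{s1}|{s2}", "group": group, "abs_diff": d}
                )
        if diffs:
            rows.append(
                {"platform": plat, "preprocessing": prep, "clock": clk,
                 "pair": "<median>", "group": "<all>",
                 "abs_diff": float(np.median(diffs))}
            )
    return pd.DataFrame(rows)
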