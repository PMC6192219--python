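"""End-to-end benchmark: simulate -> preprocess (x4) -> clocks -> evaluate.

Reproduces the benchmark's experimental grid on synthetic data: one cohort
assayed on two simulated platforms (the second lacking a subset of clock
CpGs), technical replicate pairs on platform B, four preprocessing routes,
and two clocks (pan-tissue style with calibration, blood style without),
followed by the full evaluation layer.  A fixed seed reproduces every
output bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import SampleSheet, compute_beta, snp_identity_check
from .clock import predict_dnam_age, reduce_clock
from .evaluation import (
    AgeEstimateSet,
    EvaluationReport,
    compare_estimates,
    compare_methods,
    probewise_platform_correlation,
    replicate_concordance,
)
from .preprocessing import PREPROCESSORS, preprocess
from .simulate import (
    GroundTruth,
    SimulationConfig,
    make_technical_replicates,
    simulate_cohort,
    simulate_intensities,
)

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("raw", "gs", "quantile", "noob")


@dataclass
class RunConfig:
    """Configuration of a full benchmark run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    methods: tuple[str, ...] = DEFAULT_METHODS
    calibrate_pan_tissue: bool = True
    calibrate_blood: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one preprocessing method required")
        unknown = set(self.methods) - set(PREPROCESSORS)
        if unknown:
            raise ValueError(f"unknown preprocessing methods: {sorted(unknown)}")

    @property
    def seed(self) -> int:
        return self.sim.seed

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "methods": list(self.methods),
            "calibrate_pan_tissue": self.calibrate_pan_tissue,
            "calibrate_blood": self.calibrate_blood,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StudyResult:
    """Everything a run produced: estimates, betas, report, provenance."""

    config: RunConfig
    sheets: dict[str, SampleSheet]
    truth: GroundTruth
    betas: dict[tuple[str, str], pd.DataFrame]  # (platform, method) -> beta
    estimates: AgeEstimateSet
    report: EvaluationReport


def run_full_study(config: RunConfig) -> StudyResult:
    """Execute the whole benchmark grid; see the module docstring.

    A preprocessing condition that fails is logged and excluded; the run
    continues with the remaining conditions.
    """
    sim = config.sim
    base_sheet, truth = simulate_cohort(sim)
    intensities = {"A": simulate_intensities(truth, sim, "A"),
                   "B": simulate_intensities(truth, sim, "B")}
    sheets = {"A": SampleSheet(base_sheet.table.assign(platform="A"))}
    # technical replicates enter on platform B, as in the benchmarked design
    intensities["B"], sheet_b = make_technical_replicates(
        intensities["B"], SampleSheet(base_sheet.table.assign(platform="B")),
        pairs=sim.replicate_pairs, noise_sd=sim.replicate_noise_sd, seed=sim.seed,
    )
    sheets["B"] = sheet_b

    betas: dict[tuple[str, str], pd.DataFrame] = {}
    rows = []
    clocks = {
        truth.clock.name: (truth.clock, config.calibrate_pan_tissue),
        truth.blood_clock.name: (truth.blood_clock, config.calibrate_blood),
    }
    for platform, inten in intensities.items():
        ages = sheets[platform].ages()
        for method in config.methods:
            try:
                beta = preprocess(inten, method)
            except Exception:
                logger.exception("preprocessing %s failed on platform %s; skipped",
                                 method, platform)
                continue
            betas[(platform, method)] = beta
            for clock_name, (clock, calibrate) in clocks.items():
                try:
                    pred = predict_dnam_age(beta, clock, calibrate=calibrate)
                except Exception:
                    logger.exception("clock %s failed on (%s, %s); skipped",
                                     clock_name, platform, method)
                    continue
                for sample_id, rec in pred.iterrows():
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "platform": platform,
                            "preprocessing": method,
                            "clock": clock_name,
                            "dnam_age": float(rec["dnam_age"]),
                            "chronological_age": float(ages[sample_id]),
                            "n_imputed": int(rec["n_imputed"]),
                            "calibrated": bool(rec["calibrated"]),
                        }
                    )
    estimates = AgeEstimateSet(pd.DataFrame(rows))
    report = evaluate_study(config, truth, sheets, betas, estimates)
    result = StudyResult(
        config=config, sheets=sheets, truth=truth, betas=betas,
        estimates=estimates, report=report,
    )
    if config.output_dir is not None:
        write_study(result, config.output_dir)
    return result


def evaluate_study(
    config: RunConfig,
    truth: GroundTruth,
    sheets: dict[str, SampleSheet],
    betas: dict[tuple[str, str], pd.DataFrame],
    estimates: AgeEstimateSet,
) -> EvaluationReport:
    report = EvaluationReport()
    subjects = [s for s in sheets["A"].sample_ids]

    # cross-platform agreement per (preprocessing, clock), shared subjects
    xp_rows, chrono_rows = [], []
    for platform, prep, clk in estimates.conditions():
        cond = estimates.condition(platform, prep, clk)
        stats_ = compare_estimates(cond["dnam_age"], cond["chronological_age"])
        chrono_rows.append({"platform": platform, "preprocessing": prep, "clock": clk, **stats_})
    for prep in dict.fromkeys(estimates.table["preprocessing"]):
        for clk in dict.fromkeys(estimates.table["clock"]):
            a = estimates.condition("A", prep, clk)["dnam_age"]
            b = estimates.condition("B", prep, clk)["dnam_age"]
            common = [s for s in subjects if s in a.index and s in b.index]
            if len(common) < 3:
                continue
            stats_ = compare_estimates(a.loc[common], b.loc[common])
            xp_rows.append({"preprocessing": prep, "clock": clk, **stats_})
    report.cross_platform = pd.DataFrame(xp_rows)
    report.chronological = pd.DataFrame(chrono_rows)

    # reduced-clock experiment: platform A data, pan-tissue clock CpGs
    absent_clock = [c for c in truth.platform_b_absent if c in truth.clock_cpgs]
    red_rows = []
    for method in config.methods:
        beta = betas.get(("A", method))
        if beta is None:
            continue
        exp = reduce_clock(beta, truth.clock, absent_clock,
                           calibrate=config.calibrate_pan_tissue)
        red_rows.append({"preprocessing": method, "n_masked": len(absent_clock),
                         "n": len(exp.full), "r": exp.r})
    report.reduced_clock = pd.DataFrame(red_rows)

    # preprocessing-method contrasts on platform B subjects (no replicates)
    subject_est = AgeEstimateSet(
        estimates.table[estimates.table["sample_id"].isin(subjects)].copy()
    )
    for metric in ("difference", "residual", "dnam_age"):
        try:
            report.method_comparison[metric] = compare_methods(
                subject_est, metric=metric, platform="B", clock=truth.clock.name
            )
        except Exception:
            logger.exception("method comparison (%s) failed; skipped", metric)
    dnam_cmp = report.method_comparison.get("dnam_age")
    if dnam_cmp is not None and len(dnam_cmp):
        methods = sorted(set(dnam_cmp["method_1"]) | set(dnam_cmp["method_2"]))
        tau = pd.DataFrame(1.0, index=methods, columns=methods)
        for _, row in dnam_cmp.iterrows():
            tau.loc[row["method_1"], row["method_2"]] = row["kendall_tau"]
            tau.loc[row["method_2"], row["method_1"]] = row["kendall_tau"]
        report.kendall_tau_matrix = tau

    # probe-wise cross-platform correlation at the common clock CpGs
    common_clock = [c for c in truth.clock_cpgs if c not in set(truth.platform_b_absent)]
    pw_tables = []
    pw_summaries = {}
    for method in config.methods:
        ba, bb = betas.get(("A", method)), betas.get(("B", method))
        if ba is None or bb is None:
            continue
        table, summary = probewise_platform_correlation(ba, bb[subjects], probes=common_clock)
        table.insert(0, "preprocessing", method)
        pw_tables.append(table)
        pw_summaries[method] = summary
    if pw_tables:
        report.probewise = pd.concat(pw_tables, ignore_index=True)
        report.probewise_summary = pw_summaries

    # technical replicate concordance (replicates live on platform B)
    groups = sheets["B"].replicate_groups()
    if groups:
        b_est = AgeEstimateSet(estimates.table[estimates.table["platform"] == "B"].copy())
        report.replicate = replicate_concordance(b_est, groups)

    # SNP identity across platforms (raw betas)
    ba = betas.get(("A", "raw"))
    bb = betas.get(("B", "raw"))
    if ba is None:
        ba = compute_beta(simulate_intensities(truth, config.sim, "A"))
    if bb is not None or ba is not None:
        if bb is None:
            bb = ba
        pairing, _ = snp_identity_check(ba, bb[[c for c in bb.columns if c in subjects]],
                                        truth.snp_probes)
        report.snp_pairing = pairing
    return report


def write_study(result: StudyResult, output_dir) -> None:
    """Write estimates, report tables, sample sheets and a provenance sidecar."""
    from . import io as eio

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.estimates.table.to_csv(out / "age_estimates.csv", index=False)
    eio.write_report(result.report.tables(), out / "report")
    for platform, sheet in result.sheets.items():
        eio.write_sample_sheet(sheet, out / f"sample_sheet_{platform}.csv")
    eio.write_clock(result.truth.clock, out / "clock_pan_tissue.csv")
    eio.write_clock(result.truth.blood_clock, out / "clock_blood.csv")
    sidecar = {
        "config": result.config.to_dict(),
        "config_hash": result.config.digest(),
        "seed": result.config.seed,
        "package_version": __version__,
    }
    if result.report.probewise_summary is not None:
        sidecar["probewise_summary"] = result.report.probewise_summary
    (out / "provenance.json").write_text(json.dumps(sidecar, indent=2, default=str))
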