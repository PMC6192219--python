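"""Synthetic two-platform Infinium-style methylation data.

The generator emulates the statistical structure the downstream analysis
assumes, without any real cohort data:

* a cohort of adults (default ages 19-50) whose clock CpGs drift with age
  on the clock's transformed age scale: CpG ``j`` has mean beta
  ``logistic(a_j + b_j * F(age))`` with probe effects drawn once per clock;
* age-invariant CpGs (constant mean per probe), and trimodal SNP identity
  probes reading genotype (0 / 0.5 / 1 with equal probabilities);
* fluorescence intensities built as exponential-tempered signal
  proportional to beta plus Gaussian background, with per-channel dye bias
  applied multiplicatively to in-band signals; out-of-band and
  negative-control intensities carry background only, so background
  correction has an honest target;
* two platforms sharing subjects, the second lacking a configurable subset
  of clock CpGs (defaults: 19/353 pan-tissue, 6/71 blood-clock CpGs);
* technical replicates obtained by re-measuring a sample's intensities
  under independent multiplicative log-normal noise.

The bundled clock definitions are not hard-coded: they are fitted to a
noiseless calibration cohort drawn from the same generative model, so any
``n_clock_cpgs`` works and noiseless prediction interpolates the true ages.
"""

from __future__ import annotations

import zlib
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .clock import ClockDefinition, transform_age
from .core import CHANNELS, EpiclockError, IntensityData, Manifest, SampleSheet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_intensities",
    "make_technical_replicates",
    "drop_platform_probes",
]


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Defaults mirror the benchmarked study design: 172 subjects aged 19-50,
    a 353-CpG pan-tissue-style clock missing 19 CpGs on the second
    platform, a 71-CpG blood-style clock missing 6, 59 SNP identity probes
    and 12 technical replicate pairs.
    """

    n_subjects: int = 172
    age_range: tuple[float, float] = (19.0, 50.0)
    n_clock_cpgs: int = 353
    n_blood_clock_cpgs: int = 71
    n_invariant_cpgs: int = 300
    n_snp_probes: int = 59
    beta_noise_sd: float = 0.02
    bg_mean: float = 500.0
    bg_sd: float = 100.0
    signal_scale: float = 3000.0
    signal_temper: float = 0.2
    dye_bias: dict = field(default_factory=lambda: {"Grn": 1.2, "Red": 1.0})
    replicate_pairs: int = 12
    replicate_noise_sd: float = 0.05
    platform_b_missing_clock_cpgs: int = 19
    platform_b_missing_blood_cpgs: int = 6
    n_oob_draws: int = 300
    n_negative_controls: int = 100
    n_norm_controls: int = 50
    norm_control_level: float = 0.8
    type1_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_subjects,
            self.n_clock_cpgs,
            self.n_blood_clock_cpgs,
            self.n_invariant_cpgs,
            self.n_snp_probes,
            self.replicate_pairs,
            self.platform_b_missing_clock_cpgs,
            self.platform_b_missing_blood_cpgs,
        )
        if any(c < 0 for c in counts):
            raise EpiclockError("all counts must be >= 0")
        if self.beta_noise_sd < 0 or self.bg_sd < 0 or self.replicate_noise_sd < 0:
            raise EpiclockError("standard deviations must be >= 0")
        if not self.age_range[0] < self.age_range[1]:
            raise EpiclockError("age_range must be increasing")
        if self.platform_b_missing_clock_cpgs > self.n_clock_cpgs:
            raise EpiclockError("cannot drop more clock CpGs than exist")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Noise-free cohort state: betas before any measurement corruption."""

    true_beta: pd.DataFrame
    ages: pd.Series
    clock: ClockDefinition
    blood_clock: ClockDefinition
    snp_genotypes: pd.DataFrame
    clock_cpgs: list[str]
    blood_cpgs: list[str]
    invariant_cpgs: list[str]
    snp_probes: list[str]
    manifests: dict[str, Manifest]
    platform_b_absent: list[str]

    @property
    def clocks(self) -> dict[str, ClockDefinition]:
        return {self.clock.name: self.clock, self.blood_clock.name: self.blood_clock}


def _rng_for(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage generator keyed by the run seed and a label."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _fit_linear_clock(
    name: str,
    cpgs: list[str],
    target: np.ndarray,
    betas: np.ndarray,
    adult_age: float,
    use_transform: bool,
) -> ClockDefinition:
    """Ridge fit (tiny penalty) of the target scale on noiseless betas.

    The regressors (logistic curves in F(age)) are massively collinear, so
    a small ridge penalty is used to keep coefficient norms bounded while
    still interpolating the calibration cohort to well below the clock's
    own error.
    """
    n_cal = betas.shape[0]
    model = Ridge(alpha=1e-6 * n_cal, fit_intercept=True)
    model.fit(betas, target)
    return ClockDefinition(
        name=name,
        intercept=float(model.intercept_),
        coefficients=pd.Series(model.coef_, index=pd.Index(cpgs, name="cpg")),
        gold_standard_mean=pd.Series(betas.mean(axis=0), index=pd.Index(cpgs, name="cpg")),
        adult_age=adult_age,
        use_transform=use_transform,
    )


def _probe_effects(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    a = rng.uniform(-1.5, 1.5, size=n)
    b = rng.uniform(0.25, 0.9, size=n) * rng.choice([-1.0, 1.0], size=n)
    return a, b


def _build_manifest(
    platform: str,
    cg_probes: pd.Index,
    snp_probes: list[str],
    design_type: pd.Series,
    color_channel: pd.Series,
    config: SimulationConfig,
) -> Manifest:
    rows = []
    for pid in cg_probes:
        cls = "rs" if pid in set(snp_probes) else "cg"
        rows.append((pid, design_type[pid], color_channel[pid], cls))
    for i in range(config.n_negative_controls):
        rows.append((f"neg_{i:04d}", "II", "Both", "negative_control"))
    for i in range(config.n_norm_controls):
        rows.append((f"norm_{i:04d}", "II", "Both", "norm_control"))
    table = pd.DataFrame(
        rows, columns=["probe_id", "design_type", "color_channel", "probe_class"]
    ).set_index("probe_id")
    return Manifest(table, platform=platform)


def simulate_cohort(config: SimulationConfig) -> tuple[SampleSheet, GroundTruth]:
    """Draw a cohort, its noise-free betas, and consistent clock definitions."""
    if config.n_subjects < 3:
        raise EpiclockError("need n_subjects >= 3 (regression stages undefined below that)")
    rng = _rng_for(config.seed, "cohort")
    ages = rng.uniform(*config.age_range, size=config.n_subjects)
    sample_ids = [f"S{i:04d}" for i in range(config.n_subjects)]

    clock_cpgs = [f"cg_clk_{i:05d}" for i in range(config.n_clock_cpgs)]
    blood_cpgs = [f"cg_bld_{i:05d}" for i in range(config.n_blood_clock_cpgs)]
    invariant_cpgs = [f"cg_inv_{i:05d}" for i in range(config.n_invariant_cpgs)]
    snp_probes = [f"rs_{i:04d}" for i in range(config.n_snp_probes)]

    adult_age = 20.0
    f_ages = transform_age(ages, adult_age)

    eff_rng = _rng_for(config.seed, "probe-effects")
    a_clk, b_clk = _probe_effects(eff_rng, config.n_clock_cpgs)
    a_bld, b_bld = _probe_effects(eff_rng, config.n_blood_clock_cpgs)
    inv_levels = eff_rng.beta(0.5, 0.5, size=config.n_invariant_cpgs)

    noise_rng = _rng_for(config.seed, "beta-noise")

    def noisy(mean: np.ndarray) -> np.ndarray:
        if config.beta_noise_sd == 0:
            return np.clip(mean, 0.0, 1.0)
        return np.clip(mean + noise_rng.normal(0.0, config.beta_noise_sd, mean.shape), 0.0, 1.0)

    beta_clk = noisy(_logistic(a_clk[:, None] + b_clk[:, None] * f_ages[None, :]))
    beta_bld = noisy(_logistic(a_bld[:, None] + b_bld[:, None] * f_ages[None, :]))
    beta_inv = noisy(np.repeat(inv_levels[:, None], config.n_subjects, axis=1))
    genotypes = rng.choice([0.0, 0.5, 1.0], size=(config.n_snp_probes, config.n_subjects))

    all_probes = clock_cpgs + blood_cpgs + invariant_cpgs + snp_probes
    true_beta = pd.DataFrame(
        np.vstack([beta_clk, beta_bld, beta_inv, genotypes]),
        index=pd.Index(all_probes, name="probe_id"),
        columns=pd.Index(sample_ids, name="sample_id"),
    )

    # clocks fitted to a separate noiseless calibration cohort
    cal_rng = _rng_for(config.seed, "calibration-cohort")
    n_cal = max(2 * config.n_clock_cpgs, 400)
    cal_ages = cal_rng.uniform(*config.age_range, size=n_cal)
    cal_f = transform_age(cal_ages, adult_age)
    cal_clk = _logistic(a_clk[None, :] + b_clk[None, :] * cal_f[:, None])
    cal_bld = _logistic(a_bld[None, :] + b_bld[None, :] * cal_f[:, None])
    clock = _fit_linear_clock(
        "pan-tissue-353", clock_cpgs, cal_f, cal_clk, adult_age, use_transform=True
    )
    blood_clock = _fit_linear_clock(
        "blood-71", blood_cpgs, cal_ages, cal_bld, adult_age, use_transform=False
    )

    # platform design metadata, shared across platforms for common probes
    design_rng = _rng_for(config.seed, "design")
    probe_index = pd.Index(all_probes)
    is_type1 = design_rng.random(len(probe_index)) < config.type1_fraction
    design_type = pd.Series(np.where(is_type1, "I", "II"), index=probe_index)
    chan = np.where(design_rng.random(len(probe_index)) < 0.5, "Grn", "Red")
    color_channel = pd.Series(np.where(is_type1, chan, "Both"), index=probe_index)

    absent_clk = list(
        design_rng.choice(clock_cpgs, size=config.platform_b_missing_clock_cpgs, replace=False)
    )
    absent_bld = list(
        design_rng.choice(blood_cpgs, size=config.platform_b_missing_blood_cpgs, replace=False)
    )
    absent = absent_clk + absent_bld
    manifest_a = _build_manifest("A", probe_index, snp_probes, design_type, color_channel, config)
    manifest_b = _build_manifest(
        "B", probe_index.difference(pd.Index(absent), sort=False), snp_probes,
        design_type, color_channel, config,
    )

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "age": ages,
                "platform": "A",
                "tissue": "monocyte",
                "replicate_group": pd.NA,
            }
        )
    )
    truth = GroundTruth(
        true_beta=true_beta,
        ages=pd.Series(ages, index=sample_ids, name="age"),
        clock=clock,
        blood_clock=blood_clock,
        snp_genotypes=true_beta.loc[snp_probes],
        clock_cpgs=clock_cpgs,
        blood_cpgs=blood_cpgs,
        invariant_cpgs=invariant_cpgs,
        snp_probes=snp_probes,
        manifests={"A": manifest_a, "B": manifest_b},
        platform_b_absent=absent,
    )
    return sheet, truth


def simulate_intensities(
    truth: GroundTruth, config: SimulationConfig, platform: str = "A"
) -> IntensityData:
    """Corrupt true betas into fluorescence intensities for one platform.

    Signal for the methylated read is ``signal_scale * beta * dye(channel)``
    times an Exp(1)-tempered multiplicative draw ``1 + temper*(E - 1)``
    (mean 1, coefficient of variation = ``signal_temper``); the
    unmethylated read is analogous with ``1 - beta``.  Gaussian background
    (truncated at zero) is added to every read; out-of-band and
    negative-control entries carry background only; normalization controls
    carry a fixed signal level so dye bias is estimable.
    """
    if platform not in truth.manifests:
        raise EpiclockError(f"unknown platform {platform!r}")
    manifest = truth.manifests[platform]
    rng = _rng_for(config.seed, f"intensities-{platform}")
    assay = manifest.table[~manifest.table["probe_class"].isin(["negative_control", "norm_control"])]
    probes = assay.index
    beta = truth.true_beta.loc[probes].to_numpy(dtype=float)
    n_probes, n_samples = beta.shape
    samples = list(truth.true_beta.columns)

    is2 = (assay["design_type"] == "II").to_numpy()
    chan_m = np.where(is2, "Grn", assay["color_channel"].to_numpy())
    chan_u = np.where(is2, "Red", assay["color_channel"].to_numpy())
    dye_m = np.vectorize(config.dye_bias.__getitem__)(chan_m).astype(float)
    dye_u = np.vectorize(config.dye_bias.__getitem__)(chan_u).astype(float)

    def temper(shape) -> np.ndarray:
        if config.signal_temper == 0:
            return np.ones(shape)
        return 1.0 + config.signal_temper * (rng.exponential(1.0, shape) - 1.0)

    def background(shape) -> np.ndarray:
        if config.bg_sd == 0:
            return np.full(shape, float(config.bg_mean))
        return np.clip(rng.normal(config.bg_mean, config.bg_sd, shape), 0.0, None)

    s_m = config.signal_scale * beta * dye_m[:, None] * temper(beta.shape)
    s_u = config.signal_scale * (1.0 - beta) * dye_u[:, None] * temper(beta.shape)
    meth = np.clip(s_m + background(beta.shape), 0.0, None)
    unmeth = np.clip(s_u + background(beta.shape), 0.0, None)

    oob = {
        ch: pd.DataFrame(background((config.n_oob_draws, n_samples)), columns=samples)
        for ch in CHANNELS
    }

    ctrl_rows = []
    ctrl_vals = []
    for ch in CHANNELS:
        for i in range(config.n_negative_controls):
            ctrl_rows.append(("negative_control", ch, f"neg_{i:04d}"))
            ctrl_vals.append(background((n_samples,)))
        level = config.signal_scale * config.norm_control_level * config.dye_bias[ch]
        for i in range(config.n_norm_controls):
            ctrl_rows.append(("norm_control", ch, f"norm_{i:04d}"))
            ctrl_vals.append(np.clip(level * temper((n_samples,)) + background((n_samples,)), 0.0, None))
    controls = pd.DataFrame(
        np.vstack(ctrl_vals),
        index=pd.MultiIndex.from_tuples(ctrl_rows, names=["probe_class", "channel", "probe_id"]),
        columns=samples,
    )

    return IntensityData(
        methylated=pd.DataFrame(meth, index=probes, columns=samples),
        unmethylated=pd.DataFrame(unmeth, index=probes, columns=samples),
        oob=oob,
        controls=controls,
        manifest=manifest,
        platform=platform,
    )


def make_technical_replicates(
    intensities: IntensityData,
    sheet: SampleSheet,
    pairs: int,
    noise_sd: float,
    seed: int = 0,
) -> tuple[IntensityData, SampleSheet]:
    """Duplicate the first ``pairs`` samples under multiplicative noise.

    Every intensity entry of a replicate (in-band, out-of-band and control)
    is the original times an independent ``exp(N(0, noise_sd))`` factor,
    emulating re-hybridization of the same bisulfite-converted DNA.  The
    sample sheet gains the replicate rows, grouped with their originals.
    """
    samples = list(intensities.sample_ids)
    if pairs > len(samples):
        raise EpiclockError(f"requested {pairs} replicate pairs but only {len(samples)} samples")
    rng = np.random.default_rng([seed, zlib.crc32(b"replicates")])
    chosen = samples[:pairs]

    def perturb(col: np.ndarray) -> np.ndarray:
        if noise_sd == 0:
            return col.copy()
        return col * np.exp(rng.normal(0.0, noise_sd, col.shape))

    meth = intensities.methylated.copy()
    unmeth = intensities.unmethylated.copy()
    oob = {ch: df.copy() for ch, df in intensities.oob.items()}
    controls = None if intensities.controls is None else intensities.controls.copy()
    new_rows = []
    sheet_idx = sheet.table.set_index("sample_id")
    for s in chosen:
        rep = f"{s}_rep"
        meth[rep] = perturb(meth[s].to_numpy(dtype=float))
        unmeth[rep] = perturb(unmeth[s].to_numpy(dtype=float))
        for ch in oob:
            oob[ch][rep] = perturb(oob[ch][s].to_numpy(dtype=float))
        if controls is not None:
            controls[rep] = perturb(controls[s].to_numpy(dtype=float))
        meta = sheet_idx.loc[s]
        new_rows.append(
            {
                "sample_id": rep,
                "age": meta["age"],
                "platform": intensities.platform,
                "tissue": meta["tissue"],
                "replicate_group": s,
            }
        )
    table = sheet.table.copy()
    table.loc[table["sample_id"].isin(chosen), "replicate_group"] = table.loc[
        table["sample_id"].isin(chosen), "sample_id"
    ]
    table = pd.concat([table, pd.DataFrame(new_rows)], ignore_index=True)
    out = IntensityData(
        methylated=meth,
        unmethylated=unmeth,
        oob=oob,
        controls=controls,
        manifest=intensities.manifest,
        platform=intensities.platform,
    )
    return out, SampleSheet(table)


def drop_platform_probes(data, probe_list):
    """Remove probe rows from a beta matrix or IntensityData.

    Probes not present trigger a warning, not an error, so the same absent
    list can be applied to matrices that were already subset.
    """
    probe_list = list(probe_list)
    if isinstance(data, pd.DataFrame):
        present = [p for p in probe_list if p in data.index]
        _warn_absent(probe_list, present)
        return data.drop(index=present)
    if isinstance(data, IntensityData):
        present = [p for p in probe_list if p in data.methylated.index]
        _warn_absent(probe_list, present)
        return IntensityData(
            methylated=data.methylated.drop(index=present),
            unmethylated=data.unmethylated.drop(index=present),
            oob=data.oob,
            controls=data.controls,
            manifest=None if data.manifest is None else data.manifest.subset(
                data.manifest.probe_ids.difference(pd.Index(present))
            ),
            platform=data.platform,
        )
    raise EpiclockError(f"cannot drop probes from {type(data).__name__}")


def _warn_absent(requested: list, present: list) -> None:
    missing = set(requested) - set(present)
    if missing:
        warnings.warn(f"{len(missing)} probes to drop were not present", stacklevel=3)
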