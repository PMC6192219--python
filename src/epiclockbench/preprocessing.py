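"""Preprocessing methods mapping raw intensities to beta values.

Four routes are provided, mirroring common Infinium practice:

``raw``
    Betas straight from uncorrected intensities.
``noob``
    Normal-exponential background deconvolution using out-of-band (OOB)
    intensities: per sample and color channel, the background is modelled
    as Normal(mu_b, sigma_b) estimated from OOB draws, the true signal as
    Exponential(alpha), and every observed intensity is replaced by the
    posterior mean E[S | X = x]; followed by a dye-bias correction scaling
    the green channel so its normalization-control mean matches the red
    channel's.
``quantile``
    Design-type-stratified quantile normalization of betas across samples.
``gs``
    An emulation of GenomeStudio's color correction / background
    subtraction: per sample and channel, subtract the negative-control mean
    (floored at a small positive constant), then scale channels to equalize
    normalization-control means.  GenomeStudio's exact algorithm is
    proprietary; this implements the shift-and-scale normalization it is
    described as performing.

``noob`` and ``gs`` are strictly per-sample operations; ``quantile`` is the
only cross-sample method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clock import normexp_signal
from .core import CHANNELS, EpiclockError, IntensityData, compute_beta

MIN_OOB_DRAWS = 30
ALPHA_FLOOR = 1.0  # fluorescence units; floor for the exponential-mean estimate
GS_FLOOR = 1.0  # fluorescence units; floor after negative-control subtraction
REFERENCE_CHANNEL = "Red"

__all__ = [
    "NormexpParams",
    "DyeCorrection",
    "preprocess_raw",
    "noob_correct",
    "quantile_normalize",
    "gs_correct",
    "preprocess",
    "PREPROCESSORS",
]


@dataclass
class NormexpParams:
    """Fitted normal+exponential parameters, one row per (sample, channel).

    ``table`` columns: ``mu_b`` (background mean), ``sigma_b`` (background
    sd) and ``alpha`` (signal exponential mean), all in fluorescence units.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table["sigma_b"] <= 0).any() or (self.table["alpha"] <= 0).any():
            raise EpiclockError("normexp parameters require sigma_b > 0 and alpha > 0")


@dataclass
class DyeCorrection:
    """Per-sample, per-channel multiplicative scales; reference scale is 1."""

    scales: pd.DataFrame  # samples x channels
    reference: str = REFERENCE_CHANNEL

    def __post_init__(self) -> None:
        if (self.scales.to_numpy() <= 0).any():
            raise EpiclockError("dye-correction scales must be positive")
        if not np.allclose(self.scales[self.reference].to_numpy(), 1.0):
            raise EpiclockError("reference channel scale must be 1")


def _probe_channels(intensities: IntensityData) -> tuple[pd.Series, pd.Series]:
    """Color channel of each probe's methylated and unmethylated reads.

    Type I probes read both alleles in their design channel; type II probes
    read methylated in green and unmethylated in red.
    """
    if intensities.manifest is None:
        raise EpiclockError("intensity data carries no manifest; channel assignment unknown")
    man = intensities.manifest.table.reindex(intensities.probe_ids)
    if man["design_type"].isna().any():
        missing = man.index[man["design_type"].isna()].tolist()
        raise EpiclockError(f"probes absent from manifest: {missing[:5]}")
    is2 = man["design_type"] == "II"
    chan_m = man["color_channel"].where(~is2, "Grn")
    chan_u = man["color_channel"].where(~is2, "Red")
    return chan_m, chan_u


def _control_block(intensities: IntensityData, probe_class: str, channel: str) -> pd.DataFrame:
    if intensities.controls is None:
        raise EpiclockError(f"no control-probe intensities available ({probe_class})")
    try:
        block = intensities.controls.xs((probe_class, channel), level=("probe_class", "channel"))
    except KeyError:
        raise EpiclockError(f"no {probe_class} controls for channel {channel}") from None
    if block.empty:
        raise EpiclockError(f"no {probe_class} controls for channel {channel}")
    return block


# ---------------------------------------------------------------------------
# raw
# ---------------------------------------------------------------------------


def preprocess_raw(intensities: IntensityData, offset: float = 100.0) -> pd.DataFrame:
    """Betas from uncorrected intensities."""
    return compute_beta(intensities, offset=offset)


# ---------------------------------------------------------------------------
# noob
# ---------------------------------------------------------------------------


def noob_correct(
    intensities: IntensityData, dye_correct: bool = True
) -> tuple[IntensityData, NormexpParams]:
    """Normal-exponential background correction on out-of-band intensities.

    Per sample and channel: ``mu_b``/``sigma_b`` are the mean/sd of that
    channel's OOB draws; ``alpha`` is the plug-in moment estimate
    ``max(mean(observed) - mu_b, 1)``.  Every in-band intensity is replaced
    by the normexp posterior mean (always > 0), then the green channel is
    scaled so its normalization-control mean matches the red channel's.
    """
    chan_m, chan_u = _probe_channels(intensities)
    meth = intensities.methylated.to_numpy(dtype=float).copy()
    unmeth = intensities.unmethylated.to_numpy(dtype=float).copy()
    rows = []
    samples = list(intensities.sample_ids)
    corrected_controls = None if intensities.controls is None else intensities.controls.copy()
    for channel in CHANNELS:
        if channel not in intensities.oob:
            raise EpiclockError(f"no out-of-band intensities for channel {channel}")
        m_mask = (chan_m == channel).to_numpy()
        u_mask = (chan_u == channel).to_numpy()
        for j, sample in enumerate(samples):
            draws = intensities.oob[channel][sample].dropna().to_numpy(dtype=float)
            if draws.size < MIN_OOB_DRAWS:
                raise EpiclockError(
                    f"sample {sample}, channel {channel}: {draws.size} OOB draws "
                    f"(minimum {MIN_OOB_DRAWS})"
                )
            mu_b = float(draws.mean())
            sigma_b = float(max(draws.std(ddof=1), 1e-6))
            observed = np.concatenate([meth[m_mask, j], unmeth[u_mask, j]])
            observed = observed[~np.isnan(observed)]
            alpha = float(max(observed.mean() - mu_b, ALPHA_FLOOR)) if observed.size else ALPHA_FLOOR
            meth[m_mask, j] = normexp_signal(meth[m_mask, j], mu_b, sigma_b, alpha)
            unmeth[u_mask, j] = normexp_signal(unmeth[u_mask, j], mu_b, sigma_b, alpha)
            if corrected_controls is not None:
                idx = corrected_controls.index.get_level_values("channel") == channel
                corrected_controls.loc[idx, sample] = normexp_signal(
                    corrected_controls.loc[idx, sample].to_numpy(dtype=float), mu_b, sigma_b, alpha
                )
            rows.append((sample, channel, mu_b, sigma_b, alpha))
    params = NormexpParams(
        pd.DataFrame(rows, columns=["sample_id", "channel", "mu_b", "sigma_b", "alpha"]).set_index(
            ["sample_id", "channel"]
        )
    )
    out = IntensityData(
        methylated=pd.DataFrame(meth, index=intensities.probe_ids, columns=intensities.sample_ids),
        unmethylated=pd.DataFrame(
            unmeth, index=intensities.probe_ids, columns=intensities.sample_ids
        ),
        oob=intensities.oob,
        controls=corrected_controls,
        manifest=intensities.manifest,
        platform=intensities.platform,
    )
    if dye_correct and corrected_controls is not None:
        out, _ = apply_dye_correction(out)
    return out, params


def apply_dye_correction(intensities: IntensityData) -> tuple[IntensityData, DyeCorrection]:
    """Scale non-reference channels so norm-control means match the reference."""
    chan_m, chan_u = _probe_channels(intensities)
    samples = list(intensities.sample_ids)
    ref_means = _control_block(intensities, "norm_control", REFERENCE_CHANNEL)[samples].mean(axis=0)
    scales = pd.DataFrame(1.0, index=pd.Index(samples, name="sample_id"), columns=list(CHANNELS))
    meth = intensities.methylated.copy()
    unmeth = intensities.unmethylated.copy()
    for channel in CHANNELS:
        if channel == REFERENCE_CHANNEL:
            continue
        ch_means = _control_block(intensities, "norm_control", channel)[samples].mean(axis=0)
        scale = (ref_means / ch_means).astype(float)
        scales[channel] = scale.to_numpy()
        m_mask = (chan_m == channel).to_numpy()
        u_mask = (chan_u == channel).to_numpy()
        meth.loc[m_mask] = meth.loc[m_mask].mul(scale, axis=1)
        unmeth.loc[u_mask] = unmeth.loc[u_mask].mul(scale, axis=1)
    out = IntensityData(
        methylated=meth,
        unmethylated=unmeth,
        oob=intensities.oob,
        controls=intensities.controls,
        manifest=intensities.manifest,
        platform=intensities.platform,
    )
    return out, DyeCorrection(scales=scales)


# ---------------------------------------------------------------------------
# quantile
# ---------------------------------------------------------------------------


def quantile_normalize(
    values: pd.DataFrame, strata: pd.Series | None = None
) -> pd.DataFrame:
    """Force identical within-stratum value distributions across samples.

    Within each stratum (typically probe design type, whose two chemistries
    have different beta distributions), every sample's sorted values are
    replaced by the across-sample mean of sorted values; ties receive
    averaged ranks.  Missing entries stay missing and do not contribute to
    the reference distribution.
    """
    if values.shape[1] < 2:
        warnings.warn("quantile normalization with a single sample is the identity", stacklevel=2)
        return values.copy()
    out = values.copy()
    if strata is None:
        strata = pd.Series("all", index=values.index)
    strata = strata.reindex(values.index)
    for _, probe_ids in strata.groupby(strata).groups.items():
        block = values.loc[probe_ids]
        out.loc[probe_ids] = _quantile_normalize_block(block)
    return out


def _quantile_normalize_block(block: pd.DataFrame) -> pd.DataFrame:
    arr = block.to_numpy(dtype=float)
    n_probes, n_samples = arr.shape
    counts = (~np.isnan(arr)).sum(axis=0)
    if counts.min() == 0:
        raise EpiclockError("quantile normalization: a sample has no observed values in a stratum")
    # reference quantile function: mean of per-sample quantile functions on a
    # common grid of max(counts) points (exact when counts are equal)
    n_ref = int(counts.max())
    grid = np.linspace(0.0, 1.0, n_ref) if n_ref > 1 else np.array([0.5])
    ref = np.zeros(n_ref)
    for j in range(n_samples):
        col = np.sort(arr[~np.isnan(arr[:, j]), j])
        pos = np.linspace(0.0, 1.0, col.size) if col.size > 1 else np.array([0.5])
        ref += np.interp(grid, pos, col)
    ref /= n_samples
    out = arr.copy()
    for j in range(n_samples):
        mask = ~np.isnan(arr[:, j])
        col = arr[mask, j]
        # average ranks for ties, mapped to the reference quantile function
        order = col.argsort(kind="mergesort")
        sorted_col = col[order]
        uniq, inv, cnt = np.unique(sorted_col, return_inverse=True, return_counts=True)
        start = np.concatenate([[0], np.cumsum(cnt)[:-1]])
        mean_rank_of_uniq = start + (cnt - 1) / 2.0
        tied_ranks = np.empty(col.size)
        tied_ranks[order] = mean_rank_of_uniq[inv]
        pos = tied_ranks / (col.size - 1) if col.size > 1 else np.full(col.size, 0.5)
        out[mask, j] = np.interp(pos, grid, ref)
    return pd.DataFrame(out, index=block.index, columns=block.columns)


def quantile_preprocess(intensities: IntensityData, offset: float = 100.0) -> pd.DataFrame:
    """Raw betas followed by design-type-stratified quantile normalization."""
    beta = compute_beta(intensities, offset=offset)
    strata = None
    if intensities.manifest is not None:
        strata = intensities.manifest.table["design_type"].reindex(beta.index)
    return quantile_normalize(beta, strata=strata)


# ---------------------------------------------------------------------------
# GenomeStudio-style
# ---------------------------------------------------------------------------


def gs_correct(intensities: IntensityData) -> IntensityData:
    """Negative-control background subtraction plus channel equalization.

    Per sample and channel the negative-control mean is subtracted from all
    in-band intensities (floored at a small positive constant), after which
    channels are rescaled so normalization-control means agree with the
    reference (red) channel.
    """
    chan_m, chan_u = _probe_channels(intensities)
    samples = list(intensities.sample_ids)
    meth = intensities.methylated.copy()
    unmeth = intensities.unmethylated.copy()
    corrected_controls = None if intensities.controls is None else intensities.controls.copy()
    for channel in CHANNELS:
        neg = _control_block(intensities, "negative_control", channel)[samples].mean(axis=0)
        m_mask = (chan_m == channel).to_numpy()
        u_mask = (chan_u == channel).to_numpy()
        meth.loc[m_mask] = (meth.loc[m_mask] - neg).clip(lower=GS_FLOOR)
        unmeth.loc[u_mask] = (unmeth.loc[u_mask] - neg).clip(lower=GS_FLOOR)
        if corrected_controls is not None:
            idx = (
                corrected_controls.index.get_level_values("channel") == channel
            ) & (corrected_controls.index.get_level_values("probe_class") != "negative_control")
            corrected_controls.loc[idx, samples] = (
                corrected_controls.loc[idx, samples].sub(neg, axis=1).clip(lower=GS_FLOOR)
            )
    shifted = IntensityData(
        methylated=meth,
        unmethylated=unmeth,
        oob=intensities.oob,
        controls=corrected_controls,
        manifest=intensities.manifest,
        platform=intensities.platform,
    )
    out, _ = apply_dye_correction(shifted)
    return out


def gs_preprocess(intensities: IntensityData, offset: float = 100.0) -> pd.DataFrame:
    return compute_beta(gs_correct(intensities), offset=offset)


def noob_preprocess(intensities: IntensityData, offset: float = 100.0) -> pd.DataFrame:
    corrected, _ = noob_correct(intensities)
    return compute_beta(corrected, offset=offset)


PREPROCESSORS = {
    "raw": preprocess_raw,
    "gs": gs_preprocess,
    "quantile": quantile_preprocess,
    "noob": noob_preprocess,
}


def preprocess(intensities: IntensityData, method: str, offset: float = 100.0) -> pd.DataFrame:
    """Dispatch to one of ``raw``, ``gs``, ``quantile`` or ``noob``."""
    try:
        fn = PREPROCESSORS[method]
    except KeyError:
        raise EpiclockError(
            f"unknown preprocessing method {method!r}; choose from {sorted(PREPROCESSORS)}"
        ) from None
    return fn(intensities, offset=offset)
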