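"""DNA-methylation age prediction.

The pan-tissue style predictor is a linear model on CpG beta values whose
output lives on a transformed age scale: ages are log-compressed below an
``adult_age`` knot (default 20 years) and linear above it,

    F(age) = log(age + 1) - log(adult_age + 1)      if age <= adult_age
    F(age) = (age - adult_age) / (adult_age + 1)    otherwise

so the predicted score is mapped back to years with the inverse of F.
Blood-specific (Hannum-style) predictors use the raw-age scale instead
(``use_transform=False``).

Prediction proceeds as: impute missing clock CpGs with the clock's
gold-standard means, optionally calibrate each sample's clock-CpG beta
distribution to the gold-standard profile with a three-component
beta-mixture quantile map, form the linear score, and anti-transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr

from .core import EpiclockError

logger = logging.getLogger(__name__)

__all__ = [
    "ClockDefinition",
    "CalibrationModel",
    "transform_age",
    "inverse_transform",
    "impute_missing",
    "calibrate_to_gold_standard",
    "predict_dnam_age",
    "reduce_clock",
]


# ---------------------------------------------------------------------------
# Age transform
# ---------------------------------------------------------------------------


def transform_age(age, adult_age: float = 20.0):
    """Map chronological age (years) to the clock's transformed scale.

    Continuous, strictly increasing, with ``F(adult_age) = 0``.  Defined for
    ``age > -1``.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1):
        raise EpiclockError("transform_age requires age > -1")
    young = np.log(age + 1.0) - np.log(adult_age + 1.0)
    old = (age - adult_age) / (adult_age + 1.0)
    out = np.where(age <= adult_age, young, old)
    return float(out) if out.ndim == 0 else out


def inverse_transform(y, adult_age: float = 20.0):
    """Inverse of :func:`transform_age`; defined on all reals."""
    y = np.asarray(y, dtype=float)
    young = np.exp(y + np.log(adult_age + 1.0)) - 1.0
    old = y * (adult_age + 1.0) + adult_age
    out = np.where(y <= 0, young, old)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Clock definition
# ---------------------------------------------------------------------------


@dataclass
class ClockDefinition:
    """A linear epigenetic-age predictor.

    Attributes
    ----------
    intercept
        Model intercept on the (possibly transformed) age scale.
    coefficients
        Per-CpG weights, indexed by CpG ID.
    gold_standard_mean
        Reference mean beta per clock CpG; used both to impute missing
        CpGs and as the calibration target profile.
    adult_age
        Knot of the age transform, in years.
    use_transform
        True for pan-tissue style clocks (predict on the F scale),
        False for Hannum-style clocks (predict age directly).
    """

    name: str
    intercept: float
    coefficients: pd.Series
    gold_standard_mean: pd.Series
    adult_age: float = 20.0
    use_transform: bool = True

    def __post_init__(self) -> None:
        if len(self.coefficients) == 0:
            raise EpiclockError("clock has no coefficients")
        if self.adult_age <= 0:
            raise EpiclockError("adult_age must be > 0")
        missing = set(self.coefficients.index) - set(self.gold_standard_mean.index)
        if missing:
            raise EpiclockError(
                f"gold_standard_mean lacks {len(missing)} clock CpGs, e.g. {sorted(missing)[:3]}"
            )

    @property
    def cpgs(self) -> pd.Index:
        return self.coefficients.index

    def drop_cpgs(self, cpgs) -> "ClockDefinition":
        """A reduced clock lacking the listed CpGs (coefficients removed)."""
        keep = self.coefficients.index.difference(pd.Index(cpgs))
        return ClockDefinition(
            name=f"{self.name}-reduced{len(keep)}",
            intercept=self.intercept,
            coefficients=self.coefficients.loc[keep],
            gold_standard_mean=self.gold_standard_mean,
            adult_age=self.adult_age,
            use_transform=self.use_transform,
        )


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute_missing(
    beta_clock: pd.DataFrame, clock: ClockDefinition
) -> tuple[pd.DataFrame, pd.Series]:
    """Fill missing / platform-absent clock CpGs with gold-standard means.

    Returns the completed clock-CpG beta matrix (rows exactly the clock's
    CpGs, in clock order) and the per-sample count of imputed CpGs.
    """
    present = clock.cpgs.intersection(beta_clock.index)
    full = beta_clock.reindex(clock.cpgs)
    observed = full.notna().sum(axis=0)
    none_observed = observed[observed == 0].index.tolist()
    if len(present) == 0 or len(none_observed) == len(full.columns) > 0:
        raise EpiclockError("no observed clock CpGs")
    if none_observed:
        raise EpiclockError(f"no observed clock CpGs for samples: {none_observed}")
    n_imputed = full.isna().sum(axis=0)
    gold = clock.gold_standard_mean.reindex(clock.cpgs)
    filled = full.apply(lambda col: col.fillna(gold))
    return filled, n_imputed.rename("n_imputed")


# ---------------------------------------------------------------------------
# Beta-mixture calibration
# ---------------------------------------------------------------------------

_EPS = 1e-6


@dataclass
class BetaMixture:
    """Three-component beta mixture fitted by EM."""

    shapes: np.ndarray  # (3, 2) array of (a, b)
    weights: np.ndarray  # (3,) summing to 1
    converged: bool = True
    n_iter: int = 0

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, _EPS, 1 - _EPS)
        out = np.zeros_like(x, dtype=float)
        for (a, b), w in zip(self.shapes, self.weights):
            out += w * stats.beta.cdf(x, a, b)
        return out


@dataclass
class CalibrationModel:
    """Monotone quantile map from a sample's beta distribution to the gold standard."""

    sample_fit: BetaMixture
    gold_fit: BetaMixture
    grid: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.grid is None:
            self.grid = np.linspace(_EPS, 1 - _EPS, 4001)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        u = self.sample_fit.cdf(np.asarray(x, dtype=float))
        gold_cdf = self.gold_fit.cdf(self.grid)
        # enforce strict monotonicity for interpolation
        gold_cdf = np.maximum.accumulate(gold_cdf)
        gold_cdf += np.arange(gold_cdf.size) * 1e-12
        return np.clip(np.interp(u, gold_cdf, self.grid), 0.0, 1.0)


def _moment_shapes(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted method-of-moments beta shape estimates, guarded."""
    wsum = w.sum()
    if wsum <= 0:
        return 1.0, 1.0
    m = float(np.dot(w, x) / wsum)
    v = float(np.dot(w, (x - m) ** 2) / wsum)
    m = min(max(m, _EPS), 1 - _EPS)
    v = max(v, 1e-8)
    common = m * (1 - m) / v - 1.0
    if common <= 0:
        common = 0.01
    a = np.clip(m * common, 0.01, 1e4)
    b = np.clip((1 - m) * common, 0.01, 1e4)
    return float(a), float(b)


def fit_beta_mixture(
    values: np.ndarray,
    n_components: int = 3,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> BetaMixture:
    """EM fit of a beta mixture to values in (0, 1).

    Components are initialized from value terciles (a deterministic,
    k-means-like split on sorted values), then refined by EM with
    method-of-moments M-steps.  The moment M-step approaches the tolerance
    geometrically, so the iteration cap is generous; non-convergence is
    reported via the ``converged`` flag and callers fall back to the
    identity map.
    """
    x = np.clip(np.asarray(values, dtype=float), _EPS, 1 - _EPS)
    x = x[~np.isnan(x)]
    log_x = np.log(x)
    log_1mx = np.log1p(-x)
    from scipy.special import betaln

    def logpdf(a: float, b: float) -> np.ndarray:
        return (a - 1) * log_x + (b - 1) * log_1mx - betaln(a, b)

    order = np.argsort(x)
    splits = np.array_split(order, n_components)
    shapes = []
    weights = []
    for part in splits:
        w = np.zeros_like(x)
        w[part] = 1.0
        shapes.append(_moment_shapes(x, w))
        weights.append(max(len(part), 1) / len(x))
    shapes = np.array(shapes)
    weights = np.array(weights)
    weights /= weights.sum()

    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = np.stack(
            [np.log(w + 1e-300) + logpdf(a, b) for (a, b), w in zip(shapes, weights)]
        )
        mx = logp.max(axis=0)
        lse = mx + np.log(np.exp(logp - mx).sum(axis=0))
        resp = np.exp(logp - lse)
        ll = float(lse.sum())
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1.0):
            converged = True
            break
        prev_ll = ll
        weights = resp.sum(axis=1) / len(x)
        weights = np.clip(weights, 1e-6, None)
        weights /= weights.sum()
        shapes = np.array([_moment_shapes(x, resp[k]) for k in range(n_components)])
    return BetaMixture(shapes=shapes, weights=weights, converged=converged, n_iter=it)


def calibrate_to_gold_standard(
    beta_clock: pd.DataFrame,
    clock: ClockDefinition,
    enabled: bool = True,
    min_cpgs: int = 30,
) -> tuple[pd.DataFrame, pd.Series]:
    """Map each sample's clock-CpG betas onto the gold-standard distribution.

    Per sample, a three-component beta mixture is fitted by EM to the
    sample's clock betas and to the gold-standard profile; values are then
    transported through the monotone quantile map between the two fitted
    distributions.  With fewer than ``min_cpgs`` observed CpGs, or on EM
    failure for a sample, the identity map is used (and logged).

    Returns the calibrated matrix and a boolean per-sample ``calibrated``
    flag.
    """
    if not enabled:
        flags = pd.Series(False, index=beta_clock.columns, name="calibrated")
        return beta_clock.copy(), flags
    if len(beta_clock.index) < min_cpgs:
        warnings.warn(
            f"only {len(beta_clock.index)} clock CpGs observed (< {min_cpgs}); "
            "calibration skipped",
            stacklevel=2,
        )
        flags = pd.Series(False, index=beta_clock.columns, name="calibrated")
        return beta_clock.copy(), flags
    gold = clock.gold_standard_mean.reindex(beta_clock.index).dropna().to_numpy()
    gold_fit = fit_beta_mixture(gold)
    out = beta_clock.copy()
    flags = pd.Series(True, index=beta_clock.columns, name="calibrated")
    for sample in beta_clock.columns:
        vals = beta_clock[sample].to_numpy(dtype=float)
        try:
            sample_fit = fit_beta_mixture(vals)
        except Exception:  # pragma: no cover - defensive
            sample_fit = None
        if sample_fit is None or not sample_fit.converged:
            logger.warning("calibration EM did not converge for %s; identity used", sample)
            flags[sample] = False
            continue
        model = CalibrationModel(sample_fit=sample_fit, gold_fit=gold_fit)
        out[sample] = model(vals)
    return out, flags


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_dnam_age(
    beta: pd.DataFrame,
    clock: ClockDefinition,
    calibrate: bool = False,
) -> pd.DataFrame:
    """Predict DNAm age (years) for every sample of a beta matrix.

    Non-clock probe rows are ignored; probe row order is irrelevant.
    Returns a DataFrame indexed by sample with columns ``dnam_age``,
    ``n_imputed`` and ``calibrated``.
    """
    clock_rows = beta.index.intersection(clock.cpgs)
    filled, n_imputed = impute_missing(beta.loc[clock_rows], clock)
    calibrated, flags = calibrate_to_gold_standard(filled, clock, enabled=calibrate)
    coef = clock.coefficients.reindex(calibrated.index).to_numpy()
    scores = clock.intercept + calibrated.to_numpy(dtype=float).T @ coef
    if clock.use_transform:
        ages = inverse_transform(scores, clock.adult_age)
    else:
        ages = scores
    return pd.DataFrame(
        {
            "dnam_age": np.atleast_1d(ages),
            "n_imputed": n_imputed.reindex(calibrated.columns).to_numpy(),
            "calibrated": flags.reindex(calibrated.columns).to_numpy(),
        },
        index=calibrated.columns.rename("sample_id"),
    )


@dataclass
class ReducedClockExperiment:
    """Full-clock vs reduced-clock (masked CpGs, gold-mean imputed) estimates."""

    full: pd.Series
    reduced: pd.Series
    masked_cpgs: list[str]
    r: float


def reduce_clock(
    beta: pd.DataFrame,
    clock: ClockDefinition,
    absent_cpgs,
    calibrate: bool = False,
) -> ReducedClockExperiment:
    """Predict age with the full clock and with ``absent_cpgs`` masked.

    The masked run removes the listed CpG rows from the input so they are
    gold-mean imputed, emulating a platform that lacks them; the coefficient
    set is unchanged.  Returns both estimate vectors and their Pearson r.
    """
    absent_cpgs = list(absent_cpgs)
    stray = set(absent_cpgs) - set(clock.cpgs)
    if stray:
        warnings.warn(f"{len(stray)} masked CpGs are not clock CpGs", stacklevel=2)
    full = predict_dnam_age(beta, clock, calibrate=calibrate)["dnam_age"]
    masked_beta = beta.drop(index=[c for c in absent_cpgs if c in beta.index])
    reduced = predict_dnam_age(masked_beta, clock, calibrate=calibrate)["dnam_age"]
    if len(absent_cpgs) == 0:
        r = 1.0
    else:
        r = float(stats.pearsonr(full.to_numpy(), reduced.to_numpy()).statistic)
    return ReducedClockExperiment(full=full, reduced=reduced, masked_cpgs=absent_cpgs, r=r)


# ---------------------------------------------------------------------------
# normexp posterior mean (shared with preprocessing's noob)
# ---------------------------------------------------------------------------


def normexp_signal(x, mu_b: float, sigma_b: float, alpha: float):
    """Posterior mean E[S | X = x] under X = S + B, S ~ Exp(alpha), B ~ N(mu_b, sigma_b).

    Computed in log space (``log_ndtr``) so it is stable far into the
    background tail; always strictly positive.
    """
    x = np.asarray(x, dtype=float)
    if sigma_b <= 0:
        return np.maximum(x - mu_b, _EPS)
    mu_sf = x - mu_b - sigma_b**2 / alpha
    z = mu_sf / sigma_b
    log_phi = stats.norm.logpdf(z)
    log_Phi = log_ndtr(z)
    out = mu_sf + sigma_b * np.exp(log_phi - log_Phi)
    return np.maximum(out, _EPS)
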