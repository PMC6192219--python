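"""Core domain types and probe-level primitives.

Conventions used throughout the package:

* A *beta matrix* is a :class:`pandas.DataFrame` with probe IDs as the row
  index and sample IDs as columns.  Values are methylation fractions in
  ``[0, 1]``; missing measurements are ``NaN`` (never a sentinel number).
* Intensity matrices share the same orientation and are non-negative
  fluorescence units.
* Probes are keyed by ID only; genomic coordinates play no role in any
  computation here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DESIGN_TYPES = ("I", "II")
CHANNELS = ("Grn", "Red")
PROBE_CLASSES = ("cg", "ch", "rs", "negative_control", "norm_control")


class EpiclockError(ValueError):
    """Base class for domain errors raised by this package."""


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


@dataclass
class Manifest:
    """Per-platform probe universe with Infinium design metadata.

    Parameters
    ----------
    table
        DataFrame indexed by ``probe_id`` with columns ``design_type``
        (``"I"``/``"II"``), ``color_channel`` (``"Grn"``/``"Red"``/``"Both"``)
        and ``probe_class`` (``cg``/``ch``/``rs``/control classes).
    platform
        Free-form platform label (e.g. ``"450K"``, ``"EPIC"``).
    """

    table: pd.DataFrame
    platform: str = "platform"

    def __post_init__(self) -> None:
        required = {"design_type", "color_channel", "probe_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise EpiclockError(f"manifest missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise EpiclockError(f"duplicate probe_ids in manifest: {dups[:5]}")
        bad_design = set(self.table["design_type"]) - set(DESIGN_TYPES)
        if bad_design:
            raise EpiclockError(f"unknown design types: {sorted(bad_design)}")
        type2 = self.table["design_type"] == "II"
        if not (self.table.loc[type2, "color_channel"] == "Both").all():
            raise EpiclockError("type II probes must have color_channel 'Both'")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    @property
    def snp_probes(self) -> list[str]:
        """The rs-class SNP identity probe set."""
        return list(self.table.index[self.table["probe_class"] == "rs"])

    def subset(self, probe_ids) -> "Manifest":
        keep = self.table.index.intersection(pd.Index(probe_ids))
        return Manifest(self.table.loc[keep].copy(), platform=self.platform)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Intensities
# ---------------------------------------------------------------------------


@dataclass
class IntensityData:
    """Per-probe, per-sample methylated/unmethylated fluorescence signals.

    ``oob`` maps channel label to a draws x samples matrix of out-of-band
    intensities (type I probes read in the color channel opposite their
    design, so they carry background-only signal for that channel).
    ``controls`` holds control-probe intensities with a row MultiIndex
    ``(probe_class, channel, probe_id)``.
    """

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    oob: dict[str, pd.DataFrame] = field(default_factory=dict)
    controls: pd.DataFrame | None = None
    manifest: Manifest | None = None
    platform: str = "platform"

    def __post_init__(self) -> None:
        if self.methylated.shape != self.unmethylated.shape:
            raise EpiclockError("methylated/unmethylated shapes differ")
        if not self.methylated.index.equals(self.unmethylated.index):
            raise EpiclockError("methylated/unmethylated probe axes differ")
        if not self.methylated.columns.equals(self.unmethylated.columns):
            raise EpiclockError("methylated/unmethylated sample axes differ")
        for name, mat in (("methylated", self.methylated), ("unmethylated", self.unmethylated)):
            vals = mat.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise EpiclockError(f"negative intensities in {name} matrix")

    @property
    def probe_ids(self) -> pd.Index:
        return self.methylated.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.methylated.columns

    def copy(self) -> "IntensityData":
        return IntensityData(
            methylated=self.methylated.copy(),
            unmethylated=self.unmethylated.copy(),
            oob={ch: df.copy() for ch, df in self.oob.items()},
            controls=None if self.controls is None else self.controls.copy(),
            manifest=self.manifest,
            platform=self.platform,
        )


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Sample metadata: chronological age, platform, tissue, replicate group.

    Samples sharing a non-null ``replicate_group`` are technical replicates
    of one another (same bisulfite-converted DNA assayed more than once).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "age", "platform", "tissue"}
        missing = required - set(self.table.columns)
        if missing:
            raise EpiclockError(f"sample sheet missing columns: {sorted(missing)}")
        if "replicate_group" not in self.table.columns:
            self.table = self.table.assign(replicate_group=pd.NA)
        ages = pd.to_numeric(self.table["age"], errors="coerce")
        bad = self.table.loc[ages.isna(), "sample_id"].tolist()
        if bad:
            raise EpiclockError(f"non-numeric age for samples: {bad}")
        if (ages <= 0).any():
            bad = self.table.loc[ages <= 0, "sample_id"].tolist()
            raise EpiclockError(f"non-positive age for samples: {bad}")
        self.table = self.table.assign(age=ages.astype(float))
        groups = self.table["replicate_group"].dropna()
        sizes = groups.value_counts()
        singles = sizes.index[sizes < 2].tolist()
        if singles:
            raise EpiclockError(f"replicate groups of size < 2: {singles}")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def ages(self, sample_ids=None) -> pd.Series:
        s = self.table.set_index("sample_id")["age"]
        return s if sample_ids is None else s.loc[list(sample_ids)]

    def replicate_groups(self) -> dict[str, list[str]]:
        """Map group label -> member sample IDs (groups of size >= 2)."""
        out: dict[str, list[str]] = {}
        sub = self.table.dropna(subset=["replicate_group"])
        for grp, block in sub.groupby("replicate_group"):
            out[str(grp)] = list(block["sample_id"])
        return out


# ---------------------------------------------------------------------------
# Beta values
# ---------------------------------------------------------------------------


def check_beta(beta: pd.DataFrame) -> pd.DataFrame:
    """Validate a beta matrix: every non-missing value in [0, 1]."""
    vals = beta.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise EpiclockError("beta values outside [0, 1]")
    return beta


def compute_beta(intensities: IntensityData, offset: float = 100.0) -> pd.DataFrame:
    """Methylation fraction ``M / (M + U + offset)`` per probe and sample.

    The additive offset (Illumina convention: 100 fluorescence units)
    regularizes low-intensity probes; with ``offset > 0`` the result lies in
    ``[0, 1)``.  Entries where either signal is missing are NaN.
    """
    if offset < 0:
        raise EpiclockError("offset must be >= 0")
    m = intensities.methylated.to_numpy(dtype=float)
    u = intensities.unmethylated.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = m + u + offset
        vals = np.where(denom > 0, m / denom, 0.0)
    vals = np.where(np.isnan(m) | np.isnan(u), np.nan, vals)
    return pd.DataFrame(vals, index=intensities.probe_ids, columns=intensities.sample_ids)


# ---------------------------------------------------------------------------
# Platform harmonization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonizationResult:
    """Probe-set overlap between two platform manifests."""

    common_probes: frozenset
    only_in_a: frozenset
    only_in_b: frozenset

    @property
    def n_common(self) -> int:
        return len(self.common_probes)


def harmonize_platforms(a: Manifest, b: Manifest) -> HarmonizationResult:
    """Exact probe-ID set intersection/differences between two manifests."""
    if len(a) == 0 or len(b) == 0:
        raise EpiclockError("manifests must be non-empty")
    sa, sb = set(a.probe_ids), set(b.probe_ids)
    return HarmonizationResult(
        common_probes=frozenset(sa & sb),
        only_in_a=frozenset(sa - sb),
        only_in_b=frozenset(sb - sa),
    )


# ---------------------------------------------------------------------------
# SNP identity check
# ---------------------------------------------------------------------------


def snp_identity_check(
    beta_a: pd.DataFrame,
    beta_b: pd.DataFrame,
    snp_probes,
    threshold: float = 0.99,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confirm sample identity across runs via SNP (rs) probe genotypes.

    SNP probes read genotype, not methylation, so their betas cluster near
    0 / 0.5 / 1 and act as a per-individual fingerprint.  For every pair of
    samples the Pearson correlation over SNP-probe betas is computed; a pair
    with ``r >= threshold`` is called a match.

    Returns
    -------
    pairing : DataFrame
        One row per sample of ``beta_a``: best-matching ``beta_b`` sample,
        its correlation, the match flag, and an ``evaluable`` flag (False
        when the sample's SNP vector has zero variance).
    corr : DataFrame
        Full samples_a x samples_b correlation matrix.
    """
    snp_probes = list(snp_probes)
    if len(snp_probes) < 3:
        raise EpiclockError("need at least 3 SNP probes for identity checking")
    for name, beta in (("a", beta_a), ("b", beta_b)):
        absent = set(snp_probes) - set(beta.index)
        if absent:
            raise EpiclockError(f"SNP probes missing from matrix {name}: {sorted(absent)[:5]}")
    xa = beta_a.loc[snp_probes].to_numpy(dtype=float)
    xb = beta_b.loc[snp_probes].to_numpy(dtype=float)
    sd_a = xa.std(axis=0)
    sd_b = xb.std(axis=0)
    za = (xa - xa.mean(axis=0)) / np.where(sd_a > 0, sd_a, np.nan)
    zb = (xb - xb.mean(axis=0)) / np.where(sd_b > 0, sd_b, np.nan)
    corr = pd.DataFrame(
        za.T @ zb / len(snp_probes), index=beta_a.columns, columns=beta_b.columns
    )
    rows = []
    for sample in beta_a.columns:
        r_row = corr.loc[sample]
        if r_row.isna().all():
            rows.append((sample, None, np.nan, False, False))
            continue
        best = r_row.idxmax()
        r = float(r_row[best])
        rows.append((sample, best, r, bool(r >= threshold) and not np.isnan(r), not np.isnan(r)))
    pairing = pd.DataFrame(
        rows, columns=["sample_a", "best_match_b", "r", "matched", "evaluable"]
    )
    return pairing, corr


def pairwise_snp_correlation(
    beta_a: pd.DataFrame, beta_b: pd.DataFrame, snp_probes, pairs, threshold: float = 0.99
) -> pd.DataFrame:
    """Correlation of SNP betas for explicitly named (sample_a, sample_b) pairs."""
    snp_probes = list(snp_probes)
    rows = []
    for sa, sb in pairs:
        va = beta_a.loc[snp_probes, sa].to_numpy(dtype=float)
        vb = beta_b.loc[snp_probes, sb].to_numpy(dtype=float)
        if va.std() == 0 or vb.std() == 0:
            rows.append((sa, sb, np.nan, False, False))
            continue
        r = float(stats.pearsonr(va, vb).statistic)
        rows.append((sa, sb, r, r >= threshold, True))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "r", "matched", "evaluable"])
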