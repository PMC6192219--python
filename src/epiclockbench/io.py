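"""Readers and writers for the package's plain-text formats.

All formats are deliberately simple CSV/TSV dialects:

* manifest: CSV with ``probe_id, design_type, color_channel, probe_class``
* intensities: a directory holding ``methylated.tsv`` / ``unmethylated.tsv``
  (probes x samples), ``oob.tsv`` (``draw_id, channel`` + sample columns) and
  ``controls.tsv`` (``probe_id, probe_class, channel`` + sample columns)
* sample sheet: CSV ``sample_id, age, platform, tissue, replicate_group``
* clock definition: CSV ``cpg, coefficient, gold_standard_mean`` with one
  reserved ``(Intercept)`` row and ``#key=value`` metadata header lines
* beta matrix: TSV, probes x samples, ``NA`` for missing

Loaders reject malformed input with errors naming the offending row rather
than silently coercing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import EpiclockError, IntensityData, Manifest, SampleSheet
from .clock import ClockDefinition

NA_TOKEN = "NA"


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def load_manifest(path, platform: str | None = None) -> Manifest:
    df = pd.read_csv(path, dtype=str)
    if "probe_id" not in df.columns:
        raise EpiclockError(f"{path}: manifest lacks a probe_id column")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise EpiclockError(f"{path}: duplicate probe_id rows: {dup.tolist()[:5]}")
    table = df.set_index("probe_id")
    label = platform or Path(path).stem
    return Manifest(table, platform=label)


def write_manifest(manifest: Manifest, path) -> None:
    manifest.table.rename_axis("probe_id").to_csv(path)


# ---------------------------------------------------------------------------
# Beta matrices & intensity matrices
# ---------------------------------------------------------------------------


def write_beta(beta: pd.DataFrame, path) -> None:
    beta.rename_axis("probe_id").to_csv(path, sep="\t", na_rep=NA_TOKEN)


def load_beta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False,
                     float_precision="round_trip")
    if "probe_id" not in df.columns:
        raise EpiclockError(f"{path}: beta table lacks probe_id column")
    df = df.set_index("probe_id")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise EpiclockError(f"{path}: non-numeric beta value ({exc})") from exc
    return df


def write_intensities(intensities: IntensityData, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    intensities.methylated.rename_axis("probe_id").to_csv(
        directory / "methylated.tsv", sep="\t", na_rep=NA_TOKEN
    )
    intensities.unmethylated.rename_axis("probe_id").to_csv(
        directory / "unmethylated.tsv", sep="\t", na_rep=NA_TOKEN
    )
    if intensities.oob:
        blocks = []
        for channel, draws in intensities.oob.items():
            block = draws.copy()
            block.insert(0, "channel", channel)
            block.insert(0, "draw_id", np.arange(len(block)))
            blocks.append(block)
        pd.concat(blocks, ignore_index=True).to_csv(
            directory / "oob.tsv", sep="\t", index=False, na_rep=NA_TOKEN
        )
    if intensities.controls is not None:
        intensities.controls.reset_index().to_csv(
            directory / "controls.tsv", sep="\t", index=False, na_rep=NA_TOKEN
        )


def load_intensities(directory, manifest: Manifest | None = None, platform: str = "platform") -> IntensityData:
    directory = Path(directory)
    meth = load_beta_like(directory / "methylated.tsv")
    unmeth = load_beta_like(directory / "unmethylated.tsv")
    oob: dict[str, pd.DataFrame] = {}
    oob_path = directory / "oob.tsv"
    if oob_path.exists():
        raw = pd.read_csv(oob_path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False,
                          float_precision="round_trip")
        for channel, block in raw.groupby("channel"):
            oob[str(channel)] = (
                block.drop(columns=["channel"]).set_index("draw_id").astype(float).reset_index(drop=True)
            )
    controls = None
    controls_path = directory / "controls.tsv"
    if controls_path.exists():
        raw = pd.read_csv(controls_path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False,
                          float_precision="round_trip")
        controls = raw.set_index(["probe_class", "channel", "probe_id"]).astype(float)
    return IntensityData(
        methylated=meth,
        unmethylated=unmeth,
        oob=oob,
        controls=controls,
        manifest=manifest,
        platform=platform,
    )


def load_beta_like(path) -> pd.DataFrame:
    """Probe x sample numeric TSV with a probe_id first column."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False,
                     float_precision="round_trip")
    if "probe_id" not in df.columns:
        raise EpiclockError(f"{path}: table lacks probe_id column")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise EpiclockError(f"{path}: duplicate probe_id rows: {dup.tolist()[:5]}")
    return df.set_index("probe_id").astype(float)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


def load_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "age", "platform", "tissue"}
    missing = required - set(df.columns)
    if missing:
        raise EpiclockError(f"{path}: sample sheet missing columns {sorted(missing)}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    bad = df.loc[ages.isna()]
    if len(bad):
        offending = bad.iloc[0]
        raise EpiclockError(
            f"{path}: non-numeric age {offending['age']!r} for sample "
            f"{offending['sample_id']!r} (row {bad.index[0] + 2})"
        )
    df = df.assign(age=ages)
    if "replicate_group" in df.columns:
        df["replicate_group"] = df["replicate_group"].replace({"": pd.NA, NA_TOKEN: pd.NA})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, index=False, na_rep=NA_TOKEN)


# ---------------------------------------------------------------------------
# Clock definitions
# ---------------------------------------------------------------------------

INTERCEPT_ROW = "(Intercept)"


def load_clock(path) -> ClockDefinition:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(path, skiprows=body_start, float_precision="round_trip")
    required = {"cpg", "coefficient", "gold_standard_mean"}
    missing = required - set(df.columns)
    if missing:
        raise EpiclockError(f"{path}: clock file missing columns {sorted(missing)}")
    dup = df["cpg"][df["cpg"].duplicated()]
    if len(dup):
        raise EpiclockError(f"{path}: duplicate CpG rows: {dup.tolist()[:5]}")
    if INTERCEPT_ROW not in set(df["cpg"]):
        raise EpiclockError(f"{path}: clock file lacks an {INTERCEPT_ROW} row")
    df = df.set_index("cpg")
    intercept = float(df.loc[INTERCEPT_ROW, "coefficient"])
    body = df.drop(index=INTERCEPT_ROW)
    return ClockDefinition(
        name=meta.get("name", Path(path).stem),
        intercept=intercept,
        coefficients=body["coefficient"].astype(float),
        gold_standard_mean=body["gold_standard_mean"].astype(float),
        adult_age=float(meta.get("adult_age", 20.0)),
        use_transform=meta.get("use_transform", "true").lower() in ("true", "1", "yes"),
    )


def write_clock(clock: ClockDefinition, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name={clock.name}\n")
        fh.write(f"#adult_age={clock.adult_age}\n")
        fh.write(f"#use_transform={'true' if clock.use_transform else 'false'}\n")
        fh.write("cpg,coefficient,gold_standard_mean\n")
        fh.write(f"{INTERCEPT_ROW},{clock.intercept:.17g},\n")
        for cpg in clock.coefficients.index:
            coef = clock.coefficients[cpg]
            gold = clock.gold_standard_mean.get(cpg, np.nan)
            fh.write(f"{cpg},{coef:.17g},{gold:.17g}\n")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(tables: dict[str, pd.DataFrame], directory) -> None:
    """Write each report table as ``<name>.tsv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        if not isinstance(table, pd.DataFrame):
            continue
        table.to_csv(directory / f"{name}.tsv", sep="\t", na_rep=NA_TOKEN,
                     index=not isinstance(table.index, pd.RangeIndex))
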