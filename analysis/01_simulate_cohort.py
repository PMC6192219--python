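#!/usr/bin/env python
"""Stage 1 — simulate the two-platform cohort.

Generates the default synthetic study: 172 subjects aged 19-50, assayed on
platform A (full probe set) and platform B (missing 19/353 pan-tissue and
6/71 blood clock CpGs), with 12 technical replicate pairs on platform B.
Writes intensities, manifests, sample sheets and the ground truth under
results/data/.
"""

from pathlib import Path

from epiclockbench import SampleSheet, SimulationConfig
from epiclockbench import io as eio
from epiclockbench.simulate import make_technical_replicates, simulate_cohort, simulate_intensities

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main(seed: int = 1) -> None:
    cfg = SimulationConfig(seed=seed)
    sheet, truth = simulate_cohort(cfg)
    print(f"simulated cohort: n={cfg.n_subjects}, ages "
          f"{truth.ages.min():.1f}-{truth.ages.max():.1f} y, "
          f"{len(truth.true_beta)} probes "
          f"({cfg.n_clock_cpgs} pan-tissue clock, {cfg.n_blood_clock_cpgs} blood clock, "
          f"{cfg.n_snp_probes} SNP)")
    print(f"platform B lacks {len(truth.platform_b_absent)} clock CpGs")

    OUT.mkdir(parents=True, exist_ok=True)
    for platform in ("A", "B"):
        inten = simulate_intensities(truth, cfg, platform)
        plat_sheet = SampleSheet(sheet.table.assign(platform=platform))
        if platform == "B":
            inten, plat_sheet = make_technical_replicates(
                inten, plat_sheet, cfg.replicate_pairs, cfg.replicate_noise_sd, seed=cfg.seed
            )
            print(f"platform B: added {cfg.replicate_pairs} technical replicate pairs")
        eio.write_intensities(inten, OUT / f"platform_{platform}")
        eio.write_sample_sheet(plat_sheet, OUT / f"sample_sheet_{platform}.csv")
        eio.write_manifest(truth.manifests[platform], OUT / f"manifest_{platform}.csv")
    gt = OUT / "ground_truth"
    gt.mkdir(exist_ok=True)
    eio.write_beta(truth.true_beta, gt / "true_beta.tsv")
    truth.ages.rename_axis("sample_id").to_csv(gt / "ages.csv")
    eio.write_clock(truth.clock, gt / "clock_pan_tissue.csv")
    eio.write_clock(truth.blood_clock, gt / "clock_blood.csv")
    (gt / "platform_b_absent.txt").write_text("\n".join(truth.platform_b_absent) + "\n")
    print(f"wrote data to {OUT}")


if __name__ == "__main__":
    main()
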