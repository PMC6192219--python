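#!/usr/bin/env python
"""Stage 2 — preprocess both platforms four ways.

Reads the stage-1 intensities and produces a beta matrix per (platform,
method) for raw, GenomeStudio-style, quantile and noob preprocessing,
reporting how far each sits from the known true betas (the generator's
ground truth makes the usual rationale for background correction directly
measurable).
"""

from pathlib import Path

import numpy as np

from epiclockbench import io as eio
from epiclockbench.preprocessing import PREPROCESSORS, preprocess

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
OUT = ROOT / "betas"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    true_beta = eio.load_beta(DATA / "ground_truth" / "true_beta.tsv")
    for platform in ("A", "B"):
        manifest = eio.load_manifest(DATA / f"manifest_{platform}.csv", platform=platform)
        inten = eio.load_intensities(DATA / f"platform_{platform}", manifest=manifest,
                                     platform=platform)
        for method in PREPROCESSORS:
            beta = preprocess(inten, method)
            eio.write_beta(beta, OUT / f"beta_{platform}_{method}.tsv")
            common = beta.index.intersection(true_beta.index)
            subjects = [s for s in beta.columns if s in true_beta.columns]
            rmse = float(np.sqrt(np.nanmean(
                (beta.loc[common, subjects].to_numpy()
                 - true_beta.loc[common, subjects].to_numpy()) ** 2
            )))
            print(f"platform {platform} / {method:8s}: RMSE vs true beta = {rmse:.4f}")
    print(f"wrote beta matrices to {OUT}")


if __name__ == "__main__":
    main()
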