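#!/usr/bin/env python
"""HMM model selection on the dynamic dataset: K = 2..6 states by AIC.

Fits pooled Gaussian-emission HMMs with 2-6 states to the QC-passing E*
traces and compares log-likelihood and AIC; the three-state model should
win, with the recovered means near E* = 0.20 / 0.30 / 0.41.  Run
01_simulate.py and 02_qc_correct.py first.
"""

import shutil
import sys
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

from clampfret.pipeline import PipelineConfig, stage_hmm  # noqa: E402

DATA = REPO / "scratch" / "datasets"
RUNS = REPO / "scratch" / "runs"
RESULTS = REPO / "results"


def main() -> None:
    cfg = PipelineConfig(
        outdir=str(RUNS / "dynamic"), input_dir=str(DATA / "dynamic"),
        seed=11, log_level="WARNING",
    )
    out = stage_hmm(cfg)
    for fname in ("model_selection.csv", "hmm_params.json"):
        shutil.copy(RUNS / "dynamic" / fname, RESULTS / fname)
    print(f"AIC selects K = {out['K']} states")
    print("state E* means:", [round(m, 3) for m in out["means"]])
    print(f"wrote {RESULTS / 'model_selection.csv'} and {RESULTS / 'hmm_params.json'}")


if __name__ == "__main__":
    main()
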