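#!/usr/bin/env python
"""GREML PVE estimates across GRM designs and covariate adjustments.

Reproduces the study's estimate grid on the simulated cohort: the full IBS
GRM mixes common-SNP and narrow-sense heritability; zeroing entries below
0.05 approximates an IBD (family) matrix and captures rare-variant and
shared-environment signal; the unrelated subset isolates the common-SNP
component; adjusting for the two major-locus tag SNPs removes the major
locus's share.
"""

from pathlib import Path

from asherit.workflow import PipelineConfig, build_dataset, run_heritability

import sys
from importlib import import_module

sys.path.insert(0, str(Path(__file__).resolve().parent))
CONFIG = import_module("01_simulate_cohort").CONFIG  # same cohort

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    config = PipelineConfig(simulation=CONFIG, seed=CONFIG.seed)
    data = build_dataset(config)
    table = run_heritability(config, data)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "heritability_grid.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    thr = table.query("design=='thresholded_grm' and adjustment=='covariates'")
    full = table.query("design=='full_grm' and adjustment=='covariates'")
    print(f"\nfamily-style (thresholded) estimate {100*thr['pve'].iloc[0]:.0f}% "
          f"vs mixed full-GRM estimate {100*full['pve'].iloc[0]:.0f}%: the gap "
          "reflects untyped rare variants and sibship-shared environment.")


if __name__ == "__main__":
    main()
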