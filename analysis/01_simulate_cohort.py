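#!/usr/bin/env python
"""Generate the study cohorts.

Writes, under results/study/: the training expression matrix (probes x
samples) with probe annotation, the log2-SUV phenotype, per-patient PET
covariates, the independent validation cohort (containing one planted
influential observation below the training uptake minimum), the planted
ground truth, and the synthetic gene-set collection used downstream.
"""

from _common import run_stage

if __name__ == "__main__":
    run_stage("simulate")
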