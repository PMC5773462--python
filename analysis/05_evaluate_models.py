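#!/usr/bin/env python
"""Compare PLS-3, PCR, SVM and random forest on 50 paired resamples (tenfold CV x 5) with paired t / Wilcoxon tests (Bonferroni), validate the frozen signature externally with and without the influential observation, and sweep the selection threshold and coefficient signs. Writes resample, comparison, per-sample validation and sweep tables.
"""

from _common import run_stage

if __name__ == "__main__":
    run_stage("evaluate")
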