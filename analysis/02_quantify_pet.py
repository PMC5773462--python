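#!/usr/bin/env python
"""Compute the PET quantification table (LBM, SUL, SUVglu, MTV, TLG, T/B, log2 SUV) for every patient and screen the uptake distribution for normality. Writes quantification.csv and a cohort summary JSON.
"""

from _common import run_stage

if __name__ == "__main__":
    run_stage("quantify")
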