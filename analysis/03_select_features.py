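#!/usr/bin/env python
"""Standardize probes, score each by its univariate slope against log2 SUV, and choose the |beta| threshold and principal-component count by tenfold cross-validation. Writes the full score table, the CV grid with the chosen pair, and the selected probe list.
"""

from _common import run_stage

if __name__ == "__main__":
    run_stage("select")
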