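#!/usr/bin/env python
"""Fit the final PLS-3 signature on the selected probes, compute per-probe VIP importances, and report how many probes reach VIP >= 1 and whether unannotated probes are under-represented among them (Fisher exact test). Serializes the portable model JSON.
"""

from _common import run_stage

if __name__ == "__main__":
    run_stage("train")
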