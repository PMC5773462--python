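#!/usr/bin/env python
"""Cluster samples hierarchically (1 - Spearman rho, complete linkage, k=5) on the signature probes and, as a negative control, on all probes; compare cluster mean SUV by one-way ANOVA and pairwise t-tests.
"""

from _common import run_stage

if __name__ == "__main__":
    run_stage("cluster")
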