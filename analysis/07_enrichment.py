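#!/usr/bin/env python
"""Summarize probes to genes (max-intensity probe per gene), score every gene set per sample by ssGSEA, and correlate the scores with log2 SUV (Pearson). Writes the score matrix and the correlation table.
"""

from _common import run_stage

if __name__ == "__main__":
    run_stage("enrich")
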