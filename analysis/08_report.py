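#!/usr/bin/env python
"""Aggregate the stage artifacts into a single machine-readable run report.
"""

from _common import run_stage

if __name__ == "__main__":
    run_stage("report")
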