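#!/usr/bin/env python
"""Repertoire diversity and between-ecotype similarity.

Hill numbers q=0,1,2 (observed and asymptotic) with sample coverage per
ecotype, coverage-based rarefaction/extrapolation curves to twice the
smaller sample (84% bootstrap CIs), Horn and Morisita-Horn similarity, and
the 1000-permutation test for ecotype-specific categories.  Ends by
printing the consolidated pipeline report.
"""

import json
from pathlib import Path

from stenella.pipeline import PipelineConfig, make_report, run_pipeline

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = PipelineConfig.from_yaml(HERE / "config.yaml")
    summary = run_pipeline(cfg, stages=["diversity"])
    print(make_report(json.loads((Path(cfg.outdir) / "summary.json").read_text())))


if __name__ == "__main__":
    main()
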