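#!/usr/bin/env python
"""ART2 categorization of the combined repertoire at 96% vigilance.

Whistles join the category whose reference contour they resemble at >= 96%
DTW similarity, or found a new one; references are warped running averages
of their members.  The resulting categories are classified into the
six-class contour taxonomy and tabulated by ecotype sharing.
"""

from pathlib import Path

from stenella.pipeline import PipelineConfig, run_pipeline

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = PipelineConfig.from_yaml(HERE / "config.yaml")
    summary = run_pipeline(cfg, stages=["categorize"])
    cat = summary["categorize"]
    print(
        f"{cat['n_categories']} categories "
        f"(converged={cat['converged']} in {cat['n_iterations']} passes)"
    )
    print(f"sharing: {cat['sharing']}")
    for eco, shapes in cat["abundance_by_shape"].items():
        total = sum(shapes.values())
        mix = ", ".join(
            f"{s} {100 * c / total:.0f}%" for s, c in sorted(shapes.items(), key=lambda kv: -kv[1]) if c
        )
        print(f"  {eco}: {mix}")


if __name__ == "__main__":
    main()
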