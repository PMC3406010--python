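#!/usr/bin/env python
"""Run the whole pipeline end-to-end from one config and print the summary.

Equivalent to `introscan run-all` on the study-condition scenario; the
individual drivers 01-05 expose the same stages step by step from their
serialised intermediates.
"""

from pathlib import Path

from introscan.pipeline import PipelineConfig, run_pipeline, setup_logging, summarize_report


def main() -> None:
    setup_logging()
    cfg = PipelineConfig.from_dict(
        {"seed": 1, "output_dir": "results/pipeline", "simulate": {}}
    )
    bundle = run_pipeline(cfg)
    print(summarize_report(bundle))
    print(f"full bundle under {Path('results/pipeline').resolve()}")


if __name__ == "__main__":
    main()
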