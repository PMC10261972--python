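#!/usr/bin/env python
"""Run the whole pipeline end to end from one config.

Equivalent to steps 01-05 driven through `sphagspec.pipeline.run_pipeline`
with a single seeded configuration; all artifacts land under
results/pipeline/ together with a manifest carrying the config hash.
"""

from sphagspec.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    cfg = PipelineConfig(
        out_dir="results/pipeline",
        synthetic=True,
        seed=42,
        times=("0h", "1week"),
        ri_stride_nm=5,
    )
    artifacts = run_pipeline(cfg)
    print(f"pipeline complete, config hash {cfg.config_hash()}")
    for name, path in sorted(artifacts.items()):
        print(f"  {name:>24} -> {path}")


if __name__ == "__main__":
    main()
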