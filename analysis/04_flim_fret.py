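#!/usr/bin/env python
"""End-to-end FLIM-FRET analysis of a synthetic two-population scene.

Runs the full pipeline on the demo configuration (10 donor-only vs 10
tandem-construct cells): segmentation, per-cell model-selected reconvolution
fits, amplitude-weighted mean lifetimes, FRET efficiencies against the
donor-only control, 3-s.d. significance calls, and per-component distance
estimates.  All tables land in results/flim_run/.
"""

from pathlib import Path

from flimfret.config import load_config
from flimfret.pipeline import run_pipeline

HERE = Path(__file__).resolve().parent
cfg = load_config(HERE / "demo_config.yaml")
result = run_pipeline(cfg)

summary = result["summary"]
print("per-population summary (written to results/flim_run/summary.csv):")
print(summary.to_string(index=False))

control = result["control"]
print(f"\ndonor-only control: mean {control.mean_lifetime_ns:.3f} ns, "
      f"sd {control.sd_ns:.4f} ns, n = {control.n}; "
      f"3-s.d. threshold {control.threshold_ns:.3f} ns")

cells = result["cells"]
n_sig = int(cells["fret_significant"].sum())
print(f"cells called FRET-positive: {n_sig} of {len(cells)} "
      f"(expected: the 10 tandem cells)")
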