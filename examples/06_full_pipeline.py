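"""Run the full staging pipeline on the demonstration configuration.

Equivalent to `shapestage run --out out/` with the built-in demo config:
simulate -> per-stage matched case-control effect maps -> spin similarity
between consecutive stage maps -> binary + ordinal nested-CV classification.
Takes a couple of minutes on one CPU.
"""

import json
from pathlib import Path

from shapestage import run_pipeline
from shapestage.pipeline import DEMO_CONFIG

out = run_pipeline(DEMO_CONFIG, Path("scratch") / "demo_out")
print(f"report directory: {out}")
for f in sorted(out.iterdir()):
    print(" ", f.name)

spins = json.loads((out / "spin_results.json").read_text())
rp = spins.get("hy1_vs_hy2/putamen_right")
if rp:
    print(f"\nHY1 vs HY2 right putamen: r = {rp['r_obs']:.2f}, p = {rp['p']:.3g}")
cls = json.loads((out / "classification.json").read_text())
for task, rep in cls.items():
    print(f"{task}: mean {rep['metric']} = {rep['mean_metric']:.3f}")
# Consecutive stage maps correlate because the planted staging effects grow
# incrementally; re-running with the same config reproduces every output
# byte for byte.
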