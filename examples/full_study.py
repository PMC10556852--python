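"""Run the complete study pipeline in one call.

Simulates a six-herd panel, applies QC, calls ROH with every configured
parameterization, and writes the full table bundle (QC attrition, .hom
tables, FROH, herd summaries, length classes, chromosome ranks, the
het/missing sweep, method agreement, and planted-tract recovery).
"""

import logging
import tempfile
from pathlib import Path

from rohscan import SimParams, StudyConfig, run_study

logging.basicConfig(level=logging.INFO, format="%(message)s")

out_dir = Path(tempfile.mkdtemp()) / "study"
cfg = StudyConfig(
    sim=SimParams(n_samples=30, group_sizes=(5,) * 6, seed=1),
    detectors=("consecutive-20", "consecutive-15", "sliding-20", "plink-paper"),
    out_dir=str(out_dir),
    seed=1,
)
result = run_study(cfg)

print(f"\ntables written to {out_dir}:")
for p in sorted(out_dir.iterdir()):
    print(f"  {p.name}")

print("\nplanted-tract recovery per detector:")
print(result.recovery[["detector", "recall", "precision"]].to_string(index=False))
print("\nthe same seed always reproduces this bundle byte for byte.")
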