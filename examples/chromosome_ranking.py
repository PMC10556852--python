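"""Rank chromosomes by length-normalised ROH load and compare methods.

A chromosome's score is its share of all ROH segments divided by its share
of the genome length (score 1 = ROH load proportional to size).  Rankings
from the consecutive and sliding detectors are compared with Spearman's
rank correlation.
"""

from rohscan import (
    BTA_LENGTHS_BP,
    SimParams,
    compare_methods,
    detect_consecutive,
    detect_sliding,
    get_preset,
    rank_chromosomes,
    simulate_panel,
)

gm, _ = simulate_panel(SimParams(n_samples=30, seed=11))

ranks = {}
for name, detector in [("consecutive", detect_consecutive),
                       ("sliding", detect_sliding)]:
    segs = detector(gm, get_preset(f"{name}-20"))
    ranks[name] = rank_chromosomes(segs, BTA_LENGTHS_BP)

print("rank  BTA  n_roh  score   (consecutive runs)")
for r in sorted(ranks["consecutive"], key=lambda r: r.rank)[:5]:
    print(f"{r.rank:4d}  {r.chrom:3d}  {r.n_roh:5d}  {r.score:.3f}")

rho, p = compare_methods(ranks["consecutive"], ranks["sliding"])
print(f"\nSpearman rho between method rankings: {rho:.3f} (p = {p:.2e})")
print("scores above 1 mark chromosomes carrying more ROH than their length "
      "share predicts; under this neutral simulator scores hover near 1 and "
      "the two methods rank chromosomes nearly identically.")
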