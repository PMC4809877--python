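"""Electrophoretic size calibration with a gamma GLM (inverse link).

Ladder standards give (size, migration distance) pairs; the fitted curve
E[size] = 1/(b0 + b1*distance) converts a sample band's migration into an
RNA size with a 95% interval, so a blot-derived size can be checked against
the size implied by transcriptome coverage.
"""

from srnakit import SimulationConfig, calibrate_ladder, predict_size
from srnakit.synthetic import simulate_ladder

cfg = SimulationConfig(seed=1)
ladder = simulate_ladder(cfg)
cal = calibrate_ladder(ladder["size"], ladder["distance"])

print(f"standards         : {cal.n_standards}")
print(f"b0 (true {cfg.ladder_b0:.1e}) : {cal.b0:.3e}")
print(f"b1 (true {cfg.ladder_b1:.1e}) : {cal.b1:.3e}")
print(f"gamma shape       : {cal.shape:.1f}")

distance = 25.0
pred = predict_size(cal, distance)
print(f"\nband at distance {distance}:")
print(f"  estimated size  : {pred.estimate:.0f} nt")
print(f"  95% interval    : [{pred.lower:.0f}, {pred.upper:.0f}] nt")
transcriptome_size = 341
print(f"  transcriptome size {transcriptome_size} nt inside interval: "
      f"{pred.contains(transcriptome_size)}")
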