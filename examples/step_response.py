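"""Population response to a step current: simulation against all four theories.

A population of adapting spike-response-model neurons is driven by a current
step (10 -> 70 pA at t = 0.5 s).  The PSTH shows an initial peak, damped
oscillations (refractoriness) and a slow adapting decay; we compare the
time-dependent renewal, quasi-renewal (QR) and first/second-order moment
expansion (EME1/EME2) predictions against the simulated plateau.
"""

import numpy as np

import qrpop

model = qrpop.default_model()
current = qrpop.step_current(baseline=10.0, amplitude=60.0, t_on=500.0,
                             duration=5000.0, dt=0.5)
h = qrpop.filtered_input(current, model.kappa)

sim = qrpop.simulate_population(model, h=h, n_neurons=5000, seed=1)
tail = sim.counts[int(3500 / 0.5):]
plateau_sim = tail.sum() / (5000 * 0.5 * tail.size)

print("plateau activity after a 10->70 pA step (last 1.5 s):")
print(f"  simulation (5000 neurons): {1000 * plateau_sim:7.2f} Hz")
for name, encode in [("renewal", qrpop.encode_renewal), ("QR", qrpop.encode_qr),
                     ("EME1", qrpop.encode_eme1), ("EME2", qrpop.encode_eme2)]:
    a = encode(model, h)
    print(f"  {name:<8} theory:          {1000 * a.values[-1]:7.2f} Hz")

stats = qrpop.isi_statistics(sim.raster, t_split=500.0)
print(f"\nmean first ISI after the step: {stats.mean_first:6.1f} ms")
print(f"mean last ISI:                 {stats.mean_last:6.1f} ms")
print("the last interval is longer than the first because each spike adds")
print("self-inhibition: the population adapts. Renewal theory (no adaptation)")
print("overshoots the plateau; QR matches it; EME1/EME2 fall in between.")
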