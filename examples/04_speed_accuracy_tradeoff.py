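"""The central speed-accuracy tradeoff of demand-dependent detachment.

Sweeps the detachment scale of a DDD model on the reference cable
(100 compartments, 800 µm, D = 10 µm²/s, six even demand hotspots) and
prints the resulting operating points: faster delivery costs accuracy.
"""

import numpy as np

from sushibelt import StrategyConfig, build_cable, ddd, tradeoff_sweep
from sushibelt.demand import hotspots

tree = build_cable(100, 800.0)
demand = hotspots(100, 6)


def build(c_max):
    return ddd(demand, tree, StrategyConfig(c_max=c_max, D=10.0))


curve = tradeoff_sweep(build, np.logspace(-6, -3, 7), demand, q=0.95)
print("detachment scale (1/s)   mean error (%)   time to deliver 95% (days)")
for c, e, t in zip(curve.parameter, curve.error_pct, curve.time_s):
    print(f"{c:>20.1e}   {e:>14.2f}   {t / 86400:>26.2f}")
print(
    "\nReaching ~10% mean error takes days; ~1% takes weeks. Slow detachment"
    "\nlets cargo equilibrate along the microtubules before it commits"
    "\n(accurate but slow); fast detachment strands cargo proximally."
)
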