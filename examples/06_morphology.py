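"""Morphology shapes the speed-precision tradeoff.

Runs identical transport kinetics (uniform demand, geometry-scaled rates at
D = 10 µm²/s, slow irreversible detachment at 8e-5 /s) on two synthetic
morphologies of contrasting size and branching complexity, mimicking a
compact granule-like cell and an elaborately branched Purkinje-like cell.
Real SWC reconstructions can be swapped in with `read_swc` + `resample`.
"""

import numpy as np

from sushibelt import (
    DemandProfile,
    TransportSystem,
    build_tree,
    delivered_distribution,
    delivery_time,
    mean_percent_error,
    scale_rates_to_geometry,
)


def symmetric_tree(depth, seg_comps, seg_len, n_children=2):
    parents, lengths = [-1], [seg_len / seg_comps]
    frontier = [0]
    for _ in range(depth):
        nxt = []
        for node in frontier:
            for _ in range(n_children):
                attach = node
                for _ in range(seg_comps):
                    parents.append(attach)
                    lengths.append(seg_len / seg_comps)
                    attach = len(parents) - 1
                nxt.append(attach)
        frontier = nxt
    return build_tree(parents, np.array(lengths))


cells = {
    "granule-like (compact)": symmetric_tree(depth=2, seg_comps=8, seg_len=60.0),
    "Purkinje-like (branched)": symmetric_tree(depth=5, seg_comps=4, seg_len=40.0),
}

print(f"{'cell':<26} {'cable (µm)':>10} {'mean error (%)':>15} {'t90 (days)':>11}")
for name, tree in cells.items():
    a, b = scale_rates_to_geometry(10.0, tree)
    system = TransportSystem(tree, a, b, c=np.full(tree.n, 8e-5))
    demand = DemandProfile(np.ones(tree.n))
    err = mean_percent_error(delivered_distribution(system), demand)
    t90 = delivery_time(system, 0.9)
    print(f"{name:<26} {tree.total_length_um:>10.0f} {err:>15.1f} {t90 / 86400:>11.2f}")
print(
    "\nDelivery speed is set by the detachment rate and is similar across"
    "\ncells, but larger and more elaborately branched trees pay a steep"
    "\naccuracy cost at the same kinetics."
)
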