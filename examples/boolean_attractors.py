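"""Enumerate the stationary expression patterns of the flower GRN.

The 12-gene *Arabidopsis thaliana* flower-morphogenesis network is a signed
threshold Boolean network; its fixed points are the stable expression
patterns, one per floral organ fate.
"""

import numpy as np

import grnscape as g

net = g.at_flower_network()
fixed_points = g.find_fixed_points(net)

print("genes:", " ".join(net.genes))
for x in fixed_points:
    active = [name for name, v in zip(net.genes, x) if v]
    print("".join(map(str, x)), " active:", ", ".join(active) or "(none)")
print(f"{len(fixed_points)} stationary states "
      "(each corresponds to one phenotypic stage)")
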