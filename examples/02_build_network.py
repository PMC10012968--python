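"""Generate a synthetic two-lung circulation and inspect its morphometry.

Builds lung shapes (right lung 52.5 % of volume), grows volume-filling
arterial trees into jittered-grid acinar seed points, assigns Strahler
diameters, mirrors a venous tree and closes the circulation through ladder
acini; then writes the network tables and a VTK centerline file.
"""

import numpy as np

import pulmoperf as pp
from pulmoperf import io as pio

net = pp.build_circulation(n_acini=1500, rng_seed=0)

left, right = pp.generate_lung_shapes()
print(f"lung volumes: left {left.volume*1e3:.2f} L, right {right.volume*1e3:.2f} L "
      f"(right fraction {right.volume/(left.volume+right.volume)*100:.1f} %)")
print(f"network: {net.n_nodes} nodes, {net.n_elements} elements, "
      f"{net.n_acini} acini")

art = [e for e in range(net.n_elements)
       if net.elem_type[e] == 0 and e not in set(net.macro_element_ids)]
orders = net.elem_order[art]
print("\nmean arterial diameter by Strahler order (mm):")
for o in range(1, orders.max() + 1):
    d = net.elem_D0[np.array(art)][orders == o]
    print(f"  order {o:2d}: {d.mean()*1e3:6.3f}  (n={len(d)})")
ratios = []
for o in range(1, orders.max()):
    d1 = net.elem_D0[np.array(art)][orders == o].mean()
    d2 = net.elem_D0[np.array(art)][orders == o + 1].mean()
    ratios.append(d2 / d1)
print(f"mean inter-order diameter ratio: {np.mean(ratios):.3f} "
      f"(generator target 1.52)")

pio.write_network(net, "scratch_network")
pio.export_vtk(net, "scratch_network/centerlines.vtk")
print("\nwrote scratch_network/{nodes,elements,acini}.csv and centerlines.vtk")
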