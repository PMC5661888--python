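"""Central pooling: kernel counts, layout, and a pooled feature map.

Builds the pooling plan for a 9-voxel axis (the worked example size) and for
the network's 35 -> 18 -> 9 chain, then pools a small feature map and shows
how centre detail survives while the periphery is compressed.
"""

import numpy as np

from cfcnn.pooling import central_pool_forward, plan_for_axis, solve_kernel_counts

n1, n2, n3, r = solve_kernel_counts(9)
plan9 = plan_for_axis(9)
print(f"axis length 9 -> n1={n1}, n2={n2}, n3={n3} (residual {r})")
print(f"kernel layout: {list(plan9.order)}")
print("  -> size-1 kernels sit at the axis centre: centre voxels pass through")

for O in (35, 18):
    p = plan_for_axis(O)
    print(f"axis {O:2d} -> output {p.output_length} with counts "
          f"({p.n1}, {p.n2}, {p.n3})")

# pool a map that is 1 everywhere except a bright dot inside the central
# size-1 windows (layout {3,2,1,1,2} covers indices 5 and 6 with 1x1 windows)
x = np.ones((9, 9))
x[5, 5] = 9.0
pooled, argmax = central_pool_forward(x, plan9, plan9)
print("a bright value in a central 1x1 window passes through unchanged:")
print(pooled)
print("(1x1 windows copy near-centre features; 3-wide edge windows each")
print(" collapse 9 voxels to a single maximum)")
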