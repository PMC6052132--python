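"""Build a cube muscle with embedded fibers and analyze decompositions.

Constructs the strong-scaling geometry (12×12×8 elements, 24×24 fibers
along z), verifies its entity counts, and compares a pillar-like and a
cuboid decomposition of the weak-scaling base mesh in terms of the
structural quantities that drive parallel communication cost: shared
boundary area, ghost elements and cut fibers.
"""

import numpy as np

from musclesim import (
    average_boundary_area,
    build_cube_geometry,
    count_entities,
    decompose,
    factorize_process_count,
    fibers_cut,
    ghost_element_counts,
    neighbor_sets,
)

geom = build_cube_geometry(
    extent=(1.0, 1.0, 1.0),
    elements3d=(12, 12, 8),
    fiber_axis="z",
    fibers_per_cross_section_element=(2, 2),
    elements_per_fiber_per_3d_element=3,
)
c = count_entities(geom)
print(f"strong-scaling mesh: {c.elements_3d} 3D elements, {c.fibers} fibers, "
      f"{c.elements_1d} 1D elements, {c.sarcomere_points} sarcomere points")

# weak-scaling base mesh: choose subdivisions for 24 processes
base = build_cube_geometry(elements3d=(2, 12, 8), fiber_axis="x",
                           fibers_per_cross_section_element=(2, 2),
                           elements_per_fiber_per_3d_element=3)
sub = factorize_process_count(24, base, "cuboid", atomic_block=(2, 2, 2))
print(f"\n24 processes on a 2×12×8 mesh with a 2×2×2 atomic block -> "
      f"subdivisions {sub}")

# a larger mesh where the two strategies genuinely differ (192 processes)
big = build_cube_geometry(elements3d=(45, 16, 12), fiber_axis="x",
                          fibers_per_cross_section_element=(2, 2),
                          elements_per_fiber_per_3d_element=3)
for strategy, subdivisions in (("pillar", (1, 16, 12)),
                               ("cuboid", (12, 4, 4))):
    part = decompose(big, subdivisions, strategy)
    nbrs = neighbor_sets(part)
    print(f"\n{strategy} {subdivisions} on the 45×16×12 mesh: "
          f"avg boundary area {average_boundary_area(part, big):.4f} cm², "
          f"mean ghosts {np.mean(ghost_element_counts(part)):.1f}, "
          f"cut fibers {fibers_cut(part, big)} of {big.n_fibers}, "
          f"max neighbors {max(len(s) for s in nbrs)}")

# Cut fibers cost 1D communication; boundary area costs 3D communication.
# Pillars cut nothing but expose more surface; cuboids are the reverse.
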