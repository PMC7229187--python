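"""Build tumor-microenvironment regions and detect tumor buds.

A 2 x 2 mm square tumor with its top edge as the invasive front gives
closed-form region areas (IM 2.0 mm^2, core 3.0 mm^2, TBROI 2.0 mm^2); a
planted 3-cell cluster and a 5-cell chain show the "up to four cells" rule.
"""

import numpy as np
from shapely.geometry import LineString, Polygon, box

from sioi import build_regions, detect_buds

tumor = Polygon([(0, 0), (2000, 0), (2000, 2000), (0, 2000)])
front = LineString([(0, 0), (2000, 0)])
regions = build_regions(tumor, front, im_half_width_um=500, tbroi_width_um=1000,
                        tissue_extent=box(0, -500, 2000, 2000))
print("region areas (mm^2):", regions.areas_mm2)

bud = np.array([[300.0, 300.0], [310.0, 300.0], [305.0, 309.0]])   # 3 cells
chain = np.array([[800.0 + 10 * i, 300.0] for i in range(5)])      # 5 cells
buds = detect_buds(np.vstack([bud, chain]), regions.TBROI, link_distance_um=15.0)
print(f"{len(buds)} bud detected, sizes: {[b.n_cells for b in buds]}")
# Only the 3-cell cluster is a bud: the 5-cell chain is one connected
# component of size 5, above the 4-cell budding limit.
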