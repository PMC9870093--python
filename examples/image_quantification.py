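"""Quantify a simulated lineage-tracing field: masks, single-nucleus
filter, morphology, fluorescence and lineage calls.

Renders a noiseless field of GFP- and mCherry-labelled elliptical
cells (one binucleate), segments it with Otsu masks, keeps cells with
exactly one nucleus, and reports per-cell measurements.
"""

from hepaquant.imaging import (
    ChannelImage,
    cellular_mask,
    classify_lineage,
    filter_single_nucleus,
    measure_cells,
    nuclear_mask,
)
from hepaquant.simulate import random_field_spec, simulate_image

spec = random_field_spec(seed=3, n_cells=6, binucleate_fraction=0.3, cfp_fraction=0.5)
planes, truth = simulate_image(spec)
img = ChannelImage(planes, spec.channel_roles)

cells = cellular_mask(img)
nuclei = nuclear_mask(img)
records = measure_cells(cells, nuclei, img)
kept = filter_single_nucleus(records)
kept = classify_lineage(kept, gfp_threshold=30.0, mcherry_threshold=30.0)

cols = ["cell", "area", "eccentricity", "nucleus_count", "mean_cfp", "lineage"]
print(f"segmented cells      : {len(records)}")
print(f"mononucleate retained: {len(kept)}")
print(kept[cols].round(3).to_string(index=False))
print()
print("Area is the mask pixel count (px^2); eccentricity comes from the")
print("moment-matched ellipse (0 = circle); lineage is called from the")
print("GFP/mCherry reporter intensities.")
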