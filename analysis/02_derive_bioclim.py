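"""Derive the window-specific bioclim variable sets (annual and
reproductive May-July) from the monthly rasters of script 01."""

import numpy as np

from _common import SCRATCH, WORLD_DIR
from parityniche import MonthlyClimateStack, derive_bioclim, window_by_name

stack = MonthlyClimateStack.load(WORLD_DIR)
for window_name in ("reproductive", "annual"):
    bs = derive_bioclim(stack, window_by_name(window_name))
    outdir = SCRATCH / f"bioclim_{window_name}"
    bs.save(outdir)
    print(f"{window_name}: wrote {len(bs.variables)} layers -> {outdir}")
    for var in ("BIO4", "BIO15", "BIO3"):
        layer = bs[var]
        print(
            f"  {var}: spatial mean {np.nanmean(layer):.1f}, "
            f"SD {np.nanstd(layer):.1f}"
        )
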