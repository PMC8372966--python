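#!/usr/bin/env python
"""Build per-species climate envelopes from the world's files.

Thins occurrences to one record per climate pixel, extracts the twelve
climate variables at each retained pixel, summarizes each species by the
five envelope statistics per variable, and reports how much climate
variation the leading principal components of the standardized envelope
matrix carry.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS  # noqa: E402

from arborclim.climate_summaries import (  # noqa: E402
    extract_climate,
    pca,
    prune_to_pixels,
    standardize_matrix,
    summarize_species,
    summary_matrix,
)
from arborclim.raster import read_raster_text  # noqa: E402


def main() -> None:
    world_dir = Path(RESULTS) / "world"
    raster = read_raster_text(world_dir / "raster")
    occurrences = pd.read_csv(world_dir / "occurrences.csv")

    pruned = prune_to_pixels(occurrences, raster)
    values = extract_climate(pruned, raster)
    summaries = summarize_species(values, raster.variable_codes, min_pixels=3)

    out = Path(RESULTS) / "species_climate_summaries.csv"
    summaries.to_csv(out, index=False)

    X, species, columns = summary_matrix(summaries, raster.variable_codes)
    Z = standardize_matrix(X, columns)
    res = pca(Z, n_axes=5)
    frac = 100 * res.variance_fraction[:5]

    print(f"summaries for {len(summaries)} species written to {out}")
    print(
        f"  {len(occurrences)} records -> {len(pruned)} after pixel thinning"
    )
    print(
        "  PC1-PC5 variance: "
        + ", ".join(f"{v:.2f}%" for v in frac)
        + f" (cumulative {frac.sum():.1f}%)"
    )


if __name__ == "__main__":
    main()
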