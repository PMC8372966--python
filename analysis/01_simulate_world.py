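#!/usr/bin/env python
"""Generate the synthetic study world and write its input files.

Produces, under results/world/: the 12-layer climate raster as a
plain-text grid bundle, the occurrence table, the microhabitat table, and
the chronogram in Newick. These are the same inputs every later driver
regenerates in memory; writing them makes the world inspectable and lets
the whole analysis be re-run from files alone.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, study_world  # noqa: E402

from arborclim.raster import write_raster_text  # noqa: E402
from arborclim.synthetic_world import build_world, write_newick  # noqa: E402


def main() -> None:
    out = Path(RESULTS) / "world"
    out.mkdir(parents=True, exist_ok=True)
    world = build_world(study_world())

    write_raster_text(world.raster, out / "raster")
    world.occurrences.to_csv(out / "occurrences.csv", index=False)
    world.microhabitats.to_csv(out / "microhabitats.csv", index=False)
    write_newick(world.tree, out / "chronogram.nwk")

    n_arb = sum(1 for v in world.labels.values() if v == "arboreal")
    per_species = world.occurrences.groupby("species").size()
    print(f"world written to {out}")
    print(
        f"  {len(world.species)} species "
        f"({n_arb} arboreal, {len(world.species) - n_arb} terrestrial)"
    )
    print(
        f"  {len(world.occurrences)} occurrence records "
        f"({per_species.min()}-{per_species.max()} per species)"
    )
    print(
        f"  raster {world.raster.n_rows}x{world.raster.n_cols} pixels at "
        f"{world.raster.pixel_size} arc-minutes"
    )


if __name__ == "__main__":
    main()
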