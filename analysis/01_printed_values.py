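#!/usr/bin/env python
"""Stage 1 — reproduce the platform's headline numbers from the physics.

With the bundled default geometry and water at 37 °C this recomputes the
pressure budget of the perfusion circuit (hydrostatic head, capillary burst
pressure of the outlet port, centrifugal pressure at 100 rpm), the speed ↔
RCF ladder at the tissue-chamber radius, the effective gravity sensed by the
cells during slow perfusion, and the cell-budget arithmetic for loading a
full disc.  Results go to results/printed_values.json.
"""

import json
from pathlib import Path

import discflow as df
from discflow.rotation import SpinState, format_rcf

OUT = Path(__file__).resolve().parents[1] / "results" / "printed_values.json"


def main() -> None:
    geom = df.default_geometry()
    water = df.water_properties(37.0)

    budget = df.pressure_budget(geom, water, SpinState(100.0))
    ladder = {
        rpm: df.rcf(SpinState(rpm), geom.chamber_radius)
        for rpm in (100, 200, 500, 1000, 1500, 4000)
    }
    rcf_100 = ladder[100]
    single = df.Suspension(4000.0, 5.0).cells
    layer = df.Suspension(1000.0, 5.0).cells

    out = {
        "hydrostatic_pressure_Pa": round(budget.dp_hydrostatic, 2),
        "burst_pressure_max_Pa": round(budget.p_burst, 2),
        "centrifugal_pressure_100rpm_Pa": round(budget.dp_centrifugal, 2),
        "rcf_ladder_g": {str(k): round(v, 3) for k, v in ladder.items()},
        "effective_gravity_100rpm_g": round(df.effective_gravity(rcf_100), 4),
        "cells_per_chamber_single_step": single,
        "cells_per_chamber_per_layer": layer,
        "disc_budget_double_load": df.disc_cell_budget(geom, 2 * single),
    }

    OUT.parent.mkdir(exist_ok=True)
    OUT.write_text(json.dumps(out, indent=2))

    print(f"hydrostatic head ({geom.head_height*1e3:g} mm water, 37 °C): "
          f"{budget.dp_hydrostatic:.1f} Pa")
    print(f"max burst pressure ({geom.port_diameter*1e3:g} mm port, 180°): "
          f"{budget.p_burst:.0f} Pa")
    print(f"centrifugal pressure at 100 rpm: {budget.dp_centrifugal:.1f} Pa")
    print("speed -> RCF at the tissue chamber:")
    for rpm, g in ladder.items():
        print(f"  {rpm:>5} rpm -> {format_rcf(g)}")
    print(f"effective gravity at 100 rpm: "
          f"{df.effective_gravity(rcf_100):.2f} g (in-plane {rcf_100:.2f} g)")
    print(f"cells per chamber: {single} per standard load, {layer} per layer; "
          f"double-loading all {geom.total_chambers} chambers needs "
          f"{df.disc_cell_budget(geom, 2 * single):,} cells (< 1e6)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
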