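#!/usr/bin/env python
"""Generate the five synthetic laboratory monitoring scenarios.

Emits background/emission session pairs (binned-CSV dialect) plus the
generator's ground truth for each scenario: silver synthesis, gold
synthesis, gold application on carbon-black electrodes, graphene synthesis
and MWCNT synthesis, each parameterised so the expected net total matches
the measured session total for that material.
"""

import json
from pathlib import Path

import numpy as np

from nanorisk import generate_session, preset_scenarios, write_session_csv

OUT = Path(__file__).resolve().parents[1] / "results" / "sessions"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, scenario in preset_scenarios(seed).items():
        background, emission, truth = generate_session(scenario)
        write_session_csv(background, OUT / f"{name}_background.csv")
        write_session_csv(emission, OUT / f"{name}_emission.csv")
        (OUT / f"{name}_truth.json").write_text(json.dumps(
            {k: v.tolist() if isinstance(v, np.ndarray) else v
             for k, v in truth.items()}, indent=2))
        print(f"{name:18s} net_total={truth['net_total']:10.4g} #/cm^3  "
              f"closed-form mass={truth['mass_ug_m3']:8.4g} ug/m^3")
    print(f"\nwrote session pairs to {OUT}")


if __name__ == "__main__":
    main()
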