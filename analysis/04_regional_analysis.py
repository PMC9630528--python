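#!/usr/bin/env python
"""Classify the focus-region regimes with threshold sensitivity.

Aggregates the FFL-ZL and FFL-NBr strength-difference fields over the
planted focus regions at rho in {0.20, 0.25, 0.30}, labels each region
(directed lens / washing machine / directed corridor), checks the labels
against the generator's ground truth, and complements the annual view with
a 12-month profile including three seasonal regime flips in the lens block.
"""

from pathlib import Path

import pandas as pd

from moistnet import monthly_profile, sensitivity_over_rho
from moistnet.regions import summaries_to_frame
from moistnet.synthetic import (
    block_regions,
    default_regime_spec,
    generate_monthly_fields,
    generate_regime_flow_field,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 0


def main() -> None:
    (ROOT / "results").mkdir(exist_ok=True)
    spec = default_regime_spec(seed=SEED)
    field, truth = generate_regime_flow_field(spec)
    regions = block_regions(truth)

    frames = []
    for link_class in ("all_to_all", "land_to_land"):
        summaries = sensitivity_over_rho(field, regions, link_class=link_class)
        frames.append(summaries_to_frame(summaries))
    table = pd.concat(frames, ignore_index=True)
    table["expected"] = table.region.map(truth.regimes)
    table.to_csv(ROOT / "results" / "04_regional_summaries.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    hits = (table.label == table.expected).sum()
    print(
        f"\nFinding: {hits}/{len(table)} region-pair rows carry the planted "
        "label; the lens block aggregates positive FFL-ZL at every rho, the "
        "washing machines stay negative, and the corridor's FFL-NBr is the "
        "more negative of its two differences."
    )

    flips = {m: {"AB_lens": "washing_machine"} for m in (6, 7, 8)}
    monthly_fields, _ = generate_monthly_fields(spec, regime_overrides=flips)
    prof = monthly_profile(
        monthly_fields, [r for r in regions if r.name == "AB_lens"]
    )
    prof.to_csv(ROOT / "results" / "04_monthly_profile.tsv", sep="\t", index=False)
    mean_row = prof[prof.month == "monthly_mean"].value.iloc[0]
    print(
        f"\nMonthly profile (AB lens analog, 3 washing-machine months): the "
        f"monthly-mean FFL-ZL aggregate is {mean_row:+.3f} - the majority "
        "(lens) regime still dominates the average."
    )


if __name__ == "__main__":
    main()
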