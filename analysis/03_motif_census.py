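#!/usr/bin/env python
"""Census the FFL / ZL / NBr motifs on the reference backbone.

Counts per-node motif roles at rho = 0.25 for both link classes, plus
per-edge participation and per-node involvement - the degree to which the
backbone is locally organized in motifs.
"""

from pathlib import Path

import pandas as pd

from moistnet import census, degrees
from moistnet.backbone import backbone_for_link_class
from moistnet.synthetic import default_regime_spec, generate_regime_flow_field

ROOT = Path(__file__).resolve().parents[1]
SEED = 0


def main() -> None:
    (ROOT / "results").mkdir(exist_ok=True)
    field, _ = generate_regime_flow_field(default_regime_spec(seed=SEED))
    rows = []
    for link_class in ("all_to_all", "land_to_land"):
        net = backbone_for_link_class(field, 0.25, link_class)
        for mode in ("pattern", "induced"):
            cen = census(net, mode)
            deg = degrees(net)
            active = (deg.k_in + deg.k_out) > 0
            rows.append(
                {
                    "link_class": link_class,
                    "mode": mode,
                    "ffl_total": cen.n_ffl,
                    "zl_pairs": cen.n_zl_pairs,
                    "nbr_total": cen.n_nbr,
                    "mean_participation_per_edge": round(float(cen.edge_participation.mean()), 3),
                    "mean_involvement_per_node": round(
                        float(cen.total_involvement[active].mean()), 3
                    ),
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "results" / "03_motif_totals.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    pat = table[(table.link_class == "all_to_all") & (table["mode"] == "pattern")].iloc[0]
    print(
        f"\nFinding: the all-to-all backbone holds {pat.ffl_total} FFLs, "
        f"{pat.zl_pairs} reciprocal pairs and {pat.nbr_total} NBrs (pattern "
        "mode); induced counts are bounded above by pattern counts, and the "
        "planted blocks supply essentially all motif mass."
    )


if __name__ == "__main__":
    main()
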