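#!/usr/bin/env python
"""Extract backbone networks over the sensitivity threshold range.

Builds the unweighted directed backbone at rho in {0.20, 0.25, 0.30} for
both link classes (all-to-all and land-to-land) and summarizes edge counts,
captured volume and degree statistics - the in-degree spread exceeding the
out-degree spread is the super-receiver signature.
"""

from pathlib import Path

import pandas as pd

from moistnet import degrees
from moistnet.backbone import backbone_for_link_class, write_network
from moistnet.synthetic import default_regime_spec, generate_regime_flow_field

ROOT = Path(__file__).resolve().parents[1]
SEED = 0


def main() -> None:
    (ROOT / "scratch").mkdir(exist_ok=True)
    (ROOT / "results").mkdir(exist_ok=True)
    field, _ = generate_regime_flow_field(default_regime_spec(seed=SEED))
    rows = []
    for link_class in ("all_to_all", "land_to_land"):
        for rho in (0.20, 0.25, 0.30):
            net = backbone_for_link_class(field, rho, link_class)
            deg = degrees(net)
            rows.append(
                {
                    "link_class": link_class,
                    "rho": rho,
                    "edges": net.n_edges,
                    "captured_fraction": round(net.captured_fraction, 4),
                    "max_k_in": int(deg.k_in.max()),
                    "max_k_out": int(deg.k_out.max()),
                    "nodes_with_edges": int(((deg.k_in + deg.k_out) > 0).sum()),
                }
            )
            if rho == 0.25:
                write_network(net, ROOT / "scratch" / f"backbone_{link_class}_rho25.edges")
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "results" / "02_backbone_summary.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    ref = table[(table.link_class == "all_to_all") & (table.rho == 0.25)].iloc[0]
    print(
        f"\nFinding: at rho = 0.25 the all-to-all backbone keeps {ref.edges} of "
        "the strongest links while capturing just over a quarter of total "
        "volume; edge sets grow monotonically with rho and the land-to-land "
        "backbone is thresholded against the land-land subtotal."
    )


if __name__ == "__main__":
    main()
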