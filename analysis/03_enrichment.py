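"""Step 3: gene-set over-representation of the co-expressed gene list.

Takes the intersection list from step 2 as the query, all tested genes as
the universe, and the GMT from step 1 as the set collection; writes
results/enrichment.tsv (hypergeometric tail p, BH q per term).
"""

import argparse
from pathlib import Path

import pandas as pd

from coexsurv.enrichment import enrich
from coexsurv.io import read_gmt, write_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--screen", type=Path, default=ROOT / "results" / "screen.tsv")
    parser.add_argument(
        "--gmt", type=Path, default=ROOT / "results" / "data" / "single_cell" / "sets.gmt"
    )
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "enrichment.tsv")
    args = parser.parse_args()

    screen = pd.read_csv(args.screen, sep="\t")
    query = list(screen.loc[screen["in_intersection"], "gene_id"])
    universe = list(screen["gene_id"])
    records = enrich(query, read_gmt(args.gmt), universe)
    write_table(records, args.out)

    print(f"query {len(query)} genes, universe {len(universe)}, {len(records)} terms tested")
    for r in records[:3]:
        print(f"  {r.term_id}: overlap {r.overlap}/{r.set_size}, p={r.p:.3g}, q={r.q:.3g}")


if __name__ == "__main__":
    main()
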