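"""Step 1: generate the synthetic study inputs with known ground truth.

Writes under results/data/:
  panel/expression.tsv         bulk-panel matrix (anchor + NTN4 stand-in pair)
  single_cell/expression.tsv   2000 x 300 counts matrix with a planted module
  single_cell/module_truth.txt ground-truth module gene ids
  single_cell/sets.gmt         gene sets: the planted module + random sets
  cohort/cohort.tsv            92-patient survival cohort with planted hazard
  cohort/cohort_truth.json     generator parameters incl. the true beta
"""

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

import coexsurv as cs
from coexsurv.pipeline import stage_seed

ROOT = Path(__file__).resolve().parents[1]


def write_expression(mat, path: Path) -> None:
    df = mat.to_frame()
    df.insert(0, "gene_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "data")
    args = parser.parse_args()

    for sub in ("panel", "single_cell", "cohort"):
        (args.out_dir / sub).mkdir(parents=True, exist_ok=True)

    panel, _ = cs.simulate_expression(
        cs.preset_expression_config("panel", seed=stage_seed(args.seed, "panel"))
    )
    write_expression(panel, args.out_dir / "panel" / "expression.tsv")

    sc_dir = args.out_dir / "single_cell"
    mat, truth = cs.simulate_expression(
        cs.preset_expression_config("single-cell", seed=stage_seed(args.seed, "sc"))
    )
    write_expression(mat, sc_dir / "expression.tsv")
    (sc_dir / "module_truth.txt").write_text("\n".join(sorted(truth)) + "\n")

    # gene sets: the planted module plus random background sets
    rng = np.random.default_rng(stage_seed(args.seed, "gmt"))
    background = [g for g in mat.gene_ids if g.startswith("BG")]
    lines = ["SET:MODULE\tplanted anchor module\t" + "\t".join(sorted(truth))]
    for i in range(20):
        members = rng.choice(background, size=25, replace=False)
        lines.append(f"SET:RAND{i:02d}\trandom background set {i}\t" + "\t".join(members))
    (sc_dir / "sets.gmt").write_text("\n".join(lines) + "\n")

    cfg = cs.preset_cohort_config(seed=stage_seed(args.seed, "cohort"))
    cohort, beta = cs.simulate_cohort(cfg)
    table = pd.DataFrame(
        {"patient_id": cohort.patient_ids, "time": cohort.time, "event": cohort.event}
    )
    for gene in cohort.expr.columns:
        table[gene] = cohort.expr[gene].to_numpy()
    table.to_csv(args.out_dir / "cohort" / "cohort.tsv", sep="\t", index=False)
    (args.out_dir / "cohort" / "cohort_truth.json").write_text(
        json.dumps({"beta": beta, **dataclasses.asdict(cfg)}, sort_keys=True) + "\n"
    )

    print(f"panel: {panel.n_genes} genes x {panel.n_samples} samples")
    print(f"single-cell: {mat.n_genes} genes x {mat.n_samples} cells, module size {len(truth)}")
    print(f"cohort: {cohort.n_patients} patients, {int(cohort.event.sum())} events, beta={beta}")


if __name__ == "__main__":
    main()
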