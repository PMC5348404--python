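#!/usr/bin/env python
"""Generate the study's synthetic inputs with planted, recoverable structure.

Produces, under results/inputs/:
  * a stage/group expression cohort (RHOA-like gene up in Stage I of one
    group only; an anti-correlated RHOA/RHOB-like pair) + truth table,
  * a screening library (reference inhibitor scaffold, graded analogs,
    unrelated decoys) as .smi and TSV,
  * a docked-pose table around 9 candidate binding regions with 5% of
    compounds given a planted 3 kcal/mol specificity gap + truth table.
"""

from pathlib import Path

from bindgap import dockpose, synthgen

SEED = 17
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

# expression cohort: 200 genes, 2 groups x 5 stages x 10 samples
expr_cfg = synthgen.ExprSimConfig(
    n_genes=200,
    samples_per_stage=10,
    effect_profiles={
        "RHOA": {"Asian": {"I": 2.0, "II": 1.0, "III": 1.0, "IV": 1.0}},
        "PLD1": {"Asian": {"I": 1.0, "II": 1.0, "III": 1.5, "IV": 1.5}},
        "RHOB": {"Asian": {"I": -1.5, "II": -1.5, "III": -1.5, "IV": -1.5}},
    },
    anticorr_pairs=[("RHOA", "RHOB", -0.8)],
    seed=SEED,
)
dataset, expr_truth = synthgen.gen_expression(expr_cfg)
synthgen.write_expression(dataset, OUT / "expression.tsv", OUT / "samples.tsv")
expr_truth.to_csv(OUT / "expression_truth.tsv", sep="\t", index=False)
print(
    f"expression: {dataset.values.shape[0]} genes x {dataset.values.shape[1]} samples, "
    f"{len(expr_truth)} planted stage/group shifts"
)

# compound library: reference + 60 analogs + 40 decoys
lib_cfg = synthgen.LibrarySimConfig(n_analogs=60, n_decoys=40, seed=SEED + 1)
library = synthgen.gen_library(lib_cfg)
synthgen.write_library(library, OUT / "library.smi")
library.to_csv(OUT / "library.tsv", sep="\t", index=False)
print(f"library: {len(library)} compounds ({lib_cfg.n_analogs} analogs, {lib_cfg.n_decoys} decoys)")

# docked poses for every library compound, 5% planted specific
dock_cfg = synthgen.DockSimConfig(
    n_compounds=len(library), compound_ids=library["id"].tolist(), seed=SEED + 2
)
pose_truth, poses = synthgen.gen_poses(dock_cfg)
dockpose.write_pose_table(poses, OUT / "poses.tsv")
pose_truth.to_csv(OUT / "pose_truth.tsv", sep="\t", index=False)
n_spec = int(pose_truth["is_specific"].sum())
print(f"poses: {len(poses)} poses, {dock_cfg.n_sites} sites, {n_spec} specific compounds planted")
print(f"written to {OUT}")
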