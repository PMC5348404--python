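"""Cascade orchestration: similarity -> dockability -> specificity -> rule of five.

:func:`run_screen` executes the full small-molecule filter cascade over a
compound library and a docked-pose table, recording a per-stage survivor
ledger (input count, survivor count) and the final ranked candidate table.
:func:`run_expression` runs the stage-stratified expression analysis.
:func:`run_from_config` drives both from a single YAML/JSON config, simulating
any input not given as a file, and writes all outputs plus a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from bindgap import chemlib, dockpose, specbind, synthgen
from bindgap import exprstats

__all__ = ["ScreenFilters", "CascadeReport", "run_screen", "run_expression", "run_from_config"]


@dataclass(frozen=True)
class ScreenFilters:
    """Cascade thresholds, in stage order.

    ``dock_ceiling`` is the least favorable energy (kcal/mol) a pose may have
    for its compound to count as dockable; ``alpha`` is the specificity
    q-value cut (alpha >= 1 disables the specificity filter entirely, passing
    single-region compounds through as well).
    """

    tanimoto_threshold: float = 0.6
    dock_ceiling: float = -5.0
    cluster_cutoff: float = 4.0
    alpha: float = 0.05
    max_violations: int = 1


@dataclass
class CascadeReport:
    """Per-stage survivor ledger plus the final candidate table and audits."""

    ledger: pd.DataFrame  # stage, n_in, n_out
    candidates: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int | None = None
    status: str = "ok"

    def check_invariants(self) -> None:
        n_in = self.ledger["n_in"].to_numpy()
        n_out = self.ledger["n_out"].to_numpy()
        if (n_out > n_in).any():
            raise AssertionError("ledger: survivors exceed inputs at some stage")
        if len(n_in) > 1 and (n_in[1:] != n_out[:-1]).any():
            raise AssertionError("ledger: stage inputs do not chain from previous survivors")


def run_screen(
    library: Sequence[chemlib.Compound],
    reference: chemlib.Compound,
    poses: pd.DataFrame,
    filters: ScreenFilters = ScreenFilters(),
    spec_config: specbind.SpecificityConfig = specbind.SpecificityConfig(),
) -> CascadeReport:
    """Run the four-stage cascade and return the survivor ledger and candidates.

    Stage order: Tanimoto similarity to the reference (inclusive threshold),
    dockability (at least one pose at or below the energy ceiling), binding
    specificity (region clustering + gap significance at q <= alpha), and
    Lipinski rule-of-five. An empty stage input short-circuits with status
    ``empty_cascade`` and a ledger recorded up to that point.
    """
    ledger_rows: list[dict] = []
    tables: dict[str, pd.DataFrame] = {}

    def stage(name: str, n_in: int, n_out: int) -> None:
        ledger_rows.append({"stage": name, "n_in": n_in, "n_out": n_out})

    def report(status: str = "ok", candidates: pd.DataFrame | None = None) -> CascadeReport:
        rep = CascadeReport(
            ledger=pd.DataFrame(ledger_rows, columns=["stage", "n_in", "n_out"]),
            candidates=candidates if candidates is not None else pd.DataFrame(),
            tables=tables,
            status=status,
        )
        rep.check_invariants()
        return rep

    # 1. similarity
    sim = chemlib.similarity_screen(library, reference, threshold=filters.tanimoto_threshold)
    tables["similarity"] = sim
    sim_ids = set(sim.loc[sim["survives"], "id"])
    stage("similarity", len(library), len(sim_ids))
    if not sim_ids:
        return report("empty_cascade")

    # 2. dockability
    sub = poses[poses["compound_id"].isin(sim_ids)]
    dockable = set(
        sub.loc[sub["energy_kcal_mol"] <= filters.dock_ceiling, "compound_id"].unique()
    )
    tables["dockability"] = pd.DataFrame(
        {
            "id": sorted(sim_ids),
            "best_energy": [
                float(sub.loc[sub["compound_id"] == c, "energy_kcal_mol"].min())
                if (sub["compound_id"] == c).any()
                else np.nan
                for c in sorted(sim_ids)
            ],
        }
    ).assign(survives=lambda d: d["id"].isin(dockable))
    stage("dockability", len(sim_ids), len(dockable))
    if not dockable:
        return report("empty_cascade")

    # 3. specificity
    dock_poses = sub[sub["compound_id"].isin(dockable)]
    clusters = dockpose.cluster_poses(dock_poses, cutoff=filters.cluster_cutoff)
    tables["cluster_summary"] = clusters.summary
    tables["cluster_assignments"] = clusters.assignments
    records = specbind.build_records(clusters, dock_poses)
    permissive = filters.alpha >= 1.0
    n_testable = int((~records["single_cluster_flag"]).sum())
    if permissive and n_testable < spec_config.min_batch:
        records["z"] = records["p"] = records["q"] = np.nan
        spec_ids = set(records["compound_id"])
        ranked = records.assign(survives=True)
    else:
        records = specbind.significance(records, spec_config)
        ranked = specbind.rank_candidates(records, alpha=filters.alpha)
        spec_ids = set(ranked.loc[ranked["survives"], "compound_id"])
        if permissive:  # single-region compounds pass through when the filter is off
            spec_ids |= set(records.loc[records["single_cluster_flag"], "compound_id"])
    tables["specificity"] = records
    stage("specificity", len(dockable), len(spec_ids))
    if not spec_ids:
        return report("empty_cascade")

    # 4. Lipinski rule of five
    spec_lib = [c for c in library if c.id in spec_ids]
    lip = chemlib.lipinski_filter(spec_lib, max_violations=filters.max_violations)
    tables["lipinski"] = lip
    final_ids = set(lip.loc[lip["survives"], "id"])
    stage("lipinski", len(spec_ids), len(final_ids))

    candidates = (
        records[records["compound_id"].isin(final_ids)]
        .merge(lip[["id", "mw", "logp", "hbd", "hba"]], left_on="compound_id", right_on="id")
        .drop(columns=["id"])
        .sort_values(
            ["q", "delta_Er", "compound_id"],
            ascending=[True, False, True],
            ignore_index=True,
            na_position="last",
        )
    )
    return report("ok" if final_ids else "empty_cascade", candidates)


def run_expression(
    dataset: exprstats.ExpressionDataset,
    genes: Sequence[str],
    groups: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    contrast=exprstats.DEFAULT_CONTRAST,
    log2: bool = True,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, str]:
    """Stage-stratified per-gene, per-group analysis; returns (table, summary text)."""
    if log2 and dataset.transform == "none":
        dataset = exprstats.log_transform(dataset, pseudocount)
    table = exprstats.run_group_analysis(
        dataset, genes, groups, n_perm=n_perm, seed=seed, contrast=contrast
    )
    lines = []
    for _, r in table.iterrows():
        direction = ""
        if "contrast_estimate" in r and pd.notna(r.get("contrast_estimate")):
            way = "up" if r["contrast_estimate"] > 0 else "down"
            direction = (
                f"; Stage-I-vs-normal contrast {r['contrast_estimate']:+.2f} log2 units "
                f"({way} in Stage I, p={r['p_contrast']:.4f})"
            )
        emp = f", empirical p={r['p_empirical']:.3f}" if "p_empirical" in r else ""
        lines.append(
            f"{r['gene_id']} [{r['group']}]: F={r['f_obs']:.2f} "
            f"(df {int(r['df_between'])},{int(r['df_within'])}), ANOVA p={r['p_anova']:.4f}"
            f"{emp}{direction}"
        )
    return table, "\n".join(lines)


# ---------------------------------------------------------------------------
# Study-level simulations

def null_permutation_calibration(
    n_genes: int = 2000,
    samples_per_stage: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical p-values for many null genes: a type-I calibration study.

    Generates a zero-effect expression matrix (one group, 5 stages x
    ``samples_per_stage``), log2-transforms it, and runs the permutation F
    test per gene with per-gene seeds derived from ``seed``. Under the null
    the stage labels are exchangeable, so the returned ``p_empirical`` column
    should be uniform on [0, 1] up to the 1/n_perm permutation grid.
    """
    config = synthgen.ExprSimConfig(
        n_genes=n_genes,
        samples_per_stage=samples_per_stage,
        groups=("A",),
        seed=_seed_for(seed, 10),
    )
    dataset, _ = synthgen.gen_expression(config)
    dataset = exprstats.log_transform(dataset)
    stages = dataset.sample_meta.loc[dataset.values.columns, "stage"].to_numpy()
    codes = np.unique(stages, return_inverse=True)[1]
    values = dataset.values.to_numpy()
    rows = []
    for i in range(n_genes):
        res = exprstats.permutation_f_from_arrays(
            values[i], codes, n_perm=n_perm, seed=_seed_for(seed, 100 + i)
        )
        rows.append({"gene_id": dataset.gene_ids[i], "p_empirical": res.p_empirical})
    return pd.DataFrame(rows)


def planted_screen_metrics(
    seed: int,
    alpha: float = 0.05,
    dock_config: synthgen.DockSimConfig | None = None,
    cutoff: float = 4.0,
) -> dict:
    """Recovery metrics for one planted specificity screen.

    Runs cluster_poses -> specificity significance on a synthetic screen and
    compares the q <= alpha survivors against the planted truth flags.
    Returns true/false positive and false negative counts.
    """
    config = dock_config or synthgen.DockSimConfig(seed=seed)
    if dock_config is not None:
        config = synthgen.DockSimConfig(**{**dock_config.__dict__, "seed": seed})
    truth, poses = synthgen.gen_poses(config)
    poses = poses[dockpose.POSE_COLUMNS]
    clusters = dockpose.cluster_poses(poses, cutoff=cutoff)
    records = specbind.significance(specbind.build_records(clusters, poses))
    ranked = specbind.rank_candidates(records, alpha=alpha)
    called = set(ranked.loc[ranked["survives"], "compound_id"])
    planted = set(truth.loc[truth["is_specific"], "compound_id"])
    return {
        "tp": len(called & planted),
        "fp": len(called - planted),
        "fn": len(planted - called),
        "n_planted": len(planted),
        "n_called": len(called),
    }


# ---------------------------------------------------------------------------
# Config-driven runner

def _seed_for(master: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(master), int(stream)]).generate_state(1)[0] % (2**31))


def run_from_config(config: dict, outdir: str | Path) -> dict:
    """Execute the configured analyses and write TSV outputs plus a manifest.

    Config sections: ``seed`` (master), ``library`` / ``docking`` /
    ``filters`` (screen cascade), ``expression`` (stage analysis). Each input
    section either names files (``path`` / ``poses`` / ``matrix`` + ``meta``)
    or carries generator settings used to simulate it. Returns the manifest
    (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(config.get("seed", 0))
    manifest: dict = {
        "seed": master,
        "seed_streams": {"library": 1, "poses": 2, "expression": 3},
        "config": config,
        "outputs": [],
    }

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index)
        manifest["outputs"].append(name)

    if "library" in config or "docking" in config:
        lib_cfg = dict(config.get("library", {}))
        if "path" in lib_cfg:
            compounds = chemlib.read_smi(lib_cfg["path"])
            lib_truth = None
        else:
            sim = synthgen.LibrarySimConfig(
                reference_smiles=lib_cfg.get("reference_smiles", synthgen.DEFAULT_REFERENCE_SMILES),
                n_analogs=int(lib_cfg.get("n_analogs", 60)),
                n_decoys=int(lib_cfg.get("n_decoys", 40)),
                decoration_depth=int(lib_cfg.get("decoration_depth", 3)),
                seed=_seed_for(master, 1),
            )
            lib_table = synthgen.gen_library(sim)
            lib_truth = lib_table[["id", "kind"]]
            save(lib_table, "library.tsv")
            compounds = chemlib.make_library(lib_table[["id", "smiles"]].itertuples(index=False))
        ref_smiles = lib_cfg.get("reference_smiles", synthgen.DEFAULT_REFERENCE_SMILES)
        reference = chemlib.make_library([("REF", ref_smiles)])[0]

        dock_cfg = dict(config.get("docking", {}))
        if "poses" in dock_cfg:
            poses = dockpose.read_pose_table(dock_cfg["poses"])
            pose_truth = None
        else:
            ids = [c.id for c in compounds]
            sim = synthgen.DockSimConfig(
                n_sites=int(dock_cfg.get("n_sites", 9)),
                site_scatter_sd=float(dock_cfg.get("site_scatter_sd", 0.5)),
                n_compounds=len(ids),
                poses_per_compound=int(dock_cfg.get("poses_per_compound", 9)),
                background_energy_mean=float(dock_cfg.get("background_energy_mean", -7.0)),
                background_energy_sd=float(dock_cfg.get("background_energy_sd", 0.2)),
                specific_fraction=float(dock_cfg.get("specific_fraction", 0.05)),
                planted_gap=float(dock_cfg.get("planted_gap", 3.0)),
                compound_ids=ids,
                seed=_seed_for(master, 2),
            )
            pose_truth, poses = synthgen.gen_poses(sim)
            save(pose_truth, "pose_truth.tsv")
            dockpose.write_pose_table(poses, outdir / "poses.tsv")
            manifest["outputs"].append("poses.tsv")

        filt = ScreenFilters(**config.get("filters", {}))
        report = run_screen(compounds, reference, poses, filt)
        save(report.ledger, "cascade_ledger.tsv")
        save(report.candidates, "candidates.tsv")
        for name, tbl in report.tables.items():
            save(tbl, f"audit_{name}.tsv")
        manifest["cascade_status"] = report.status
        manifest["ledger"] = report.ledger.to_dict(orient="records")
        if lib_truth is not None:
            manifest["n_library_truth_analogs"] = int((lib_truth["kind"] == "analog").sum())

    if "expression" in config:
        expr_cfg = dict(config.get("expression", {}))
        if "matrix" in expr_cfg:
            dataset = exprstats.read_expression(expr_cfg["matrix"], expr_cfg["meta"])
        else:
            sim = synthgen.ExprSimConfig(
                n_genes=int(expr_cfg.get("n_genes", 100)),
                samples_per_stage=expr_cfg.get("samples_per_stage", 10),
                effect_profiles=expr_cfg.get("effect_profiles", {}),
                anticorr_pairs=[tuple(p) for p in expr_cfg.get("anticorr_pairs", [])],
                seed=_seed_for(master, 3),
            )
            dataset, expr_truth = synthgen.gen_expression(sim)
            synthgen.write_expression(dataset, outdir / "expression.tsv", outdir / "samples.tsv")
            manifest["outputs"] += ["expression.tsv", "samples.tsv"]
            save(expr_truth, "expression_truth.tsv")
        genes = expr_cfg.get("genes") or list(dataset.gene_ids[:3])
        groups = expr_cfg.get("groups") or sorted(dataset.sample_meta["group"].unique())
        table, summary = run_expression(
            dataset,
            genes,
            groups,
            n_perm=int(expr_cfg.get("n_perm", 1000)),
            seed=_seed_for(master, 3),
        )
        save(table, "stage_tests.tsv")
        (outdir / "stage_tests_summary.txt").write_text(summary + "\n")
        manifest["outputs"].append("stage_tests_summary.txt")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    manifest["outputs"].append("manifest.json")
    return manifest
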