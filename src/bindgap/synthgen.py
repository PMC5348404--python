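"""Synthetic inputs with planted, recoverable structure.

Three generators supply everything the pipeline consumes:

* :func:`gen_expression` — an RPKM-like genes x samples matrix with a 5-level
  stage factor (normal, I-IV) and two groups, group-specific additive stage
  shifts on the log2 scale for planted genes, and anti-correlated gene pairs
  coupled through a shared latent factor.
* :func:`gen_poses` — docked-pose centers of mass scattered around K binding
  sites with Gaussian positional noise, background binding energies, and a
  planted specificity gap (extra depth at one designated site) for a chosen
  fraction of compounds.
* :func:`gen_library` — a SMILES library around a reference scaffold:
  analogs produced by enumerated small decorations (a graded similarity
  ladder) plus decoys from unrelated scaffold families.

Every generator is a pure function of its config, whose ``seed`` drives a
dedicated ``numpy`` generator; truth tables are emitted alongside the data so
downstream recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from bindgap.exprstats import DEFAULT_STAGES, ExpressionDataset

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ExprSimConfig",
    "DockSimConfig",
    "LibrarySimConfig",
    "DEFAULT_REFERENCE_SMILES",
    "gen_expression",
    "gen_poses",
    "gen_library",
    "write_expression",
    "write_library",
]

#: Stand-in reference inhibitor: an N-acylhydrazone with a piperonyl head,
#: the scaffold family of the Rhosin-like compounds the screen is built around.
DEFAULT_REFERENCE_SMILES = "O=C(NN=Cc1ccc2c(c1)OCO2)c1ccccc1"


# ---------------------------------------------------------------------------
# Expression

@dataclass
class ExprSimConfig:
    """Generative settings for the stage/group expression matrix.

    ``effect_profiles`` maps a planted gene id to per-group, per-stage
    additive shifts on the log2 scale, e.g.
    ``{"RHOA": {"Asian": {"I": 2.0}}}`` plants a Stage-I upshift in one group
    only. ``anticorr_pairs`` couples two planted genes through a shared
    latent factor with signed coupling ``rho``.
    """

    n_genes: int = 100
    samples_per_stage: Mapping[str, int] | int = 10
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    groups: tuple[str, ...] = ("Asian", "Caucasian")
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    noise_log_sd: float = 1.0
    effect_profiles: Mapping[str, Mapping[str, Mapping[str, float]]] = field(default_factory=dict)
    anticorr_pairs: Sequence[tuple[str, str, float]] = ()
    seed: int = 0

    def stage_counts(self) -> dict[str, int]:
        if isinstance(self.samples_per_stage, int):
            return {s: self.samples_per_stage for s in self.stage_labels}
        return dict(self.samples_per_stage)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.stage_labels) < 2:
            raise ValueError("need at least 2 stage labels")
        counts = self.stage_counts()
        if set(counts) != set(self.stage_labels):
            raise ValueError("samples_per_stage keys must match stage_labels")
        if any(c < 2 for c in counts.values()):
            raise ValueError("all per-stage sample counts must be >= 2")
        for gene, per_group in self.effect_profiles.items():
            for group, shifts in per_group.items():
                if group not in self.groups:
                    raise ValueError(f"unknown group {group!r} in effect profile for {gene}")
                bad = set(shifts) - set(self.stage_labels)
                if bad:
                    raise ValueError(f"invalid stage label(s) {sorted(bad)} in effect profile for {gene}")
        for ga, gb, rho in self.anticorr_pairs:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"coupling rho must be in [-1, 1], got {rho} for ({ga}, {gb})")


def gen_expression(config: ExprSimConfig) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Simulate the expression matrix; returns (dataset, planted-truth table).

    Each cell is ``2**(baseline_g + shift + latent + noise)`` with
    gene-level baselines ``N(baseline_log_mean, baseline_log_sd)`` and
    i.i.d. cell noise ``N(0, noise_log_sd)`` — multiplicative noise around a
    log-normal baseline. Anti-correlated pairs split their noise variance
    between a shared per-sample latent factor (weight ``sqrt(|rho|)``, sign
    applied to the second gene) and private noise, so the pair's log2 Pearson
    correlation is ``rho`` in expectation with unchanged marginal variance.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.stage_counts()

    sample_ids, stages, groups = [], [], []
    for group in config.groups:
        for stage in config.stage_labels:
            for i in range(counts[stage]):
                sample_ids.append(f"{group}_{stage}_{i + 1:02d}")
                stages.append(stage)
                groups.append(group)
    n_samples = len(sample_ids)

    planted = list(config.effect_profiles)
    paired = [g for pair in config.anticorr_pairs for g in pair[:2]]
    named = list(dict.fromkeys(planted + paired))
    if len(named) > config.n_genes:
        raise ValueError("n_genes smaller than the number of planted genes")
    gene_ids = named + [f"G{i + 1:04d}" for i in range(config.n_genes - len(named))]

    baselines = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    log2 = baselines[:, None] + rng.normal(0.0, config.noise_log_sd, (config.n_genes, n_samples))

    # anti-correlated pairs: re-draw their noise as shared-latent + private
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for ga, gb, rho in config.anticorr_pairs:
        z = rng.standard_normal(n_samples)
        shared = np.sqrt(abs(rho)) * config.noise_log_sd
        private = np.sqrt(1.0 - abs(rho)) * config.noise_log_sd
        log2[gene_pos[ga]] = baselines[gene_pos[ga]] + shared * z + private * rng.standard_normal(n_samples)
        log2[gene_pos[gb]] = baselines[gene_pos[gb]] + np.sign(rho) * shared * z + private * rng.standard_normal(n_samples)

    truth_rows = []
    stage_arr = np.array(stages)
    group_arr = np.array(groups)
    for gene, per_group in config.effect_profiles.items():
        for group, shifts in per_group.items():
            for stage, shift in shifts.items():
                mask = (stage_arr == stage) & (group_arr == group)
                log2[gene_pos[gene], mask] += shift
                truth_rows.append({"gene_id": gene, "group": group, "stage": stage, "log2_shift": shift})

    values = pd.DataFrame(2.0**log2, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    meta = pd.DataFrame(
        {"stage": stages, "group": groups}, index=pd.Index(sample_ids, name="sample_id")
    )
    dataset = ExpressionDataset(values=values, sample_meta=meta, stage_order=config.stage_labels)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "group", "stage", "log2_shift"])
    return dataset, truth


def write_expression(dataset: ExpressionDataset, matrix_path, meta_path) -> None:
    dataset.values.to_csv(matrix_path, sep="\t")
    dataset.sample_meta.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# Docked poses

@dataclass
class DockSimConfig:
    """Generative settings for docked poses around K binding sites.

    Defaults emulate a standard planted screen: 100 compounds, 9 poses each
    (a docking engine's usual output count), 9 candidate sites, 5% of
    compounds specific with a 3 kcal/mol planted gap over a N(-7, 0.2)
    kcal/mol energy background, 0.5 Angstrom positional scatter around site
    centers 20 Angstrom apart.
    """

    n_sites: int = 9
    site_centers: np.ndarray | None = None  # K x 3, Angstrom
    site_scatter_sd: float = 0.5
    n_compounds: int = 100
    poses_per_compound: int = 9
    background_energy_mean: float = -7.0
    background_energy_sd: float = 0.2
    specific_fraction: float = 0.05
    planted_gap: float = 3.0
    compound_ids: Sequence[str] | None = None
    auto_center_spacing: float = 20.0
    seed: int = 0

    def centers(self) -> np.ndarray:
        if self.site_centers is not None:
            c = np.asarray(self.site_centers, dtype=float)
        else:
            c = np.zeros((self.n_sites, 3))
            c[:, 0] = np.arange(self.n_sites) * self.auto_center_spacing
        if len(c) != self.n_sites:
            raise ValueError("site_centers length must equal n_sites")
        if len(c) > 1:
            d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 5.0 * self.site_scatter_sd:
                raise ValueError(
                    f"site centers must be pairwise separated by >= 5 x scatter sd "
                    f"({5.0 * self.site_scatter_sd:.2f} A); min distance {d.min():.2f} A"
                )
        return c

    def validate(self) -> None:
        if self.n_sites < 1 or self.n_compounds < 1 or self.poses_per_compound < 1:
            raise ValueError("n_sites, n_compounds and poses_per_compound must be positive")
        if not 0.0 <= self.specific_fraction <= 1.0:
            raise ValueError("specific_fraction must be in [0, 1]")
        if self.planted_gap < 0:
            raise ValueError("planted_gap must be >= 0")
        self.centers()


def gen_poses(config: DockSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate docked poses; returns (truth table, pose table).

    Each pose lands at ``site_center + N(0, scatter_sd) per axis`` with a
    background energy draw; a specific compound's poses at its designated
    site are deepened by ``planted_gap``, so its lowest-energy region beats
    its second-best by about the gap. Every compound's first pose is forced
    to its designated site so the designated region is always sampled.
    The truth table records each compound's designated site (generator-local
    index from 1) and specificity flag.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    centers = config.centers()
    K = config.n_sites

    if config.compound_ids is not None:
        ids = list(config.compound_ids)
        if len(ids) != config.n_compounds:
            raise ValueError("compound_ids length must equal n_compounds")
    else:
        ids = [f"CMP{i + 1:04d}" for i in range(config.n_compounds)]

    n_specific = int(round(config.specific_fraction * config.n_compounds))
    specific = np.zeros(config.n_compounds, dtype=bool)
    if n_specific:
        specific[rng.choice(config.n_compounds, size=n_specific, replace=False)] = True

    rows = []
    truth_rows = []
    for ci, cid in enumerate(ids):
        designated = int(rng.integers(K))
        sites = rng.integers(0, K, size=config.poses_per_compound)
        sites[0] = designated
        energies = rng.normal(
            config.background_energy_mean, config.background_energy_sd, config.poses_per_compound
        )
        if specific[ci]:
            energies[sites == designated] -= config.planted_gap
        coords = centers[sites] + rng.normal(0.0, config.site_scatter_sd, (config.poses_per_compound, 3))
        for pi in range(config.poses_per_compound):
            rows.append(
                {
                    "compound_id": cid,
                    "pose_id": pi + 1,
                    "x": coords[pi, 0],
                    "y": coords[pi, 1],
                    "z": coords[pi, 2],
                    "energy_kcal_mol": energies[pi],
                    "true_site": int(sites[pi]) + 1,
                }
            )
        truth_rows.append(
            {"compound_id": cid, "designated_site": designated + 1, "is_specific": bool(specific[ci])}
        )

    poses = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return truth, poses


# ---------------------------------------------------------------------------
# Compound library

@dataclass
class LibrarySimConfig:
    reference_smiles: str = DEFAULT_REFERENCE_SMILES
    n_analogs: int = 60
    n_decoys: int = 40
    decoration_depth: int = 3
    seed: int = 0

    def validate(self) -> None:
        if Chem.MolFromSmiles(self.reference_smiles) is None:
            raise ValueError(f"reference SMILES does not parse: {self.reference_smiles!r}")
        if self.n_analogs < 0 or self.n_decoys < 0:
            raise ValueError("n_analogs and n_decoys must be non-negative")
        if self.decoration_depth < 1:
            raise ValueError("decoration_depth must be >= 1")


# substituents attached (at their first atom) to an aromatic CH of the scaffold
_SUBSTITUENTS = ["C", "N", "O", "F", "Cl", "Br", "CO", "OC", "C(F)(F)F", "CC", "C#N"]

# unrelated scaffold families for decoys: aliphatic chains/rings, sugars,
# saturated heterocycles — deliberately far from the aroyl-hydrazone reference
_DECOY_SCAFFOLDS = [
    "CCCCCCCCCC",
    "CCCCCC(=O)OCC",
    "CC(C)CC(C)(C)O",
    "C1CCCCC1CCN",
    "C1CCOC1CO",
    "OCC1OC(O)C(O)C(O)C1O",
    "CC(N)C(=O)OCC(C)C",
    "C1CCC2CCCCC2C1",
    "CC1CCCCN1CCO",
    "OCCOCCOCCO",
    "CC(C)(C)OC(=O)NC1CCNCC1",
    "C1CSCCS1",
    "CC(O)CC(O)CC(O)C",
    "N1CCN(CCO)CC1",
    "CCCCN(CCCC)CCCC",
    "CC12CCC(CC1)C(C)(C)O2",
]


def _decorate_once(mol: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
    """Attach one small substituent to a random C-H carbon; None if impossible."""
    cands = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
    ]
    if not cands:
        return None
    anchor = int(rng.choice(cands))
    frag = Chem.MolFromSmiles(_SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))])
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(anchor, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _decorated_smiles(base: Chem.Mol, depth: int, rng: np.random.Generator) -> str | None:
    mol = base
    n_edits = int(rng.integers(1, depth + 1))
    for _ in range(n_edits):
        out = _decorate_once(mol, rng)
        if out is None:
            break
        mol = out
    smi = Chem.MolToSmiles(mol)
    return smi if Chem.MolFromSmiles(smi) is not None else None


def gen_library(config: LibrarySimConfig) -> pd.DataFrame:
    """Simulate a screening library; returns a table (id, smiles, kind).

    The reference is emitted first (kind ``reference``), then analogs — the
    reference scaffold with 1..decoration_depth enumerated single-substituent
    decorations, giving a graded similarity ladder — then decoys drawn from a
    disjoint set of non-aromatic scaffold families, themselves lightly
    decorated for variety. All emitted SMILES are guaranteed to re-parse.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ref = Chem.MolFromSmiles(config.reference_smiles)

    rows = [{"id": "REF", "smiles": Chem.MolToSmiles(ref), "kind": "reference"}]
    made = 0
    attempts = 0
    while made < config.n_analogs and attempts < 50 * max(config.n_analogs, 1):
        attempts += 1
        smi = _decorated_smiles(ref, config.decoration_depth, rng)
        if smi is None:
            continue
        made += 1
        rows.append({"id": f"A{made:04d}", "smiles": smi, "kind": "analog"})
    if made < config.n_analogs:
        raise RuntimeError("analog generation failed to converge")

    for i in range(config.n_decoys):
        base = Chem.MolFromSmiles(_DECOY_SCAFFOLDS[int(rng.integers(len(_DECOY_SCAFFOLDS)))])
        smi = _decorated_smiles(base, config.decoration_depth, rng) or Chem.MolToSmiles(base)
        rows.append({"id": f"D{i + 1:04d}", "smiles": smi, "kind": "decoy"})
    return pd.DataFrame(rows, columns=["id", "smiles", "kind"])


def write_library(library: pd.DataFrame, path) -> None:
    """Write a .smi file: 'SMILES<space>id' per line."""
    with open(path, "w") as fh:
        for _, row in library.iterrows():
            fh.write(f"{row['smiles']} {row['id']}\n")
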