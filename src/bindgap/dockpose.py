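"""Docked-pose ingestion, centers of mass, and binding-region clustering.

A pose is one docked placement of a compound: a center of mass (COM, in
Angstrom) and a binding energy (kcal/mol, more negative = more favorable).
Poses arrive either as a tab-separated pose table or as multi-model
Vina-style PDBQT text, in which case the COM is computed from the atom
records as the mass-weighted mean of atomic coordinates.

Binding regions ("clusters") are found by deterministic energy-ordered
leader clustering: poses are visited from most to least favorable energy,
each joining the first cluster whose representative (founding, lowest-energy)
COM lies within the distance cutoff, else founding a new cluster. Cluster ids
are assigned from 1 by ascending representative energy, so cluster 1 is the
deepest region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "POSE_COLUMNS",
    "ATOMIC_MASSES",
    "BindingClusterSet",
    "PoseFormatError",
    "read_pose_table",
    "write_pose_table",
    "read_vina_poses",
    "center_of_mass",
    "cluster_poses",
]

POSE_COLUMNS = ["compound_id", "pose_id", "x", "y", "z", "energy_kcal_mol"]

# standard atomic weights for elements common in docked ligands
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06,
    "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Fe": 55.845, "Zn": 65.38,
    "Se": 78.971, "Br": 79.904, "I": 126.904,
}

# AutoDock atom types that are not plain element symbols
_AUTODOCK_TYPES = {
    "A": "C", "OA": "O", "NA": "N", "SA": "S", "HD": "H", "HS": "H",
    "CL": "Cl", "BR": "Br", "FE": "Fe", "ZN": "Zn", "MG": "Mg", "MN": "Mn",
}


class PoseFormatError(ValueError):
    pass


def read_pose_table(path) -> pd.DataFrame:
    """Read a pose TSV with header exactly compound_id, pose_id, x, y, z, energy_kcal_mol."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise PoseFormatError(f"pose table missing column(s): {missing}")
    df = df[POSE_COLUMNS].copy()
    for col in ("x", "y", "z", "energy_kcal_mol"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), col].iloc[0]
            raise PoseFormatError(f"non-numeric value {bad!r} in column {col!r}")
        if not np.isfinite(vals).all():
            raise PoseFormatError(f"non-finite value in column {col!r}")
        df[col] = vals.astype(float)
    dup = df.duplicated(subset=["compound_id", "pose_id"])
    if dup.any():
        key = df.loc[dup, ["compound_id", "pose_id"]].iloc[0].tolist()
        raise PoseFormatError(f"duplicate (compound_id, pose_id): {key}")
    return df


def write_pose_table(poses: pd.DataFrame, path) -> None:
    poses[POSE_COLUMNS].to_csv(path, sep="\t", index=False)


def center_of_mass(atoms) -> tuple[float, float, float]:
    """Mass-weighted mean of atomic coordinates.

    ``atoms`` is an iterable of (element, x, y, z); elements must be in the
    standard atomic mass table.
    """
    atoms = list(atoms)
    if not atoms:
        raise ValueError("center of mass of zero atoms is undefined")
    masses, coords = [], []
    for elem, x, y, z in atoms:
        if elem not in ATOMIC_MASSES:
            raise KeyError(f"unknown element {elem!r}; no standard atomic mass available")
        masses.append(ATOMIC_MASSES[elem])
        coords.append((x, y, z))
    m = np.asarray(masses)
    c = np.asarray(coords, dtype=float)
    com = (m[:, None] * c).sum(axis=0) / m.sum()
    return (float(com[0]), float(com[1]), float(com[2]))


def _element_from_pdbqt_line(line: str) -> str:
    token = line[77:79].strip() if len(line) >= 78 else ""
    if not token:
        parts = line.split()
        token = parts[-1] if parts else ""
    if token in ATOMIC_MASSES:
        return token
    mapped = _AUTODOCK_TYPES.get(token.upper())
    if mapped:
        return mapped
    # atom-name fallback: first alphabetic character of the atom name field
    name = line[12:16].strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise PoseFormatError(f"cannot determine element from atom line: {line.rstrip()!r}")


def read_vina_poses(path, compound_id: str | None = None) -> pd.DataFrame:
    """Read multi-model Vina-style PDBQT output into a pose table.

    One pose per MODEL; the energy comes from the first numeric field of the
    "REMARK VINA RESULT:" line and the COM from the model's atom records.
    """
    if compound_id is None:
        import os

        compound_id = os.path.splitext(os.path.basename(str(path)))[0]
    rows = []
    model_no = 0
    energy: float | None = None
    atoms: list[tuple[str, float, float, float]] = []
    in_model = False

    def _flush() -> None:
        nonlocal energy, atoms
        if energy is None:
            raise PoseFormatError(f"MODEL {model_no} has no 'REMARK VINA RESULT:' line")
        if not atoms:
            raise PoseFormatError(f"MODEL {model_no} has no atom records")
        x, y, z = center_of_mass(atoms)
        rows.append(
            {"compound_id": compound_id, "pose_id": model_no,
             "x": x, "y": y, "z": z, "energy_kcal_mol": energy}
        )
        energy, atoms = None, []

    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                model_no = int(line.split()[1]) if len(line.split()) > 1 else model_no + 1
            elif line.startswith("REMARK VINA RESULT:"):
                try:
                    energy = float(line.split(":", 1)[1].split()[0])
                except (IndexError, ValueError) as exc:
                    raise PoseFormatError(f"unparseable VINA RESULT line: {line.rstrip()!r}") from exc
            elif rec in ("ATOM", "HETATM"):
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise PoseFormatError(f"unparseable atom line: {line.rstrip()!r}") from exc
                atoms.append((_element_from_pdbqt_line(line), x, y, z))
            elif rec == "ENDMDL":
                _flush()
                in_model = False
    if in_model and (atoms or energy is not None):
        _flush()
    if not rows:
        raise PoseFormatError(f"no poses found in {path}")
    return pd.DataFrame(rows, columns=POSE_COLUMNS)


@dataclass
class BindingClusterSet:
    """Partition of poses into binding regions.

    ``assignments`` maps every input pose to a cluster id (1..K, ascending
    representative energy); ``summary`` has one row per cluster with the
    centroid (mean member COM), member count, and the representative
    (lowest-energy) pose's compound, pose id and energy.
    """

    cutoff: float
    assignments: pd.DataFrame  # compound_id, pose_id, cluster_id
    summary: pd.DataFrame  # cluster_id, centroid_x/y/z, n_members, rep_*

    @property
    def n_clusters(self) -> int:
        return len(self.summary)

    def poses_with_clusters(self, poses: pd.DataFrame) -> pd.DataFrame:
        return poses.merge(self.assignments, on=["compound_id", "pose_id"], validate="one_to_one")


def cluster_poses(poses: pd.DataFrame, cutoff: float = 4.0) -> BindingClusterSet:
    """Energy-ordered leader clustering of pose COMs at a distance cutoff.

    Deterministic and invariant to input row order: poses are processed by
    ascending energy (ties by compound_id then pose_id), each joining the
    first existing cluster whose representative COM is within ``cutoff``
    Angstrom, else founding a new cluster. Because processing order is by
    energy, each cluster's founder is its lowest-energy (representative)
    member, and founding order equals ascending representative energy.
    """
    if len(poses) == 0:
        raise ValueError("cannot cluster zero poses")
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    df = poses.sort_values(
        ["energy_kcal_mol", "compound_id", "pose_id"], kind="mergesort", ignore_index=True
    )
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    leaders: list[np.ndarray] = []
    labels = np.empty(len(df), dtype=int)
    for i in range(len(df)):
        assigned = -1
        for k, leader in enumerate(leaders):
            if np.linalg.norm(coords[i] - leader) <= cutoff:
                assigned = k
                break
        if assigned < 0:
            leaders.append(coords[i])
            assigned = len(leaders) - 1
        labels[i] = assigned
    df = df.assign(cluster_id=labels + 1)

    summary_rows = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        rep = grp.iloc[0]  # grp preserves energy-sorted order
        summary_rows.append(
            {
                "cluster_id": int(cid),
                "centroid_x": float(grp["x"].mean()),
                "centroid_y": float(grp["y"].mean()),
                "centroid_z": float(grp["z"].mean()),
                "n_members": int(len(grp)),
                "rep_compound_id": rep["compound_id"],
                "rep_pose_id": rep["pose_id"],
                "rep_energy_kcal_mol": float(rep["energy_kcal_mol"]),
            }
        )
    summary = pd.DataFrame(summary_rows)
    assignments = df[["compound_id", "pose_id", "cluster_id"]].copy()
    return BindingClusterSet(cutoff=float(cutoff), assignments=assignments, summary=summary)
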