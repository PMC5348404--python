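"""Compound ingestion, fingerprints, Tanimoto screening, rule-of-five filtering.

Structures are parsed and canonicalized with RDKit. Fingerprints are
linear-path bitsets (all atom-bond paths up to ``max_path`` bonds hashed into
``n_bits`` positions); similarity is the Tanimoto coefficient
``|a AND b| / |a OR b|``. Drug-likeness uses the classic rule-of-five
descriptor set: molecular weight, Crippen atom-contribution logP, H-bond
donors as N-H/O-H hydrogens and acceptors as N+O atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Compound",
    "FingerprintParams",
    "LipinskiDescriptors",
    "parse_smiles",
    "fingerprint",
    "tanimoto",
    "similarity_screen",
    "lipinski_descriptors",
    "lipinski_filter",
    "read_smi",
    "write_smi",
]


class SmilesParseError(ValueError):
    pass


@dataclass(frozen=True)
class FingerprintParams:
    """Linear-path fingerprint settings (path length in bonds, bitset size)."""

    max_path: int = 7
    n_bits: int = 1024


class LipinskiDescriptors(NamedTuple):
    mw: float
    logp: float
    hbd: int
    hba: int


@dataclass
class Compound:
    """A parsed library member: canonical structure, fingerprint, descriptors."""

    id: str
    smiles: str  # canonical
    mol: Chem.Mol
    fp: np.ndarray  # boolean bitset

    @property
    def descriptors(self) -> LipinskiDescriptors:
        return lipinski_descriptors(self.mol)


def parse_smiles(text: str) -> Chem.Mol:
    """Parse a SMILES string into a sanitized molecule with implicit H.

    Raises :class:`SmilesParseError` naming the input on syntactically
    invalid or valence-impossible SMILES.
    """
    if not text or not text.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {text!r}")
    return mol


def fingerprint(mol: Chem.Mol, params: FingerprintParams = FingerprintParams()) -> np.ndarray:
    """Linear-path fingerprint as a boolean numpy bitset.

    Hashes every linear atom-bond path of 0..max_path bonds of the canonical
    structure into an ``n_bits`` bitset, so two SMILES spellings of the same
    molecule yield identical fingerprints. Length-0 paths (lone atoms, hashed
    by element) guarantee a non-empty bitset even for single-atom molecules.
    """
    if mol.GetNumAtoms() == 0:
        raise ValueError("cannot fingerprint an empty molecule")
    bv = Chem.RDKFingerprint(
        mol,
        minPath=1,
        maxPath=params.max_path,
        fpSize=params.n_bits,
        branchedPaths=False,
    )
    arr = np.zeros(params.n_bits, dtype=bool)
    arr[list(bv.GetOnBits())] = True
    for atom in mol.GetAtoms():  # length-0 paths: one bit per element present
        arr[(atom.GetAtomicNum() * 2654435761) % params.n_bits] = True
    return arr


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two equal-length bitsets."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"bitset lengths differ: {a.size} vs {b.size}")
    union = int((a | b).sum())
    if union == 0:
        raise ValueError("Tanimoto undefined: both bitsets empty")
    return float((a & b).sum()) / union


def _build_compound(cid: str, smiles: str, params: FingerprintParams) -> Compound:
    mol = parse_smiles(smiles)
    return Compound(id=cid, smiles=Chem.MolToSmiles(mol), mol=mol, fp=fingerprint(mol, params))


def make_library(
    entries: Iterable[tuple[str, str]], params: FingerprintParams = FingerprintParams()
) -> list[Compound]:
    """Parse (id, smiles) pairs into Compound objects."""
    return [_build_compound(cid, smi, params) for cid, smi in entries]


def similarity_screen(
    library: Sequence[Compound],
    reference: Compound,
    threshold: float = 0.6,
) -> pd.DataFrame:
    """Tanimoto screen against a reference; inclusive threshold.

    Returns the full audit table (id, tanimoto, survives) sorted by score
    descending; survivors are compounds with tanimoto >= threshold. The
    screening threshold of 0.6 retains "similar backbone" compounds.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    rows = [
        {
            "id": c.id,
            "tanimoto": tanimoto(c.fp, reference.fp),
        }
        for c in library
    ]
    out = pd.DataFrame(rows, columns=["id", "tanimoto"])
    out["survives"] = out["tanimoto"] >= threshold
    return out.sort_values(["tanimoto", "id"], ascending=[False, True], ignore_index=True)


def lipinski_descriptors(mol: Chem.Mol) -> LipinskiDescriptors:
    """Rule-of-five descriptor quadruple (MW, logP, HBD, HBA).

    MW sums standard atomic masses including implicit hydrogens; logP is the
    Crippen atom-contribution estimate; HBD counts O-H and N-H hydrogens and
    HBA counts N and O atoms (Lipinski's original convention).
    """
    if mol.GetNumAtoms() == 0:
        raise ValueError("descriptors undefined for an empty molecule")
    return LipinskiDescriptors(
        mw=float(Descriptors.MolWt(mol)),
        logp=float(Crippen.MolLogP(mol)),
        hbd=int(Lipinski.NHOHCount(mol)),
        hba=int(Lipinski.NOCount(mol)),
    )


RULE_OF_FIVE_LIMITS = {"mw": 500.0, "logp": 5.0, "hbd": 5, "hba": 10}


def lipinski_violations(desc: LipinskiDescriptors) -> dict[str, bool]:
    return {
        "mw": desc.mw > RULE_OF_FIVE_LIMITS["mw"],
        "logp": desc.logp > RULE_OF_FIVE_LIMITS["logp"],
        "hbd": desc.hbd > RULE_OF_FIVE_LIMITS["hbd"],
        "hba": desc.hba > RULE_OF_FIVE_LIMITS["hba"],
    }


def lipinski_filter(library: Sequence[Compound], max_violations: int = 1) -> pd.DataFrame:
    """Rule-of-five filter with a per-compound violation breakdown.

    A compound survives when its violation count over {MW > 500, logP > 5,
    HBD > 5, HBA > 10} is <= ``max_violations`` (default 1, the original
    rule's allowance; 0 gives strict mode).
    """
    rows = []
    for c in library:
        desc = c.descriptors
        viol = lipinski_violations(desc)
        rows.append(
            {
                "id": c.id,
                "mw": desc.mw,
                "logp": desc.logp,
                "hbd": desc.hbd,
                "hba": desc.hba,
                **{f"violates_{k}": v for k, v in viol.items()},
                "n_violations": int(sum(viol.values())),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "id", "mw", "logp", "hbd", "hba",
            "violates_mw", "violates_logp", "violates_hbd", "violates_hba",
            "n_violations",
        ],
    )
    out["survives"] = out["n_violations"] <= max_violations
    return out


def read_smi(path, params: FingerprintParams = FingerprintParams()) -> list[Compound]:
    """Read a .smi file (SMILES whitespace id per line; '#' comments allowed)."""
    compounds = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smi = parts[0]
            cid = parts[1] if len(parts) > 1 else f"line{i}"
            compounds.append(_build_compound(cid, smi, params))
    return compounds


def write_smi(compounds: Sequence[Compound], path) -> None:
    with open(path, "w") as fh:
        for c in compounds:
            fh.write(f"{c.smiles} {c.id}\n")
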