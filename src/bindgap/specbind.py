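"""Binding-specificity statistic and screening significance.

For each compound, the representative energy of a binding region is the
minimum energy among the compound's poses in that region. With representatives
sorted ascending, ``E1`` and ``E2`` are the two lowest and the specificity gap
``delta_Er = E2 - E1`` measures how much deeper the best region binds than the
runner-up: larger gaps mean more site-specific binding.

Significance conditions the gap ``M = delta_Er`` on the signal axis
``A = (E1 + E2) / 2`` (an MA-style conditional null): for each compound, a
local window of the batch nearest in A supplies a robust null. The window
median and MAD give the reported standardized statistic
``z = (M - median) / (1.4826 * MAD)``; the one-sided p-value comes from a
median-calibrated exponential survival function ``p = 2**(-M / median)``,
matching the right-skewed spacing-type null of a between-region gap (the
normal upper tail is badly anti-conservative here). Benjamini-Hochberg
adjustment across the batch yields q-values. Compounds whose poses fall in a
single region have no gap; they are flagged and excluded from the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from bindgap.dockpose import BindingClusterSet

__all__ = [
    "SpecificityConfig",
    "representative_energies",
    "specificity_gap",
    "build_records",
    "significance",
    "rank_candidates",
]


@dataclass(frozen=True)
class SpecificityConfig:
    window_frac: float = 0.1  # fraction of batch nearest in A per window
    min_window: int = 50  # lower bound on window size (capped at batch size)
    min_batch: int = 20  # minimum non-flagged records for null estimation
    median_floor: float = 1e-9  # guards the exponential calibration


def _member_energies(clusters: BindingClusterSet, poses: pd.DataFrame) -> pd.DataFrame:
    return clusters.poses_with_clusters(poses)


def representative_energies(
    clusters: BindingClusterSet, poses: pd.DataFrame, compound_id: str
) -> pd.DataFrame:
    """Per-cluster minimum energy for one compound, sorted ascending.

    Ties in energy are ordered by cluster_id for reproducibility. Raises
    KeyError when the compound has no pose in the cluster set.
    """
    merged = _member_energies(clusters, poses)
    mine = merged[merged["compound_id"] == compound_id]
    if len(mine) == 0:
        raise KeyError(f"compound {compound_id!r} absent from cluster set")
    reps = (
        mine.groupby("cluster_id", as_index=False)["energy_kcal_mol"]
        .min()
        .sort_values(["energy_kcal_mol", "cluster_id"], ignore_index=True)
    )
    return reps


def specificity_gap(energies: pd.DataFrame) -> dict:
    """E1, E2 and their gap from an ascending representative-energy table.

    A compound represented in a single cluster has no second energy; it is
    flagged (``single_cluster_flag``) rather than assigned an artificial E2.
    """
    if len(energies) == 0:
        raise ValueError("empty representative-energy collection")
    e = energies["energy_kcal_mol"].to_numpy(dtype=float)
    top = int(energies["cluster_id"].iloc[0])
    if len(e) == 1:
        return {
            "top_cluster_id": top, "E1": float(e[0]), "E2": np.nan,
            "delta_Er": np.nan, "A": np.nan, "single_cluster_flag": True,
        }
    return {
        "top_cluster_id": top,
        "E1": float(e[0]),
        "E2": float(e[1]),
        "delta_Er": float(e[1] - e[0]),
        "A": float((e[0] + e[1]) / 2.0),
        "single_cluster_flag": False,
    }


def build_records(clusters: BindingClusterSet, poses: pd.DataFrame) -> pd.DataFrame:
    """One specificity record per compound in the pose table."""
    merged = _member_energies(clusters, poses)
    rows = []
    for cid, grp in merged.groupby("compound_id", sort=True):
        reps = (
            grp.groupby("cluster_id", as_index=False)["energy_kcal_mol"]
            .min()
            .sort_values(["energy_kcal_mol", "cluster_id"], ignore_index=True)
        )
        rows.append({"compound_id": cid, **specificity_gap(reps)})
    return pd.DataFrame(rows)


def significance(records: pd.DataFrame, config: SpecificityConfig = SpecificityConfig()) -> pd.DataFrame:
    """Attach z, p and BH q to a batch of specificity records.

    Flagged (single-cluster) records pass through with NaN statistics; the
    batch of testable records must reach ``config.min_batch``. For each
    record, the window is the ``max(min_window, ceil(window_frac * n))``
    records nearest in A (capped at the batch size).
    """
    out = records.copy()
    testable = out.index[~out["single_cluster_flag"]]
    n = len(testable)
    if n < config.min_batch:
        raise ValueError(
            f"batch of {n} testable records is below the minimum of {config.min_batch}"
        )
    M = out.loc[testable, "delta_Er"].to_numpy(dtype=float)
    A = out.loc[testable, "A"].to_numpy(dtype=float)
    w = min(n, max(config.min_window, int(np.ceil(config.window_frac * n))))

    z = np.empty(n)
    p = np.empty(n)
    for j in range(n):
        idx = np.argsort(np.abs(A - A[j]), kind="mergesort")[:w]
        window = M[idx]
        med = float(np.median(window))
        if med <= config.median_floor:
            raise ValueError("window median gap is zero: null spread degenerate")
        mad = float(np.median(np.abs(window - med)))
        spread = max(1.4826 * mad, config.median_floor)
        z[j] = (M[j] - med) / spread
        p[j] = min(1.0, 2.0 ** (-M[j] / med))

    q = multipletests(p, method="fdr_bh")[1]
    for col in ("z", "p", "q"):
        out[col] = np.nan
    out.loc[testable, "z"] = z
    out.loc[testable, "p"] = p
    out.loc[testable, "q"] = q
    return out


def rank_candidates(
    records: pd.DataFrame, alpha: float | None = None, top_k: int | None = None
) -> pd.DataFrame:
    """Rank tested records and select survivors by q <= alpha or the top k.

    Sorted by (q ascending, delta_Er descending, compound_id); flagged
    records are excluded. Exactly the selection columns of the candidate
    table are returned, with a ``survives`` marker.
    """
    if alpha is None and top_k is None:
        raise ValueError("provide alpha or top_k")
    if "q" not in records.columns:
        raise ValueError("significance() must run before ranking")
    tested = records[~records["single_cluster_flag"]].copy()
    tested = tested.sort_values(
        ["q", "delta_Er", "compound_id"], ascending=[True, False, True], ignore_index=True
    )
    if alpha is not None:
        tested["survives"] = tested["q"] <= alpha
    else:
        tested["survives"] = False
        tested.loc[: top_k - 1, "survives"] = True
    return tested[["compound_id", "top_cluster_id", "E1", "E2", "delta_Er", "A", "z", "p", "q", "survives"]]
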