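"""Stage-stratified expression statistics.

Per-gene, per-group one-way ANOVA across tumor stages, a planned single-df
contrast (by default Stage I vs normal) on the pooled within-stage error, a
label-permutation empirical p-value for the F statistic, and exact 2x2
proportion tests for group-vs-trait comparisons.

The empirical p-value follows the strict-exceedance definition
``Pr(F > f_obs)``: the fraction of label permutations whose F statistic
strictly exceeds the observed one. This can legitimately be exactly 0; an
add-one smoothed estimator ``(1 + #{F >= f_obs}) / (1 + n_perm)`` is available
behind a flag. Permutations shuffle stage labels jointly over the samples of
the analyzed group only, never across groups, mirroring race-stratified
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionDataset",
    "TwoByTwoTable",
    "AnovaResult",
    "ContrastResult",
    "PermutationResult",
    "ProportionResult",
    "DegenerateDataError",
    "read_expression",
    "log_transform",
    "one_way_anova",
    "stage_contrast",
    "permutation_f_test",
    "proportion_test",
    "run_group_analysis",
]

DEFAULT_STAGES: tuple[str, ...] = ("normal", "I", "II", "III", "IV")


class DegenerateDataError(ValueError):
    """All values identical within and between levels: F is 0/0, undefined."""


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with per-sample stage/group labels.

    ``values`` is indexed by gene id with one column per sample id;
    ``sample_meta`` is indexed by sample id with columns ``stage`` and
    ``group``. Values are RPKM-like non-negative reals until
    :func:`log_transform` sets ``transform`` to ``"log2"``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    transform: str = "none"
    stage_order: tuple[str, ...] = field(default=DEFAULT_STAGES)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)[:5]}")
        for col in ("stage", "group"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {col!r}")
        if self.transform == "none" and (self.values.to_numpy() < 0).any():
            raise ValueError("untransformed expression values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_in_group(self, group: str) -> pd.Index:
        meta = self.sample_meta.loc[self.values.columns]
        sel = meta.index[meta["group"] == group]
        if len(sel) == 0:
            raise KeyError(
                f"unknown group {group!r}; available: "
                f"{sorted(self.sample_meta['group'].unique())}"
            )
        return sel

    def gene_values(self, gene: str, group: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, stage labels) for one gene, optionally one group."""
        if gene not in self.values.index:
            raise KeyError(
                f"unknown gene {gene!r}; available: {list(self.values.index[:10])}..."
            )
        cols = self.values.columns if group is None else self.samples_in_group(group)
        y = self.values.loc[gene, cols].to_numpy(dtype=float)
        stages = self.sample_meta.loc[cols, "stage"].to_numpy()
        return y, stages


def read_expression(matrix_path, meta_path, stage_order: Sequence[str] = DEFAULT_STAGES) -> ExpressionDataset:
    """Read an expression TSV (gene_id + sample columns) and a metadata TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    return ExpressionDataset(values=values, sample_meta=meta, stage_order=tuple(stage_order))


def log_transform(dataset: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """Return a copy with every value x replaced by log2(x + pseudocount)."""
    if dataset.transform != "none":
        raise ValueError(f"dataset already transformed ({dataset.transform})")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log2(dataset.values + pseudocount)
    return replace(dataset, values=logged, transform="log2")


# ---------------------------------------------------------------------------
# ANOVA core

class AnovaResult(NamedTuple):
    f: float
    df_between: int
    df_within: int
    p: float


class ContrastResult(NamedTuple):
    estimate: float
    t: float
    p: float
    df: int


class PermutationResult(NamedTuple):
    p_empirical: float
    f_obs: float
    n_perm: int
    seed: int


def _encode_levels(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels, codes = np.unique(labels, return_inverse=True)
    return codes, list(levels)


def _sums_of_squares(y: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    """Classical between/within sums of squares for a one-way layout."""
    n = y.size
    total = y.sum()
    group_sums = np.bincount(codes, weights=y, minlength=k)
    group_n = np.bincount(codes, minlength=k)
    ssb = float((group_sums**2 / group_n).sum() - total**2 / n)
    sst = float((y**2).sum() - total**2 / n)
    return ssb, max(sst - ssb, 0.0)


def _check_layout(y: np.ndarray, codes: np.ndarray) -> int:
    k = int(codes.max()) + 1 if codes.size else 0
    if k < 2:
        raise ValueError("one-way ANOVA needs at least 2 factor levels present")
    if y.size - k < 1:
        raise ValueError("within-group degrees of freedom must be >= 1")
    return k


def anova_from_arrays(y: np.ndarray, codes: np.ndarray) -> AnovaResult:
    """One-way ANOVA from a value vector and integer level codes."""
    y = np.asarray(y, dtype=float)
    k = _check_layout(y, codes)
    ssb, ssw = _sums_of_squares(y, codes, k)
    dfb, dfw = k - 1, y.size - k
    if ssw <= 0.0 and ssb <= 0.0:
        raise DegenerateDataError("all values identical: F statistic is 0/0")
    if ssw <= 0.0:
        return AnovaResult(np.inf, dfb, dfw, 0.0)
    f = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(f), dfb, dfw, float(stats.f.sf(f, dfb, dfw)))


def one_way_anova(dataset: ExpressionDataset, gene: str, group: str | None = None) -> AnovaResult:
    """One-way ANOVA of a gene's expression across stage levels.

    When ``group`` is given, only that group's samples enter the layout.
    """
    y, stages = dataset.gene_values(gene, group)
    codes, _ = _encode_levels(stages)
    return anova_from_arrays(y, codes)


def stage_contrast(
    dataset: ExpressionDataset,
    gene: str,
    weights: Mapping[str, float],
    group: str | None = None,
) -> ContrastResult:
    """Single-df planned contrast on stage means with pooled within-stage MSE.

    ``weights`` maps stage labels to contrast weights summing to zero, e.g.
    ``{"normal": -1, "I": +1}`` for the Stage-I-vs-normal comparison. The
    standard error uses the pooled mean square from *all* levels, as in a
    contrast within a one-way ANOVA (not a two-sample subset t test).
    """
    y, stages = dataset.gene_values(gene, group)
    codes, levels = _encode_levels(stages)
    k = _check_layout(y, codes)
    absent = [lv for lv in weights if lv not in levels]
    if absent:
        raise ValueError(f"contrast references absent stage level(s): {absent}")
    w = np.array([float(weights.get(lv, 0.0)) for lv in levels])
    if abs(w.sum()) > 1e-9:
        raise ValueError(f"contrast weights must sum to 0, got {w.sum()}")
    group_n = np.bincount(codes, minlength=k)
    means = np.bincount(codes, weights=y, minlength=k) / group_n
    _, ssw = _sums_of_squares(y, codes, k)
    dfw = y.size - k
    mse = ssw / dfw
    estimate = float(w @ means)
    se = float(np.sqrt(mse * (w**2 / group_n).sum()))
    if se == 0.0:
        t = 0.0 if estimate == 0.0 else np.inf * np.sign(estimate)
    else:
        t = estimate / se
    p = float(2.0 * stats.t.sf(abs(t), dfw)) if np.isfinite(t) else 0.0
    if t == 0.0:
        p = 1.0
    return ContrastResult(estimate, float(t), p, dfw)


def _permuted_f(y: np.ndarray, codes: np.ndarray, k: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """F statistics for ``n_perm`` label permutations, vectorized over perms.

    Permuting the stage labels over samples is equivalent to permuting the
    value vector against fixed labels; each row below is one such shuffle
    (sampling the label assignment without replacement).
    """
    n = y.size
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    yp = y[perm_idx]  # n_perm x n
    group_n = np.bincount(codes, minlength=k).astype(float)
    onehot = np.eye(k)[codes]  # n x k
    group_sums = yp @ onehot
    total = y.sum()
    sst = float((y**2).sum() - total**2 / n)
    ssb = (group_sums**2 / group_n).sum(axis=1) - total**2 / n
    ssw = np.maximum(sst - ssb, 0.0)
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore"):
        return np.where(ssw > 0, (ssb / dfb) / (ssw / dfw), np.inf)


def permutation_f_from_arrays(
    y: np.ndarray,
    codes: np.ndarray,
    n_perm: int,
    seed: int,
    smoothed: bool = False,
) -> PermutationResult:
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    k = _check_layout(y, codes)
    f_obs = anova_from_arrays(y, codes).f
    rng = np.random.default_rng(seed)
    f_perm = _permuted_f(y, codes, k, n_perm, rng)
    # tolerance so recomputation round-off cannot turn a tie into an exceedance
    tol = 1e-9 * (1.0 + abs(f_obs)) if np.isfinite(f_obs) else 0.0
    if smoothed:
        p = (1.0 + float((f_perm >= f_obs - tol).sum())) / (1.0 + n_perm)
    else:
        p = float((f_perm > f_obs + tol).sum()) / n_perm
    return PermutationResult(p, f_obs, n_perm, seed)


def permutation_f_test(
    dataset: ExpressionDataset,
    gene: str,
    n_perm: int = 1000,
    seed: int = 0,
    group: str | None = None,
    smoothed: bool = False,
) -> PermutationResult:
    """Empirical p-value Pr(F > f_obs) over stage-label permutations.

    Stage labels are permuted jointly over the analyzed samples (all samples,
    or one group's samples when ``group`` is given); the F statistic is
    recomputed for each shuffle and the strict-exceedance fraction returned.
    """
    y, stages = dataset.gene_values(gene, group)
    codes, _ = _encode_levels(stages)
    return permutation_f_from_arrays(y, codes, n_perm, seed, smoothed)


# ---------------------------------------------------------------------------
# 2x2 proportion tests

@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts with rows = groups and columns = trait present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("empty table: all counts zero")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


class ProportionResult(NamedTuple):
    odds_ratio: float
    p: float


def proportion_test(table: TwoByTwoTable) -> ProportionResult:
    """Sample odds ratio ad/bc and two-sided exact Fisher p.

    The p-value sums hypergeometric point probabilities <= that of the
    observed table over all tables with the same margins. A zero ``b`` or
    ``c`` cell yields an infinite odds ratio; 0/0 is reported as NaN.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        oddsr = np.nan if a * d == 0 else np.inf
    else:
        oddsr = (a * d) / (b * c)
    _, p = stats.fisher_exact(table.to_array(), alternative="two-sided")
    return ProportionResult(float(oddsr), float(p))


# ---------------------------------------------------------------------------
# Batch driver

DEFAULT_CONTRAST: dict[str, float] = {"normal": -1.0, "I": 1.0}


def _child_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_group_analysis(
    dataset: ExpressionDataset,
    genes: Sequence[str],
    groups: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    contrast: Mapping[str, float] | None = DEFAULT_CONTRAST,
    smoothed: bool = False,
) -> pd.DataFrame:
    """One StageTestResult row per (gene, group).

    Each (gene, group) pair receives its own permutation seed derived
    deterministically from the master seed and the pair's position, so the
    full table is reproducible and insensitive to which subsets are rerun.
    With ``n_perm = 0`` the permutation columns are omitted (parametric-only).
    """
    for g in genes:
        if g not in dataset.values.index:
            raise KeyError(f"unknown gene {g!r}")
    rows = []
    idx = 0
    for gene in genes:
        for group in groups:
            anova = one_way_anova(dataset, gene, group=group)
            row = {
                "gene_id": gene,
                "group": group,
                "f_obs": anova.f,
                "df_between": anova.df_between,
                "df_within": anova.df_within,
                "p_anova": anova.p,
            }
            if contrast is not None:
                con = stage_contrast(dataset, gene, contrast, group=group)
                row["contrast_estimate"] = con.estimate
                row["p_contrast"] = con.p
            if n_perm > 0:
                child = _child_seed(seed, idx)
                perm = permutation_f_test(
                    dataset, gene, n_perm=n_perm, seed=child, group=group, smoothed=smoothed
                )
                row["p_empirical"] = perm.p_empirical
                row["n_perm"] = n_perm
                row["seed"] = child
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)
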