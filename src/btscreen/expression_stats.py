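"""Fold-change and paired-test statistics for expression comparisons.

Two designs are covered.  The array-style comparison takes normalized
expression matrices for stimulated and non-stimulated co-cultures paired
by donor pool, and reports per gene the fold change (mean stimulated /
mean control), the absolute paired-t statistic, its two-sided p value
and a Benjamini–Hochberg FDR.  The qRT-PCR comparison converts Ct values
to relative expression 2^-Ct, normalises to a reference gene (β-actin),
and reports the stimulated/control fold change as mean ± sd across donor
pools.

Tables report fold changes at 2 decimals; all internal computation is
full precision, with rounding confined to the reporting layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class ExpressionError(ValueError):
    """Raised on malformed expression or Ct inputs."""


@dataclass
class PairedExpressionMatrix:
    """Gene × donor-pool matrices for a paired stimulated/control design."""

    stim: pd.DataFrame
    ctrl: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.stim.index.equals(self.ctrl.index):
            raise ExpressionError("stim and ctrl must share the gene index")
        if not self.stim.columns.equals(self.ctrl.columns):
            raise ExpressionError("stim and ctrl must share the pool columns (paired design)")
        if self.stim.shape[1] < 2:
            raise ExpressionError("paired tests need >= 2 donor pools")
        for name, mat in (("stim", self.stim), ("ctrl", self.ctrl)):
            arr = mat.to_numpy(dtype=float)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ExpressionError(f"{name} matrix must be finite and non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.stim.index)

    @property
    def pools(self) -> list[str]:
        return list(self.stim.columns)


@dataclass(frozen=True)
class GeneStat:
    gene: str
    fold_change: float
    t_abs: float
    p: float
    fdr: float


def fold_change(stim_mean: float, ctrl_mean: float) -> float:
    """Stimulated mean divided by control mean (both strictly positive)."""
    if not (math.isfinite(stim_mean) and stim_mean > 0):
        raise ExpressionError(f"stimulated mean must be positive, got {stim_mean!r}")
    if not (math.isfinite(ctrl_mean) and ctrl_mean > 0):
        raise ExpressionError(f"control mean must be positive, got {ctrl_mean!r}")
    return stim_mean / ctrl_mean


def paired_t(stim_row: Sequence[float], ctrl_row: Sequence[float]) -> tuple[float, float]:
    """Classical paired t on donor-matched values: (|t|, two-sided p).

    t = mean(d) / (sd(d)/sqrt(n)) with d the per-pool differences and
    df = n - 1.  Degenerate case: when the differences have zero variance
    the statistic is reported as +inf with p = 0 (and a warning) if the
    common difference is non-zero, or (0, 1) if the rows are identical.
    """
    stim = np.asarray(stim_row, dtype=float)
    ctrl = np.asarray(ctrl_row, dtype=float)
    if stim.shape != ctrl.shape or stim.ndim != 1:
        raise ExpressionError("paired rows must be 1-D and equal length")
    n = stim.size
    if n < 2:
        raise ExpressionError("paired t needs >= 2 pools")
    d = stim - ctrl
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        warnings.warn(
            "zero variance of paired differences with non-zero mean; "
            "reporting t = inf, p = 0",
            stacklevel=2,
        )
        return math.inf, 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return abs(float(t)), float(p)


def adjust_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ExpressionError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def compute_gene_stats(matrix: PairedExpressionMatrix) -> pd.DataFrame:
    """Per-gene table: means, sds, |t|, p, BH-FDR and fold change.

    Column layout mirrors the array-comparison table: mean_stim, sd_stim,
    mean_ctrl, sd_ctrl, t_abs, p, fdr, fold_change (sd with ddof = 1).
    """
    rows = []
    for gene in matrix.genes:
        s = matrix.stim.loc[gene].to_numpy(dtype=float)
        c = matrix.ctrl.loc[gene].to_numpy(dtype=float)
        t_abs, p = paired_t(s, c)
        rows.append(
            {
                "gene": gene,
                "mean_stim": s.mean(),
                "sd_stim": s.std(ddof=1),
                "mean_ctrl": c.mean(),
                "sd_ctrl": c.std(ddof=1),
                "t_abs": t_abs,
                "p": p,
                "fold_change": fold_change(s.mean(), c.mean()),
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    table["fdr"] = adjust_fdr(table["p"].tolist())
    return table[["mean_stim", "sd_stim", "mean_ctrl", "sd_ctrl",
                  "t_abs", "p", "fdr", "fold_change"]]


def ddct_fold_change(ct: pd.DataFrame, gene: str,
                     pools: Sequence[str] | None = None,
                     reference_gene: str = "ACTB") -> tuple[float, float, dict[str, float]]:
    """Reference-normalised 2^-Ct fold change of stimulated over control.

    ``ct`` has columns gene, pool, condition ('stim'/'ctrl'), ct.  Per
    pool and condition the relative expression is 2^-Ct(gene) / 2^-Ct(ref)
    = 2^-(Ct(gene) - Ct(ref)); the fold is the stim/ctrl ratio of these,
    and the summary is its mean ± sd (ddof = 1) across pools.  Adding a
    constant to both gene and reference Ct within a condition cancels.
    """
    required = {"gene", "pool", "condition", "ct"}
    if not required <= set(ct.columns):
        raise ExpressionError(f"Ct table needs columns {sorted(required)}")
    if pools is None:
        pools = sorted(ct["pool"].unique())

    def one_ct(pool: str, condition: str, which: str) -> float:
        rows = ct[(ct["gene"] == which) & (ct["pool"] == pool)
                  & (ct["condition"] == condition)]
        if len(rows) != 1:
            label = "reference" if which == reference_gene else "gene"
            raise ExpressionError(
                f"expected one {label} Ct for ({which}, pool {pool}, {condition}), "
                f"found {len(rows)}"
            )
        return float(rows["ct"].iloc[0])

    per_pool: dict[str, float] = {}
    for pool in pools:
        dct_stim = one_ct(pool, "stim", gene) - one_ct(pool, "stim", reference_gene)
        dct_ctrl = one_ct(pool, "ctrl", gene) - one_ct(pool, "ctrl", reference_gene)
        per_pool[pool] = 2.0 ** (dct_ctrl - dct_stim)
    folds = np.array(list(per_pool.values()))
    sd = float(folds.std(ddof=1)) if folds.size > 1 else 0.0
    return float(folds.mean()), sd, per_pool


def rank_genes(gene_stats: Iterable[GeneStat] | pd.DataFrame,
               by: str = "fold_change", top_n: int | None = None) -> list[GeneStat]:
    """Descending rank by fold_change or t_abs; ties break by gene symbol."""
    if by not in {"fold_change", "t_abs"}:
        raise ExpressionError(f"cannot rank by {by!r}")
    if isinstance(gene_stats, pd.DataFrame):
        stats_list = [
            GeneStat(gene=str(g), fold_change=row["fold_change"],
                     t_abs=row["t_abs"], p=row["p"], fdr=row["fdr"])
            for g, row in gene_stats.iterrows()
        ]
    else:
        stats_list = list(gene_stats)
    if not stats_list:
        raise ExpressionError("no gene statistics to rank")
    ranked = sorted(stats_list, key=lambda s: (-getattr(s, by), s.gene))
    return ranked if top_n is None else ranked[:top_n]
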