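"""The X-derepression statistic and supporting expression utilities.

The headline quantity is

    d = median(log2FC of X-linked genes) - median(log2FC of autosomal genes)

between two conditions, with 2^d its fold-change equivalent and a Wilcoxon
rank-sum test comparing the two log2FC distributions.  Real-data analyses
enter through a per-gene differential-expression table; synthetic count
matrices reach a log2FC table through a minimal median-of-ratios
normalization and pseudocounted mean ratio, keeping the statistic decoupled
from any external differential-expression tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CHROMOSOMES = ("I", "II", "III", "IV", "V", "X")

#: WBcel235 chromosome lengths in bp.
CHROM_LENGTHS = {
    "I": 15_072_434,
    "II": 15_279_421,
    "III": 13_783_801,
    "IV": 17_493_829,
    "V": 20_924_180,
    "X": 17_718_942,
}


@dataclass
class DerepressionResult:
    """d, its medians, the rank-sum comparison, and the fold equivalent."""

    d: float
    median_x: float
    median_a: float
    n_x: int
    n_a: int
    statistic: float  # rank-sum W of the X sample
    p_value: float

    @property
    def fold(self) -> float:
        return fold_change_equivalent(self.d)

    def summary(self) -> str:
        return (
            f"X derepression d = {self.d:.3f} ({self.fold:.3g}-fold), "
            f"median X = {self.median_x:.3f} (n={self.n_x}), "
            f"median autosome = {self.median_a:.3f} (n={self.n_a}), "
            f"Wilcoxon W = {self.statistic:.1f}, p = {self.p_value:.3g}"
        )


def validate_dge(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a differential-expression table.

    Requires ``gene_id, chrom, log2fc`` (plus optional ``start, pvalue,
    base_mean``).  Rows on chromosomes outside the nuclear vocabulary
    (mitochondrial, unplaced) are dropped with a logged count; non-finite
    log2FC and duplicated gene ids are errors.
    """
    needed = {"gene_id", "chrom", "log2fc"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"DGE table is missing columns {sorted(missing)}")
    out = table.copy()
    keep = out["chrom"].isin(CHROMOSOMES)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d genes on chromosomes outside %s", dropped, CHROMOSOMES)
        out = out[keep]
    if out["gene_id"].duplicated().any():
        raise ValueError("gene ids must be unique")
    if not np.isfinite(out["log2fc"].to_numpy(dtype=float)).all():
        raise ValueError("log2fc must be finite")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# minimal normalization / log2FC estimation for synthetic counts

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    factor_j = median over genes positive in all samples of
    count_gj / geometric-mean_g(counts).
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene is positive in all samples")
    sub = mat[allpos]
    geo = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    factors = np.median(sub / geo, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log2_fold_changes(
    counts: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    gene_info: pd.DataFrame | None = None,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
    with_pvalues: bool = False,
) -> pd.DataFrame:
    """Per-gene log2 fold changes of normalized group means.

    ``groups`` maps each sample column to ``"control"`` or ``"treatment"``.
    log2FC = log2((mean normalized treatment + c) / (mean normalized
    control + c)) with pseudocount ``c``.  With ``with_pvalues=True`` a
    per-gene rank-sum p across samples is added (only meaningful for a few
    replicates; the headline X-vs-autosome test is a single comparison).
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    if set(groups.index) != set(counts.columns) or set(groups.unique()) != {
        "control",
        "treatment",
    }:
        raise ValueError("groups must label every sample column as control or treatment")
    ctrl_cols = [c for c in counts.columns if groups[c] == "control"]
    trt_cols = [c for c in counts.columns if groups[c] == "treatment"]
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    norm = pd.DataFrame(norm, index=counts.index, columns=counts.columns)
    mean_c = norm[ctrl_cols].mean(axis=1)
    mean_t = norm[trt_cols].mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))

    table = pd.DataFrame({"gene_id": counts.index.astype(str), "log2fc": log2fc.to_numpy()})
    table["base_mean"] = ((mean_c + mean_t) / 2).to_numpy()
    if with_pvalues:
        ctrl = norm[ctrl_cols].to_numpy()
        trt = norm[trt_cols].to_numpy()
        pvals = np.empty(len(table))
        for i in range(len(table)):
            _, pvals[i] = wilcoxon_rank_sum(trt[i], ctrl[i])
        table["pvalue"] = pvals
    if gene_info is not None:
        table = table.merge(
            gene_info[[c for c in ("gene_id", "chrom", "start") if c in gene_info.columns]],
            on="gene_id",
            how="left",
        )
    return table


# ---------------------------------------------------------------------------
# the statistic

def wilcoxon_rank_sum(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank sum of the first sample (mid-ranks for ties).  With
    ``method="auto"`` the p-value is exact (enumeration over rank
    assignments) when the pooled size is at most 12 with no ties, otherwise
    a normal approximation with tie and continuity corrections; pass
    ``"exact"`` or ``"asymptotic"`` to force either route.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    elif method not in ("exact", "asymptotic"):
        raise ValueError("method must be auto, exact, or asymptotic")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    w = float(res.statistic + x.size * (x.size + 1) / 2.0)
    return w, float(res.pvalue)


def fold_change_equivalent(d: float) -> float:
    """2^d, the multiplicative expression change equivalent to a log2 shift d."""
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    return float(2.0**d)


def round_sig(value: float, digits: int = 3) -> float:
    """Round to significant figures (reporting convention for fold changes)."""
    if value == 0:
        return 0.0
    from math import floor, log10

    return round(value, -int(floor(log10(abs(value)))) + digits - 1)


def derepression(table: pd.DataFrame) -> DerepressionResult:
    """Compute the X-derepression statistic from a DGE table.

    Medians use the even-n convention (mean of the two central order
    statistics, the numpy/R default); the test is a two-sided Wilcoxon
    rank-sum comparison of X-linked vs autosomal log2FC values.
    """
    table = validate_dge(table)
    on_x = table["chrom"] == "X"
    x_vals = table.loc[on_x, "log2fc"].to_numpy(dtype=float)
    a_vals = table.loc[~on_x, "log2fc"].to_numpy(dtype=float)
    if x_vals.size == 0 or a_vals.size == 0:
        raise ValueError("need at least one X-linked and one autosomal gene")
    med_x = float(np.median(x_vals))
    med_a = float(np.median(a_vals))
    w, p = wilcoxon_rank_sum(x_vals, a_vals)
    return DerepressionResult(
        d=med_x - med_a,
        median_x=med_x,
        median_a=med_a,
        n_x=int(x_vals.size),
        n_a=int(a_vals.size),
        statistic=w,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# chromosome-coordinate profiles

def chromosome_profile(
    table: pd.DataFrame,
    lengths: dict[str, int] | None = None,
    bin_size: int = 500_000,
    p_max: float | None = 0.05,
) -> pd.DataFrame:
    """Binned mean log2FC along each chromosome (plot-ready table).

    Genes with ``p >= p_max`` are dropped first when a ``pvalue`` column is
    present; remaining genes are assigned to fixed-width bins by start
    coordinate.  Bins tile each chromosome (1-based, inclusive ends); empty
    bins carry count 0 and NaN mean.
    """
    table = validate_dge(table)
    if "start" not in table.columns:
        raise ValueError("chromosome profiles need a start coordinate column")
    lengths = dict(CHROM_LENGTHS if lengths is None else lengths)
    if p_max is not None and "pvalue" in table.columns:
        table = table[table["pvalue"] < p_max]
    rows = []
    for chrom in CHROMOSOMES:
        if chrom not in lengths:
            continue
        length = int(lengths[chrom])
        sub = table[table["chrom"] == chrom]
        if len(sub) and int(sub["start"].max()) > length:
            raise ValueError(f"gene beyond the stated length of chromosome {chrom}")
        n_bins = int(np.ceil(length / bin_size))
        starts = sub["start"].to_numpy(dtype=np.int64)
        idx = (starts - 1) // bin_size
        fc = sub["log2fc"].to_numpy(dtype=float)
        for b in range(n_bins):
            sel = idx == b
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": b * bin_size + 1,
                    "bin_end": min((b + 1) * bin_size, length),
                    "mean_log2fc": float(fc[sel].mean()) if sel.any() else np.nan,
                    "n_genes": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)
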