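"""Cell quality control and small deterministic utilities.

QC keeps cells with (strictly) more than 10,000 autosomal fragments, more
than 500 autosomal genes detected, less than 20% mitochondrial fragments
and less than 30% of autosomal fragments in the 100 most expressed genes.
Expression is normalised as logCPM = log(1 + 1e6 * count / library size)
(natural log).  Also here: the 30x30 grid geometric-mean aggregation used
to feed bulk-level predictors, and the binomial allele-specific-expression
genotype caller (success probabilities 0.01 / 0.5 / 0.99 for genotypes
0 / 1 / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .synthetic_data import ASE_P

__all__ = [
    "QcThresholds",
    "qc_filter_cells",
    "logcpm",
    "grid_aggregate",
    "genotype_from_ase",
]

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}
MITO = {"MT", "chrM", "M", "chrMT"}


@dataclass
class QcThresholds:
    min_fragments: int = 10_000
    min_genes: int = 500
    max_mito_pct: float = 20.0
    max_top100_pct: float = 30.0

    def __post_init__(self) -> None:
        if min(self.min_fragments, self.min_genes) <= 0 or \
                min(self.max_mito_pct, self.max_top100_pct) <= 0:
            raise ValueError("thresholds must be positive")


def qc_filter_cells(counts: pd.DataFrame, gene_annotations: pd.DataFrame,
                    thresholds: QcThresholds | None = None) -> pd.DataFrame:
    """Per-cell QC metrics and pass flags.

    Parameters
    ----------
    counts : DataFrame (cells x genes) of raw fragment counts
    gene_annotations : DataFrame indexed by gene id with a ``chrom`` column
    thresholds : QcThresholds; all four comparisons are strict

    Returns a DataFrame with fragments, genes detected, mito %, top-100 %
    and ``pass`` per cell.
    """
    th = thresholds or QcThresholds()
    missing = [g for g in counts.columns if g not in gene_annotations.index]
    if missing:
        raise ValueError(f"genes without chromosome annotation: "
                         f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    chrom = gene_annotations.loc[counts.columns, "chrom"].astype(str)
    auto = chrom.isin(AUTOSOMES).to_numpy()
    mito = chrom.isin(MITO).to_numpy()
    c = counts.to_numpy(dtype=float)
    auto_counts = c[:, auto]
    fragments = auto_counts.sum(axis=1)
    genes_detected = (auto_counts > 0).sum(axis=1)
    total = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(total > 0,
                            100.0 * c[:, mito].sum(axis=1) / total, 0.0)
        top100 = np.sort(auto_counts, axis=1)[:, -100:].sum(axis=1)
        top100_pct = np.where(fragments > 0,
                              100.0 * top100 / fragments, 100.0)
    ok = ((fragments > th.min_fragments)
          & (genes_detected > th.min_genes)
          & (mito_pct < th.max_mito_pct)
          & (top100_pct < th.max_top100_pct))
    return pd.DataFrame({
        "fragments": fragments.astype(int),
        "genes_detected": genes_detected.astype(int),
        "mito_pct": mito_pct,
        "top100_pct": top100_pct,
        "pass": ok,
    }, index=counts.index)


def logcpm(counts) -> np.ndarray | pd.DataFrame:
    """log(1 + 1e6 * count / library size), natural log, per cell (row)."""
    arr = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) \
        else np.atleast_2d(np.asarray(counts, dtype=float))
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    lib = arr.sum(axis=1, keepdims=True)
    if np.any(lib == 0):
        raise ValueError("zero library size")
    out = np.log1p(1e6 * arr / lib)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def grid_aggregate(values, coords, n_grid: int = 30,
                   mode: str = "literal") -> pd.DataFrame:
    """Geometric-mean aggregation over an equispaced 2-D grid.

    The bounding box of ``coords`` is split into ``n_grid`` x ``n_grid``
    equal cells; values of cells falling in the same grid cell are combined
    by geometric mean.  ``mode='literal'`` takes the geometric mean of the
    (logCPM) values themselves, excluding zeros and counting exclusions;
    ``mode='log_of_mean'`` takes the arithmetic mean (the geometric mean on
    the CPM scale).  Empty grid cells are omitted.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    xy = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("coordinates must be finite")
    if mode not in {"literal", "log_of_mean"}:
        raise ValueError("mode must be 'literal' or 'log_of_mean'")
    lo = xy.min(axis=0)
    span = np.where(xy.max(axis=0) > lo, xy.max(axis=0) - lo, 1.0)
    idx = np.clip((xy - lo) / span * n_grid, 0, n_grid - 1e-9).astype(int)
    rows = []
    for (gx, gy), grp in pd.DataFrame(
            {"gx": idx[:, 0], "gy": idx[:, 1]}).groupby(["gx", "gy"]):
        vals = v[grp.index.to_numpy()]
        if mode == "literal":
            n_excl = int(np.sum(vals <= 0))
            agg = [float(np.exp(np.mean(np.log(col[col > 0]))))
                   if np.any(col > 0) else np.nan for col in vals.T]
        else:
            n_excl = 0
            agg = list(np.mean(vals, axis=0))
        rows.append((gx, gy, len(vals), n_excl, *agg))
    cols = ["grid_x", "grid_y", "n_cells", "n_excluded"] + \
        [f"value_{k}" for k in range(v.shape[1])]
    return pd.DataFrame(rows, columns=cols)


def genotype_from_ase(ref_count: int, alt_count: int,
                      margin: float = 2.0):
    """Maximum-likelihood genotype from allele-specific read counts.

    Fits Binomial(n = ref+alt, p) to the alt count with p in
    {0.01, 0.5, 0.99} for genotypes 0/1/2.  Returns (genotype, logliks);
    genotype is None when n = 0 or when the best log-likelihood beats the
    runner-up by less than ``margin`` log units.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be nonnegative")
    n = ref_count + alt_count
    logliks = np.array([binom.logpmf(alt_count, n, p) for p in ASE_P])
    if n == 0:
        return None, logliks
    order = np.argsort(logliks)[::-1]
    if logliks[order[0]] - logliks[order[1]] < margin:
        return None, logliks
    return int(order[0]), logliks
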