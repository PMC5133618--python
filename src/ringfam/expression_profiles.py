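"""Expression-atlas profiling, responsiveness flagging and
sequence-expression association.

The atlas path is median-centering followed by hierarchical clustering
on Pearson distance (1 - r, average linkage).  Per-contrast differential
expression tables are thresholded into a responsive-gene flag, and two
distance matrices over the same genes can be compared with a one-sided
permutation Mantel test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "MantelResult",
    "bh_adjust",
    "coexpression_matrix",
    "flag_responsive",
    "hcluster",
    "mantel_test",
    "median_center",
    "pearson_distance_matrix",
    "welch_de_table",
]


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene row's median; row medians become exactly 0."""
    if matrix.shape[1] < 1:
        raise ValueError("matrix needs at least one sample column")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise TypeError("expression matrix must be numeric")
    return matrix.sub(matrix.median(axis=1), axis=0)


def pearson_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Gene-by-gene Pearson distance d = 1 - r.

    Zero-variance rows cannot be correlated; their distance to every
    other gene is defined as 1 with a warning.
    """
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance rows; distance set to 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    d = 1.0 - r
    d[degenerate, :] = 1.0
    d[:, degenerate] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return d


def hcluster(
    matrix: pd.DataFrame, n_clusters: int | None = None, linkage: str = "average"
) -> tuple[np.ndarray, pd.Series | None]:
    """Hierarchical clustering of genes on Pearson distance.

    Returns the scipy linkage matrix and, when ``n_clusters`` is given,
    a flat cluster label per gene (maxclust cut).
    """
    if matrix.shape[0] < 2:
        raise ValueError("at least two genes required")
    d = pearson_distance_matrix(matrix)
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    labels = None
    if n_clusters is not None:
        flat = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
        labels = pd.Series(flat, index=matrix.index, name="cluster")
    return z, labels


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values with monotonicity."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def flag_responsive(
    de: pd.DataFrame,
    lfc_min: float = 0.5,
    fdr_max: float = 0.05,
    min_conditions: int = 2,
) -> pd.DataFrame:
    """Per-gene responsiveness from a long-format DE table.

    ``de`` columns: gene, contrast, log2fc, fdr.  A gene is responsive
    when |log2fc| > ``lfc_min`` and fdr < ``fdr_max`` in at least
    ``min_conditions`` contrasts.  The relaxed count (significant in >=1
    contrast at any fold change) is reported alongside.  Missing values
    are treated as not significant and counted.
    """
    required = {"gene", "contrast", "log2fc", "fdr"}
    if not required.issubset(de.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    n_contrasts = de["contrast"].nunique()
    if n_contrasts < min_conditions:
        raise ValueError(
            f"only {n_contrasts} contrasts available, need >= {min_conditions}"
        )
    work = de.copy()
    n_missing = int(work[["log2fc", "fdr"]].isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(f"{n_missing} DE rows with missing statistics treated as ns")
    work["strict"] = (work["log2fc"].abs() > lfc_min) & (work["fdr"] < fdr_max)
    work["relaxed"] = work["fdr"] < fdr_max
    work[["strict", "relaxed"]] = work[["strict", "relaxed"]].fillna(False)
    grouped = work.groupby("gene", sort=True)
    out = pd.DataFrame(
        {
            "n_strict": grouped["strict"].sum(),
            "n_relaxed": grouped["relaxed"].sum(),
            "n_up": grouped.apply(
                lambda g: int((g["strict"] & (g["log2fc"] > 0)).sum()),
                include_groups=False,
            ),
            "n_down": grouped.apply(
                lambda g: int((g["strict"] & (g["log2fc"] < 0)).sum()),
                include_groups=False,
            ),
        }
    )
    out["responsive"] = out["n_strict"] >= min_conditions
    out["relaxed_responsive"] = out["n_relaxed"] >= 1
    out.attrs["n_missing"] = n_missing
    return out


def welch_de_table(
    matrix: pd.DataFrame, groups: pd.Series, contrasts: list[tuple[str, str]]
) -> pd.DataFrame:
    """Plain two-group Welch-t stand-in for model-based DE fitting.

    For each (treatment, control) contrast: log2fc is the difference of
    group means (matrix assumed log2 scale), p from Welch's t, FDR by
    Benjamini-Hochberg within the contrast.  Not equivalent to
    limma/DESeq2 moderated statistics; for synthetic end-to-end runs.
    """
    rows = []
    for treat, ctrl in contrasts:
        a = matrix.loc[:, groups[matrix.columns] == treat].to_numpy()
        b = matrix.loc[:, groups[matrix.columns] == ctrl].to_numpy()
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError(f"contrast {treat} vs {ctrl} needs >=2 samples per group")
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        rows.append(
            pd.DataFrame(
                {
                    "gene": matrix.index,
                    "contrast": f"{treat}_vs_{ctrl}",
                    "log2fc": a.mean(axis=1) - b.mean(axis=1),
                    "p_value": p,
                    "fdr": bh_adjust(np.nan_to_num(p, nan=1.0)),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def coexpression_matrix(
    matrix: pd.DataFrame, weights=None
) -> pd.DataFrame:
    """Weighted Pearson correlation between gene rows.

    ``weights`` is one non-negative value per sample (default: unit
    weights, i.e. ordinary Pearson).  Genes with zero weighted variance
    get NaN correlations.
    """
    x = matrix.to_numpy(dtype=float)
    n_samples = x.shape[1]
    if weights is None:
        w = np.ones(n_samples)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (n_samples,):
        raise ValueError("one weight per sample required")
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    mean = x @ w
    xc = x - mean[:, None]
    cov = (xc * w) @ xc.T
    var = np.diag(cov).copy()
    degenerate = var <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(np.outer(var, var))
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=matrix.index, columns=matrix.index)


@dataclass(frozen=True)
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int
    n_objects: int


def mantel_test(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """One-sided permutation Mantel test between two square symmetric
    matrices over the same objects.

    The statistic is the Pearson correlation of the upper-triangle
    entries; the p-value is ``(1 + #{permuted >= observed}) / (n_perm +
    1)`` under joint row+column permutation of ``matrix_b``.
    """
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    n = a.shape[0]
    if n < 3:
        raise ValueError("at least 3 objects required")
    for name, m in (("first", a), ("second", b)):
        if not np.allclose(m, m.T):
            raise ValueError(f"{name} matrix is not symmetric")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    observed = _pearson(va, b[iu])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    rows = perms[:, iu[0]]
    cols = perms[:, iu[1]]
    permuted = b[rows, cols]  # (n_perm, n_pairs)
    stats_perm = _pearson_rows(va, permuted)
    if alternative == "greater":
        count = int(np.sum(stats_perm >= observed))
    elif alternative == "less":
        count = int(np.sum(stats_perm <= observed))
    elif alternative == "two-sided":
        count = int(np.sum(np.abs(stats_perm) >= abs(observed)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + count) / (n_perm + 1)
    return MantelResult(float(observed), float(p), n_perm, n)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def _pearson_rows(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = yc @ xc
    den = np.sqrt((xc @ xc) * np.sum(yc * yc, axis=1))
    return num / den
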