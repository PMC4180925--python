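"""Strain-genetic statistics over the behavioral parameter matrix.

Per parameter: an optional log10 transform (applied when it reduces
positive skew), Winsorizing at mean +/- 5 SD of the pooled data, a
narrow-sense heritability estimate from between/within-strain variance
components with an unequal-group-size correction, and a one-way ANOVA
across strains with stringent Bonferroni correction (alpha / number of
parameters).

Heritability follows the inbred-panel variance-component estimator:
with ``a`` strains of sizes n_i (N total),

    n0        = (N - sum(n_i^2) / N) / (a - 1)
    V_between = max(0, (MS_between - MS_within) / n0)
    V_within  = MS_within
    h^2       = (V_between / 2) / (V_between / 2 + V_within)

The factor 1/2 corrects for the doubling of additive genetic variance
among fully inbred strains, so h^2 estimates the narrow-sense fraction in
a random-breeding population.

Cohort-level analyses: PCA on the correlation matrix of complete cases
with Kaiser's criterion (retain eigenvalues strictly above 1) and varimax
rotation of the retained loadings; pairwise shared genetic variance as
the squared Pearson correlation between strain-mean vectors; and a
one-way ANOVA of per-parameter heritability across the six parameter
categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "VarianceComponents",
    "maybe_log10",
    "winsorize_5sd",
    "heritability",
    "anova_bonferroni",
    "varimax",
    "pca_kaiser",
    "shared_genetic_variance",
    "effectsize_by_category",
    "run_strain_stats",
    "StrainStatsReport",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VarianceComponents:
    n_strains: int
    group_sizes: tuple[int, ...]
    n_total: int
    ms_between: float
    ms_within: float
    n0: float
    v_between: float
    v_within: float


def maybe_log10(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """log10-transform iff it reduces a positive skew.

    Skewness is the adjusted Fisher-Pearson sample coefficient.  Values
    containing zeros or negatives are returned untransformed (logged).
    """
    v = np.asarray(values, float)
    finite = v[np.isfinite(v)]
    if len(finite) < 3:
        return v.copy(), False
    if np.any(finite <= 0):
        log.debug("log10 skipped: nonpositive values present")
        return v.copy(), False
    skew_before = sps.skew(finite, bias=False)
    skew_after = sps.skew(np.log10(finite), bias=False)
    if skew_before > 0 and skew_after < skew_before:
        out = np.where(np.isfinite(v), np.log10(np.where(v > 0, v, 1.0)), v)
        return out, True
    return v.copy(), False


def winsorize_5sd(values: np.ndarray, n_sd: float = 5.0) -> tuple[np.ndarray, int]:
    """Replace values beyond mean +/- n_sd * SD (pooled over all animals,
    not per strain) with the limit itself; returns the count replaced."""
    v = np.asarray(values, float).copy()
    finite = np.isfinite(v)
    if finite.sum() < 3:
        return v, 0
    m = float(np.mean(v[finite]))
    sd = float(np.std(v[finite], ddof=1))
    if sd == 0:
        return v, 0
    lo, hi = m - n_sd * sd, m + n_sd * sd
    n = int(np.sum((v[finite] < lo) | (v[finite] > hi)))
    v[finite] = np.clip(v[finite], lo, hi)
    return v, n


def _group_arrays(values: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    ok = np.isfinite(values)
    return [values[ok & (labels == g)] for g in pd.unique(labels[ok])]


def heritability(values: np.ndarray, labels: np.ndarray) -> tuple[float, VarianceComponents]:
    """Narrow-sense heritability from an inbred strain panel (see module
    docstring).  All-identical values give h^2 = 0."""
    groups = [g for g in _group_arrays(values, labels) if len(g) > 0]
    a = len(groups)
    if a < 2 or sum(len(g) >= 2 for g in groups) < 2:
        raise ValueError("need >= 2 strains with >= 2 animals each")
    n_i = np.array([len(g) for g in groups], float)
    N = n_i.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - np.sum(n_i ** 2) / N) / (a - 1)
    v_between = max(0.0, (ms_between - ms_within) / n0)
    v_within = ms_within
    denom = 0.5 * v_between + v_within
    h2 = (0.5 * v_between / denom) if denom > 0 else 0.0
    vc = VarianceComponents(
        n_strains=a, group_sizes=tuple(int(n) for n in n_i), n_total=int(N),
        ms_between=ms_between, ms_within=ms_within, n0=float(n0),
        v_between=v_between, v_within=v_within,
    )
    return h2, vc


def anova_bonferroni(matrix: pd.DataFrame, labels: pd.Series,
                     alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA across strains per parameter; a parameter is
    significant iff p < alpha / (number of parameters in the matrix)."""
    n_params = matrix.shape[1]
    threshold = alpha / n_params
    lab = labels.loc[matrix.index].to_numpy()
    out = []
    for name in matrix.columns:
        groups = [g for g in _group_arrays(matrix[name].to_numpy(), lab)
                  if len(g) >= 2]
        if len(groups) < 2 or all(np.all(g == g[0]) for g in groups):
            out.append((name, np.nan, np.nan, False))
            continue
        try:
            F, p = sps.f_oneway(*groups)
        except Exception:
            F, p = np.nan, np.nan
        if not np.isfinite(F):
            out.append((name, np.nan, np.nan, False))
            continue
        out.append((name, float(F), float(p), bool(p < threshold)))
    df = pd.DataFrame(out, columns=["parameter", "F", "p", "significant"])
    df.attrs["threshold"] = threshold
    return df.set_index("parameter")


def varimax(loadings: np.ndarray, tol: float = 1e-10,
            max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser) of a loading matrix.

    Communalities (row sums of squared loadings) are preserved exactly by
    the orthogonality of the rotation.
    """
    L = np.asarray(loadings, float).copy()
    n, k = L.shape
    if k < 2:
        return L
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag(np.sum(Lr ** 2, axis=0)) / n))
        R = u @ vt
        var_new = float(np.sum(s))
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    return L @ R


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    n_retained: int
    loadings: pd.DataFrame          # varimax-rotated, parameters x PCs
    high_loadings: pd.DataFrame     # |loading| >= cutoff flags
    n_dropped_rows: int
    dropped_columns: tuple[str, ...] = ()


def pca_kaiser(matrix: pd.DataFrame, loading_cutoff: float = 0.4) -> PCAResult:
    """Correlation-matrix PCA with Kaiser's criterion.

    Rows with any missing value are dropped (complete-case, logged);
    constant columns are excluded from the decomposition.  Components with
    eigenvalue strictly greater than 1 are retained and varimax-rotated;
    loadings at or above ``loading_cutoff`` in magnitude are flagged.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 parameters for PCA")
    complete = matrix.dropna(axis=0)
    n_dropped = matrix.shape[0] - complete.shape[0]
    if n_dropped:
        log.info("PCA: dropped %d incomplete animals", n_dropped)
    sd = complete.std(ddof=1)
    keep = sd > 0
    dropped_cols = tuple(complete.columns[~keep])
    if dropped_cols:
        log.info("PCA: dropped %d constant parameters", len(dropped_cols))
    z = (complete.loc[:, keep] - complete.loc[:, keep].mean()) / sd[keep]
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # strictly greater than 1, with a tolerance so an exactly-unit
    # eigenvalue (identity correlation) is never retained off fp noise
    retained = int(np.sum(eigval > 1.0 + 1e-9))
    if retained:
        raw = eigvec[:, :retained] * np.sqrt(eigval[:retained])
        rot = varimax(raw)
        cols = [f"PC{i + 1}" for i in range(retained)]
        loadings = pd.DataFrame(rot, index=z.columns, columns=cols)
    else:
        loadings = pd.DataFrame(index=z.columns)
    return PCAResult(
        eigenvalues=eigval,
        n_retained=retained,
        loadings=loadings,
        high_loadings=loadings.abs() >= loading_cutoff,
        n_dropped_rows=n_dropped,
        dropped_columns=dropped_cols,
    )


def shared_genetic_variance(matrix: pd.DataFrame,
                            labels: pd.Series) -> pd.DataFrame:
    """Pairwise squared Pearson correlation between strain-mean vectors.

    Each parameter is reduced to its vector of strain means; r^2 between
    two such vectors is the fraction of genetic (between-strain) variance
    the parameters share.  Pairs involving a constant strain-mean vector
    are NaN.
    """
    strain_means = matrix.groupby(labels.loc[matrix.index]).mean()
    if strain_means.shape[0] < 3:
        raise ValueError("need >= 3 strains for shared genetic variance")
    X = strain_means.to_numpy()
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r2 = r ** 2
    bad = sd == 0
    r2[bad, :] = np.nan
    r2[:, bad] = np.nan
    np.fill_diagonal(r2, 1.0)
    r2[np.ix_(bad, bad)] = np.nan
    return pd.DataFrame(r2, index=matrix.columns, columns=matrix.columns)


def r2_histogram(r2: pd.DataFrame, bin_width: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the off-diagonal (unordered pair) r^2 values."""
    vals = r2.to_numpy()[np.triu_indices(len(r2), k=1)]
    vals = vals[np.isfinite(vals)]
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    return counts, edges


def effectsize_by_category(h2: pd.Series, categories: dict[str, str]) -> dict:
    """One-way ANOVA of per-parameter heritability across categories.

    Parameters are the observations, their category the factor; df is
    (k - 1, n_params - k).  Degenerate cases (zero within-category
    variance) are reported missing rather than as infinite F.
    """
    cats = pd.Series({p: categories[p] for p in h2.index})
    ok = h2.notna()
    groups = [h2[ok][cats[ok] == c].to_numpy()
              for c in pd.unique(cats[ok])]
    groups = [g for g in groups if len(g) >= 1]
    k = len(groups)
    n = sum(len(g) for g in groups)
    if k < 2:
        raise ValueError("need >= 2 populated categories")
    F, p = sps.f_oneway(*[g for g in groups if len(g) >= 1])
    if not np.isfinite(F):
        return {"F": np.nan, "p": np.nan, "df": (k - 1, n - k),
                "note": "degenerate (zero within-category variance)"}
    return {"F": float(F), "p": float(p), "df": (k - 1, n - k), "note": ""}


@dataclass
class StrainStatsReport:
    per_parameter: pd.DataFrame     # transform, n_winsorized, h2, F, p, significant
    bonferroni_threshold: float
    pca: PCAResult
    shared_variance: pd.DataFrame
    category_anova: dict


def run_strain_stats(matrix: pd.DataFrame, labels: pd.Series,
                     categories: dict[str, str],
                     alpha: float = 0.05) -> StrainStatsReport:
    """The full per-parameter and cohort-level statistical workflow.

    Order per parameter: transform decision, then Winsorizing, then
    variance components and ANOVA on the processed values.
    """
    processed = {}
    meta = []
    for name in matrix.columns:
        v = matrix[name].to_numpy()
        v, applied = maybe_log10(v)
        v, n_w = winsorize_5sd(v)
        processed[name] = v
        meta.append((name, applied, n_w))
    proc = pd.DataFrame(processed, index=matrix.index)

    lab = labels.loc[matrix.index]
    anova = anova_bonferroni(proc, lab, alpha=alpha)
    rows = []
    for name, applied, n_w in meta:
        try:
            h2, vc = heritability(proc[name].to_numpy(), lab.to_numpy())
        except ValueError:
            h2 = np.nan
        rows.append({
            "parameter": name,
            "category": categories.get(name, ""),
            "log10": applied,
            "n_winsorized": n_w,
            "h2": h2,
            "F": anova.loc[name, "F"],
            "p": anova.loc[name, "p"],
            "significant": anova.loc[name, "significant"],
        })
    per_param = pd.DataFrame(rows).set_index("parameter")

    pca = pca_kaiser(proc)
    if lab.nunique() >= 3:
        shared = shared_genetic_variance(proc, lab)
    else:
        log.warning("shared genetic variance needs >= 3 strains; skipped")
        shared = pd.DataFrame(index=matrix.columns, columns=matrix.columns,
                              dtype=float)
    cat = effectsize_by_category(per_param["h2"], categories)
    return StrainStatsReport(
        per_parameter=per_param,
        bonferroni_threshold=alpha / matrix.shape[1],
        pca=pca,
        shared_variance=shared,
        category_anova=cat,
    )
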