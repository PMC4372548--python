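"""Negative-binomial differential-expression triage of candidate genes.

The stage mirrors a standard count-based RNA-seq workflow: genes with fewer
than 1 count per million in at least ``min_samples`` samples are dropped
(``min_samples`` defaults to the smallest group size), per-sample scaling
factors are computed by the trimmed-mean-of-M-values method, per-gene
negative-binomial dispersions are estimated by maximizing the Cox-Reid
adjusted profile likelihood (a common value pooled over genes, then tagwise
values shrunk toward it with a prior-degrees-of-freedom weight), and each
gene is tested for a group effect by a likelihood-ratio test of nested NB
log-linear models with Benjamini-Hochberg adjustment of the p-values.

GLM fitting is a batched iteratively reweighted least squares engine
vectorized across genes (log link, per-sample offsets, fixed per-gene
dispersion), which makes the thousands of refits the dispersion profile
needs practical on one CPU.

logFC convention: log2, aneurysm over control (positive = higher in
aneurysm tissue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from famvar.cohort import CountMatrix

_PHI_FLOOR = 1e-8


@dataclass
class DEConfig:
    cpm_threshold: float = 1.0
    min_samples: Optional[int] = None  # None -> size of smallest group
    prior_df: float = 10.0
    fdr_threshold: float = 0.05
    covariates: tuple[str, ...] = ("group", "age", "sex", "rupture")

    def __post_init__(self) -> None:
        if self.prior_df <= 0:
            raise ValueError("prior_df must be positive")
        if self.min_samples is not None and self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class DEResult:
    gene: str
    logfc: Optional[float]
    p_value: Optional[float]
    fdr: Optional[float]
    dispersion: float
    mean_expression: float
    converged: bool = True


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------


def cpm(counts: np.ndarray, library_sizes: np.ndarray) -> np.ndarray:
    return counts / library_sizes[None, :] * 1e6


def _smallest_group_size(meta: pd.DataFrame) -> int:
    return int(meta["group"].value_counts().min())


def filter_low_counts(matrix: CountMatrix, config: DEConfig | None = None) -> CountMatrix:
    """Drop genes below the CPM threshold in all but < min_samples samples."""
    config = config or DEConfig()
    counts = matrix.values()
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = [matrix.samples[i] for i in np.where(lib == 0)[0]]
        raise ValueError(f"samples with zero total counts: {bad}")
    n = config.min_samples or _smallest_group_size(matrix.sample_meta)
    keep = (cpm(counts, lib) >= config.cpm_threshold).sum(axis=1) >= n
    return matrix.subset_genes([g for g, k in zip(matrix.genes, keep) if k])


def tmm_factors(
    counts: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_index: Optional[int] = None,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    For each sample against a reference sample (the one whose upper-quartile
    CPM is closest to the mean, unless given), per-gene log ratios (M) and
    average log abundances (A) are computed over genes expressed in both;
    the most extreme ``trim_m`` of M and ``trim_a`` of A on each side are
    discarded and the remaining M values are averaged with inverse
    approximate-variance weights.  All-zero rows never contribute.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if ref_index is None:
        uq = np.array([
            np.quantile(c[c > 0] / l, 0.75) if (c > 0).any() else 0.0
            for c, l in zip(counts.T, lib)
        ])
        ref_index = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[:, ref_index]
    ref_lib = lib[ref_index]

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        obs, obs_lib = counts[:, j], lib[j]
        mask = (obs > 0) & (ref > 0)
        if not mask.any() or j == ref_index:
            continue
        p_obs, p_ref = obs[mask] / obs_lib, ref[mask] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic (delta-method) variance of M
        w = (
            (obs_lib - obs[mask]) / (obs_lib * obs[mask])
            + (ref_lib - ref[mask]) / (ref_lib * ref[mask])
        )
        m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if keep.any():
            log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    factors = 2.0 ** log_factors
    return factors / np.exp(np.mean(np.log(factors)))


def normalize(matrix: CountMatrix) -> np.ndarray:
    """Per-sample TMM scaling factors for a count matrix."""
    return tmm_factors(matrix.values())


# ---------------------------------------------------------------------------
# Batched NB GLM (log link, offset, fixed dispersion)
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood; phi -> 0 reduces to Poisson."""
    phi = np.maximum(np.asarray(phi, dtype=float), 0.0)[:, None]
    mu = np.maximum(mu, 1e-300)
    poisson = y * np.log(mu) - mu - gammaln(y + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.0 / np.where(phi > 0, phi, 1.0)
        nb = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    out = np.where(phi > 0, nb, poisson)
    return out.sum(axis=1)


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB log-linear models for G genes simultaneously.

    y: (G, S) counts; X: (S, p) design; offset: (S,) or (G, S) log offsets;
    phi: (G,) dispersions.  Returns (beta (G,p), mu (G,S), loglik (G,),
    converged (G,) bool).
    """
    y = np.asarray(y, dtype=float)
    G, S = y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,)).copy()
    offset = np.broadcast_to(offset, (G, S))

    eta = np.log(np.maximum(y, 0.5)) - offset
    beta = np.linalg.lstsq(X, eta.T, rcond=None)[0].T  # (G, p)
    delta = np.full(G, np.inf)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset, -60.0, 60.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi[:, None] * mu)  # (G, S)
        z = eta - offset + (y - mu) / np.maximum(mu, 1e-300)
        XtWX = np.einsum("sp,gs,sq->gpq", X, w, X, optimize=True)
        XtWz = np.einsum("sp,gs,gs->gp", X, w, z, optimize=True)
        # ridge guard for ill-conditioned weights
        XtWX += np.eye(p)[None, :, :] * 1e-10
        try:
            beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.stack(
                [np.linalg.lstsq(a, b, rcond=None)[0] for a, b in zip(XtWX, XtWz)]
            )
        beta_new = np.clip(beta_new, -50.0, 50.0)
        delta = np.abs(beta_new - beta).max(axis=1)
        beta = beta_new
        if (delta < tol).all():
            break
    eta = np.clip(beta @ X.T + offset, -60.0, 60.0)
    mu = np.exp(eta)
    ll = _nb_loglik(y, mu, phi)
    converged = (delta < 1e-4) & np.isfinite(ll)
    return beta, mu, ll, converged


def _cr_apl(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood of phi, per gene."""
    beta, mu, ll, _ = _irls_nb(y, X, offset, phi)
    w = mu / (1.0 + np.asarray(phi)[:, None] * mu)
    XtWX = np.einsum("sp,gs,sq->gpq", X, w, X, optimize=True)
    sign, logdet = np.linalg.slogdet(XtWX + np.eye(X.shape[1])[None] * 1e-12)
    return ll - 0.5 * logdet


def estimate_dispersion(
    counts: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray,
    prior_df: float = 10.0,
    grid: Optional[np.ndarray] = None,
    design_names: Optional[Sequence[str]] = None,
) -> tuple[float, np.ndarray]:
    """Common and tagwise NB dispersions by Cox-Reid profile likelihood.

    The common dispersion maximizes the pooled (summed over genes) adjusted
    profile likelihood on a log-spaced grid with parabolic refinement.
    Tagwise dispersions maximize the weighted objective
    ``APL_g(phi) + prior_n * mean_g APL(phi)`` where
    ``prior_n = prior_df / residual_df`` — empirical-Bayes shrinkage toward
    the common value whose strength grows with ``prior_df`` (tagwise
    converges to common as prior_df -> infinity).
    """
    y = np.asarray(counts, dtype=float)
    G, S = y.shape
    p = design.shape[1]
    if np.linalg.matrix_rank(design) < p:
        raise ValueError(_collinear_message(design, design_names))
    resid_df = max(S - p, 1)
    if grid is None:
        grid = 2.0 ** np.linspace(-20.0, 6.0, 40)
    apl = np.empty((G, len(grid)))
    for j, phi in enumerate(grid):
        apl[:, j] = _cr_apl(y, design, offset, np.full(G, phi))
    pooled = apl.mean(axis=0)

    def refine(values: np.ndarray, idx: int) -> float:
        # parabolic interpolation on log2(phi)
        if idx == 0 or idx == len(grid) - 1:
            return float(grid[idx])
        x = np.log2(grid[idx - 1 : idx + 2])
        v = values[idx - 1 : idx + 2]
        denom = (v[0] - 2 * v[1] + v[2])
        if denom >= 0:
            return float(grid[idx])
        shift = 0.5 * (v[0] - v[2]) / denom
        return float(2.0 ** (x[1] + np.clip(shift, -1, 1) * (x[2] - x[1])))

    common = refine(pooled, int(np.argmax(pooled)))

    # shared curve counts as prior_df / residual_df gene-equivalents, so the
    # effective extra degrees of freedom per gene equal prior_df
    prior_n = prior_df / resid_df
    weighted = apl + prior_n * pooled[None, :]
    idx = np.argmax(weighted, axis=1)
    tagwise = np.array([refine(weighted[g], int(idx[g])) for g in range(G)])
    tagwise = np.maximum(tagwise, _PHI_FLOOR)
    return max(common, _PHI_FLOOR), tagwise


def _collinear_message(X: np.ndarray, names: Optional[Sequence[str]] = None) -> str:
    names = list(names or [f"col{i}" for i in range(X.shape[1])])
    # identify a minimal set of dependent columns via QR pivoting
    r = np.linalg.matrix_rank(X)
    dependent = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
        else:
            dependent.append(names[j])
    return (
        f"design matrix is not full rank (rank {r} < {X.shape[1]}); "
        f"collinear columns: {dependent}"
    )


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def build_design(meta: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, group indicator (aneurysm = 1), then
    requested covariates.  Rupture is nested within group, so it is coded as
    a single indicator {ruptured = 1, otherwise 0}."""
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for cov in covariates:
        if cov == "group":
            cols.append((meta["group"] == "aneurysm").astype(float).values)
            names.append("group")
        elif cov == "age":
            age = meta["age"].astype(float)
            cols.append(((age - age.mean()) / max(age.std(ddof=0), 1e-12)).values)
            names.append("age")
        elif cov == "sex":
            cols.append((meta["sex"] == "female").astype(float).values)
            names.append("sex")
        elif cov == "rupture":
            cols.append((meta["rupture"] == "ruptured").astype(float).values)
            names.append("rupture")
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return np.column_stack(cols), names


def fit_nb_de(
    matrix: CountMatrix,
    config: DEConfig | None = None,
    dispersion: Optional[np.ndarray | float] = None,
    norm_factors: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-gene NB GLM likelihood-ratio test of the group effect.

    Returns a DataFrame indexed by gene with columns logfc (log2, aneurysm
    over control), p_value, fdr, dispersion, mean_expression, converged.
    Genes whose fit fails to converge are reported with absent p-values and
    excluded from the BH adjustment.
    """
    config = config or DEConfig()
    y = matrix.values().astype(float)
    G, S = y.shape
    meta = matrix.sample_meta
    lib = y.sum(axis=0)
    if norm_factors is None:
        norm_factors = tmm_factors(y)
    offset = np.log(lib * norm_factors)

    X_full, names = build_design(meta, config.covariates)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError(_collinear_message(X_full, names))
    group_col = names.index("group")
    X_red = np.delete(X_full, group_col, axis=1)

    if dispersion is None:
        _, phi = estimate_dispersion(y, X_full, offset, prior_df=config.prior_df)
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (G,)).copy()
        phi = np.maximum(phi, 0.0)

    phi_fit = np.maximum(phi, _PHI_FLOOR)
    beta_f, mu_f, ll_f, conv_f = _irls_nb(y, X_full, offset, phi_fit)
    _, _, ll_r, conv_r = _irls_nb(y, X_red, offset, phi_fit)
    lrt = np.maximum(2.0 * (ll_f - ll_r), 0.0)
    converged = conv_f & conv_r & np.isfinite(lrt)
    p = np.where(converged, chi2.sf(lrt, df=1), np.nan)

    fdr = np.full(G, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        fdr[ok] = bh_fdr(p[ok])

    logfc = beta_f[:, group_col] / np.log(2.0)
    return pd.DataFrame(
        {
            "logfc": np.where(converged, logfc, np.nan),
            "p_value": p,
            "fdr": fdr,
            "dispersion": phi,
            "mean_expression": y.mean(axis=1),
            "converged": converged,
        },
        index=pd.Index(matrix.genes, name="gene"),
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def integrate_expression(
    candidates,
    de_results: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> None:
    """Attach logFC/FDR to candidates by gene symbol; genes absent from the
    expression results are marked not-available.  Mutates in place."""
    for cand in candidates:
        gene = cand.gene
        if gene is None or gene not in de_results.index:
            cand.expression_available = False
            cand.logfc = None
            cand.fdr = None
            cand.differentially_expressed = False
            continue
        row = de_results.loc[gene]
        cand.expression_available = True
        cand.logfc = None if pd.isna(row["logfc"]) else float(row["logfc"])
        cand.fdr = None if pd.isna(row["fdr"]) else float(row["fdr"])
        cand.differentially_expressed = (
            cand.fdr is not None and cand.fdr < fdr_threshold
        )
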