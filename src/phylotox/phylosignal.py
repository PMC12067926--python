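"""Comparative-trait statistics on a phylogeny.

Implements the signal tests applied to per-chemical relative-growth traits:

* **Blomberg's K** — ratio of the observed partitioning of trait variance
  (ordinary vs phylogenetically corrected mean squared error) to its
  expectation under Brownian motion; K ≈ 1 under Brownian evolution, K → 0
  as signal vanishes. Significance by permuting trait values across tips.
* **Pagel's λ** — maximum-likelihood multiplier of the off-diagonal entries
  of the Brownian covariance; λ = 0 means star-like independence, λ = 1
  Brownian motion. Significance by likelihood-ratio test against λ = 0.
* **Mantel test with Kendall's τ** — permutation association test between a
  phenotypic distance matrix and the patristic distance matrix, using the
  rank correlation τ-b of the lower-triangle entries as the statistic.
* **Phylogenetic correlogram** — Moran's I autocorrelation of a trait within
  sliding patristic-distance classes, with tip-bootstrap confidence bands.
* **Benjamini–Hochberg** step-up FDR adjustment across chemicals.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .trees import patristic_distances, phylo_vcv

__all__ = [
    "SignalResult",
    "MantelResult",
    "Correlogram",
    "blomberg_k",
    "pagels_lambda",
    "mantel_kendall",
    "phylo_correlogram",
    "bh_adjust",
    "phenotype_distances",
    "signal_screen",
]


@dataclass
class SignalResult:
    statistic: str
    estimate: float
    p_raw: float
    n_tips: int
    detail: dict
    p_adj: float | None = None


@dataclass
class MantelResult:
    tau: float
    p: float
    n_permutations: int
    n: int


@dataclass
class Correlogram:
    """Per-distance-class Moran's I with bootstrap confidence bands.

    ``classes`` has columns midpoint, lower, upper, moran_i, ci_low, ci_high,
    n_pairs, significant; ``null_expectation`` is −1/(n−1).
    """

    classes: pd.DataFrame
    null_expectation: float


# ---------------------------------------------------------------------------
# helpers


def _align_trait(tree_or_vcv, trait: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Return (V, x) with the VCV restricted and ordered to the trait labels."""
    if isinstance(tree_or_vcv, pd.DataFrame):
        V = tree_or_vcv
    elif isinstance(tree_or_vcv, dendropy.Tree):
        V = phylo_vcv(tree_or_vcv)
    else:
        raise TypeError("expected a dendropy.Tree or a VCV DataFrame")
    trait = pd.Series(trait).dropna()
    missing = set(trait.index) - set(V.index)
    if missing:
        raise ValueError(f"trait labels not in tree: {sorted(missing)}")
    x = trait.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trait contains non-finite values")
    Vm = V.loc[trait.index, trait.index].to_numpy(dtype=float)
    return Vm, x


def _gls_mse(Vinv: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """(MSE0, MSE) about the GLS phylogenetic mean."""
    n = len(x)
    w = Vinv.sum(axis=1)
    ahat = float(w @ x / w.sum())
    e = x - ahat
    mse0 = float(e @ e) / (n - 1)
    mse = float(e @ Vinv @ e) / (n - 1)
    return mse0, mse


# ---------------------------------------------------------------------------
# Blomberg's K


def blomberg_k(
    tree_or_vcv,
    trait: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K with a tip-permutation significance test.

    K = (MSE0/MSE) / E_BM[MSE0/MSE], where MSE0 is the mean squared deviation
    of tip values from the GLS phylogenetic mean, MSE the V⁻¹-weighted
    version, and the Brownian expectation is
    (tr V − n / Σᵢⱼ V⁻¹ᵢⱼ) / (n − 1). The p-value is the rank of the observed
    MSE (small MSE = strong signal) in the distribution over random
    reassignments of trait values to tips.
    """
    V, x = _align_trait(tree_or_vcv, trait)
    n = len(x)
    if n < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    if np.ptp(x) == 0.0:
        raise ValueError("trait is constant; K is undefined")
    try:
        c, low = linalg.cho_factor(V)
    except linalg.LinAlgError as err:
        raise ValueError(
            f"singular phylogenetic covariance (condition number "
            f"{np.linalg.cond(V):.3g}); check for zero-length splits"
        ) from err
    Vinv = linalg.cho_solve((c, low), np.eye(n))

    mse0, mse = _gls_mse(Vinv, x)
    expected = (np.trace(V) - n / Vinv.sum()) / (n - 1)
    k = (mse0 / mse) / expected

    if n_perm == 0:
        return SignalResult(
            "K", float(k), np.nan, n,
            {"mse0": mse0, "mse": mse, "expected_ratio": float(expected), "n_perm": 0},
        )
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    w = Vinv.sum(axis=1)
    ahat = perms @ w / w.sum()
    e = perms - ahat[:, None]
    mse_perm = np.einsum("ij,jk,ik->i", e, Vinv, e) / (n - 1)
    p = (1.0 + np.sum(mse_perm <= mse)) / (n_perm + 1.0)
    return SignalResult(
        "K",
        float(k),
        float(p),
        n,
        {"mse0": mse0, "mse": mse, "expected_ratio": float(expected), "n_perm": n_perm},
    )


# ---------------------------------------------------------------------------
# Pagel's lambda


def _lambda_vcv(V: np.ndarray, lam: float) -> np.ndarray:
    Vl = lam * V
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def _bm_loglik(V: np.ndarray, x: np.ndarray) -> float:
    """Profile Brownian log-likelihood (mean and σ² maximised analytically)."""
    n = len(x)
    c, low = linalg.cho_factor(V)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv_x = linalg.cho_solve((c, low), x)
    Vinv_1 = linalg.cho_solve((c, low), np.ones(n))
    ahat = float(Vinv_x.sum() / Vinv_1.sum())
    e = x - ahat
    s2 = float(e @ linalg.cho_solve((c, low), e)) / n
    if s2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def _max_lambda(V: np.ndarray, cap: float = 1.2) -> float:
    """Largest λ ≤ cap keeping the λ-transformed covariance positive-definite."""

    def is_pd(lam: float) -> bool:
        try:
            linalg.cho_factor(_lambda_vcv(V, lam))
            return True
        except linalg.LinAlgError:
            return False

    if is_pd(cap):
        return cap
    lo, hi = 1.0, cap
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if is_pd(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _grid_loglik(V: np.ndarray, X: np.ndarray, lam: float) -> np.ndarray:
    """Profile Brownian log-likelihood of every trait column of X at one λ."""
    n = X.shape[0]
    c, low = linalg.cho_factor(_lambda_vcv(V, lam))
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    VinvX = linalg.cho_solve((c, low), X)
    sum_Vinv1 = linalg.cho_solve((c, low), np.ones(n)).sum()
    ahat = VinvX.sum(axis=0) / sum_Vinv1
    quad = np.einsum("ij,ij->j", X, VinvX) - ahat**2 * sum_Vinv1
    s2 = quad / n
    with np.errstate(divide="ignore"):
        return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def pagels_lambda(
    tree_or_vcv,
    trait: pd.Series,
    p_method: str = "permutation",
    n_perm: int = 999,
    seed: int | None = None,
    lambda_cap: float = 1.2,
    xtol: float = 1e-6,
    grid_size: int = 41,
) -> SignalResult:
    """Maximum-likelihood Pagel's λ with a likelihood-ratio test of λ = 0.

    λ scales the off-diagonal entries of the Brownian covariance; it is
    maximised by bounded scalar search on [0, λ_max] with λ_max the largest
    value (capped at ``lambda_cap``) keeping the transformed covariance
    positive-definite.

    The likelihood-ratio statistic's reference distribution is controlled by
    ``p_method``:

    * ``"permutation"`` (default) — the LRT is recomputed on a shared λ grid
      for ``n_perm`` random reassignments of trait values to tips. Under
      λ = 0 tip values are exchangeable, so this reference is exactly
      calibrated; the analytic references below are strongly conservative on
      ultrametric trees, where the null MLE sits on the λ = 0 boundary far
      more often than the asymptotic half of the time.
    * ``"boundary"`` — the ½χ²₀ + ½χ²₁ boundary mixture.
    * ``"chisq1"`` — plain χ²₁.
    """
    V, x = _align_trait(tree_or_vcv, trait)
    n = len(x)
    if n < 4:
        raise ValueError("Pagel's lambda needs at least 4 tips")
    if np.ptp(x) == 0.0:
        raise ValueError("trait is constant; lambda is undefined")
    if p_method not in ("permutation", "boundary", "chisq1"):
        raise ValueError("p_method must be 'permutation', 'boundary' or 'chisq1'")
    lam_max = _max_lambda(V, cap=lambda_cap)

    def nll(lam: float) -> float:
        try:
            return -_bm_loglik(_lambda_vcv(V, lam), x)
        except linalg.LinAlgError:
            return np.inf

    res = minimize_scalar(nll, bounds=(0.0, lam_max), method="bounded", options={"xatol": xtol})
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"lambda optimisation failed: {res}")
    # bounded search can miss boundary optima; compare endpoints explicitly
    cands = [(float(res.x), float(res.fun)), (0.0, nll(0.0)), (lam_max, nll(lam_max))]
    lam_hat, nll_hat = min(cands, key=lambda t: t[1])
    lrt = max(2.0 * (nll(0.0) - nll_hat), 0.0)
    detail = {
        "loglik": -nll_hat,
        "loglik_lambda0": -nll(0.0),
        "lrt": lrt,
        "lambda_max": lam_max,
        "p_method": p_method,
    }
    if p_method == "boundary":
        p = 0.5 * stats.chi2.sf(lrt, df=1) if lrt > 0 else 1.0
    elif p_method == "chisq1":
        p = stats.chi2.sf(lrt, df=1) if lrt > 0 else 1.0
    else:
        rng = np.random.default_rng(seed)
        grid = np.linspace(0.0, lam_max, grid_size)
        X = np.empty((n, n_perm + 1))
        X[:, 0] = x
        for j in range(1, n_perm + 1):
            X[:, j] = rng.permutation(x)
        logliks = np.full((grid_size, n_perm + 1), -np.inf)
        for g, lam in enumerate(grid):
            try:
                logliks[g] = _grid_loglik(V, X, lam)
            except linalg.LinAlgError:
                continue
        lrt_grid = 2.0 * (logliks.max(axis=0) - logliks[0])
        p = (1.0 + np.sum(lrt_grid[1:] >= lrt_grid[0])) / (n_perm + 1.0)
        detail["n_perm"] = n_perm
        detail["lrt_grid"] = float(lrt_grid[0])
    return SignalResult("lambda", lam_hat, float(p), n, detail)


# ---------------------------------------------------------------------------
# Mantel test (Kendall's tau)


def _check_square(D: pd.DataFrame, name: str) -> None:
    M = D.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1] or not D.index.equals(D.columns):
        raise ValueError(f"{name} must be square with matching labels")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(M), 0.0, atol=1e-8):
        raise ValueError(f"{name} has a nonzero diagonal")


def mantel_kendall(
    D_pheno: pd.DataFrame,
    D_phylo: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test with Kendall's τ-b as the statistic.

    τ is computed between the corresponding lower-triangle entries of the two
    matrices; the null distribution permutes the row/column labels of the
    second matrix jointly. One-sided (greater), testing for positive
    phylogeny–phenotype association.
    """
    _check_square(D_pheno, "D_pheno")
    _check_square(D_phylo, "D_phylo")
    if set(D_pheno.index) != set(D_phylo.index):
        raise ValueError("distance matrices have different label sets")
    n = len(D_pheno)
    if n < 3:
        raise ValueError("Mantel test needs at least 3 labels")
    A = D_pheno.to_numpy(dtype=float)
    B = D_phylo.loc[D_pheno.index, D_pheno.index].to_numpy(dtype=float)
    il = np.tril_indices(n, k=-1)
    tau_obs = stats.kendalltau(A[il], B[il]).statistic
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Bp = B[np.ix_(perm, perm)]
        if stats.kendalltau(A[il], Bp[il]).statistic >= tau_obs:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return MantelResult(float(tau_obs), float(p), n_perm, n)


def phenotype_distances(response: pd.DataFrame, log10: bool = False) -> pd.DataFrame:
    """Pairwise Euclidean distance between cultures' chemical-response profiles.

    ``response`` is the cultures × chemicals dAUC matrix; ``log10=True``
    computes distances on log10(dAUC) instead of the raw ratios.
    """
    X = response.to_numpy(dtype=float)
    if log10:
        if (X <= 0).any():
            raise ValueError("log10 scale requires strictly positive dAUC values")
        X = np.log10(X)
    if np.isnan(X).any():
        raise ValueError("response matrix contains missing values")
    D = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=response.index, columns=response.index)


# ---------------------------------------------------------------------------
# phylogenetic correlogram


def _moran_i(z: np.ndarray, W: np.ndarray) -> float:
    n = len(z)
    denom = float(z @ z)
    s0 = W.sum()
    if s0 == 0 or denom == 0:
        return np.nan
    return float(n / s0 * (z @ W @ z) / denom)


def phylo_correlogram(
    tree: dendropy.Tree,
    trait,
    n_classes: int = 20,
    n_boot: int = 199,
    seed: int | None = None,
    min_pairs: int = 3,
) -> Correlogram:
    """Moran's I trait autocorrelation across sliding patristic-distance classes.

    Distance classes are ``n_classes`` equal-width windows spanning the
    observed patristic range, each overlapping its neighbour by half a
    window. For a multivariate trait matrix (tips × chemicals) the first
    principal coordinate of the Euclidean phenotype distance matrix is used
    as the scalar trait. 95% confidence bands per class come from
    bootstrapping tips; classes with fewer than ``min_pairs`` tip pairs are
    flagged and their bands suppressed.
    """
    D = patristic_distances(tree)
    if isinstance(trait, pd.DataFrame):
        from .community_structure import pcoa  # avoids import cycle at module load

        ord_ = pcoa(phenotype_distances(trait))
        trait = ord_.coordinates.iloc[:, 0]
    trait = pd.Series(trait).dropna()
    n = len(trait)
    if n < 8:
        raise ValueError("correlogram needs at least 8 tips")
    if np.ptp(trait.to_numpy(dtype=float)) == 0.0:
        raise ValueError("trait is constant; Moran's I is undefined")
    Dm = D.loc[trait.index, trait.index].to_numpy(dtype=float)
    x = trait.to_numpy(dtype=float)

    off = Dm[np.triu_indices(n, k=1)]
    dmin, dmax = off.min(), off.max()
    width = 2.0 * (dmax - dmin) / (n_classes + 1)
    starts = dmin + 0.5 * width * np.arange(n_classes)
    null_expect = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n, size=(n_boot, n))

    rows = []
    for start in starts:
        stop = start + width
        W = ((Dm >= start) & (Dm <= stop)).astype(float)
        np.fill_diagonal(W, 0.0)
        n_pairs = int(W.sum() // 2)
        z = x - x.mean()
        i_obs = _moran_i(z, W)
        if n_pairs < min_pairs or not np.isfinite(i_obs):
            rows.append((start + width / 2, start, stop, i_obs, np.nan, np.nan, n_pairs, False))
            continue
        boots = []
        for idx in boot_idx:
            xb = x[idx]
            zb = xb - xb.mean()
            Wb = W[np.ix_(idx, idx)].copy()
            np.fill_diagonal(Wb, 0.0)
            ib = _moran_i(zb, Wb)
            if np.isfinite(ib):
                boots.append(ib)
        if len(boots) < max(20, n_boot // 4):
            rows.append((start + width / 2, start, stop, i_obs, np.nan, np.nan, n_pairs, False))
            continue
        lo, hi = np.percentile(boots, [2.5, 97.5])
        sig = not (lo <= null_expect <= hi)
        rows.append((start + width / 2, start, stop, i_obs, lo, hi, n_pairs, sig))
    classes = pd.DataFrame(
        rows,
        columns=["midpoint", "lower", "upper", "moran_i", "ci_low", "ci_high", "n_pairs", "significant"],
    )
    return Correlogram(classes=classes, null_expectation=null_expect)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signal_screen(
    tree: dendropy.Tree,
    response: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    lambda_p_method: str = "permutation",
) -> pd.DataFrame:
    """Per-chemical Blomberg's K and Pagel's λ with BH-adjusted p-values.

    ``response`` is the cultures × chemicals dAUC matrix (rows must be tree
    tips). Returns a tidy DataFrame indexed by chemical with columns
    K, p_K, p_K_adj, lambda, p_lambda, p_lambda_adj.
    """
    V = phylo_vcv(tree)
    rows = {}
    rng = np.random.default_rng(seed)
    for chem in response.columns:
        trait = response[chem].dropna()
        k = blomberg_k(V, trait, n_perm=n_perm, seed=int(rng.integers(2**31)))
        lam = pagels_lambda(
            V, trait, p_method=lambda_p_method, n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        rows[chem] = {
            "K": k.estimate,
            "p_K": k.p_raw,
            "lambda": lam.estimate,
            "p_lambda": lam.p_raw,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "chemical_id"
    tiny = np.finfo(float).tiny  # chi-square survival can underflow to 0
    out["p_K_adj"] = bh_adjust(out["p_K"].clip(lower=tiny))
    out["p_lambda_adj"] = bh_adjust(out["p_lambda"].clip(lower=tiny))
    return out[["K", "p_K", "p_K_adj", "lambda", "p_lambda", "p_lambda_adj"]]
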