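"""Heritability: broad-sense from RIAIL vs parental variance, and REML
variance components with additive and pairwise-interaction (Hadamard) kernels.

Broad-sense heritability is H^2 = (sigma_R^2 - sigma_P^2) / sigma_R^2, where
sigma_R^2 is the phenotypic variance among the recombinant strains (genetic +
environmental) and sigma_P^2 the variance among parental-strain values
(environmental only, under the isogenic-parents assumption).

Narrow-sense and interaction components come from the linear mixed model

    y = mu + a + i + e,   cov(a) = sA^2 * A,  cov(i) = sI^2 * (A o A),
                          cov(e) = sE^2 * I,

where A is the additive relatedness matrix (correlation of marker genotypes
between strains) and A o A its Hadamard product with itself — the standard
kernel for pairwise (additive x additive) epistasis.  Variances are estimated
by restricted maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from riailmap.sim import GenotypeMatrix

_JITTER = 1e-6


@dataclass
class HeritabilityResult:
    trait: str
    model: str  # "one-component" | "two-component"
    h2_additive: float
    interaction_fraction: float
    residual_fraction: float
    loglik: float
    variances: dict[str, float]  # raw (unclamped) REML variance estimates
    converged: bool


def broad_sense_h2(
    riail_values: np.ndarray | pd.Series,
    parental_values: np.ndarray | pd.Series,
) -> dict[str, float]:
    """Broad-sense heritability from panel vs parental phenotypic variance.

    Returns H2 (clamped to [0, 1]), the raw unclamped value, and the two
    variances.  By default the parental variance pools all parental replicate
    values of both strains (so it includes the between-parent genetic
    difference; see the package docs for the within-strain-pooled variant).
    """
    r = np.asarray(riail_values, dtype=float)
    p = np.asarray(parental_values, dtype=float)
    r, p = r[~np.isnan(r)], p[~np.isnan(p)]
    if len(r) < 2 or len(p) < 2:
        raise ValueError("need >= 2 values in each group")
    s_r = float(np.var(r, ddof=1))
    s_p = float(np.var(p, ddof=1))
    if s_r == 0:
        raise ValueError("zero variance among recombinant strains")
    raw = (s_r - s_p) / s_r
    return {
        "H2": float(np.clip(raw, 0.0, 1.0)),
        "H2_raw": raw,
        "sigma_R2": s_r,
        "sigma_P2": s_p,
    }


def broad_sense_h2_pooled_within(
    riail_values: np.ndarray,
    parent_a_values: np.ndarray,
    parent_b_values: np.ndarray,
) -> dict[str, float]:
    """Variant using the pooled *within-parent* variance as sigma_P^2.

    This excludes the genetic difference between the two parents from the
    noise estimate (each parent centred before pooling).
    """
    a = np.asarray(parent_a_values, dtype=float)
    b = np.asarray(parent_b_values, dtype=float)
    pooled = np.concatenate([a - np.nanmean(a), b - np.nanmean(b)])
    res = broad_sense_h2(riail_values, pooled)
    res["sigma_P2_kind"] = "within-parent pooled"
    return res


def additive_kernel(geno: GenotypeMatrix) -> pd.DataFrame:
    """Additive relatedness: Pearson correlation of marker genotypes per strain pair."""
    if geno.n_markers < 2:
        raise ValueError("need >= 2 markers")
    calls = geno.calls
    if np.isnan(calls).any():
        calls = np.where(np.isnan(calls), np.nanmean(calls, axis=0)[None, :], calls)
    sds = calls.std(axis=1)
    if (sds == 0).any():
        warnings.warn("strain(s) with zero genotype variance (pure parental); "
                      "correlations against them are degenerate")
    A = np.corrcoef(calls)
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=geno.strain_ids, columns=geno.strain_ids)


def interaction_kernel(A: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-interaction relatedness: the Hadamard product A o A.

    PSD whenever A is (Schur product theorem)."""
    return A * A


def _reml_nll(log_s2: np.ndarray, y: np.ndarray, kernels: list[np.ndarray]) -> float:
    n = y.size
    s2 = np.exp(log_s2)
    V = s2[-1] * np.eye(n)
    for s, K in zip(s2[:-1], kernels):
        V += s * K
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e10
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    Vi_y = np.linalg.solve(V, y)
    Vi_1 = np.linalg.solve(V, np.ones(n))
    xvx = Vi_1.sum()  # 1' V^-1 1
    beta = Vi_y.sum() / xvx
    r = y - beta
    quad = float(r @ np.linalg.solve(V, r))
    return 0.5 * (logdetV + np.log(xvx) + quad)


def fit_variance_components(
    y: np.ndarray | pd.Series,
    A: pd.DataFrame | np.ndarray,
    with_interaction: bool = False,
    trait: str = "",
) -> HeritabilityResult:
    """REML fit of the additive (and optionally interaction) mixed model.

    Returns variance *fractions* (additive, interaction, residual) that sum
    to 1, plus the restricted log-likelihood.  The kernel is jittered on the
    diagonal if its smallest eigenvalue is negative.  Optimization runs
    quasi-Newton on log-variances from several starting points; negative
    components cannot occur in this parametrization (estimates at the zero
    boundary appear as vanishingly small variances).
    """
    yv = np.asarray(y, dtype=float)
    Amat = np.asarray(A, dtype=float)
    ok = ~np.isnan(yv)
    yv = yv[ok]
    Amat = Amat[np.ix_(ok, ok)]
    if np.var(yv) == 0:
        raise ValueError("zero-variance trait")
    if np.linalg.eigvalsh(Amat).min() < -1e-10:
        warnings.warn("additive kernel not PSD; adding diagonal jitter")
        Amat = Amat + _JITTER * np.eye(len(yv))
    yv = (yv - yv.mean()) / yv.std(ddof=1)
    kernels = [Amat]
    names = ["additive"]
    if with_interaction:
        kernels.append(Amat * Amat)
        names.append("interaction")

    k = len(kernels) + 1
    best = None
    starts = [np.zeros(k)]
    for frac in (0.6, 0.2):
        s = np.full(k, np.log((1 - frac) / max(k - 1, 1)))
        s[:-1] = np.log(frac / (k - 1))
        starts.append(s)
    if with_interaction:
        # warm start at the one-component optimum with a vanishing interaction
        # variance, so the nested model's likelihood is never lost
        sub = None
        for x0 in (np.zeros(2), np.log([0.6, 0.4]), np.log([0.2, 0.8])):
            r = minimize(_reml_nll, x0, args=(yv, kernels[:1]), method="L-BFGS-B",
                         bounds=[(-30.0, 5.0)] * 2)
            if sub is None or r.fun < sub.fun:
                sub = r
        starts.append(np.array([sub.x[0], -30.0, sub.x[1]]))
    for x0 in starts:
        res = minimize(
            _reml_nll, x0, args=(yv, kernels), method="L-BFGS-B",
            bounds=[(-30.0, 5.0)] * k,
        )
        if best is None or res.fun < best.fun:
            best = res
    s2 = np.exp(best.x)
    total = s2.sum()
    fracs = s2 / total
    variances = {nm: float(v) for nm, v in zip(names + ["residual"], s2)}
    return HeritabilityResult(
        trait=trait,
        model="two-component" if with_interaction else "one-component",
        h2_additive=float(fracs[0]),
        interaction_fraction=float(fracs[1]) if with_interaction else 0.0,
        residual_fraction=float(fracs[-1]),
        loglik=float(-best.fun),
        variances=variances,
        converged=bool(best.success),
    )
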