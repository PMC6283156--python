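"""Single-marker LOD linkage mapping with permutation thresholds, forward
cofactor search, LOD-drop confidence intervals, and two-dimensional
interaction scans.

The marker-trait association statistic is the marker-regression LOD

    LOD_m = -n * ln(1 - r_m^2) / (2 ln 10),

with ``r_m`` the Pearson correlation between strain genotypes at marker ``m``
and the trait, and ``n`` the complete-case strain count at that marker.  This
is algebraically the log10 likelihood-ratio of the single-marker linear model
against the intercept-only null, (n/2) * log10(SST/SSE).

Genome-wide significance is controlled by permuting strain labels: one strain
permutation per replicate is applied jointly to all trait columns, preserving
the correlation structure among phenotypes, and the threshold is the
(1 - alpha) quantile of the per-replicate maximum LOD across markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from riailmap.sim import GenotypeMatrix

_LN10 = np.log(10.0)
_R2_CAP = 1.0 - 1e-12


def scale_phenotype(y: np.ndarray) -> np.ndarray:
    """Scale to mean 0, variance 1 (NaNs preserved)."""
    mu = np.nanmean(y)
    sd = np.nanstd(y, ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError("zero-variance phenotype")
    return (y - mu) / sd


def lod_from_r2(r2: np.ndarray, n: np.ndarray | int) -> np.ndarray:
    """LOD from squared correlation; r^2 is capped just below 1."""
    r2 = np.minimum(np.asarray(r2, dtype=float), _R2_CAP)
    return -np.asarray(n, dtype=float) * np.log(1.0 - r2) / (2.0 * _LN10)


@dataclass
class ScanResult:
    """One trait's LOD curve over all markers."""

    trait: str
    markers: pd.DataFrame
    lod: np.ndarray
    n: np.ndarray
    threshold: float | None = None
    cofactors: list[int] = field(default_factory=list)

    def peak_index(self) -> int:
        return int(np.argmax(self.lod))  # leftmost on ties


@dataclass
class QTLRecord:
    """A mapped locus: peak, 1.5-LOD-drop confidence interval, effect size."""

    trait: str
    chrom: str
    peak_marker: str
    peak_index: int
    peak_pos_cM: float
    peak_lod: float
    ci_left_index: int
    ci_right_index: int
    ci_left_marker: str
    ci_right_marker: str
    ci_left_cM: float
    ci_right_cM: float
    threshold: float
    variance_explained: float | None = None


def _complete_case_lods(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker r^2 and complete-case n, handling missing data exactly."""
    M = G.shape[1]
    r2 = np.zeros(M)
    n = np.zeros(M, dtype=int)
    y_ok = ~np.isnan(y)
    if not np.isnan(G).any():
        g = G[y_ok]
        yy = y[y_ok]
        n[:] = y_ok.sum()
        gc = g - g.mean(axis=0)
        yc = yy - yy.mean()
        gss = (gc**2).sum(axis=0)
        denom = gss * (yc**2).sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(denom > 0, (gc.T @ yc) ** 2 / denom, 0.0)
        return r2, n
    for m in range(M):
        ok = y_ok & ~np.isnan(G[:, m])
        n[m] = ok.sum()
        if n[m] < 3:
            continue
        g = G[ok, m]
        yy = y[ok]
        if np.var(g) == 0 or np.var(yy) == 0:
            continue
        r = np.corrcoef(g, yy)[0, 1]
        r2[m] = r * r
    return r2, n


def lod_scan(
    y: pd.Series | np.ndarray,
    geno: GenotypeMatrix,
    trait: str = "",
    prescaled: bool = False,
) -> ScanResult:
    """LOD score at every marker for one trait.

    The phenotype is scaled to mean 0, variance 1 first (scaling does not
    change any LOD — the statistic depends only on correlations — but matches
    the processing contract).  Monomorphic markers get LOD 0.
    """
    yv = np.asarray(y, dtype=float)
    if (~np.isnan(yv)).sum() < 3:
        raise ValueError("need >= 3 strains with phenotype")
    if not prescaled:
        yv = scale_phenotype(yv)
    r2, n = _complete_case_lods(yv, geno.calls)
    return ScanResult(trait=trait, markers=geno.markers, lod=lod_from_r2(r2, n), n=n)


def _filled_genotypes(geno: GenotypeMatrix) -> np.ndarray:
    """Genotypes with missing calls mean-imputed (for vectorized permutation work)."""
    G = geno.calls
    if not np.isnan(G).any():
        return G
    col_mean = np.nanmean(G, axis=0)
    return np.where(np.isnan(G), col_mean[None, :], G)


def _lod_matrix(Y: np.ndarray, Gz: np.ndarray, n: int) -> np.ndarray:
    """LODs (markers x traits) for complete data given pre-z-scored genotypes."""
    Yz = (Y - Y.mean(axis=0)) / Y.std(axis=0)
    r = (Gz.T @ Yz) / n
    return lod_from_r2(r**2, n)


def permutation_threshold(
    pheno: pd.DataFrame | pd.Series | np.ndarray,
    geno: GenotypeMatrix,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    joint: bool = True,
) -> pd.Series | float:
    """Permutation genome-wide LOD threshold at error rate ``alpha``.

    Strain indices are permuted once per replicate and applied jointly to all
    trait columns (``joint=True``), maintaining the correlation structure
    among phenotypes; the per-trait threshold is the (1 - alpha) quantile of
    the replicate maxima of the LOD curve.  ``joint=False`` permutes each
    trait independently (sensitivity check only).

    A Series input returns a float.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    single = isinstance(pheno, (pd.Series, np.ndarray)) and np.ndim(pheno) == 1
    Y = pd.DataFrame(pheno).to_numpy(dtype=float)
    if Y.shape[0] != geno.n_strains:
        raise ValueError("phenotype rows must match strains")
    if Y.shape[0] < 3:
        raise ValueError("need >= 3 strains")
    ok = ~np.isnan(Y).any(axis=1)
    Y = Y[ok]
    G = _filled_genotypes(geno)[ok]
    n = Y.shape[0]
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0  # monomorphic markers contribute LOD 0
    Gz = (G - G.mean(axis=0)) / sd
    Gz[:, G.std(axis=0) == 0] = 0.0

    T = Y.shape[1]
    maxima = np.empty((n_perm, T))
    for p in range(n_perm):
        if joint:
            Yp = Y[rng.permutation(n)]
        else:
            Yp = np.column_stack([Y[rng.permutation(n), t] for t in range(T)])
        maxima[p] = _lod_matrix(Yp, Gz, n).max(axis=0)
    thr = np.quantile(maxima, 1.0 - alpha, axis=0)
    if single:
        return float(thr[0])
    cols = pheno.columns if isinstance(pheno, pd.DataFrame) else range(T)
    return pd.Series(thr, index=cols)


def lod_drop_interval(
    scan: ScanResult, peak_index: int, drop: float = 1.5
) -> tuple[int, int]:
    """Confidence interval: contiguous markers within ``drop`` LOD of the peak.

    Extends left and right from the peak over markers with
    LOD >= peak - drop, stopping at the first marker below that level, and
    never leaving the peak's chromosome.  Returns (left, right) marker
    indices, inclusive.
    """
    chrom = scan.markers.iloc[peak_index]["chrom"]
    on_chrom = np.flatnonzero((scan.markers["chrom"] == chrom).to_numpy())
    lo, hi = on_chrom[0], on_chrom[-1]
    if scan.lod[peak_index] < scan.lod[lo : hi + 1].max() - 1e-12:
        raise ValueError("peak_index is not the maximum on its chromosome")
    cutoff = scan.lod[peak_index] - drop
    left = peak_index
    while left > lo and scan.lod[left - 1] >= cutoff:
        left -= 1
    right = peak_index
    while right < hi and scan.lod[right + 1] >= cutoff:
        right += 1
    return left, right


def _make_record(
    trait: str, scan: ScanResult, peak: int, threshold: float, drop: float
) -> QTLRecord:
    left, right = lod_drop_interval(scan, peak, drop)
    mk = scan.markers
    return QTLRecord(
        trait=trait,
        chrom=str(mk.iloc[peak]["chrom"]),
        peak_marker=str(mk.iloc[peak]["marker"]),
        peak_index=peak,
        peak_pos_cM=float(mk.iloc[peak]["pos_cM"]),
        peak_lod=float(scan.lod[peak]),
        ci_left_index=left,
        ci_right_index=right,
        ci_left_marker=str(mk.iloc[left]["marker"]),
        ci_right_marker=str(mk.iloc[right]["marker"]),
        ci_left_cM=float(mk.iloc[left]["pos_cM"]),
        ci_right_cM=float(mk.iloc[right]["pos_cM"]),
        threshold=float(threshold),
    )


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [1, X] (missing X entries mean-imputed)."""
    Xf = np.column_stack([np.ones(len(y)), np.nan_to_num(X, nan=0.0)])
    beta, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    return y - Xf @ beta


def forward_search(
    y: pd.Series | np.ndarray,
    geno: GenotypeMatrix,
    n_perm: int = 1000,
    alpha: float = 0.05,
    max_qtl: int = 10,
    seed: int = 0,
    drop: float = 1.5,
    refresh_threshold: bool = True,
    trait: str = "",
) -> list[QTLRecord]:
    """Iterative forward cofactor search for QTL.

    Each round scans the phenotype residualized on the accepted cofactor
    markers, compares the maximum LOD against a permutation threshold
    recomputed on those residuals (``refresh_threshold=False`` reuses the
    first threshold), and accepts the peak marker (leftmost on ties) as a new
    cofactor.  Stops when no marker is significant or ``max_qtl`` is reached.
    Variance explained is annotated against the original phenotype afterwards
    via :func:`annotate_variance_explained`.
    """
    yv = scale_phenotype(np.asarray(y, dtype=float))
    ss = np.random.SeedSequence(seed)
    records: list[QTLRecord] = []
    cofactors: list[int] = []
    resid = yv.copy()
    threshold = None
    for it in range(max_qtl):
        child = np.random.default_rng(ss.spawn(1)[0])
        if refresh_threshold or threshold is None:
            threshold = permutation_threshold(
                pd.Series(resid), geno, n_perm=n_perm, alpha=alpha, seed=child
            )
        scan = lod_scan(resid, geno, trait=trait)
        scan.threshold = threshold
        scan.cofactors = list(cofactors)
        peak = scan.peak_index()
        if scan.lod[peak] <= threshold:
            break
        if peak in cofactors:
            warnings.warn(f"peak marker {peak} already a cofactor; stopping")
            break
        records.append(_make_record(trait, scan, peak, threshold, drop))
        cofactors.append(peak)
        resid = _residualize(yv, geno.calls[:, cofactors])
        sd = resid.std(ddof=1)
        if sd == 0:
            break
        resid = resid / sd
    annotate_variance_explained(records, np.asarray(y, dtype=float), geno)
    return records


def annotate_variance_explained(
    qtls: list[QTLRecord],
    y: np.ndarray | pd.Series,
    geno: GenotypeMatrix,
) -> float:
    """Set each QTL's variance_explained to the squared marker-trait correlation.

    Uses the original (unscaled) trait values and the peak-marker genotypes,
    complete cases only.  Returns the per-trait sum.
    """
    yv = np.asarray(y, dtype=float)
    total = 0.0
    for q in qtls:
        g = geno.calls[:, q.peak_index]
        ok = ~np.isnan(g) & ~np.isnan(yv)
        if ok.sum() < 3 or np.var(g[ok]) == 0:
            q.variance_explained = 0.0
            continue
        r = np.corrcoef(g[ok], yv[ok])[0, 1]
        q.variance_explained = float(r * r)
        total += q.variance_explained
    return total


def qtl_table(qtls: list[QTLRecord]) -> pd.DataFrame:
    """QTL records as a tidy table."""
    cols = [
        "trait", "chrom", "peak_marker", "peak_pos_cM", "peak_lod",
        "ci_left_marker", "ci_right_marker", "ci_left_cM", "ci_right_cM",
        "variance_explained", "threshold",
    ]
    return pd.DataFrame([{c: getattr(q, c) for c in cols} for q in qtls])


# ---------------------------------------------------------------------------
# two-dimensional scan


@dataclass
class PairScanResult:
    """Marker-pair interaction scan over a thinned grid."""

    trait: str
    grid_indices: np.ndarray  # indices into the full marker table
    pairs: np.ndarray  # n_pairs x 2, indices into grid_indices
    lod_full: np.ndarray
    lod_additive: np.ndarray
    lod_interaction: np.ndarray
    threshold: float
    markers: pd.DataFrame

    def peak_pair(self) -> tuple[int, int]:
        """Grid indices of the pair with the top interaction LOD."""
        k = int(np.argmax(self.lod_interaction))
        i, j = self.pairs[k]
        return int(self.grid_indices[i]), int(self.grid_indices[j])


def thin_markers(markers: pd.DataFrame, step_cM: float) -> np.ndarray:
    """Greedy thinning to >= step_cM spacing per chromosome (first marker kept)."""
    if step_cM <= 0:
        raise ValueError("grid step must be positive")
    keep = []
    for _, grp in markers.groupby("chrom", sort=False):
        last = -np.inf
        for idx, pos in zip(grp.index, grp["pos_cM"]):
            if pos - last >= step_cM - 1e-9:
                keep.append(idx)
                last = pos
    return np.asarray(keep, dtype=int)


def _pair_rss(V: np.ndarray, Ginv: np.ndarray, yty: float) -> np.ndarray:
    """Residual SS per pair per phenotype column from cross-products V."""
    expl = np.einsum("pab,pax,pbx->px", Ginv, V, V)
    return np.maximum(yty - expl, 1e-12)


def pair_scan(
    y: pd.Series | np.ndarray,
    geno: GenotypeMatrix,
    grid_step_cM: float = 5.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    trait: str = "",
    perm_block: int = 32,
) -> PairScanResult:
    """Two-dimensional genome scan for marker-pair interactions.

    For every pair (i, j) on the thinned grid the full model {g_i, g_j,
    g_i*g_j} and the additive model {g_i, g_j} are each compared with the
    intercept-only null; LOD_interaction is their difference, i.e. the LOD of
    the product term given both marginal terms.  Genome-wide significance of
    the interaction uses the (1 - alpha) quantile of the permutation maxima
    of LOD_interaction (strain-label permutations of the phenotype).
    """
    yv = scale_phenotype(np.asarray(y, dtype=float))
    ok = ~np.isnan(yv)
    yv = yv[ok]
    n = yv.size
    grid = thin_markers(geno.markers, grid_step_cM)
    G = _filled_genotypes(geno)[np.ix_(ok, grid)]
    m = G.shape[1]
    ii, jj = np.triu_indices(m, k=1)
    pairs = np.column_stack([ii, jj])
    P = G[:, ii] * G[:, jj]  # product columns, n x n_pairs

    ones = np.ones(n)
    # per-pair Gram inverses for the additive (3x3) and full (4x4) models
    def gram_inverses() -> tuple[np.ndarray, np.ndarray]:
        s_g = G.sum(axis=0)
        GtG = G.T @ G
        GtP = G.T @ P  # m x n_pairs (col k: g_a . (g_i g_j))
        s_p = P.sum(axis=0)
        PtP = (P**2).sum(axis=0)
        npairs = len(ii)
        A = np.empty((npairs, 4, 4))
        A[:, 0, 0] = n
        A[:, 0, 1] = A[:, 1, 0] = s_g[ii]
        A[:, 0, 2] = A[:, 2, 0] = s_g[jj]
        A[:, 0, 3] = A[:, 3, 0] = s_p
        A[:, 1, 1] = GtG[ii, ii]
        A[:, 1, 2] = A[:, 2, 1] = GtG[ii, jj]
        A[:, 2, 2] = GtG[jj, jj]
        A[:, 1, 3] = A[:, 3, 1] = GtP[ii, np.arange(npairs)]
        A[:, 2, 3] = A[:, 3, 2] = GtP[jj, np.arange(npairs)]
        A[:, 3, 3] = PtP
        Ginv_add = np.linalg.pinv(A[:, :3, :3])
        Ginv_full = np.linalg.pinv(A)
        return Ginv_add, Ginv_full

    Ginv_add, Ginv_full = gram_inverses()
    yty = float(yv @ yv)

    def lods_for(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lod_add, lod_full), each n_pairs x n_cols."""
        s = ones @ Y
        U = G.T @ Y
        W = P.T @ Y
        rss0 = yty - s**2 / n
        V4 = np.stack([np.broadcast_to(s, U[ii].shape), U[ii], U[jj], W], axis=1)
        rss_add = _pair_rss(V4[:, :3], Ginv_add, yty)
        rss_full = _pair_rss(V4, Ginv_full, yty)
        lod_add = (n / 2.0) * np.log10(np.maximum(rss0 / rss_add, 1.0))
        lod_full = (n / 2.0) * np.log10(np.maximum(rss0 / rss_full, 1.0))
        return lod_add, np.maximum(lod_full, lod_add)

    lod_add, lod_full = (a[:, 0] for a in lods_for(yv[:, None]))
    lod_int = lod_full - lod_add

    rng = np.random.default_rng(seed)
    perm_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(perm_block, n_perm - done)
        Yp = np.column_stack([yv[rng.permutation(n)] for _ in range(b)])
        la, lf = lods_for(Yp)
        perm_max[done : done + b] = (lf - la).max(axis=0)
        done += b
    threshold = float(np.quantile(perm_max, 1.0 - alpha))

    return PairScanResult(
        trait=trait,
        grid_indices=grid,
        pairs=pairs,
        lod_full=lod_full,
        lod_additive=lod_add,
        lod_interaction=lod_int,
        threshold=threshold,
        markers=geno.markers,
    )
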