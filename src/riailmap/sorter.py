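"""Sorter-trait processing: well summaries, batch regression, outliers, control regression.

Raw large-particle-sorter records carry one row per measured animal with its
time of flight (TOF, a length proxy) and extinction (EXT, an optical-density
proxy).  Each well is reduced to a fixed roster of 24 summary traits; trait
values are then cleaned of assay (batch) effects by linear regression,
filtered for outlier strains, and regressed against the control condition so
that the residuals carry only the toxin-specific response.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

_MEASURES = ("TOF", "EXT", "norm.EXT")
_STATS = ("mean", "median", "q10", "q25", "q75", "q90")

#: the 24-trait roster: 6 summary stats x 3 measures, variance and CV of the
#: two raw measures, brood size and normalized brood size
TRAIT_ROSTER = tuple(
    [f"{s}.{m}" for m in _MEASURES for s in _STATS]
    + ["var.TOF", "var.EXT", "cv.TOF", "cv.EXT", "n", "norm.n"]
)


def _summary_block(x: np.ndarray, prefix: str) -> dict[str, float]:
    # quantiles use linear interpolation (R type-7), numpy's default
    return {
        f"mean.{prefix}": float(np.mean(x)),
        f"median.{prefix}": float(np.median(x)),
        f"q10.{prefix}": float(np.quantile(x, 0.10)),
        f"q25.{prefix}": float(np.quantile(x, 0.25)),
        f"q75.{prefix}": float(np.quantile(x, 0.75)),
        f"q90.{prefix}": float(np.quantile(x, 0.90)),
    }


def summarize_well(objects: pd.DataFrame, sorted_count: int) -> dict[str, float]:
    """Reduce the animals of one well to the 24-trait summary.

    ``objects`` needs columns TOF and EXT.  Animals with non-positive TOF are
    invalid sorter events and are dropped.  An empty well yields n = 0,
    norm.n = 0 and NaN for every distribution trait.  Variance is 0 by
    convention for a single animal (ddof=1 undefined), hence CV is 0 too.
    """
    if sorted_count < 1:
        raise ValueError("sorted_count must be >= 1")
    valid = objects[(objects["TOF"] > 0)]
    n = len(valid)
    out: dict[str, float] = {t: np.nan for t in TRAIT_ROSTER}
    out["n"] = float(n)
    out["norm.n"] = n / sorted_count
    if n == 0:
        return out
    tof = valid["TOF"].to_numpy(dtype=float)
    ext = valid["EXT"].to_numpy(dtype=float)
    norm_ext = ext / tof
    for x, name in ((tof, "TOF"), (ext, "EXT"), (norm_ext, "norm.EXT")):
        out.update(_summary_block(x, name))
    for x, name in ((tof, "TOF"), (ext, "EXT")):
        v = float(np.var(x, ddof=1)) if n > 1 else 0.0
        out[f"var.{name}"] = v
        m = float(np.mean(x))
        out[f"cv.{name}"] = float(np.sqrt(v) / m) if (n > 1 and m != 0) else 0.0
    return out


def summarize_plates(raw: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`summarize_well` per (assay, condition, plate, row, col, strain).

    Returns one row per well with identifying columns plus the 24 traits.
    """
    keys = [k for k in ("assay", "condition", "plate", "row", "col", "strain") if k in raw.columns]
    rows = []
    for key_vals, grp in raw.groupby(keys, sort=False):
        sc = int(grp["sorted_count"].iloc[0]) if "sorted_count" in grp.columns else max(len(grp), 1)
        rec = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        rec.update(summarize_well(grp, sc))
        rows.append(rec)
    return pd.DataFrame(rows)


def regress_assay(pheno: pd.DataFrame, trait_cols: list[str] | None = None) -> pd.DataFrame:
    """Residuals of each trait on assay label (one-way fixed-effect fit).

    The fit of ``phenotype ~ assay`` with a categorical assay term has
    residuals equal to each value minus its assay mean; a single assay level
    degenerates to plain centering.  Identifying columns are preserved.
    """
    if "assay" not in pheno.columns:
        raise ValueError("phenotype table lacks an 'assay' column")
    if trait_cols is None:
        trait_cols = [c for c in TRAIT_ROSTER if c in pheno.columns]
    out = pheno.copy()
    for lev, grp in pheno.groupby("assay", sort=False):
        if len(grp) == 1:
            warnings.warn(f"assay level {lev!r} has a single observation; residual is 0")
    for c in trait_cols:
        out[c] = pheno[c] - pheno.groupby("assay")[c].transform("mean")
    return out


def remove_outliers(
    values: pd.Series | np.ndarray,
    sd_mult: float = 2.0,
    exemption_fraction: float = 0.05,
) -> pd.Series:
    """Drop values beyond ``mean +/- sd_mult * SD``, unless too many are out.

    Mean and SD are computed once on the input (non-iteratively).  If the
    fraction of values outside the band is at least ``exemption_fraction``
    the trait is judged genuinely dispersed and *nothing* is removed.  A
    zero-variance input is returned unchanged.
    """
    s = pd.Series(values).dropna()
    if len(s) < 3:
        raise ValueError("need at least 3 values for outlier screening")
    mu, sd = s.mean(), s.std(ddof=1)
    if sd == 0:
        return s
    outside = (s - mu).abs() > sd_mult * sd
    if outside.mean() >= exemption_fraction:
        return s
    return s[~outside]


def regress_control(
    toxin: pd.Series,
    control: pd.Series,
) -> tuple[pd.Series, bool]:
    """Residuals of the toxin-condition trait on the same trait in control.

    Both inputs are indexed by strain; strains missing either value are
    dropped.  Returns (residuals, degenerate) where ``degenerate`` flags a
    zero-variance control (slope undefined; residuals are then the centred
    toxin values).
    """
    df = pd.concat({"toxin": toxin, "control": control}, axis=1).dropna()
    if len(df) < 2:
        raise ValueError("need at least 2 strains with both toxin and control values")
    x = df["control"].to_numpy()
    y = df["toxin"].to_numpy()
    if np.var(x) == 0:
        return pd.Series(y - y.mean(), index=df.index), True
    slope, intercept = np.polyfit(x, y, 1)
    return pd.Series(y - (slope * x + intercept), index=df.index), False


def process_condition(
    well_summaries: pd.DataFrame,
    condition: str,
    control: str | None = None,
    sd_mult: float = 2.0,
    exemption_fraction: float = 0.05,
    do_regress_assay: bool = True,
) -> pd.DataFrame:
    """Full trait pipeline for one condition: assay regression, outlier
    removal, then control regression (in that order).

    Returns a strains x traits residual phenotype matrix with trait columns
    named ``condition.trait``.  Wells are first averaged within strain per
    assay so each strain contributes one observation per assay.
    """
    trait_cols = [c for c in TRAIT_ROSTER if c in well_summaries.columns]
    df = well_summaries[well_summaries["condition"] == condition]
    if df.empty:
        raise ValueError(f"no wells for condition {condition!r}")
    multi_assay = "assay" in df.columns and df["assay"].nunique() > 1
    if do_regress_assay and multi_assay:
        df = regress_assay(df, trait_cols)
    # collapse replicate wells/assays to one value per strain
    strain_means = df.groupby("strain")[trait_cols].mean()

    ctrl_means = None
    if control is not None:
        cdf = well_summaries[well_summaries["condition"] == control]
        if cdf.empty:
            raise ValueError(f"no wells for control condition {control!r}")
        if do_regress_assay and "assay" in cdf.columns and cdf["assay"].nunique() > 1:
            cdf = regress_assay(cdf, trait_cols)
        ctrl_means = cdf.groupby("strain")[trait_cols].mean()

    out = {}
    for c in trait_cols:
        vals = remove_outliers(strain_means[c].dropna(), sd_mult, exemption_fraction)
        if ctrl_means is not None:
            resid, _ = regress_control(vals, ctrl_means[c])
            vals = resid
        out[f"{condition}.{c}"] = vals
    return pd.DataFrame(out)
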