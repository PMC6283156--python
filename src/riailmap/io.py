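"""Plain-text I/O for genotype and phenotype tables.

All tables are TSV.  Genotypes use parent-of-origin allele labels (default
``N2`` for parent A = -1, ``CB`` for parent B = +1, ``NA`` for missing) with
one column per strain after the marker annotation columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from riailmap.sim import GenotypeMatrix

_META_COLS = ["marker", "chrom", "pos_bp", "pos_cM"]
DEFAULT_LABELS = {"a": "N2", "b": "CB"}


def write_genotypes(
    geno: GenotypeMatrix, path: str | Path, labels: dict[str, str] | None = None
) -> None:
    labels = labels or DEFAULT_LABELS
    code = {-1.0: labels["a"], 1.0: labels["b"]}
    meta = geno.markers[_META_COLS].reset_index(drop=True)
    cols = {
        s: [code.get(v, "NA") if not np.isnan(v) else "NA" for v in geno.calls[i, :]]
        for i, s in enumerate(geno.strain_ids)
    }
    pd.concat([meta, pd.DataFrame(cols)], axis=1).to_csv(path, sep="\t", index=False)


def load_genotypes(
    path: str | Path, labels: dict[str, str] | None = None
) -> tuple[GenotypeMatrix, float]:
    """Read a genotype TSV; returns (matrix, missing fraction).

    Rejects duplicate marker ids, non-monotone genetic positions, and any
    allele token outside {parent A label, parent B label, NA} — the error
    names the offending row and strain column.
    """
    labels = labels or DEFAULT_LABELS
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    missing_meta = [c for c in ("marker", "chrom", "pos_bp") if c not in df.columns]
    if missing_meta:
        raise ValueError(f"genotype file lacks columns {missing_meta}")
    if "pos_cM" not in df.columns:
        df["pos_cM"] = np.nan
    dup = df["marker"][df["marker"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate marker ids: {sorted(set(dup))}")
    for chrom, grp in df.groupby("chrom", sort=False):
        if grp["pos_cM"].notna().all() and not grp["pos_cM"].is_monotonic_increasing:
            bad = grp.index[grp["pos_cM"].diff() < 0].tolist()
            raise ValueError(f"non-monotone pos_cM on {chrom} at line(s) {[i + 2 for i in bad]}")
    strains = [c for c in df.columns if c not in _META_COLS]
    decode = {labels["a"]: -1.0, labels["b"]: 1.0, "NA": np.nan, "": np.nan}
    calls = np.empty((len(strains), len(df)))
    for j, s in enumerate(strains):
        for i, tok in enumerate(df[s].astype(str)):
            if tok not in decode:
                raise ValueError(
                    f"unknown allele token {tok!r} at marker {df['marker'][i]!r}, strain column {s!r}"
                )
            calls[j, i] = decode[tok]
    geno = GenotypeMatrix(strains, df[_META_COLS].reset_index(drop=True), calls)
    return geno, float(np.isnan(calls).mean())


def write_phenotypes(pheno: pd.DataFrame, path: str | Path, condition: str = "") -> None:
    """Write a strains x traits matrix as long TSV (strain, condition, trait, value)."""
    long = pheno.stack().rename("value").reset_index()
    long.columns = ["strain", "trait", "value"]
    long.insert(1, "condition", condition)
    long.to_csv(path, sep="\t", index=False)


def load_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read long TSV back into a strains x traits matrix (conditions merged into trait names)."""
    long = pd.read_csv(path, sep="\t")
    if "condition" in long.columns:
        # avoid double prefix when trait names already carry the condition
        long["trait"] = [
            t if (not c or c == "nan" or t.startswith(c + ".")) else f"{c}.{t}"
            for t, c in zip(long["trait"].astype(str), long["condition"].astype(str))
        ]
    return long.pivot_table(index="strain", columns="trait", values="value", aggfunc="mean")
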