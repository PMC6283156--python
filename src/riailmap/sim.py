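"""Synthetic RIAIL panels, introgression lines, and phenotypes with known architecture.

The generator emulates a two-parent recombinant inbred advanced intercross
panel: each strain's chromosome is a two-state Markov chain over the marker
grid whose switch probability per interval comes from the inverse Haldane map
function applied to the (already expanded) genetic distances.  No pedigree is
simulated — downstream analyses consume only marginal genotype correlations,
which the Markov chain reproduces.

Alleles are coded parent A (reference, "N2-like") = -1 and parent B
("CB4856-like") = +1.  Under this symmetric coding with allele frequency 1/2,
a marker, a second unlinked marker, and their product are mutually orthogonal,
which keeps planted additive and epistatic variance fractions interpretable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

#: physical annotation only; cM is the canonical coordinate throughout
_BP_PER_CM = 12_000


@dataclass(frozen=True)
class ChromSpec:
    """One chromosome of the marker map."""

    name: str
    n_markers: int
    length_cM: float

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError(f"chromosome {self.name}: need >= 1 marker")
        if self.length_cM < 0:
            raise ValueError(f"chromosome {self.name}: negative genetic length")


@dataclass(frozen=True)
class MapSpec:
    """Marker map for simulation.

    ``length_cM`` per chromosome is the *expanded* genetic length of the
    advanced-intercross panel (map expansion is folded into the distances, not
    modelled through generations).  ``expansion_generations`` is carried for
    provenance only.
    """

    chromosomes: tuple[ChromSpec, ...]
    expansion_generations: int | None = None

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("empty map")

    @property
    def total_length_cM(self) -> float:
        return float(sum(c.length_cM for c in self.chromosomes))

    def marker_table(self) -> pd.DataFrame:
        """Markers with evenly spaced genetic positions per chromosome."""
        rows = []
        for c in self.chromosomes:
            if c.n_markers == 1:
                pos = np.array([0.0])
            else:
                pos = np.linspace(0.0, c.length_cM, c.n_markers)
            for i, p in enumerate(pos):
                rows.append(
                    {
                        "marker": f"{c.name}_{i:04d}",
                        "chrom": c.name,
                        "pos_bp": int(round(p * _BP_PER_CM)) + 1,
                        "pos_cM": float(p),
                    }
                )
        return pd.DataFrame(rows)


def default_map(marker_spacing_cM: float = 5.0) -> MapSpec:
    """Six-chromosome map with a 1,690-cM expanded genome (65 x 26-cM bins).

    Chromosome lengths are multiples of 26 cM so equal-width binning tiles the
    genome exactly; markers are placed every ``marker_spacing_cM``.
    """
    bins = {"I": 10, "II": 10, "III": 10, "IV": 12, "V": 12, "X": 11}
    chroms = []
    for name, b in bins.items():
        length = 26.0 * b
        # ceil so the realized spacing never exceeds the requested one
        n = int(np.ceil(length / marker_spacing_cM)) + 1
        chroms.append(ChromSpec(name, n, length))
    return MapSpec(tuple(chroms), expansion_generations=10)


@dataclass
class GenotypeMatrix:
    """Strains x markers allele calls in {-1, +1}, NaN for missing.

    ``markers`` columns: marker, chrom, pos_bp, pos_cM (genetic positions
    non-decreasing within each chromosome).
    """

    strain_ids: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.strain_ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.strain_ids)}, {len(self.markers)})"
            )
        ok = np.isnan(self.calls) | (np.abs(self.calls) == 1)
        if not ok.all():
            raise ValueError("allele calls must be -1, +1 or NaN")
        for _, grp in self.markers.groupby("chrom", sort=False):
            if not grp["pos_cM"].is_monotonic_increasing:
                raise ValueError("genetic positions must be non-decreasing within chromosome")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_strains(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            [self.strain_ids[i] for i in idx], self.markers, self.calls[idx]
        )


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a genetic distance via the Haldane map function."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def simulate_riail_panel(
    n_strains: int,
    map_spec: MapSpec | None = None,
    seed: int | np.random.Generator = 0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Simulate an inbred recombinant panel from two parents.

    Each chromosome is an independent two-state Markov chain along the marker
    grid; the switch probability between adjacent markers is the Haldane
    recombination fraction of their (expanded) cM separation.  Marginal allele
    frequency is 1/2 at every marker.

    Parameters
    ----------
    n_strains:
        Number of recombinant strains (>= 2); the study panel used 296.
    missing_rate:
        Optional fraction of calls blanked to NaN to exercise missing-data
        handling (default 0: fully genotyped).
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    if map_spec is None:
        map_spec = default_map()
    rng = np.random.default_rng(seed)
    markers = map_spec.marker_table()

    cols = []
    for c in map_spec.chromosomes:
        pos = markers.loc[markers["chrom"] == c.name, "pos_cM"].to_numpy()
        state = rng.choice([-1.0, 1.0], size=n_strains)
        chrom_calls = [state.copy()]
        r = haldane_r(np.diff(pos))
        for rr in r:
            flip = rng.random(n_strains) < rr
            state = np.where(flip, -state, state)
            chrom_calls.append(state.copy())
        cols.append(np.column_stack(chrom_calls))
    calls = np.concatenate(cols, axis=1)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = np.where(mask, np.nan, calls)
    strain_ids = [f"QX{i:04d}" for i in range(1, n_strains + 1)]
    return GenotypeMatrix(strain_ids, markers, calls)


def simulate_introgression_line(
    map_spec_or_markers: MapSpec | pd.DataFrame,
    background: int,
    chrom: str | None = None,
    start_cM: float | None = None,
    end_cM: float | None = None,
    strain_id: str = "NIL",
) -> GenotypeMatrix:
    """Genotype of a near-isogenic or chromosome-substitution strain.

    All markers carry ``background`` (+1 or -1) except those inside the
    introgressed interval, which carry the opposite parent's allele.  With
    ``chrom`` given but no ``start_cM``/``end_cM`` the whole chromosome is
    substituted (a CSS); with ``chrom=None`` the line is a pure parental
    genotype.  The interval is closed on marker positions.
    """
    if background not in (-1, 1):
        raise ValueError("background must be -1 or +1")
    markers = (
        map_spec_or_markers.marker_table()
        if isinstance(map_spec_or_markers, MapSpec)
        else map_spec_or_markers
    )
    calls = np.full(len(markers), float(background))
    if chrom is not None:
        on_chrom = markers["chrom"] == chrom
        if not on_chrom.any():
            raise ValueError(f"unknown chromosome {chrom!r}")
        if start_cM is None and end_cM is None:
            inside = on_chrom.to_numpy()
        else:
            lo = 0.0 if start_cM is None else float(start_cM)
            hi = (
                float(markers.loc[on_chrom, "pos_cM"].max())
                if end_cM is None
                else float(end_cM)
            )
            if lo > hi:
                raise ValueError("interval start exceeds end")
            chrom_max = markers.loc[on_chrom, "pos_cM"].max()
            if lo < 0 or hi > chrom_max:
                raise ValueError(
                    f"interval [{lo}, {hi}] outside chromosome {chrom} (0..{chrom_max} cM)"
                )
            inside = (on_chrom & (markers["pos_cM"] >= lo) & (markers["pos_cM"] <= hi)).to_numpy()
        calls[inside] = -background
    return GenotypeMatrix([strain_id], markers, calls[None, :])


@dataclass
class ArchitectureSpec:
    """Planted genetic architecture for phenotype simulation.

    Variance fractions are of the total phenotypic variance of the latent
    trait (which is simulated with unit variance): ``additive_qtl`` maps
    marker index -> fraction, ``epistatic_pairs`` maps (i, j) -> fraction for
    a product-term (g_i * g_j) interaction.  ``trait_loadings`` projects the
    latent trait onto correlated observed traits; each observed trait gets
    loading * latent + sqrt(1 - loading^2) * independent noise, so loadings
    are correlations with the latent trait.
    """

    additive_qtl: list[tuple[int, float]] = field(default_factory=list)
    epistatic_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    trait_loadings: np.ndarray | None = None
    trait_names: list[str] | None = None
    assay_effect_sd: float = 0.0
    noise_variance: float | None = None

    def genetic_fraction(self) -> float:
        return sum(f for _, f in self.additive_qtl) + sum(
            f for _, _, f in self.epistatic_pairs
        )

    def residual_variance(self) -> float:
        g = self.genetic_fraction()
        if g > 1.0 + 1e-12:
            raise ValueError(f"planted variance fractions sum to {g} > 1")
        return (1.0 - g) if self.noise_variance is None else float(self.noise_variance)


def default_trait_loadings(n_traits: int = 24) -> np.ndarray:
    """Fixed loading spectrum: a handful of strong traits shading into weak ones.

    Mirrors the empirical structure of sorter summary traits, where the size
    quantiles are highly inter-correlated and the dispersion/brood traits are
    only loosely coupled to overall growth.
    """
    return np.linspace(0.95, 0.30, n_traits)


def latent_genetic_values(geno: GenotypeMatrix, arch: ArchitectureSpec) -> np.ndarray:
    """Deterministic genetic part of the latent trait (no noise)."""
    g = np.nan_to_num(geno.calls, nan=0.0)
    z = np.zeros(geno.n_strains)
    for idx, frac in arch.additive_qtl:
        if not 0 <= idx < geno.n_markers:
            raise ValueError(f"additive QTL marker index {idx} out of range")
        z += np.sqrt(frac) * g[:, idx]
    for i, j, frac in arch.epistatic_pairs:
        if not (0 <= i < geno.n_markers and 0 <= j < geno.n_markers):
            raise ValueError(f"epistatic pair ({i}, {j}) out of range")
        z += np.sqrt(frac) * g[:, i] * g[:, j]
    return z


def simulate_phenotypes(
    geno: GenotypeMatrix,
    arch: ArchitectureSpec,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Strain-level trait matrix from a planted architecture.

    Returns a strains x traits DataFrame.  The latent trait is the sum of
    planted additive effects, planted product-term interactions, and Gaussian
    noise filling the remaining variance; observed traits are its projection
    through ``arch.trait_loadings`` plus trait-specific noise.
    """
    rng = np.random.default_rng(seed)
    resid_var = arch.residual_variance()
    z = latent_genetic_values(geno, arch) + rng.normal(
        0.0, np.sqrt(resid_var), geno.n_strains
    )
    loadings = (
        default_trait_loadings() if arch.trait_loadings is None else np.asarray(arch.trait_loadings)
    )
    n_traits = len(loadings)
    eps = rng.normal(size=(geno.n_strains, n_traits))
    traits = z[:, None] * loadings[None, :] + eps * np.sqrt(
        np.clip(1.0 - loadings**2, 0.0, None)
    )[None, :]
    names = arch.trait_names or [f"trait{t:02d}" for t in range(n_traits)]
    return pd.DataFrame(traits, index=geno.strain_ids, columns=names)


def simulate_replicate_values(
    geno: GenotypeMatrix,
    arch: ArchitectureSpec,
    n_replicates: int,
    seed: int | np.random.Generator = 0,
    replicate_noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-replicate values of the latent trait, for NIL/CSS assay simulation.

    Each replicate is the strain's latent genetic value plus strain-level
    noise shared across replicates (per ``arch``) plus independent technical
    noise.  Returns long format: strain, replicate, value.
    """
    rng = np.random.default_rng(seed)
    z = latent_genetic_values(geno, arch)
    z = z + rng.normal(0.0, np.sqrt(arch.residual_variance()), geno.n_strains)
    rows = []
    for s, base in zip(geno.strain_ids, z):
        vals = base + rng.normal(0.0, replicate_noise_sd, n_replicates)
        for r, v in enumerate(vals):
            rows.append({"strain": s, "replicate": r, "value": v})
    return pd.DataFrame(rows)


def simulate_sorter_objects(
    geno: GenotypeMatrix,
    arch: ArchitectureSpec,
    condition: str = "toxin",
    n_assays: int = 2,
    mean_brood: float = 30.0,
    sorted_count: int = 50,
    tof_base: float = 300.0,
    tof_sd: float = 30.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-animal sorter records (TOF/EXT) for each strain in each assay.

    One well per strain per assay.  The strain's latent trait shifts mean
    animal length (TOF) and brood size; per-assay batch shifts of SD
    ``arch.assay_effect_sd`` (in latent units) are added so the assay
    regression step has real signal to remove.  EXT is generated as
    TOF * norm.EXT with norm.EXT mildly strain-dependent.
    """
    rng = np.random.default_rng(seed)
    z = latent_genetic_values(geno, arch) + rng.normal(
        0.0, np.sqrt(arch.residual_variance()), geno.n_strains
    )
    shifts = rng.normal(0.0, arch.assay_effect_sd, n_assays)
    rows = []
    for a in range(n_assays):
        for s_i, strain in enumerate(geno.strain_ids):
            zz = z[s_i] + shifts[a]
            n_obj = max(1, rng.poisson(max(1.0, mean_brood * (1 + 0.1 * zz))))
            n_obj = min(n_obj, sorted_count)
            tof = rng.normal(tof_base * (1 + 0.05 * zz), tof_sd, n_obj)
            tof = np.clip(tof, 10.0, None)
            norm_ext = np.clip(rng.normal(0.5 + 0.02 * zz, 0.05, n_obj), 0.05, None)
            ext = tof * norm_ext
            for t, e in zip(tof, ext):
                rows.append(
                    {
                        "assay": f"assay{a}",
                        "plate": 1 + s_i // 96,
                        "row": "ABCDEFGH"[(s_i % 96) // 12],
                        "col": 1 + (s_i % 96) % 12,
                        "strain": strain,
                        "condition": condition,
                        "TOF": float(t),
                        "EXT": float(e),
                        "sorted_count": sorted_count,
                    }
                )
    return pd.DataFrame(rows)
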