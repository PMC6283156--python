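"""NIL/CSS validation calculus: Tukey HSD comparisons, replicate power, and
the phenotype-categorization decision trees.

A QTL predicted from linkage mapping is validated by building reciprocal
near-isogenic lines (NILs) — and for whole chromosomes, chromosome
substitution strains (CSSs) — and phenotyping them alongside both parents.
The pattern of pairwise significance (Tukey's honest significant difference
at p < 0.05) and median ordering across the four (or six) strains is mapped
to a small set of genetic-architecture categories: simple recapitulation of
the parental difference, no detectable locus effect, or transgressive
phenotypes that indicate additional loci of opposite effect inside or outside
the introgressed region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05

# primary (NIL-assay) categories
NO_PARENTAL = "no parental difference"
RECAPITULATION = "recapitulation"
NO_QTL_EFFECT = "no QTL effect"
UNIDIRECTIONAL = "unidirectional transgressive"
BIDIRECTIONAL = "bidirectional transgressive"
MISCELLANEOUS = "miscellaneous"

# combined NIL+CSS categories
INTER_EXTERNAL = "interchromosomal external"
INTER_INTERNAL = "interchromosomal internal"
INTRACHROMOSOMAL = "intrachromosomal"

#: strain roles: parents, plus introgression lines named by their *background*
ROLES_NIL = ("parent_a", "parent_b", "nil_a", "nil_b")


def tukey_hsd(values: pd.DataFrame, min_replicates: int = 2) -> pd.DataFrame:
    """All-pairs Tukey honest-significant-difference test on ``phenotype ~ strain``.

    ``values`` is long format with columns ``strain`` and ``value``.  Strains
    with fewer than ``min_replicates`` replicates are excluded with a
    warning.  If every value of every strain is identical there is nothing to
    test and all pairs get p = 1.  Returns a tidy table (strain1, strain2,
    p_value) with each unordered pair once.
    """
    groups: dict[str, np.ndarray] = {}
    for s, grp in values.groupby("strain", sort=False):
        v = grp["value"].dropna().to_numpy(dtype=float)
        if len(v) < min_replicates:
            warnings.warn(f"strain {s!r} has {len(v)} replicate(s); excluded")
            continue
        groups[s] = v
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 strains with enough replicates")
    allv = np.concatenate(list(groups.values()))
    rows = []
    if np.ptp(allv) == 0:  # identical constants: no variance anywhere
        pmat = np.ones((len(names), len(names)))
    else:
        pmat = stats.tukey_hsd(*groups.values()).pvalue
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({"strain1": names[i], "strain2": names[j], "p_value": float(pmat[i, j])})
    return pd.DataFrame(rows)


def _two_sample_power(n: int, effect: float, alpha: float) -> float:
    """Power of the two-sided two-sample t-test at n per group (noncentral t)."""
    df = 2 * n - 2
    nc = effect * math.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def replicates_for_power(
    effect: float,
    power: float = 0.80,
    alpha: float = 0.05,
    cap: int = 100,
) -> tuple[int, bool]:
    """Smallest replicates per group to detect a standardized difference.

    Uses the noncentral-t power function of the two-sided two-sample t-test.
    Returns (n, capped): if the required n exceeds ``cap`` (the practical
    assay ceiling), ``cap`` is returned with the flag set.  The minimum
    meaningful group size is 2.
    """
    if effect <= 0:
        raise ValueError("effect size must be positive")
    for n in range(2, cap + 1):
        if _two_sample_power(n, effect, alpha) >= power:
            return n, False
    return cap, True


@dataclass
class StrainComparison:
    """Pairwise test results and medians for one trait's validation assay.

    ``medians`` maps role -> median replicate value; ``pvalues`` maps an
    unordered role pair (frozenset) -> Tukey HSD p-value.  Roles follow
    :data:`ROLES_NIL` naming: ``nil_a`` has the parent-A background with the
    introgressed region from parent B, and vice versa (for CSS assays use the
    same role names for the substitution strains).
    """

    trait: str
    medians: dict[str, float]
    pvalues: dict[frozenset, float]

    def p(self, a: str, b: str) -> float:
        return self.pvalues[frozenset((a, b))]

    @classmethod
    def from_replicates(
        cls, trait: str, values: pd.DataFrame, roles: dict[str, str]
    ) -> "StrainComparison":
        """Build from long-format replicate values plus a strain -> role map."""
        df = values.copy()
        df["strain"] = df["strain"].map(roles)
        df = df.dropna(subset=["strain"])
        tk = tukey_hsd(df)
        pvals = {
            frozenset((r.strain1, r.strain2)): r.p_value for r in tk.itertuples()
        }
        med = df.groupby("strain")["value"].median().to_dict()
        return cls(trait=trait, medians=med, pvalues=pvals)


@dataclass
class CategoryResult:
    trait: str
    assay: str  # "NIL" | "CSS" | "combined"
    category: str
    directionality: str | None = None  # "unidirectional" | "bidirectional"
    transgressive_sides: dict[str, str] = field(default_factory=dict)
    parental_direction: int = 0  # sign of median(parent_b) - median(parent_a)


def _nil_patterns(cmp: StrainComparison, nil: str, bg: str, intro: str, alpha: float):
    """(recapitulates, no_effect, transgressive, side) for one introgression line.

    ``recapitulates``: significantly different from its background parent and
    shifted toward the introgression parent — but not transgressive (a line
    beyond both parents is evidence of extra loci, not of the planted one
    alone).  ``transgressive``: significantly different from *both* parents
    with its median strictly outside the closed interval of the parental
    medians.
    """
    sig_bg = cmp.p(nil, bg) < alpha
    sig_in = cmp.p(nil, intro) < alpha
    m_nil, m_bg, m_in = cmp.medians[nil], cmp.medians[bg], cmp.medians[intro]
    lo, hi = min(m_bg, m_in), max(m_bg, m_in)
    outside = m_nil < lo or m_nil > hi
    trans = sig_bg and sig_in and outside
    toward = np.sign(m_nil - m_bg) == np.sign(m_in - m_bg) and m_in != m_bg
    recap = sig_bg and toward and not trans
    no_eff = not sig_bg
    side = None
    if outside:
        side = "above" if m_nil > hi else "below"
    return recap, no_eff, trans, side


def categorize_nil(
    cmp: StrainComparison, alpha: float = ALPHA, assay: str = "NIL"
) -> CategoryResult:
    """Six-category decision tree for a reciprocal-NIL (or CSS) assay.

    Evaluated in fixed order: (1) parents not significantly different ->
    "no parental difference"; (2) both lines recapitulate -> "recapitulation";
    (3) neither line differs from its background parent -> "no QTL effect";
    (4) both lines transgressive -> "bidirectional transgressive"; (5) exactly
    one line transgressive while the other recapitulates or shows no effect ->
    "unidirectional transgressive"; (6) otherwise "miscellaneous".
    """
    missing = [r for r in ROLES_NIL if r not in cmp.medians]
    if missing:
        raise ValueError(f"missing strain role(s): {missing}")
    par_dir = int(np.sign(cmp.medians["parent_b"] - cmp.medians["parent_a"]))
    res = CategoryResult(trait=cmp.trait, assay=assay, category=MISCELLANEOUS,
                         parental_direction=par_dir)
    if cmp.p("parent_a", "parent_b") >= alpha:
        res.category = NO_PARENTAL
        return res
    rec_a, no_a, tr_a, side_a = _nil_patterns(cmp, "nil_a", "parent_a", "parent_b", alpha)
    rec_b, no_b, tr_b, side_b = _nil_patterns(cmp, "nil_b", "parent_b", "parent_a", alpha)
    if tr_a:
        res.transgressive_sides["nil_a"] = side_a
    if tr_b:
        res.transgressive_sides["nil_b"] = side_b
    if rec_a and rec_b:
        res.category = RECAPITULATION
    elif no_a and no_b:
        res.category = NO_QTL_EFFECT
    elif tr_a and tr_b:
        res.category = BIDIRECTIONAL
        res.directionality = "bidirectional"
    elif (tr_a and (rec_b or no_b)) or (tr_b and (rec_a or no_a)):
        res.category = UNIDIRECTIONAL
        res.directionality = "unidirectional"
    return res


_INTERACTING = (UNIDIRECTIONAL, BIDIRECTIONAL)
_NON_INTERACTING = (RECAPITULATION, NO_QTL_EFFECT)


def categorize_combined(
    nil_result: CategoryResult, css_result: CategoryResult
) -> CategoryResult:
    """Seven-category tree combining the NIL and CSS assays for one trait.

    "External interchromosomal": the whole-chromosome substitution shows a
    transgressive interaction but the small introgression does not, so a
    locus on the focal chromosome *outside* the NIL interval interacts with
    the rest of the genome.  "Internal interchromosomal": both assays show
    the same interaction (same uni/bi directionality and the same
    transgressive side), so a locus inside the NIL interval partners with
    another chromosome.  "Intrachromosomal": only the NIL shows the
    interaction, so both partners lie on the focal chromosome.
    """
    if nil_result.trait != css_result.trait:
        raise ValueError("NIL and CSS results are for different traits")
    res = CategoryResult(trait=nil_result.trait, assay="combined", category=MISCELLANEOUS)
    same_dir = (
        nil_result.parental_direction != 0
        and nil_result.parental_direction == css_result.parental_direction
    )
    if NO_PARENTAL in (nil_result.category, css_result.category) or not same_dir:
        res.category = NO_PARENTAL
        return res
    nil_c, css_c = nil_result.category, css_result.category
    if nil_c == RECAPITULATION and css_c == RECAPITULATION:
        res.category = RECAPITULATION
    elif nil_c == NO_QTL_EFFECT and css_c == NO_QTL_EFFECT:
        res.category = NO_QTL_EFFECT
    elif css_c in _INTERACTING and nil_c in _NON_INTERACTING:
        res.category = INTER_EXTERNAL
        res.directionality = css_result.directionality
    elif css_c in _INTERACTING and nil_c == css_c:
        same_sides = (
            set(nil_result.transgressive_sides.items())
            == set(css_result.transgressive_sides.items())
        )
        if same_sides:
            res.category = INTER_INTERNAL
            res.directionality = nil_result.directionality
    elif nil_c in _INTERACTING and css_c in _NON_INTERACTING:
        res.category = INTRACHROMOSOMAL
        res.directionality = nil_result.directionality
    return res
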