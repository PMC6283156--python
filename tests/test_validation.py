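"""NIL/CSS validation: Tukey HSD, replicate power, categorization decision trees."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import riailmap as rm
from riailmap.validation import (
    BIDIRECTIONAL,
    INTER_EXTERNAL,
    INTER_INTERNAL,
    INTRACHROMOSOMAL,
    MISCELLANEOUS,
    NO_PARENTAL,
    NO_QTL_EFFECT,
    RECAPITULATION,
    UNIDIRECTIONAL,
    CategoryResult,
    StrainComparison,
)

SIX = {NO_PARENTAL, RECAPITULATION, NO_QTL_EFFECT, UNIDIRECTIONAL, BIDIRECTIONAL, MISCELLANEOUS}


def long_values(**groups):
    rows = [
        {"strain": s, "value": v} for s, vals in groups.items() for v in vals
    ]
    return pd.DataFrame(rows)


class TestTukeyHSD:
    def test_large_effect_highly_significant(self):
        rng = np.random.default_rng(0)
        df = long_values(a=rng.normal(0, 1, 20), b=rng.normal(5, 1, 20))
        p = rm.tukey_hsd(df)["p_value"].iloc[0]
        assert p < 0.001

    def test_identical_constant_groups(self):
        df = long_values(a=[2.0] * 5, b=[2.0] * 5, c=[2.0] * 5)
        tk = rm.tukey_hsd(df)
        assert (tk["p_value"] == 1.0).all()
        assert len(tk) == 3  # each unordered pair once

    def test_single_replicate_strain_excluded(self):
        df = long_values(a=[1.0, 2.0, 1.5], b=[0.9, 2.1, 1.4], c=[5.0])
        with pytest.warns(UserWarning, match="excluded"):
            tk = rm.tukey_hsd(df)
        assert set(tk["strain1"]) | set(tk["strain2"]) == {"a", "b"}

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(1)
        rejects = 0
        for _ in range(1000):
            df = long_values(a=rng.normal(0, 1, 10), b=rng.normal(0, 1, 10))
            rejects += rm.tukey_hsd(df)["p_value"].iloc[0] < 0.05
        assert 0.03 <= rejects / 1000 <= 0.07


class TestReplicatesForPower:
    def test_huge_effect_floors_at_two(self):
        assert rm.replicates_for_power(10.0) == (2, False)

    def test_tiny_effect_hits_cap(self):
        n, capped = rm.replicates_for_power(0.1)
        assert n == 100 and capped

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            rm.replicates_for_power(0.0)

    def test_monte_carlo_power_at_returned_n(self):
        # d = 1: the analytic n should deliver ~80% power empirically and the
        # next-smaller n should not
        d = 1.0
        n, capped = rm.replicates_for_power(d)
        assert not capped
        rng = np.random.default_rng(2)
        reps = 10_000
        for nn, expect_ge in ((n, True), (n - 1, False)):
            a = rng.normal(0, 1, (reps, nn))
            b = rng.normal(d, 1, (reps, nn))
            t, p = stats.ttest_ind(a, b, axis=1)
            power = (p < 0.05).mean()
            if expect_ge:
                assert power == pytest.approx(0.80, abs=0.03)
                assert power >= 0.80 - 0.03
            else:
                assert power < 0.80


def comparison(medians, sig_pairs, trait="t"):
    """StrainComparison with p=0.01 for pairs in sig_pairs, else p=0.5."""
    roles = list(medians)
    pv = {}
    for a, b in itertools.combinations(roles, 2):
        pv[frozenset((a, b))] = 0.01 if {a, b} in [set(x) for x in sig_pairs] else 0.5
    return StrainComparison(trait=trait, medians=medians, pvalues=pv)


ALL_PAIRS = list(itertools.combinations(("parent_a", "parent_b", "nil_a", "nil_b"), 2))


class TestCategorizeNil:
    def test_nonsignificant_parents_short_circuit(self):
        cmp = comparison(
            {"parent_a": 10.0, "parent_b": 0.0, "nil_a": 0.0, "nil_b": 10.0},
            sig_pairs=[("nil_a", "parent_a"), ("nil_b", "parent_b")],
        )
        assert rm.categorize_nil(cmp).category == NO_PARENTAL

    def test_recapitulation_pattern(self):
        # each line leaves its background parent and lands near its
        # introgression parent
        cmp = comparison(
            {"parent_a": 10.0, "parent_b": 0.0, "nil_a": 0.5, "nil_b": 9.5},
            sig_pairs=[("parent_a", "parent_b"), ("nil_a", "parent_a"), ("nil_b", "parent_b")],
        )
        assert rm.categorize_nil(cmp).category == RECAPITULATION

    def test_no_qtl_effect_pattern(self):
        cmp = comparison(
            {"parent_a": 10.0, "parent_b": 0.0, "nil_a": 9.8, "nil_b": 0.2},
            sig_pairs=[("parent_a", "parent_b"), ("nil_a", "parent_b"), ("nil_b", "parent_a")],
        )
        assert rm.categorize_nil(cmp).category == NO_QTL_EFFECT

    def test_unidirectional_transgressive(self):
        # nil_b shoots past both parents; nil_a recapitulates
        cmp = comparison(
            {"parent_a": 10.0, "parent_b": 0.0, "nil_a": 0.5, "nil_b": 20.0},
            sig_pairs=[
                ("parent_a", "parent_b"), ("nil_a", "parent_a"),
                ("nil_b", "parent_b"), ("nil_b", "parent_a"),
            ],
        )
        res = rm.categorize_nil(cmp)
        assert res.category == UNIDIRECTIONAL
        assert res.transgressive_sides == {"nil_b": "above"}

    def test_bidirectional_transgressive(self):
        cmp = comparison(
            {"parent_a": 10.0, "parent_b": 0.0, "nil_a": 20.0, "nil_b": -10.0},
            sig_pairs=list(ALL_PAIRS),
        )
        res = rm.categorize_nil(cmp)
        assert res.category == BIDIRECTIONAL
        assert res.transgressive_sides == {"nil_a": "above", "nil_b": "below"}

    def test_missing_role_raises_named_error(self):
        cmp = comparison({"parent_a": 1.0, "parent_b": 0.0, "nil_a": 0.5}, [])
        with pytest.raises(ValueError, match="nil_b"):
            rm.categorize_nil(cmp)

    def test_tree_is_total_and_single_valued(self):
        # every configuration of pairwise significance and median ordering
        # maps to exactly one of the six categories
        med_grid = itertools.product([0.0, 5.0, 10.0], repeat=2)  # nil medians
        for na, nb in med_grid:
            for sig in itertools.product([True, False], repeat=6):
                pv = {
                    frozenset(p): (0.01 if s else 0.5) for p, s in zip(ALL_PAIRS, sig)
                }
                cmp = StrainComparison(
                    "t", {"parent_a": 10.0, "parent_b": 0.0, "nil_a": na, "nil_b": nb}, pv
                )
                assert rm.categorize_nil(cmp).category in SIX

    def test_invariance_under_parent_relabeling(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            med = dict(zip(("parent_a", "parent_b", "nil_a", "nil_b"),
                           rng.choice([0.0, 3.0, 7.0, 10.0, 15.0], 4)))
            pv = {frozenset(p): float(rng.choice([0.01, 0.5])) for p in ALL_PAIRS}
            cmp = StrainComparison("t", med, pv)
            swapped_med = {
                "parent_a": med["parent_b"], "parent_b": med["parent_a"],
                "nil_a": med["nil_b"], "nil_b": med["nil_a"],
            }
            relabel = {"parent_a": "parent_b", "parent_b": "parent_a",
                       "nil_a": "nil_b", "nil_b": "nil_a"}
            swapped_pv = {frozenset(relabel[x] for x in k): v for k, v in pv.items()}
            a = rm.categorize_nil(cmp)
            b = rm.categorize_nil(StrainComparison("t", swapped_med, swapped_pv))
            assert a.category == b.category


def cat_result(category, directionality=None, sides=None, par_dir=1, assay="NIL"):
    return CategoryResult(
        trait="t", assay=assay, category=category, directionality=directionality,
        transgressive_sides=sides or {}, parental_direction=par_dir,
    )


class TestCategorizeCombined:
    def test_recapitulation_in_both_assays(self):
        # the cisplatin normalized-brood-size outcome: both assays recapitulate
        res = rm.categorize_combined(cat_result(RECAPITULATION), cat_result(RECAPITULATION, assay="CSS"))
        assert res.category == RECAPITULATION

    def test_css_interaction_with_quiet_nil_is_external(self):
        # the silver median-length outcome: bidirectional CSS, no-effect NIL
        res = rm.categorize_combined(
            cat_result(NO_QTL_EFFECT),
            cat_result(BIDIRECTIONAL, "bidirectional",
                       {"nil_a": "above", "nil_b": "below"}, assay="CSS"),
        )
        assert res.category == INTER_EXTERNAL
        assert res.directionality == "bidirectional"

    def test_same_interaction_in_both_is_internal(self):
        # the carmustine median-optical-density outcome: unidirectional in both
        res = rm.categorize_combined(
            cat_result(UNIDIRECTIONAL, "unidirectional", {"nil_b": "above"}),
            cat_result(UNIDIRECTIONAL, "unidirectional", {"nil_b": "above"}, assay="CSS"),
        )
        assert res.category == INTER_INTERNAL
        assert res.directionality == "unidirectional"

    def test_nil_only_interaction_is_intrachromosomal(self):
        res = rm.categorize_combined(
            cat_result(UNIDIRECTIONAL, "unidirectional", {"nil_a": "above"}),
            cat_result(NO_QTL_EFFECT, assay="CSS"),
        )
        assert res.category == INTRACHROMOSOMAL

    def test_opposite_parental_directions_void_the_comparison(self):
        res = rm.categorize_combined(
            cat_result(RECAPITULATION, par_dir=1),
            cat_result(RECAPITULATION, par_dir=-1, assay="CSS"),
        )
        assert res.category == NO_PARENTAL

    def test_full_product_table_against_rule_oracle(self):
        cats = [NO_PARENTAL, RECAPITULATION, NO_QTL_EFFECT, UNIDIRECTIONAL,
                BIDIRECTIONAL, MISCELLANEOUS]

        def oracle(nil_c, css_c, same_sides):
            inter = {UNIDIRECTIONAL, BIDIRECTIONAL}
            quiet = {RECAPITULATION, NO_QTL_EFFECT}
            if NO_PARENTAL in (nil_c, css_c):
                return NO_PARENTAL
            if nil_c == css_c == RECAPITULATION:
                return RECAPITULATION
            if nil_c == css_c == NO_QTL_EFFECT:
                return NO_QTL_EFFECT
            if css_c in inter and nil_c in quiet:
                return INTER_EXTERNAL
            if css_c in inter and nil_c == css_c:
                return INTER_INTERNAL if same_sides else MISCELLANEOUS
            if nil_c in inter and css_c in quiet:
                return INTRACHROMOSOMAL
            return MISCELLANEOUS

        side_opts = {
            UNIDIRECTIONAL: [("unidirectional", {"nil_a": "above"}),
                             ("unidirectional", {"nil_b": "below"})],
            BIDIRECTIONAL: [("bidirectional", {"nil_a": "above", "nil_b": "below"})],
        }
        for nil_c in cats:
            for css_c in cats:
                for nd, ns in side_opts.get(nil_c, [(None, {})]):
                    for cd, cs in side_opts.get(css_c, [(None, {})]):
                        got = rm.categorize_combined(
                            cat_result(nil_c, nd, ns),
                            cat_result(css_c, cd, cs, assay="CSS"),
                        ).category
                        assert got == oracle(nil_c, css_c, ns == cs)

    def test_mismatched_traits_rejected(self):
        a = cat_result(RECAPITULATION)
        b = cat_result(RECAPITULATION, assay="CSS")
        b.trait = "other"
        with pytest.raises(ValueError):
            rm.categorize_combined(a, b)


class TestSyntheticNilAssays:
    def _nil_strains(self):
        """Parents plus reciprocal NILs for a 40-60 cM interval on chrom I."""
        from riailmap.sim import ChromSpec, MapSpec

        spec = MapSpec((ChromSpec("I", 21, 100.0),))
        markers = spec.marker_table()
        rows, ids = [], []
        for sid, bg, c, s, e in (
            ("parent_a", -1, None, None, None),
            ("parent_b", +1, None, None, None),
            ("nil_a", -1, "I", 40.0, 60.0),
            ("nil_b", +1, "I", 40.0, 60.0),
        ):
            g = rm.simulate_introgression_line(markers, bg, c, s, e, strain_id=sid)
            rows.append(g.calls[0])
            ids.append(sid)
        return rm.GenotypeMatrix(ids, markers, np.array(rows))

    def test_recapitulation_recovered_on_planted_qtl(self):
        # one additive QTL inside the introgressed interval, assayed at the
        # replicate count the power calculation prescribes for the predicted
        # effect: the recapitulation call is near-certain
        geno = self._nil_strains()
        arch = rm.ArchitectureSpec(
            additive_qtl=[(10, 0.9)], noise_variance=0.0, trait_loadings=np.array([1.0])
        )
        n_rep, _ = rm.replicates_for_power(1.0)
        recaps = 0
        for s in range(100):
            vals = rm.simulate_replicate_values(geno, arch, n_rep, seed=s,
                                                replicate_noise_sd=0.6)
            cmp = StrainComparison.from_replicates("t", vals, {r: r for r in geno.strain_ids})
            recaps += rm.categorize_nil(cmp).category == RECAPITULATION
        assert recaps >= 90

    def test_antagonistic_background_locus_yields_transgression(self):
        # a second locus outside the interval with opposite effect sign drives
        # the NILs beyond both parents
        geno = self._nil_strains()
        rng_master = np.random.default_rng(77)
        trans = 0
        n_seeds = 60
        for s in range(n_seeds):
            rng = np.random.default_rng(rng_master.integers(2**31))
            g_in = geno.calls[:, 10]   # inside interval
            g_out = geno.calls[:, 2]   # outside interval (background allele)
            z = 2.0 * g_in - 1.0 * g_out
            rows = []
            for sid, base in zip(geno.strain_ids, z):
                for v in base + rng.normal(0, 0.5, 20):
                    rows.append({"strain": sid, "value": v})
            cmp = StrainComparison.from_replicates(
                "t", pd.DataFrame(rows), {r: r for r in geno.strain_ids}
            )
            cat = rm.categorize_nil(cmp).category
            trans += cat in (UNIDIRECTIONAL, BIDIRECTIONAL)
        assert trans > n_seeds / 2
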