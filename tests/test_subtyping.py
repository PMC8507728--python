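"""Tumour microbial subtyping, B-groups and derived scores."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from triomic.categories import abundance_screen, assign_categories
from triomic.compositional import clr_transform_counts
from triomic.io import filter_taxa
from triomic.subtyping import (
    oral_fraction,
    pathogen_burden,
    subtype_cluster,
    subtype_profiles,
)

from conftest import make_table


@pytest.fixture(scope="module")
def clustered(default_cohort):
    table, clinical, truth = default_cohort
    filt = filter_taxa(table)
    clr = clr_transform_counts(filt.counts)
    cats = assign_categories(abundance_screen(clr, filt))
    tumour_genera = list(cats.index[cats["tumour_flag"]])
    res = subtype_cluster(filt, tumour_genera)
    return filt, clinical, truth, res, tumour_genera


def _separable_table(seed=0):
    """Three planted profiles with between-centroid distance >> within."""
    rng = np.random.default_rng(seed)
    g, per = 20, 8
    base = rng.normal(0, 0.05, (g, 3 * per))
    for c in range(3):
        base[c * 6 : (c + 1) * 6, c * per : (c + 1) * per] += 4.0
    counts = np.rint(1000 * np.exp(base)).astype(int)
    patients = [f"P{i}" for i in range(3 * per)]
    return make_table(counts, patients, ["tumour"] * 3 * per), np.repeat([0, 1, 2], per)


class TestSubtypeCluster:
    def test_separable_profiles_recovered_exactly(self):
        table, labels = _separable_table()
        res = subtype_cluster(table, table.genus_ids)
        assert adjusted_rand_score(labels, res.assignments["tms"]) == 1.0

    def test_planted_mixture_ari(self, clustered):
        filt, _, truth, res, _ = clustered
        pat = filt.sample_meta.loc[res.assignments.index, "patient_id"]
        ari = adjusted_rand_score(
            truth.patients.loc[pat, "subtype"], res.assignments["tms"]
        )
        assert ari >= 0.8

    def test_sample_order_invariance(self):
        table, _ = _separable_table(1)
        res1 = subtype_cluster(table, table.genus_ids)
        perm = np.random.default_rng(2).permutation(table.sample_ids).tolist()
        res2 = subtype_cluster(table.subset_samples(perm), table.genus_ids)
        joined = res1.assignments.join(res2.assignments, rsuffix="_p")
        assert (joined["tms"] == joined["tms_p"]).all()

    def test_subcomposition_property(self, clustered):
        filt, _, _, res, tumour_genera = clustered
        # adding a genus outside the tumour-genus list leaves the partition
        other = [g for g in filt.genus_ids if g not in tumour_genera]
        res2 = subtype_cluster(filt, tumour_genera + [])
        sub = filt.subset_genera(tumour_genera + other[:1])
        res3 = subtype_cluster(sub, tumour_genera)
        assert res.assignments["tms"].equals(res2.assignments["tms"])
        assert res.assignments["tms"].equals(res3.assignments["tms"])

    def test_deterministic_rerun(self, clustered):
        filt, _, _, res, tumour_genera = clustered
        res2 = subtype_cluster(filt, tumour_genera)
        assert res.assignments.equals(res2.assignments)
        assert res.genus_groups.equals(res2.genus_groups)
        assert res.sample_newick == res2.sample_newick

    def test_invariants(self, clustered):
        _, _, _, res, _ = clustered
        assert res.assignments["tms"].isin([1, 2, 3]).all()
        assert res.assignments["subgroup"].isin(["a", "b"]).all()
        assert res.assignments["tms"].value_counts().sum() == len(res.assignments)
        assert res.genus_groups["bgroup"].nunique() == 6
        assert res.sample_newick.endswith(";")

    def test_disjoint_genus_list_rejected(self, clustered):
        filt = clustered[0]
        with pytest.raises(ValueError, match="disjoint"):
            subtype_cluster(filt, ["nope1", "nope2"])


class TestProfiles:
    def test_clinical_coupling_detected(self, clustered):
        filt, clinical, _, res, _ = clustered
        _, clin_tests = subtype_profiles(
            res, filt, clinical.data, categorical_test="chi2"
        )
        clin_tests = clin_tests.set_index("variable")
        # grade and localisation are coupled to the planted subtype;
        # at 120 patients the coupling is detectable but not overwhelming
        assert clin_tests.loc["grade", "p"] < 0.1
        assert clin_tests.loc["localisation", "p"] < 0.1
        # gender is drawn independently of subtype
        assert clin_tests.loc["gender", "p"] > 0.01

    def test_signature_genus_differential(self, clustered):
        filt, clinical, truth, res, _ = clustered
        diff, _ = subtype_profiles(res, filt, clinical.data, categorical_test="chi2")
        sigs = truth.genus.index[truth.genus["signature_subtype"] >= 0]
        tum = diff[diff["environment"] == "tumour"].set_index("genus")
        sigs = [g for g in sigs if g in tum.index]
        assert (tum.loc[sigs, "kw_q"] < 0.1).mean() >= 0.9


class TestScores:
    def test_oral_fraction_extremes(self, small_cohort):
        table, _, _ = small_cohort
        all_oral = pd.Series("oral", index=table.genus_ids)
        frac, _ = oral_fraction(table, all_oral)
        np.testing.assert_allclose(frac, 100.0)
        none_oral = pd.Series("gut", index=table.genus_ids)
        with pytest.warns(UserWarning):
            frac0, _ = oral_fraction(table, none_oral)
        np.testing.assert_allclose(frac0, 0.0)

    def test_planted_oral_ordering(self, clustered):
        filt, _, truth, res, _ = clustered
        frac, test = oral_fraction(
            filt, truth.genus["origin"], res.assignments
        )
        pat = filt.sample_meta.loc[res.assignments.index, "patient_id"]
        z = truth.patients.loc[pat, "subtype"].to_numpy()
        medians = [np.median(frac[z == s]) for s in range(3)]
        # subtype 0 signatures are all oral, subtype 2's are not
        assert medians[0] > medians[2]
        assert test.p_value < 0.001

    def test_burden_bounds_and_missing_panel(self, small_cohort):
        table, _, _ = small_cohort
        panel = list(table.genus_ids[:3]) + ["absent_genus"]
        with pytest.warns(UserWarning, match="absent"):
            b = pathogen_burden(table, panel)
        assert b["burden"].between(0, len(panel)).all()

    def test_burden_extremes(self):
        counts = np.array([[10, 0], [5, 0], [3, 0], [0, 50]])
        t = make_table(counts, ["P1", "P2"], ["tumour", "tumour"])
        b = pathogen_burden(t, ["g0", "g1", "g2"])
        assert b.loc["P1_tumour", "burden"] == 3
        assert b.loc["P2_tumour", "burden"] == 0

    def test_canonical_labels_by_burden(self, clustered):
        filt, _, truth, res, tumour_genera = clustered
        # use the subtype-1 signature genera as a panel: the subtype
        # carrying them must be labelled TMS1
        panel = list(truth.genus.index[truth.genus["signature_subtype"] == 0])
        res_b = subtype_cluster(filt, tumour_genera, pathogen_panel=panel)
        burdens = pathogen_burden(filt, panel).join(res_b.assignments)
        med = burdens.groupby("tms")["burden"].median()
        assert med.idxmax() == 1
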