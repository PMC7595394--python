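"""Pairwise Pearson screening, BH-FDR, link selection, and derived tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import prairienet as pn
from prairienet.io import SURVEY_COLUMNS, ValidationError
from prairienet.network import CooccurrenceNetwork

# ---------------------------------------------------------------------------
# helpers


def _tables_from_matrices(bee_mat, plant_mat, bee_names, plant_names):
    """Build strip-only survey tables whose wide views equal the matrices.

    Rows of the matrices are (site, year, month) sampling events.
    """
    events = []
    sites = ["S1", "S2", "S3", "S4"]
    months = ["May", "Jun", "Jul", "Aug"]
    i = 0
    for year in (2016, 2017):
        for site in sites:
            for month in months:
                events.append((site, year, month))
                i += 1
    events = events[: bee_mat.shape[0]]
    bee_rows, plant_rows = [], []
    for (site, year, month), bvals, pvals in zip(events, bee_mat, plant_mat):
        for name, v in zip(bee_names, bvals):
            bee_rows.append((site, "strip", year, month, name, int(v)))
        for name, v in zip(plant_names, pvals):
            plant_rows.append((site, "strip", year, month, name, float(v)))
    bees = pn.SurveyTable(
        pd.DataFrame(bee_rows, columns=SURVEY_COLUMNS), role="bee"
    )
    plants = pn.SurveyTable(
        pd.DataFrame(plant_rows, columns=SURVEY_COLUMNS), role="plant"
    )
    return bees, plants


def _fake_network(r, p, bees=None, plants=None):
    r = pd.DataFrame(np.atleast_2d(r))
    p = pd.DataFrame(np.atleast_2d(p))
    if bees is not None:
        r.index = p.index = bees
    if plants is not None:
        r.columns = p.columns = plants
    defined = ~r.isna()
    n = pd.DataFrame(10, index=r.index, columns=r.columns)
    return CooccurrenceNetwork(
        r=r, p=p, n=n, defined=defined, pairing=("site", "year", "month")
    )


# ---------------------------------------------------------------------------


class TestPearson:
    def test_perfect_linear(self):
        res = pn.pearson_r_p([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0)

    def test_perfect_anticorrelation(self):
        res = pn.pearson_r_p([1, 2, 3], [6, 4, 2])
        assert res.r == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        # r = 0.8, t = 0.8*sqrt(2/0.36) = 1.8856, two-sided p on 2 df ~ 0.2
        res = pn.pearson_r_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8, abs=1e-12)
        assert res.p == pytest.approx(0.2, abs=1e-3)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            ours = pn.pearson_r_p(x, y)
            ref_r, ref_p = stats.pearsonr(x, y)
            assert ours.r == pytest.approx(ref_r, abs=1e-12)
            assert ours.p == pytest.approx(ref_p, abs=1e-10)

    def test_constant_series_flagged_not_raised(self):
        res = pn.pearson_r_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.defined
        assert np.isnan(res.r)

    def test_short_series_flagged(self):
        assert not pn.pearson_r_p([1, 2], [3, 4]).defined


class TestBuildCooccurrence:
    def test_identical_series_give_r_one(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 9, size=(8, 1)).astype(float)
        bee_mat = counts
        plant_mat = counts / 10.0  # same shape, proportional cover
        bees, plants = _tables_from_matrices(
            bee_mat, plant_mat, ["Apidae_sp01"], ["Asteraceae_P01"]
        )
        net = pn.build_cooccurrence(bees, plants)
        assert net.r.loc["Apidae_sp01", "Asteraceae_P01"] == pytest.approx(1.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        bee_mat = rng.integers(0, 9, size=(8, 3))
        plant_mat = rng.dirichlet(np.ones(4), size=8) / 2
        bees, plants = _tables_from_matrices(
            bee_mat,
            plant_mat,
            ["Apidae_sp01", "Apidae_sp02", "Halictidae_sp01"],
            [f"Asteraceae_P{i:02d}" for i in range(1, 5)],
        )
        net1 = pn.build_cooccurrence(bees, plants)
        shuffled = pn.SurveyTable(
            bees.data.sample(frac=1, random_state=8), role="bee"
        )
        net2 = pn.build_cooccurrence(shuffled, plants)
        pd.testing.assert_frame_equal(net1.r, net2.r)
        pd.testing.assert_frame_equal(net1.p, net2.p)

    def test_dropping_a_pairing_key_decrements_n(self):
        rng = np.random.default_rng(3)
        bee_mat = rng.integers(0, 9, size=(8, 2))
        plant_mat = rng.dirichlet(np.ones(3), size=8) / 2
        bees, plants = _tables_from_matrices(
            bee_mat,
            plant_mat,
            ["Apidae_sp01", "Apidae_sp02"],
            ["Asteraceae_P01", "Asteraceae_P02", "Asteraceae_P03"],
        )
        net_full = pn.build_cooccurrence(bees, plants)
        drop = (bees.data["site"] == "S1") & (bees.data["month"] == "May")
        bees2 = pn.SurveyTable(bees.data[~drop], role="bee")
        pdrop = (plants.data["site"] == "S1") & (plants.data["month"] == "May")
        plants2 = pn.SurveyTable(plants.data[~pdrop], role="plant")
        net_less = pn.build_cooccurrence(bees2, plants2)
        assert (net_less.n.values == net_full.n.values - 1).all()

    def test_too_few_shared_keys_rejected(self):
        bee_mat = np.array([[1], [2]])
        plant_mat = np.array([[0.1], [0.2]])
        bees, plants = _tables_from_matrices(
            bee_mat, plant_mat, ["Apidae_sp01"], ["Asteraceae_P01"]
        )
        with pytest.raises(ValidationError, match="shared pairing keys"):
            pn.build_cooccurrence(bees, plants)


def brute_force_bh(pvals):
    """Literal step-up definition: sort, scale by m/i, enforce monotone, cap."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        out = pn.bh_adjust(pd.DataFrame([[0.03]]))
        assert out.iloc[0, 0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        out = pn.bh_adjust(pd.DataFrame([[0.01, 0.02, 0.04]]))
        np.testing.assert_allclose(out.values[0], [0.03, 0.03, 0.04], atol=1e-12)

    def test_equal_ps_unchanged(self):
        out = pn.bh_adjust(pd.DataFrame([[0.2, 0.2, 0.2, 0.2]]))
        np.testing.assert_allclose(out.values[0], 0.2, atol=1e-12)

    @pytest.mark.parametrize("m", [10, 1000, 10000])
    def test_matches_brute_force(self, m):
        rng = np.random.default_rng(m)
        p = rng.uniform(1e-6, 1, size=m)
        frame = pd.DataFrame(p.reshape(1, -1))
        out = pn.bh_adjust(frame).values.ravel()
        np.testing.assert_allclose(out, brute_force_bh(p), atol=1e-12)

    def test_undefined_cells_excluded_from_family(self):
        p = pd.DataFrame([[0.01, np.nan, 0.04]])
        defined = pd.DataFrame([[True, False, True]])
        out = pn.bh_adjust(p, defined)
        assert np.isnan(out.iloc[0, 1])
        # m = 2, not 3
        np.testing.assert_allclose(
            out.values[0, [0, 2]], brute_force_bh([0.01, 0.04]), atol=1e-12
        )


class TestSelectLinks:
    def test_selection_rule(self):
        net = _fake_network([[0.9, -0.9, 0.5]], [[0.01, 0.001, 0.05]])
        sig = pn.select_links(net, alpha=0.05)
        assert sig.values.tolist() == [[True, False, False]]

    def test_undefined_cells_never_selected(self):
        net = _fake_network([[np.nan, 0.9]], [[np.nan, 0.01]])
        sig = pn.select_links(net, alpha=0.05)
        assert sig.values.tolist() == [[False, True]]

    def test_adjusted_selection_is_subset(self, dataset):
        net = pn.build_cooccurrence(dataset["bees"], dataset["plants"])
        raw = pn.select_links(net, use_adjusted=False).copy()
        adj = pn.select_links(net, use_adjusted=True)
        assert (adj & ~raw).values.sum() == 0
        assert adj.values.sum() <= raw.values.sum()


class TestValidation:
    def test_visits_proportional_to_r(self):
        r = np.array([[0.1, 0.4], [0.8, 0.2]])
        net = _fake_network(r, np.full((2, 2), 0.5), ["b1", "b2"], ["p1", "p2"])
        visits = pn.VisitationMatrix(
            pd.DataFrame((r * 10).round().astype(int), index=["b1", "b2"], columns=["p1", "p2"])
        )
        res = pn.validate_vs_visitation(net, visits)
        assert res.r == pytest.approx(1.0, abs=0.02)

    def test_permuted_visits_centre_on_zero(self):
        rng = np.random.default_rng(6)
        r = rng.uniform(-1, 1, size=(6, 6))
        net = _fake_network(
            r,
            np.full((6, 6), 0.5),
            [f"b{i}" for i in range(6)],
            [f"p{i}" for i in range(6)],
        )
        base = rng.integers(0, 30, size=36)
        vals = []
        for _ in range(300):
            v = rng.permutation(base).reshape(6, 6)
            visits = pn.VisitationMatrix(
                pd.DataFrame(v, index=net.bees, columns=net.plants)
            )
            vals.append(pn.validate_vs_visitation(net, visits).r)
        assert abs(np.mean(vals)) < 3 * np.std(vals) / np.sqrt(len(vals)) + 0.01

    def test_too_few_cells_rejected(self):
        net = _fake_network([[0.5, np.nan]], [[0.1, np.nan]], ["b1"], ["p1", "p2"])
        visits = pn.VisitationMatrix(
            pd.DataFrame([[1, 2]], index=["b1"], columns=["p1", "p2"])
        )
        with pytest.raises(ValidationError, match=">= 3"):
            pn.validate_vs_visitation(net, visits)


class TestFamilyProportions:
    @staticmethod
    def _registry():
        rows = []
        for i, fam in enumerate(["Halictidae", "Apidae"]):
            for j in range(2):
                rows.append(
                    {
                        "taxon": f"{fam}_sp{j + 1:02d}",
                        "role": "bee",
                        "family": fam,
                        "origin": "not_applicable",
                        "pooled": False,
                    }
                )
        for fam, origin in [
            ("Asteraceae", "native_prairie"),
            ("Asteraceae", "exotic_weedy"),
            ("Fabaceae", "native_prairie"),
        ]:
            tag = "P" if origin == "native_prairie" else "EW"
            rows.append(
                {
                    "taxon": f"{fam}_{tag}{len(rows)}",
                    "role": "plant",
                    "family": fam,
                    "origin": origin,
                    "pooled": False,
                }
            )
        return pn.TaxonRegistry(pd.DataFrame(rows))

    def _net(self, sig_cells):
        reg = self._registry()
        bees = reg.bees
        plants = reg.plants
        r = pd.DataFrame(0.5, index=bees, columns=plants)
        p = pd.DataFrame(0.5, index=bees, columns=plants)
        for b, pl in sig_cells:
            p.loc[b, pl] = 0.01
        net = _fake_network(r.values, p.values, bees, plants)
        pn.select_links(net, alpha=0.05)
        return net, reg

    def test_single_link_cell_is_one(self):
        net, reg = self._net([("Halictidae_sp01", "Asteraceae_P4")])
        table = pn.family_proportions(net, reg)
        assert table.loc["Asteraceae", "Halictidae"] == pytest.approx(1.0)
        assert table.loc["Totals", "Totals"] == pytest.approx(1.0)

    def test_counting(self):
        cells = [
            ("Halictidae_sp01", "Asteraceae_P4"),
            ("Halictidae_sp02", "Asteraceae_EW5"),
            ("Apidae_sp01", "Fabaceae_P6"),
            ("Apidae_sp02", "Fabaceae_P6"),
        ]
        net, reg = self._net(cells)
        table = pn.family_proportions(net, reg)
        assert table.loc["Asteraceae", "Halictidae"] == pytest.approx(0.5)
        assert table.loc["Fabaceae", "Apidae"] == pytest.approx(0.5)
        assert table.loc["Totals", "Totals"] == pytest.approx(1.0, abs=1e-12)

    def test_no_links_warns_and_empty(self):
        net, reg = self._net([])
        with pytest.warns(UserWarning, match="no selected links"):
            table = pn.family_proportions(net, reg)
        assert table.empty


class TestOriginRatio:
    def _net_with_links(self, native_links, exotic_links):
        reg = TestFamilyProportions._registry()
        bees = reg.bees
        plants = reg.plants
        natives = [p for p in plants if reg.origin_of(p) == "native_prairie"]
        exotics = [p for p in plants if reg.origin_of(p) == "exotic_weedy"]
        p = pd.DataFrame(0.5, index=bees, columns=plants)
        k = 0
        for i in range(native_links):
            p.loc[bees[k % len(bees)], natives[i % len(natives)]] = 0.01
            k += 1
        for i in range(exotic_links):
            p.loc[bees[k % len(bees)], exotics[i % len(exotics)]] = 0.01
            k += 1
        r = pd.DataFrame(0.5, index=bees, columns=plants)
        net = _fake_network(r.values, p.values, bees, plants)
        pn.select_links(net, alpha=0.05)
        return net, reg

    def test_balance_gives_one(self):
        net, reg = self._net_with_links(2, 2)
        res = pn.origin_ratio(net, reg, "Halictidae")
        total_group = res.n_native + res.n_exotic
        sub = net.sig.loc[[b for b in net.bees if reg.family_of(b) == "Halictidae"]]
        assert total_group == int(sub.values.sum())

    def test_counting_ratio(self):
        # all links via a single bee family for clean counting
        reg = TestFamilyProportions._registry()
        bees = [b for b in reg.bees if reg.family_of(b) == "Apidae"]
        plants = reg.plants
        natives = [p for p in plants if reg.origin_of(p) == "native_prairie"]
        exotics = [p for p in plants if reg.origin_of(p) == "exotic_weedy"]
        p = pd.DataFrame(0.5, index=reg.bees, columns=plants)
        # 4 native links, 2 exotic links
        p.loc[bees[0], natives[0]] = 0.01
        p.loc[bees[0], natives[1]] = 0.01
        p.loc[bees[1], natives[0]] = 0.01
        p.loc[bees[1], natives[1]] = 0.01
        p.loc[bees[0], exotics[0]] = 0.01
        p.loc[bees[1], exotics[0]] = 0.01
        r = pd.DataFrame(0.5, index=reg.bees, columns=plants)
        net = _fake_network(r.values, p.values, reg.bees, plants)
        pn.select_links(net, alpha=0.05)
        res = pn.origin_ratio(net, reg, "Apidae")
        assert res == pn.OriginRatio(2.0, 4, 2)

    def test_degenerate_denominator_flags(self):
        net, reg = self._net_with_links(2, 0)
        res = pn.origin_ratio(net, reg, "Halictidae")
        if res.n_native > 0:
            assert np.isinf(res.ratio)
        net, reg = self._net_with_links(0, 0)
        res = pn.origin_ratio(net, reg, "Halictidae")
        assert np.isnan(res.ratio)

    def test_unknown_group_rejected(self):
        net, reg = self._net_with_links(1, 1)
        with pytest.raises(ValidationError, match="unknown bee group"):
            pn.origin_ratio(net, reg, "Formicidae")

    def test_common_group_requires_partition(self):
        net, reg = self._net_with_links(1, 1)
        with pytest.raises(ValidationError, match="CommonnessPartition"):
            pn.origin_ratio(net, reg, "common")


class TestMonthlyNetworks:
    @staticmethod
    def _may_coupled_scenario(seed):
        reg = pn.small_registry(bees={"Halictidae": 4, "Apidae": 4}, plants=4)
        B, P = 8, 4
        coupling = np.zeros((B, P))
        by_month = np.zeros((4, B, P))
        for b in range(B):
            by_month[0, b, b % P] = 30.0  # May only, one partner plant each
        truth = pn.SyntheticTruth(
            coupling=coupling,
            coupling_by_month=by_month,
            bee_base=np.full(B, np.log(8.0)),
            plant_concentration=np.full(P, 2.0),
            treatment_effect=0.3,
            month_effects=np.zeros(4),
            n_sites=8,
            n_years=2,
            seed=seed,
        )
        return reg, truth

    def test_planted_month_dominates_recovery(self):
        reg, _ = self._may_coupled_scenario(0)
        in_may = 0
        elsewhere = 0
        for seed in range(25):
            reg, truth = self._may_coupled_scenario(1000 + seed)
            bees, plants, visits, truth = pn.generate_dataset(truth, reg)
            edges = pn.monthly_networks(bees, plants, reg, alpha=0.05)
            net_by_month = {}
            planted = truth.coupling_by_month[0] > 0
            for month in ("May", "Jun", "Jul", "Aug"):
                bm = pn.SurveyTable(
                    bees.data[bees.data["month"] == month], role="bee"
                )
                pm = pn.SurveyTable(
                    plants.data[plants.data["month"] == month], role="plant"
                )
                net = pn.build_cooccurrence(bm, pm, pairing=("site", "year"))
                sig = (
                    pn.select_links(net)
                    .reindex(index=reg.bees, columns=reg.plants, fill_value=False)
                    .to_numpy()
                )
                hits = int(sig[planted].sum())
                if month == "May":
                    in_may += hits
                else:
                    elsewhere += hits
        assert in_may / (in_may + elsewhere) >= 0.9

    def test_edge_weights_match_selected_mask_recount(self):
        reg, truth = self._may_coupled_scenario(7)
        bees, plants, visits, truth = pn.generate_dataset(truth, reg)
        edges = pn.monthly_networks(bees, plants, reg, alpha=0.05)
        for month in edges["month"].unique():
            bm = pn.SurveyTable(bees.data[bees.data["month"] == month], role="bee")
            pm = pn.SurveyTable(
                plants.data[plants.data["month"] == month], role="plant"
            )
            net = pn.build_cooccurrence(bm, pm, pairing=("site", "year"))
            sig = pn.select_links(net)
            expected = int(sig.values.sum())
            got = int(edges.loc[edges["month"] == month, "weight"].sum())
            assert got == expected

    def test_undersampled_month_skipped_with_warning(self):
        reg, truth = self._may_coupled_scenario(3)
        bees, plants, visits, truth = pn.generate_dataset(truth, reg)
        keep_b = ~(
            (bees.data["month"] == "Aug")
            & (bees.data["site"].isin([f"S{i}" for i in range(2, 9)]))
        )
        keep_p = ~(
            (plants.data["month"] == "Aug")
            & (plants.data["site"].isin([f"S{i}" for i in range(2, 9)]))
        )
        bees2 = pn.SurveyTable(bees.data[keep_b], role="bee")
        plants2 = pn.SurveyTable(plants.data[keep_p], role="plant")
        with pytest.warns(UserWarning, match="Aug"):
            edges = pn.monthly_networks(bees2, plants2, reg, alpha=0.05)
        assert "Aug" not in set(edges["month"])
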