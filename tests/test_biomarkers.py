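import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

import mbopls as m


@pytest.fixture(scope="module")
def kno3_model(screen, indicators):
    scaled = screen["scaled"]
    y = indicators["KNO3"].to_numpy()
    est = m.ConsensusOPLSDA(n_orthogonal=1).fit(
        [b.to_numpy() for b in scaled.values()], y
    )
    return est


class TestSplot:
    def test_feature_equal_to_score_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0.0, 1.0], 6)
        X = rng.normal(size=(12, 4)) + np.outer(y, np.ones(4))
        est = m.ConsensusOPLSDA().fit([X], y)
        tp = est.scores_
        orth = rng.normal(size=12)
        orth -= (orth @ tp) / (tp @ tp) * tp  # orthogonal to the score
        block = pd.DataFrame({"self": tp, "orth": orth})
        tab = m.splot(est, {"b": block}).set_index("feature_id")
        assert tab.loc["self", "corr"] == pytest.approx(1.0)
        assert tab.loc["self", "cov"] == pytest.approx(tp.var(ddof=1))
        assert tab.loc["orth", "cov"] == pytest.approx(0.0, abs=1e-10)
        assert tab.loc["orth", "corr"] == pytest.approx(0.0, abs=1e-10)

    def test_covariance_correlation_identity(self, kno3_model, screen):
        tab = m.splot(kno3_model, screen["scaled"])
        tp = kno3_model.scores_
        sd_t = tp.std(ddof=1)
        sds = pd.concat([b.std(ddof=1) for b in screen["scaled"].values()])
        expected = tab["corr"].to_numpy() * sd_t * sds[tab["feature_id"]].to_numpy()
        assert tab["cov"].to_numpy() == pytest.approx(expected)
        assert tab["corr"].abs().max() <= 1 + 1e-9
        # sign agreement between cov and corr
        nz = (tab["cov"].abs() > 1e-12) & (tab["corr"].abs() > 1e-12)
        assert (np.sign(tab.loc[nz, "cov"]) == np.sign(tab.loc[nz, "corr"])).all()

    def test_regulated_features_land_in_their_quadrants(self, screen, indicators):
        # simulator ground truth, pooled over four strong factors: >= 95% of
        # features regulated at magnitude >= 2 SD sit in the matching
        # extreme quadrant
        ds = screen["dataset"]
        hits, total = 0, 0
        for fac in ("MeJA", "light", "salicylic_acid", "CaCl2"):
            est = m.ConsensusOPLSDA(n_orthogonal=1).fit(
                [b.to_numpy() for b in screen["scaled"].values()],
                indicators[fac].to_numpy(),
            )
            tab = m.splot(est, screen["scaled"], features=screen["features"])
            up = {f for e in ds.ground_truth
                  if e.indicator == fac and e.direction == "up"
                  and e.magnitude >= 2 for f in e.feature_ids}
            down = {f for e in ds.ground_truth
                    if e.indicator == fac and e.direction == "down"
                    and e.magnitude >= 2 for f in e.feature_ids}
            up_rows = tab[tab["latent_id"].isin(up)]
            down_rows = tab[tab["latent_id"].isin(down)]
            # the score's sign is arbitrary; orient by the up-set
            sign = 1.0 if up_rows["cov"].mean() > 0 else -1.0
            a_up, a_down = (1, 4) if sign > 0 else (4, 1)
            hits += (up_rows["area"] == a_up).sum()
            hits += (down_rows["area"] == a_down).sum()
            total += len(up_rows) + len(down_rows)
        assert total >= 60
        assert hits / total >= 0.95

    def test_zero_variance_feature_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0.0, 1.0], 5)
        X = rng.normal(size=(10, 3)) + np.outer(y, np.ones(3))
        est = m.ConsensusOPLSDA().fit([X], y)
        block = pd.DataFrame(X, columns=["a", "b", "c"])
        block["flat"] = 1.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            tab = m.splot(est, {"b": block})
        assert "flat" not in set(tab["feature_id"])


class TestAssignArea:
    def _table(self):
        return pd.DataFrame({
            "cov": [2.0, 1.0, 0.1, -0.1, -1.0, -2.0],
            "corr": [0.9, 0.6, 0.2, -0.2, -0.6, -0.9],
            "feature_id": list("abcdef"),
        })

    def test_empty_table_selects_nothing(self):
        tab = m.assign_area(self._table().iloc[:0])
        assert len(tab) == 0

    def test_degenerate_thresholds_select_every_concordant_feature(self):
        tab = m.assign_area(self._table(), corr_threshold=0.0, cov_quantile=0.0)
        assert (tab.loc[tab["cov"] > 0, "area"] == 1).all()
        assert (tab.loc[tab["cov"] < 0, "area"] == 4).all()

    def test_monotone_raising_thresholds_never_adds_features(self):
        tab = self._table()
        loose = m.assign_area(tab, 0.3, 0.25)
        tight = m.assign_area(tab, 0.7, 0.75)
        loose_sel = set(loose.loc[loose["area"].isin((1, 4)), "feature_id"])
        tight_sel = set(tight.loc[tight["area"].isin((1, 4)), "feature_id"])
        assert tight_sel <= loose_sel

    def test_selection_precision_on_simulated_ground_truth(
        self, kno3_model, screen
    ):
        ds = screen["dataset"]
        tab = m.splot(kno3_model, screen["scaled"], features=screen["features"],
                      corr_threshold=0.5, cov_quantile=0.75)
        sel = tab[tab["area"].isin((1, 4))]
        assert len(sel) > 5
        truth = ds.truth_latents("KNO3")
        precision = sel["latent_id"].isin(truth).mean()
        assert precision >= 0.8


class TestLoadingMatrix:
    def _fake_splots(self):
        # 3 metabolites x 2 ion features, 3 factor models with p-values
        feats = ["m1_a", "m1_b", "m2_a", "m3_a"]
        base = pd.DataFrame({
            "feature_id": feats, "latent_id": feats,
        })
        splots = {
            "F1": base.assign(cov=[1.0, 3.0, -2.0, 0.5], corr=0.5),
            "F2": base.assign(cov=[0.0, 0.0, 1.0, -1.0], corr=0.5),
            "F3": base.assign(cov=[9.0, 9.0, 9.0, 9.0], corr=0.5),
        }
        pvals = {"F1": 0.001, "F2": 0.03, "F3": 0.5}
        metabolites = {"M1": ["m1_a", "m1_b"], "M2": ["m2_a"], "M3": ["m3_a"]}
        return splots, pvals, metabolites

    def test_significant_columns_and_mean_aggregation(self):
        splots, pvals, mets = self._fake_splots()
        lm = m.loading_matrix(splots, pvals, mets, p_cutoff=0.05)
        assert list(lm.values.columns) == ["F1", "F2"]  # F3 excluded at 0.05
        assert lm.values.loc["M1", "F1"] == pytest.approx(2.0)  # mean of 1 and 3
        assert lm.values.loc["M2", "F1"] == pytest.approx(-2.0)
        assert lm.values.shape == (3, 2)

    def test_single_metabolite_single_model(self):
        splots, pvals, _ = self._fake_splots()
        lm = m.loading_matrix({"F1": splots["F1"]}, {"F1": 0.01},
                              {"M2": ["m2_a"]})
        assert lm.values.shape == (1, 1)
        assert lm.values.iloc[0, 0] == pytest.approx(-2.0)

    def test_metabolite_without_features_dropped_with_warning(self):
        splots, pvals, mets = self._fake_splots()
        mets["ghost"] = ["nope"]
        with pytest.warns(RuntimeWarning, match="ghost"):
            lm = m.loading_matrix(splots, pvals, mets)
        assert "ghost" in lm.dropped
        assert "ghost" not in lm.values.index

    def test_screen_counts_match_significance_split(self, screen, indicators):
        # 45 metabolite fixtures; 17 of 19 indicator models significant when
        # the two null nutrients are excluded at p < 0.05
        splots, pvals, mets = self._fake_splots()
        names = list(indicators.columns)
        fake_p = {n: 0.001 for n in names}
        fake_p["KH2PO4"], fake_p["MgSO4"] = 0.225, 0.62
        tabs = {n: splots["F1"] for n in names}
        mm = screen["dataset"].metabolite_map
        ions = {i for v in mm.values() for i in v}
        tab = pd.DataFrame({"feature_id": sorted(ions),
                            "latent_id": sorted(ions), "cov": 1.0, "corr": 0.5})
        lm = m.loading_matrix({n: tab for n in names}, fake_p, mm)
        assert lm.values.shape == (45, 17)


class TestClusterHeatmap:
    def test_two_identical_groups_form_pure_zero_height_clusters(self):
        rows = pd.DataFrame(
            [[1.0, 0.0]] * 3 + [[0.0, 1.0]] * 3,
            index=[f"r{i}" for i in range(6)], columns=["A", "B"],
        )
        Z, leaves, _ = m.cluster_heatmap(rows)
        labels = fcluster(Z, t=2, criterion="maxclust")
        by_label = pd.Series(labels, index=sorted(rows.index))
        assert by_label[["r0", "r1", "r2"]].nunique() == 1
        assert by_label[["r3", "r4", "r5"]].nunique() == 1
        assert by_label["r0"] != by_label["r3"]
        # identical rows merge at height zero
        assert Z[0, 2] == pytest.approx(0.0)

    def test_duplicated_row_merges_first_at_zero_height(self):
        rng = np.random.default_rng(0)
        rows = pd.DataFrame(rng.normal(size=(5, 3)),
                            index=[f"r{i}" for i in range(5)])
        rows.loc["r9"] = rows.loc["r2"]
        Z, _, _ = m.cluster_heatmap(rows)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_leaf_order_deterministic_under_row_shuffling(self):
        rng = np.random.default_rng(1)
        rows = pd.DataFrame(rng.normal(size=(8, 4)),
                            index=[f"r{i}" for i in range(8)])
        _, leaves1, _ = m.cluster_heatmap(rows)
        _, leaves2, _ = m.cluster_heatmap(rows.sample(frac=1, random_state=3))
        assert leaves1 == leaves2

    def test_missing_cells_rejected(self):
        rows = pd.DataFrame({"A": [1.0, np.nan], "B": [0.0, 1.0]})
        with pytest.raises(ValueError, match="missing"):
            m.cluster_heatmap(rows)

    def test_heatmap_figure_written(self, tmp_path):
        rng = np.random.default_rng(2)
        rows = pd.DataFrame(rng.normal(size=(6, 3)),
                            index=[f"r{i}" for i in range(6)])
        out = tmp_path / "hm.png"
        m.cluster_heatmap(rows, out_png=str(out))
        assert out.stat().st_size > 0


class TestLinkedFactors:
    def _matrix(self):
        return pd.DataFrame(
            {
                "IAA": [-1.0, 2.0], "IBA": [-1.2, 2.1],
                "NAA": [2.5, 1.9], "2,4-D": [-0.9, 2.2],
            },
            index=["consistent_met", "violating_met"],
        )

    def test_three_down_one_up_is_consistent(self):
        rep = m.interpret_linked_factors(
            self._matrix(), {"auxins": ["IAA", "IBA", "NAA", "2,4-D"]},
            strong_threshold=0.5,
        )
        row = rep.set_index("metabolite")
        assert bool(row.loc["consistent_met", "consistent"])

    def test_all_same_strong_sign_flagged(self):
        rep = m.interpret_linked_factors(
            self._matrix(), {"auxins": ["IAA", "IBA", "NAA", "2,4-D"]},
            strong_threshold=0.5,
        )
        row = rep.set_index("metabolite")
        assert not bool(row.loc["violating_met", "consistent"])

    def test_empty_group_vacuously_consistent(self):
        rep = m.interpret_linked_factors(self._matrix(), {"none": ["X", "Y"]})
        assert rep.empty
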