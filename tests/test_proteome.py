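import numpy as np
import pandas as pd
import pytest

from cohortscreen.proteome import (
    ProteinQuantMatrix,
    assemble_stratified_records,
    differential,
    filter_valid,
    heatmap_matrix,
    impute_missing,
    median_normalize,
    pooled_volcano,
    stratified_differential,
)
from cohortscreen.synthetic import ProteomeSimConfig, generate_proteome


def make_quant(values: dict[str, list], lines=None, treatments=None, proteins=None):
    """ProteinQuantMatrix from run -> intensity-column mapping."""
    intensities = pd.DataFrame(values)
    if proteins is not None:
        intensities.index = proteins
    runs = pd.DataFrame(
        {
            "line_id": lines or {r: "L1" for r in values},
            "treatment": treatments or {r: "drug" for r in values},
            "replicate": {r: i + 1 for i, r in enumerate(values)},
        }
    )
    runs.index.name = "run_id"
    return ProteinQuantMatrix(intensities=intensities, runs=runs)


class TestFilterValid:
    @pytest.mark.parametrize(
        "n_present,kept",
        [(3, False), (4, True), (12, True)],  # 1/3 of 12 runs is the boundary
    )
    def test_valid_fraction_boundary(self, n_present, kept):
        vals = {f"r{i}": [25.0 if i < n_present else np.nan, 20.0] for i in range(12)}
        q = make_quant(vals, proteins=["p1", "p2"])
        out = filter_valid(q, min_frac=1 / 3)
        assert ("p1" in out.intensities.index) is kept
        assert "p2" in out.intensities.index


class TestImputeMissing:
    def test_no_missing_is_identity(self):
        q = make_quant({"r1": [20.0, 21.0, 22.0], "r2": [19.0, 20.5, 23.0]})
        out = impute_missing(q, seed=0)
        pd.testing.assert_frame_equal(out.intensities, q.intensities)

    def test_downshifted_normal_parameters(self):
        """Observed run with mean 25 and SD 2: imputed values are drawn from
        N(25 - 1.8*2, (0.3*2)^2), i.e. mean ~21.4, SD ~0.6."""
        rng = np.random.default_rng(1)
        obs = rng.normal(size=2000)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 25.0
        col = np.concatenate([obs, np.full(1000, np.nan)])
        q = make_quant({"r1": col.tolist(), "r2": np.full(3000, 24.0).tolist()})
        out = impute_missing(q, width=0.3, downshift=1.8, seed=3)
        imputed = out.intensities["r1"].to_numpy()[2000:]
        assert imputed.mean() == pytest.approx(25 - 3.6, abs=0.2)
        assert imputed.std(ddof=1) == pytest.approx(0.6, abs=0.1)

    def test_deterministic_given_seed(self):
        q = make_quant({"r1": [20.0, np.nan, 22.0, np.nan], "r2": [19.0, 20.0, 23.0, 24.0]})
        a = impute_missing(q, seed=11).intensities
        b = impute_missing(q, seed=11).intensities
        pd.testing.assert_frame_equal(a, b)

    def test_run_with_too_few_observed_rejected(self):
        q = make_quant({"r1": [20.0, np.nan, np.nan], "r2": [19.0, 20.0, 23.0]})
        with pytest.raises(ValueError, match="r1"):
            impute_missing(q)


class TestMedianNormalize:
    def test_two_runs_meet_at_grand_median(self):
        q = make_quant({"r1": [19.0, 20.0, 21.0], "r2": [21.0, 22.0, 23.0]})
        out = median_normalize(q)
        assert out.intensities["r1"].median() == pytest.approx(21.0)
        assert out.intensities["r2"].median() == pytest.approx(21.0)

    def test_idempotent_and_identity_when_equal(self):
        q = make_quant({"r1": [19.0, 20.0, 21.0], "r2": [21.0, 22.0, 23.0]})
        once = median_normalize(q)
        twice = median_normalize(once)
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)
        pd.testing.assert_frame_equal(
            median_normalize(once).intensities, once.intensities
        )


class TestDifferential:
    def _groups(self, g1, g2):
        vals = {f"a{i}": col for i, col in enumerate(g1)}
        vals |= {f"b{i}": col for i, col in enumerate(g2)}
        q = make_quant(vals)
        return q, [f"a{i}" for i in range(len(g1))], [f"b{i}" for i in range(len(g2))]

    def test_mean_difference_orientation(self):
        q, g1, g2 = self._groups(
            [[10.0, 5.0], [10.0, 5.2], [10.0, 4.8]],
            [[11.0, 5.1], [11.0, 5.0], [11.0, 4.9]],
        )
        res = differential(q, g1, g2, n_permutations=50, seed=0)
        assert res.table["log2fc"].iloc[0] == pytest.approx(-1.0)

    def test_identical_groups_fc_zero_q_one(self):
        cols = [[10.0, 12.0], [10.5, 12.5], [9.5, 11.5]]
        q, g1, g2 = self._groups(cols, cols)
        res = differential(q, g1, g2, n_permutations=100, seed=0)
        assert (res.table["log2fc"] == 0).all()
        assert (res.table["q"] >= 0.99).all()

    def test_zero_variance_in_both_groups_flagged(self):
        q, g1, g2 = self._groups(
            [[10.0, 5.0], [10.0, 5.1], [10.0, 4.9]],
            [[11.0, 5.0], [11.0, 5.2], [11.0, 4.8]],
        )
        res = differential(q, g1, g2, n_permutations=0)
        assert bool(res.table["zero_variance"].iloc[0])
        assert np.isnan(res.table["p"].iloc[0])
        assert not res.table["zero_variance"].iloc[1]

    def test_q_monotone_in_p_rank(self):
        cfg = ProteomeSimConfig(n_proteins=300, n_planted=30, seed=8)
        q, _ = generate_proteome(cfg, None, ["a", "b"], "drugX")
        q = median_normalize(impute_missing(filter_valid(q), seed=1))
        res = differential(
            q,
            q.select_runs(treatment="drugX"),
            q.select_runs(treatment="DMSO"),
            n_permutations=150,
            seed=2,
        )
        tab = res.table.dropna(subset=["p"]).sort_values("p")
        assert tab["q"].is_monotonic_increasing
        assert tab["q"].between(0, 1).all()

    def test_swap_groups_negates_fold_changes(self):
        cfg = ProteomeSimConfig(
            n_proteins=200, n_planted=20, missing_midpoint_quantile=None, seed=3
        )
        q, _ = generate_proteome(cfg, None, ["a"], "drugX")
        g1 = q.select_runs(treatment="drugX")
        g2 = q.select_runs(treatment="DMSO")
        fwd = differential(q, g1, g2, n_permutations=0)
        rev = differential(q, g2, g1, n_permutations=0)
        assert np.allclose(fwd.table["log2fc"], -rev.table["log2fc"])


class TestPooledVolcano:
    def test_planted_effects_called_with_power(self):
        """Planted up-regulated proteins (log2 effect ~1.2-2.0 in all lines)
        are nearly all recovered at q<0.05 with positive fold change in the
        12-vs-12 pooled comparison."""
        cfg = ProteomeSimConfig(
            n_proteins=600, n_planted=50, frac_down=0.0,
            responder_factors={"high": 1.0, "mid": 1.0, "low": 1.0}, seed=5,
        )
        q, truth = generate_proteome(cfg, None, ["l1", "l2", "l3", "l4"], "drugX")
        q = median_normalize(impute_missing(filter_valid(q), seed=6))
        res = pooled_volcano(
            q,
            q.select_runs(treatment="drugX"),
            q.select_runs(treatment="DMSO"),
            n_permutations=250,
            seed=7,
        )
        planted = truth.planted.index.intersection(res.table.index)
        sub = res.table.loc[planted]
        hit = (sub["q"] < 0.05) & (sub["log2fc"] > 0)
        assert hit.mean() >= 0.9

    def test_null_matrix_has_no_enrichment(self):
        cfg = ProteomeSimConfig(n_proteins=400, n_planted=0, seed=9)
        q, _ = generate_proteome(cfg, None, ["l1", "l2"], "drugX")
        q = median_normalize(impute_missing(filter_valid(q), seed=10))
        res = pooled_volcano(
            q,
            q.select_runs(treatment="drugX"),
            q.select_runs(treatment="DMSO"),
            n_permutations=250,
            seed=11,
        )
        assert (res.table["q"] < 0.05).mean() < 0.02


class TestStratified:
    def test_threshold_arithmetic(self):
        high = pd.DataFrame(
            {"log2fc": [1.0, 0.5, 0.9], "p": [0.01, 0.01, 0.04]},
            index=["p1", "p2", "p3"],
        )
        low = pd.DataFrame(
            {"log2fc": [0.2, 0.5, 0.8], "p": [0.01, 0.01, 0.2]},
            index=["p1", "p2", "p3"],
        )
        rec = assemble_stratified_records(high, low, fc_threshold=0.263, p_max=0.05)
        # p1: both p pass, |1.0 - 0.2| = 0.8 > 0.263
        assert bool(rec.loc["p1", "pass_p"]) and bool(rec.loc["p1", "pass_fc"])
        assert rec.loc["p1", "log2fc_high_low"] == pytest.approx(0.8)
        # p2: equal fold changes -> interaction 0, fails fc gate
        assert rec.loc["p2", "log2fc_high_low"] == 0.0
        assert not bool(rec.loc["p2", "pass_fc"])
        # p3: P_low 0.2 > 0.05 -> dual gate fails regardless of FC
        assert not bool(rec.loc["p3", "pass_p"])

    def _stratified(self, seed=0, swap=False):
        cfg = ProteomeSimConfig(n_proteins=400, n_planted=40, seed=seed)
        lines = ["h1", "h2", "l1", "l2"]
        q, truth = generate_proteome(cfg, None, lines, "drugX")
        # responder structure imposed directly: full effect in h*, scaled in l*
        # (truth=None gives factor 1 everywhere, so rescale the l* drug runs)
        q2 = q.intensities.copy()
        shift = truth.planted["effect"] * (1 - 0.4)
        for line in ("l1", "l2"):
            for r in q.select_runs(line_ids=[line], treatment="drugX"):
                q2.loc[truth.planted.index, r] -= shift
        q = ProteinQuantMatrix(q2, q.runs)
        q = median_normalize(impute_missing(filter_valid(q), seed=seed + 1))
        high, low = ["h1", "h2"], ["l1", "l2"]
        if swap:
            high, low = low, high
        return q, truth, stratified_differential(q, high, low, "drugX")

    def test_missing_condition_named_in_error(self):
        cfg = ProteomeSimConfig(n_proteins=50, n_planted=0, seed=1)
        q, _ = generate_proteome(cfg, None, ["h1", "l1"], "drugX")
        with pytest.raises(ValueError, match="ghost"):
            stratified_differential(q, ["h1"], ["ghost"], "drugX")

    def test_antisymmetry_under_stratum_exchange(self):
        _, _, fwd = self._stratified(seed=12)
        _, _, rev = self._stratified(seed=12, swap=True)
        assert np.allclose(
            fwd.records["log2fc_high_low"],
            -rev.records["log2fc_high_low"],
            equal_nan=True,
        )

    def test_planted_interaction_recovered_with_correct_sign(self):
        q, truth, res = self._stratified(seed=13)
        surviving = res.surviving
        planted = truth.planted
        recovered = planted.index.intersection(surviving.index)
        assert len(recovered) / len(planted) >= 0.8
        agree = np.sign(surviving.loc[recovered, "log2fc_high_low"]) == np.sign(
            planted.loc[recovered, "effect"]
        )
        assert agree.mean() >= 0.95


class TestHeatmapMatrix:
    def _setup(self, seed=20):
        cfg = ProteomeSimConfig(
            n_proteins=200, n_planted=60, missing_midpoint_quantile=None, seed=seed
        )
        lines = ["h1", "h2", "l1", "l2"]
        q, truth = generate_proteome(cfg, None, lines, "drugX")
        return q, truth, lines

    def test_rows_are_z_scored(self):
        q, truth, lines = self._setup()
        records = truth.planted
        z, _ = heatmap_matrix(records, q, lines, "drugX")
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_degenerate_rows_excluded_with_warning(self):
        q, truth, lines = self._setup()
        ints = q.intensities.copy()
        flat = truth.planted.index[0]
        ints.loc[flat] = 25.0  # identical everywhere -> zero-SD FC row
        q = ProteinQuantMatrix(ints, q.runs)
        with pytest.warns(UserWarning, match="identical fold changes"):
            z, _ = heatmap_matrix(truth.planted, q, lines, "drugX")
        assert flat not in z.index

    def test_empty_record_set_rejected(self):
        q, truth, lines = self._setup()
        with pytest.raises(ValueError):
            heatmap_matrix(truth.planted.iloc[:0], q, lines, "drugX")

    def test_kmeans_recovers_planted_partition(self):
        """Two planted response patterns (up in high lines vs up in low
        lines) are recovered by Euclidean k-means on the z-scored rows."""
        from sklearn.metrics import adjusted_rand_score

        q, truth, lines = self._setup(seed=21)
        ints = q.intensities.copy()
        planted = truth.planted.index
        up_in_low = planted[: len(planted) // 2]
        up_in_high = planted[len(planted) // 2:]
        for line in ("l1", "l2"):
            for r in q.select_runs(line_ids=[line], treatment="drugX"):
                ints.loc[up_in_low, r] += 3.0
                ints.loc[up_in_high, r] -= 3.0
        for line in ("h1", "h2"):
            for r in q.select_runs(line_ids=[line], treatment="drugX"):
                ints.loc[up_in_low, r] -= 3.0
                ints.loc[up_in_high, r] += 3.0
        q = ProteinQuantMatrix(ints, q.runs)
        z, labels = heatmap_matrix(truth.planted, q, lines, "drugX", k=2, seed=0)
        truth_labels = [int(p in set(up_in_low)) for p in z.index]
        assert adjusted_rand_score(truth_labels, labels) >= 0.9
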