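import itertools

import numpy as np
import pandas as pd
import pytest

from phenostack.geodata_io import GridSpec, ScenarioSpec, ValidationError
from phenostack.sdm_engine import BinaryMap
from phenostack.stacked_richness import stack
from phenostack.trait_communities import (
    CommunityMatrix,
    build_community_matrix,
    cell_similarity,
    combination_bits,
    decode_combination,
    encode_combination,
    rda,
    scenario_similarity,
    select_constraints,
)

GRID = GridSpec(n_rows=6, n_cols=6, origin_lon=0.0, origin_lat=6.0, cell_size=1.0)


def bmap(values, decile, scenario=None):
    return BinaryMap(
        grid=GRID,
        values=np.asarray(values, dtype=np.int16),
        valid_mask=np.ones(GRID.shape, bool),
        decile=decile,
        scenario=scenario or ScenarioSpec.current(),
    )


class TestEncoding:
    def test_full_set_and_singletons(self):
        assert encode_combination(range(1, 11)) == 1023
        assert encode_combination({1}) == 1
        assert encode_combination({10}) == 512

    def test_roundtrip_identity_on_all_masks(self):
        for mask in range(1, 1024):
            assert encode_combination(decode_combination(mask)) == mask

    def test_popcount_two_has_45_masks(self):
        assert sum(1 for m in range(1, 1024) if bin(m).count("1") == 2) == 45

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            encode_combination(set())


class TestCellSimilarity:
    def test_singleton_is_one(self):
        assert cell_similarity({4}) == 1.0

    def test_extreme_pair_is_zero(self):
        assert cell_similarity({1, 10}) == 0.0

    def test_three_decile_example(self):
        assert cell_similarity({2, 3, 4}) == pytest.approx(1 - (1 + 2 + 1) / 3 / 9)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = int(rng.integers(1, 11))
            s = set(rng.choice(range(1, 11), size=k, replace=False).tolist())
            pairs = list(itertools.combinations(sorted(s), 2))
            dbar = np.mean([abs(a - b) for a, b in pairs]) if pairs else 0.0
            assert cell_similarity(s) == pytest.approx(1 - dbar / 9)

    def test_one_only_for_singletons_zero_only_for_extreme_pair(self):
        for mask in range(1, 1024):
            s = decode_combination(mask)
            sim = cell_similarity(s)
            if sim == 1.0:
                assert len(s) == 1
            if sim == 0.0:
                assert s == {1, 10}


class TestCommunityMatrix:
    def _binaries(self, bits_array, scenario=None):
        return [
            bmap((bits_array >> (d - 1)) & 1, d, scenario=scenario) for d in range(1, 11)
        ]

    def test_single_combination_single_column(self):
        bits = np.full(GRID.shape, encode_combination({2, 3}), dtype=np.uint16)
        matrix = build_community_matrix(
            {"current": self._binaries(bits)}, {"central": np.ones(GRID.shape, bool)}
        )
        row = matrix.row("central", "current")
        assert row[6 - 1] == 36 and row.sum() == 36

    def test_row_sums_equal_suitable_cell_counts(self):
        rng = np.random.default_rng(4)
        bits = rng.integers(0, 1024, GRID.shape).astype(np.uint16)
        binaries = self._binaries(bits)
        rich = stack(binaries)
        matrix = build_community_matrix(
            {"current": binaries}, {"central": np.ones(GRID.shape, bool)}
        )
        assert matrix.row("central", "current").sum() == (rich.values >= 1).sum()

    def test_disjoint_populations_tally_independently(self):
        rng = np.random.default_rng(5)
        bits = rng.integers(0, 1024, GRID.shape).astype(np.uint16)
        top = np.zeros(GRID.shape, bool)
        top[:3] = True
        matrix = build_community_matrix(
            {"current": self._binaries(bits)}, {"northern": top, "southern": ~top}
        )
        joint = matrix.row("northern", "current") + matrix.row("southern", "current")
        full = build_community_matrix(
            {"current": self._binaries(bits)}, {"all": np.ones(GRID.shape, bool)}
        ).row("all", "current")
        np.testing.assert_array_equal(joint, full)

    def test_combination_bits_match_encode(self):
        bits = np.zeros(GRID.shape, dtype=np.uint16)
        bits[0, 0] = encode_combination({1, 5, 10})
        got = combination_bits(self._binaries(bits))
        np.testing.assert_array_equal(got, bits)


class TestScenarioSimilarity:
    def _matrix(self, rows):
        counts = pd.DataFrame(
            rows.values(),
            index=pd.MultiIndex.from_tuples(rows.keys(), names=["population", "scenario"]),
            columns=range(1, 1024),
        )
        return CommunityMatrix(counts=counts)

    def _row(self, weights):
        row = np.zeros(1023, dtype=int)
        for members, count in weights:
            row[encode_combination(members) - 1] = count
        return row

    def test_all_singletons_score_one(self):
        m = self._matrix({("central", "current"): self._row([({3}, 10), ({7}, 5)])})
        scores = scenario_similarity(m)
        assert scores[0].value == 1.0

    def test_weighted_mean_of_extremes(self):
        m = self._matrix(
            {("central", "current"): self._row([({1, 10}, 10), ({5}, 10)])}
        )
        assert scenario_similarity(m)[0].value == pytest.approx(0.5)

    def test_baseline_delta_of_current_is_zero(self):
        row = self._row([({2, 3}, 7)])
        m = self._matrix({("central", "current"): row})
        assert scenario_similarity(m)[0].baseline_delta == 0.0

    def test_narrowing_never_decreases_similarity(self):
        """Dropping the most extreme decile from every cell's set cannot
        lower the score."""
        rng = np.random.default_rng(9)
        for _ in range(30):
            masks = rng.integers(1, 1024, size=5)
            counts = rng.integers(1, 20, size=5)
            base = self._row([(decode_combination(int(m)), int(c)) for m, c in zip(masks, counts)])
            narrowed_rows = []
            for m, c in zip(masks, counts):
                s = sorted(decode_combination(int(m)))
                if len(s) > 1:
                    mid = np.mean(s)
                    extreme = max(s, key=lambda d: (abs(d - mid), d))
                    s = [d for d in s if d != extreme]
                narrowed_rows.append((set(s), int(c)))
            narrowed = self._row(narrowed_rows)
            v0 = scenario_similarity(self._matrix({("c", "current"): base}))[0].value
            v1 = scenario_similarity(self._matrix({("c", "current"): narrowed}))[0].value
            assert v1 >= v0 - 1e-12


def toy_matrix():
    rng = np.random.default_rng(2)
    return rng.poisson(5.0, size=(4, 6)).astype(float)


class TestRDA:
    def test_saturated_constraints_explain_everything(self):
        Y = toy_matrix()
        constraints = pd.DataFrame({"row": [f"r{i}" for i in range(4)]})
        res = rda(Y, constraints, n_perm=49, seed=0)
        assert res.constrained_fraction == pytest.approx(1.0)

    def test_constant_constraint_explains_nothing(self):
        Y = toy_matrix()
        constraints = pd.DataFrame({"flat": ["a"] * 4})
        res = rda(Y, constraints, n_perm=49, seed=0)
        assert res.constrained_fraction == 0.0

    def test_fraction_matches_hat_matrix_oracle(self):
        Y = toy_matrix()
        groups = ["a", "a", "b", "b"]
        constraints = pd.DataFrame({"g": groups})
        res = rda(Y, constraints, n_perm=9, seed=0)
        # oracle: explicit projection matrix on centered dummy design
        X = np.array([[1.0 if g == "b" else 0.0] for g in groups])
        X = X - X.mean(axis=0)
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        Yc = Y - Y.mean(axis=0)
        oracle = np.trace((H @ Yc) @ (H @ Yc).T) / np.trace(Yc @ Yc.T)
        assert res.constrained_fraction == pytest.approx(oracle)

    def test_aliased_levels_named(self):
        constraints = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "u", "v", "v"]}  # b aliases a
        )
        with pytest.raises(ValidationError, match="aliased"):
            rda(toy_matrix(), constraints, n_perm=9, seed=0)

    def test_permutation_p_detects_planted_structure(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(0, 1, size=(12, 8))
        Y[:6] += 4.0  # strong group difference
        constraints = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6})
        res = rda(Y, constraints, n_perm=199, seed=1)
        assert res.p_value <= 0.01


class TestSelection:
    def test_planted_factor_selected_among_noise(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(0, 1, size=(12, 10))
        Y[:6] += 3.0
        candidates = pd.DataFrame(
            {
                "signal": ["a"] * 6 + ["b"] * 6,
                "noise1": list(rng.choice(["u", "v"], 12)),
                "noise2": list(rng.choice(["p", "q"], 12)),
            }
        )
        selected = select_constraints(Y, candidates, n_perm=99, seed=0)
        assert selected == ["signal"]

    def test_all_noise_mostly_selects_nothing(self):
        rng = np.random.default_rng(11)
        empty = 0
        n_runs = 20
        for i in range(n_runs):
            Y = rng.normal(size=(10, 6))
            candidates = pd.DataFrame(
                {
                    "f1": list(rng.choice(["a", "b"], 10)),
                    "f2": list(rng.choice(["x", "y"], 10)),
                }
            )
            if not select_constraints(Y, candidates, n_perm=99, seed=i):
                empty += 1
        assert empty >= int(0.9 * n_runs) - 2  # ~type-I at alpha=0.05, two factors

    def test_saturated_factor_blocks_additions(self):
        Y = toy_matrix()
        candidates = pd.DataFrame(
            {"row": [f"r{i}" for i in range(4)], "g": ["a", "a", "b", "b"]}
        )
        selected = select_constraints(Y, candidates, n_perm=49, seed=0)
        assert "row" not in selected or len(selected) == 1
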