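from importlib import resources

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efmon.biomass import (
    ReferenceTable,
    estimate_mass,
    find_candidates,
    load_reference_table,
    region_of,
    wbf_mass_correlation,
)
from efmon.errors import ConfigError, ContractError, FormatError


def make_table(rows):
    df = pd.DataFrame(rows, columns=["taxon", "wbf_hz", "mass_mg", "in_europe", "obs_prob"])
    return ReferenceTable(df)


@pytest.fixture(scope="module")
def demo_table(tmp_path_factory):
    path = resources.files("efmon.data") / "reference_table_demo.csv"
    return load_reference_table(str(path))


class TestLoad:
    def test_packaged_fixture_loads(self, demo_table):
        assert len(demo_table) == 50
        counts = demo_table.region_counts()
        assert counts == {"dense": 40, "less_dense": 6, "sparse": 4}
        assert (demo_table.df["mass_mg"] > 0).all()

    def test_missing_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"taxon": ["a"], "wbf_hz": [100]}).to_csv(p, index=False)
        with pytest.raises(FormatError, match="missing columns"):
            load_reference_table(p)

    def test_zero_mass_rejected_with_row_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "taxon": ["a", "b"],
                "wbf_hz": [100, 200],
                "mass_mg": [5.0, 0.0],
                "in_europe": [True, True],
                "obs_prob": [1.0, 1.0],
            }
        ).to_csv(p, index=False)
        with pytest.raises(FormatError, match="row 2"):
            load_reference_table(p)


class TestRegionOf:
    @pytest.mark.parametrize(
        "wbf,region",
        [(240.0, "dense"), (100.0, "dense"), (240.01, "less_dense"),
         (300.0, "less_dense"), (340.0, "less_dense"), (340.01, "sparse"),
         (480.0, "sparse")],
    )
    def test_boundaries(self, wbf, region):
        assert region_of(wbf) == region

    def test_nonpositive_rejected(self):
        with pytest.raises(ContractError):
            region_of(0.0)


class TestFindCandidates:
    def _table(self):
        return make_table(
            [("a", 97.2, 3.0, True, 1.0), ("b", 103.0, 7.0, True, 1.0),
             ("c", 480.0, 2.0, True, 1.0)]
        )

    def test_exact_match_halfwidth_zero(self):
        cands, hw = find_candidates(103.0, 4.0, self._table())
        assert hw == 0.0
        assert list(cands["taxon"]) == ["b"]

    def test_expanding_window(self):
        # nearest entries at 2.8 and 3.0 Hz: both inside the closed
        # half-width-3.0 window, which is the first non-empty one
        cands, hw = find_candidates(100.0, 4.0, self._table())
        assert hw == pytest.approx(3.0)
        assert sorted(cands["taxon"]) == ["a", "b"]

    def test_cap_respected_empty_result(self):
        cands, hw = find_candidates(600.0, 4.0, self._table())
        assert len(cands) == 0
        assert hw <= max(10, 4.0) / 2

    def test_cap_grows_with_sigma(self):
        # entry 8 Hz away reachable only when sigma raises the cap
        table = make_table([("a", 108.0, 3.0, True, 1.0), ("s", 480.0, 2.0, True, 1.0)])
        empty, _ = find_candidates(100.0, 4.0, table)
        assert len(empty) == 0
        cands, hw = find_candidates(100.0, 16.1, table)
        assert list(cands["taxon"]) == ["a"]
        assert hw == pytest.approx(8.0)

    @given(mu=st.floats(30, 500), sigma=st.floats(0.5, 30))
    @settings(max_examples=50, deadline=None)
    def test_returned_halfwidth_is_minimal(self, mu, sigma):
        table = make_table(
            [(f"t{i}", w, 1.0, True, 1.0) for i, w in enumerate(range(40, 520, 17))]
        )
        cands, hw = find_candidates(mu, sigma, table)
        if len(cands) == 0:
            return
        if hw > 0:
            # one step tighter must be empty (minimality)
            dist = np.abs(table.df["wbf_hz"].to_numpy() - mu)
            assert not (dist <= hw - 0.5).any() or (dist < 0.01).any()
        dist = np.abs(cands["wbf_hz"].to_numpy() - mu)
        assert (dist <= max(hw, 0.01)).all()


class TestEstimateMass:
    def test_single_exact_candidate(self):
        table = make_table([("a", 123.0, 12.5, True, 1.0), ("s", 480.0, 2.0, True, 1.0)])
        est = estimate_mass(123.0, 2.0, table)
        assert est.mass_mg == 12.5
        assert est.method == "exact"

    def test_dense_median_fallback(self):
        rows = [(f"d{i}", 50.0 + i, m, True, 1.0)
                for i, m in enumerate([2, 5, 9, 20, 100])]
        rows.append(("s", 480.0, 2.0, True, 1.0))
        est = estimate_mass(200.0, 2.0, make_table(rows))
        assert est.mass_mg == 9.0
        assert est.method == "fallback_median"

    def test_less_dense_own_median_vs_flag(self):
        rows = [("d1", 100.0, 10.0, True, 1.0), ("d2", 110.0, 30.0, True, 1.0),
                ("l1", 250.0, 3.0, True, 1.0), ("l2", 252.0, 5.0, True, 1.0),
                ("s", 480.0, 2.0, True, 1.0)]
        table = make_table(rows)
        own = estimate_mass(300.0, 2.0, table)
        assert own.mass_mg == pytest.approx(4.0)  # median of less-dense masses
        dense = estimate_mass(300.0, 2.0, table, fallback_dense_median=True)
        assert dense.mass_mg == pytest.approx(20.0)

    def test_sparse_480_fallback(self):
        table = make_table([("m", 480.0, 2.4, True, 1.0)])
        est = estimate_mass(700.0, 2.0, table)
        assert est.mass_mg == 2.4
        assert est.method == "fallback_480"

    def test_sparse_fallback_without_480_entry_is_config_error(self):
        table = make_table([("d", 100.0, 5.0, True, 1.0)])
        with pytest.raises(ConfigError):
            estimate_mass(700.0, 2.0, table)

    def test_weighted_average_equal_probs(self):
        table = make_table([("a", 150.0, 10.0, True, 1.0), ("b", 150.2, 30.0, True, 1.0),
                            ("s", 480.0, 2.0, True, 1.0)])
        est = estimate_mass(150.1, 2.0, table)
        assert est.mass_mg == pytest.approx(20.0)
        assert est.method == "weighted"

    def test_weighted_average_obs_prob(self):
        table = make_table([("a", 150.0, 10.0, True, 0.75), ("b", 150.2, 30.0, True, 0.25),
                            ("s", 480.0, 2.0, True, 1.0)])
        est = estimate_mass(150.1, 2.0, table)
        assert est.mass_mg == pytest.approx(15.0)

    def test_europe_filter_to_zero(self):
        table = make_table([("a", 150.0, 10.0, False, 1.0), ("b", 150.2, 30.0, False, 1.0),
                            ("s", 480.0, 2.0, True, 1.0)])
        est = estimate_mass(150.1, 2.0, table)
        assert est.mass_mg == 0.0
        assert est.method == "zero"

    def test_europe_filter_to_single(self):
        table = make_table([("a", 150.0, 10.0, False, 1.0), ("b", 150.2, 30.0, True, 1.0),
                            ("s", 480.0, 2.0, True, 1.0)])
        est = estimate_mass(150.1, 2.0, table)
        assert est.mass_mg == 30.0
        assert est.n_candidates_initial == 2
        assert est.n_candidates_after_europe == 1

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_row_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        rows = [(f"t{i}", float(rng.uniform(30, 600)), float(rng.uniform(0.5, 50)),
                 bool(rng.random() < 0.7), 1.0) for i in range(12)]
        rows.append(("s", 480.0, 2.0, True, 1.0))
        mu, sigma = float(rng.uniform(30, 600)), float(rng.uniform(0.5, 10))
        a = estimate_mass(mu, sigma, make_table(rows))
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        b = estimate_mass(mu, sigma, make_table(shuffled))
        assert a.mass_mg == pytest.approx(b.mass_mg)
        assert a.method == b.method


class TestCorrelation:
    def test_perfect_negative_line(self):
        rows = [(f"t{i}", float(w), float(1000 - w), True, 1.0)
                for i, w in enumerate(range(50, 550, 50))]
        r, p = wbf_mass_correlation(make_table(rows))
        assert r == pytest.approx(-1.0)

    def test_shuffled_masses_near_zero(self):
        rng = np.random.default_rng(0)
        wbf = np.linspace(50, 500, 200)
        masses = rng.permutation(np.linspace(1, 100, 200))
        rows = [(f"t{i}", float(w), float(m), True, 1.0)
                for i, (w, m) in enumerate(zip(wbf, masses))]
        r, p = wbf_mass_correlation(make_table(rows))
        assert abs(r) < 0.2
        assert p > 0.01

    def test_too_few_entries(self):
        with pytest.raises(ContractError):
            wbf_mass_correlation(make_table([("a", 100, 5, True, 1.0)]))

    def test_constant_column(self):
        rows = [(f"t{i}", 100.0, float(m), True, 1.0) for i, m in enumerate((1, 2, 3))]
        with pytest.raises(ContractError):
            wbf_mass_correlation(make_table(rows))
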