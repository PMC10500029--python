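from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import nichecnn as nc
from nichecnn.enrichment import EnrichmentCounts
from nichecnn.neighborhoods import MultiCellInput


def counts_from_cells(types, in_nbhd, selected, image_id="i", sample_id="s", cond="c"):
    """Brute-force recount of the eight aggregates by explicit iteration."""
    types = list(types)
    per = {}
    for t, k, s in zip(types, in_nbhd, selected):
        d = per.setdefault(t, {"N_T": 0, "K_T": 0, "N_T_S": 0, "K_T_S": 0})
        d["N_T"] += 1
        d["K_T"] += int(k)
        d["N_T_S"] += int(s)
        d["K_T_S"] += int(k and s)
    pt = pd.DataFrame(per).T[["N_T", "K_T", "N_T_S", "K_T_S"]]
    ec = EnrichmentCounts(
        image_id=image_id, sample_id=sample_id, condition=cond,
        N=len(types), K=int(np.sum(in_nbhd)), N_S=int(np.sum(selected)),
        K_S=int(np.sum(np.asarray(in_nbhd) & np.asarray(selected))),
        per_type=pt,
    )
    ec.validate()
    return ec


def oracle_local_es(ec, t):
    if t not in ec.per_type.index:
        return None
    r = ec.per_type.loc[t]
    if ec.N == 0 or ec.N_S == 0 or r["N_T"] == 0 or ec.K == 0:
        return None
    E_T = Fraction(ec.K * int(r["N_T"]), ec.N)
    E_T_S_num = ec.K_S * int(r["N_T_S"])
    if E_T <= 0 or E_T_S_num == 0:
        return None
    E_T_S = Fraction(E_T_S_num, ec.N_S)
    S_T = Fraction(int(r["K_T"])) / E_T
    if S_T == 0:
        return None
    return float((Fraction(int(r["K_T_S"])) / E_T_S) / S_T)


def oracle_global_es(ec, t):
    if t not in ec.per_type.index:
        return None
    r = ec.per_type.loc[t]
    if ec.N == 0 or ec.N_S == 0 or r["N_T"] == 0:
        return None
    return float(Fraction(int(r["N_T_S"])) / (Fraction(ec.N_S * int(r["N_T"]), ec.N)))


HAND = counts_from_cells(
    # N=20, N_T=8, K=10, K_T=4, N^S=5, K^S=4, N_T^S=3, K_T^S=3
    types=["T"] * 8 + ["O"] * 12,
    in_nbhd=[1, 1, 1, 1, 0, 0, 0, 0] + [1] * 6 + [0] * 6,
    selected=[1, 1, 1, 0, 0, 0, 0, 0] + [1, 0, 0, 0, 0, 0] + [1, 0, 0, 0, 0, 0],
)


class TestLocalES:
    def test_hand_example_gives_1_25(self):
        assert HAND.N == 20 and HAND.K == 10 and HAND.N_S == 5 and HAND.K_S == 4
        r = HAND.per_type.loc["T"]
        assert (r["N_T"], r["K_T"], r["N_T_S"], r["K_T_S"]) == (8, 4, 3, 3)
        assert nc.local_es(HAND, "T") == pytest.approx(1.25, abs=1e-12)

    def test_type_neutral_selection_gives_unity(self):
        # selection uniform at 50% over neighborhood and image, K_T = E_T
        ec = counts_from_cells(
            types=["T", "T", "O", "O"] * 4,
            in_nbhd=[1, 0, 1, 0] * 4,
            selected=[1, 1, 0, 0] * 2 + [0, 0, 1, 1] * 2,
        )
        assert nc.local_es(ec, "T") == pytest.approx(1.0)

    def test_zero_selected_in_neighborhood_gives_zero(self):
        ec = counts_from_cells(
            types=["T", "T", "O", "O", "O", "O"],
            in_nbhd=[1, 0, 1, 1, 0, 0],
            selected=[0, 1, 1, 0, 1, 0],
        )
        assert nc.local_es(ec, "T") == 0.0

    def test_undefined_when_expectation_vanishes(self):
        ec = counts_from_cells(
            types=["T", "O", "O", "O"],
            in_nbhd=[0, 1, 1, 0],
            selected=[0, 1, 0, 0],
        )
        # N_T^S = 0 -> E_T^S = 0 -> undefined, a distinguished result
        assert nc.local_es(ec, "T") is None

    def test_matches_fraction_oracle_on_random_images(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(10, 120))
            types = rng.choice(list("ABCD"), size=n)
            in_nbhd = rng.random(n) < 0.4
            selected = rng.random(n) < rng.uniform(0.1, 0.9)
            ec = counts_from_cells(types, in_nbhd, selected)
            for t in "ABCD":
                got = nc.local_es(ec, t)
                expect = oracle_local_es(ec, t) if t in ec.per_type.index else None
                if expect is None:
                    assert got is None
                else:
                    assert got == pytest.approx(expect, abs=1e-12)


class TestGlobalES:
    def test_hand_example_gives_1_5(self):
        assert nc.global_es(HAND, "T") == pytest.approx(1.5, abs=1e-12)

    def test_select_everything_gives_unity_for_all_types(self):
        ec = counts_from_cells(
            types=["T", "T", "O", "B", "B", "B"],
            in_nbhd=[1, 0, 1, 0, 1, 0],
            selected=[1] * 6,
        )
        for t in "TOB":
            assert nc.global_es(ec, t) == pytest.approx(1.0)

    def test_algebraic_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(8, 80))
            types = rng.choice(list("AB"), size=n)
            selected = rng.random(n) < 0.5
            ec = counts_from_cells(types, rng.random(n) < 0.5, selected)
            for t in "AB":
                got = nc.global_es(ec, t)
                if got is None:
                    continue
                r = ec.per_type.loc[t]
                ident = (r["N_T_S"] / ec.N_S) / (r["N_T"] / ec.N)
                assert got == pytest.approx(ident, rel=1e-12)

    def test_duplication_invariance(self):
        types = ["T", "T", "O", "O", "O"]
        nb = [1, 0, 1, 0, 0]
        sel = [1, 0, 0, 1, 0]
        a = nc.global_es(counts_from_cells(types, nb, sel), "T")
        b = nc.global_es(counts_from_cells(types * 2, nb * 2, sel * 2), "T")
        assert a == pytest.approx(b, rel=1e-12)


class TestTabulate:
    def test_overlapping_neighborhoods_count_union(self, small_cohort):
        df = pd.DataFrame({
            "cell_id": range(12), "sample_id": ["s"] * 12, "image_id": ["i"] * 12,
            "x": np.arange(12) * 0.1, "y": np.zeros(12),
            "cell_type": ["T", "O"] * 6, "condition": ["c"] * 12,
            "m": np.linspace(-1, 1, 12),
        })
        t = nc.CellTable(df, ["m"])
        inputs = [
            MultiCellInput(np.zeros((3, 1)), np.array([0, 1, 2]), 5, "i", "s", "c"),
            MultiCellInput(np.zeros((3, 1)), np.array([2, 3, 4]), 6, "i", "s", "c"),
        ]
        sel = nc.SelectionResult(np.arange(12), df["m"].to_numpy(),
                                 df["m"].to_numpy() > 0, 0, 0.0, "all")
        counts = nc.tabulate_counts(t, sel, inputs)
        assert len(counts) == 1
        assert counts[0].K == 5  # union {0,1,2,3,4}, shared cell 2 once
        assert counts[0].N == 12

    def test_empty_selection_zeroes_superscripts(self, small_cohort, local_inputs):
        sel = nc.SelectionResult(
            small_cohort.df["cell_id"].to_numpy(),
            np.full(small_cohort.n_cells, -1.0),
            np.zeros(small_cohort.n_cells, bool), 0, 0.0, "all",
        )
        for ec in nc.tabulate_counts(small_cohort, sel, local_inputs):
            assert ec.N_S == 0 and ec.K_S == 0
            assert (ec.per_type[["N_T_S", "K_T_S"]] == 0).all().all()

    def test_invariants_hold_on_cohort(self, small_cohort, local_inputs):
        rng = np.random.default_rng(3)
        sel = nc.SelectionResult(
            small_cohort.df["cell_id"].to_numpy(),
            rng.normal(size=small_cohort.n_cells),
            rng.random(small_cohort.n_cells) < 0.3, 0, 0.0, "all",
        )
        counts = nc.tabulate_counts(small_cohort, sel, local_inputs)
        assert counts
        for ec in counts:
            ec.validate()  # sums and bound invariants


class TestAggregate:
    def test_median_and_mad(self):
        pie = pd.DataFrame({
            "sample_id": ["a", "b", "c"], "image_id": ["i1", "i2", "i3"],
            "condition": ["g"] * 3, "cell_type": ["T"] * 3, "es": [1.0, 2.0, 3.0],
        })
        out = nc.aggregate_es(pie)
        assert out.loc[0, "median_es"] == 2.0 and out.loc[0, "mad"] == 1.0

    def test_singleton(self):
        pie = pd.DataFrame({
            "sample_id": ["a"], "image_id": ["i"], "condition": ["g"],
            "cell_type": ["T"], "es": [1.7],
        })
        out = nc.aggregate_es(pie)
        assert out.loc[0, "median_es"] == 1.7 and out.loc[0, "mad"] == 0.0

    def test_undefined_excluded_and_counted(self):
        pie = pd.DataFrame({
            "sample_id": ["a", "a", "b"], "image_id": ["i1", "i2", "i3"],
            "condition": ["g"] * 3, "cell_type": ["T"] * 3,
            "es": [2.0, np.nan, np.nan],
        })
        out = nc.aggregate_es(pie)
        assert out.loc[0, "median_es"] == 2.0
        assert out.loc[0, "n_images_undefined"] == 2
        assert out.loc[0, "n_samples"] == 1

    def test_per_sample_reduction_is_median_over_images(self):
        pie = pd.DataFrame({
            "sample_id": ["a"] * 3 + ["b"], "image_id": list("wxyz"),
            "condition": ["g"] * 4, "cell_type": ["T"] * 4,
            "es": [1.0, 100.0, 2.0, 4.0],
        })
        out = nc.aggregate_es(pie)
        # sample a reduces to median(1,100,2)=2, cohort median(2,4)=3
        assert out.loc[0, "median_es"] == 3.0
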