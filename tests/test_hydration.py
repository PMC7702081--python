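"""Subpopulation labels, retardation factors, Empirical-Rule classification,
and hydration-number bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aquadyn.hydration import (
    LABELS,
    SubpopulationLabel,
    bulk_reference_tau,
    classify_empirical_rule,
    empirical_rule_iterate,
    enumerate_labels,
    hydration_number,
    label_trajectory,
    label_waters,
    retardation_factors,
    subpopulation_taus,
)
from aquadyn.structure import ShellBoundaries
from aquadyn.traj_io import build_water_topology

from conftest import make_single_frame


class TestLabelEnumeration:
    def test_eighteen_labels(self):
        assert len(enumerate_labels()) == 18

    def test_fifteen_admissible(self):
        assert sum(lab.admissible for lab in enumerate_labels()) == 15

    def test_forbidden_set(self):
        forbidden = {lab.name for lab in enumerate_labels() if not lab.admissible}
        assert forbidden == {"W_11B", "W_21B", "W_B1B"}

    def test_names_unique(self):
        names = [lab.name for lab in enumerate_labels()]
        assert len(set(names)) == 18

    @given(
        a=st.sampled_from("12B"), b=st.sampled_from("12B"), c=st.sampled_from("12B")
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_hydrogen_order_is_canonical(self, a, b, c):
        lab1 = SubpopulationLabel.make(a, b, c)
        lab2 = SubpopulationLabel.make(a, c, b)
        assert lab1 == lab2
        assert lab1.name in {x.name for x in LABELS}


class TestLabelWaters:
    def _frame(self, o, h1, h2, ions):
        elements = ["O", "H", "H"] + [sp for sp, _ in ions]
        pos = np.vstack([o, h1, h2] + [p for _, p in ions])
        traj = make_single_frame(elements, pos, box=40.0)
        topo = build_water_topology(traj)
        return traj, topo

    def _labels(self, traj, topo):
        return label_waters(
            traj.positions[0], topo, traj.cell[0], "Mg", "Cl",
            ShellBoundaries(3.0, 5.0), ShellBoundaries(2.9, 5.0),
        )

    def test_first_shell_oxygen_far_hydrogens(self):
        traj, topo = self._frame(
            [10, 10, 10], [10.76, 10.59, 10], [9.24, 10.59, 10],
            [("Mg", [12, 10, 10]), ("Cl", [25, 25, 25])],
        )
        assert LABELS[self._labels(traj, topo)[0]].name == "W_1BB"

    def test_second_shell_oxygen_mixed_hydrogens(self):
        # O at 4 A from Mg (2nd shell); one H near Cl (1st), other farther (2nd)
        traj, topo = self._frame(
            [10.0, 10, 10], [10.96, 10, 10], [9.7, 10.7, 10],
            [("Mg", [6.0, 10, 10]), ("Cl", [13.3, 10, 10])],
        )
        assert LABELS[self._labels(traj, topo)[0]].name == "W_212"

    def test_no_ions_gives_bulk(self):
        traj, topo = self._frame(
            [10, 10, 10], [10.76, 10.59, 10], [9.24, 10.59, 10], []
        )
        assert LABELS[self._labels(traj, topo)[0]].name == "W_BBB"

    def test_populations_sum_to_water_count(self, designed_solution, designed_shells):
        _, traj, topo, _ = designed_solution
        cat_sh, an_sh = designed_shells
        labels = label_trajectory(traj, topo, "Mg", "Cl", cat_sh, an_sh)
        assert labels.shape == (traj.n_frames, topo.n_molecules)
        counts = np.apply_along_axis(np.bincount, 1, labels, minlength=18)
        np.testing.assert_array_equal(counts.sum(axis=1), topo.n_molecules)


class TestRetardation:
    def _table(self, f_values, pops=None, a=None):
        n = len(f_values)
        tau = np.asarray(f_values) * 5.0
        df = pd.DataFrame(
            {
                "label": [f"L{i}" for i in range(n)],
                "a": a if a is not None else ["B"] * n,
                "b": ["B"] * n,
                "c": ["B"] * n,
                "admissible": [True] * n,
                "population": pops if pops is not None else np.ones(n),
                "pop_sigma": np.zeros(n),
                "tau_ps": tau,
                "tau_sigma": np.zeros(n),
                "n_origins": np.full(n, 100),
                "class": [""] * n,
            }
        ).set_index("label")
        return retardation_factors(df, 5.0)

    def test_factor_of_one_for_bulk_tau(self):
        df = self._table([1.0, 1.0])
        assert np.allclose(df["f"], 1.0)

    def test_factor_scales_linearly(self):
        df = self._table([5.0])
        assert df["f"].iloc[0] == pytest.approx(5.0)

    def test_nonpositive_bulk_tau_rejected(self):
        df = self._table([1.0])
        with pytest.raises(ValueError):
            retardation_factors(df, 0.0)


class TestEmpiricalRule:
    def test_all_near_unity_is_all_bulk(self):
        rng = np.random.default_rng(2)
        f = 1.0 + 0.01 * rng.normal(size=8)
        tbl = TestRetardation()._table(f)
        out = classify_empirical_rule(tbl)
        assert (out["class"] == "bulk-like").all()

    def test_small_outlier_population_is_slow(self):
        # slow subpopulations are small; the population weighting lets the
        # iteration shed them from the bulk statistics
        f = [1.0, 1.01, 0.99, 1.02, 5.0]
        pops = [10.0, 10.0, 10.0, 10.0, 0.5]
        tbl = TestRetardation()._table(f, pops=pops)
        out = classify_empirical_rule(tbl)
        assert out["class"].iloc[-1] == "slow"
        assert (out["class"].iloc[:-1] == "bulk-like").all()

    def test_null_normal_coverage_near_997(self):
        """Retardation factors drawn from the bulk normal distribution are
        classified bulk-like with probability ~ 99.7% (3-sigma band)."""
        rng = np.random.default_rng(10)
        n = 100_000
        f = rng.normal(1.0, 0.05, size=n)
        bulk, _, _ = empirical_rule_iterate(
            f, np.ones(n), np.ones(n, dtype=bool), n_sigma=3.0
        )
        frac = bulk.mean()
        assert abs(frac - 0.997) < 0.05

    def test_deterministic_given_table(self):
        f = [1.0, 1.05, 0.95, 3.5]
        tbl = TestRetardation()._table(f)
        out1 = classify_empirical_rule(tbl)
        out2 = classify_empirical_rule(tbl)
        assert (out1["class"] == out2["class"]).all()

    def test_seed_excludes_first_shell_and_h1(self):
        # a slow first-shell label must not contaminate the seed statistics
        f = [1.0, 1.02, 0.98, 4.0]
        tbl = TestRetardation()._table(f, a=["B", "B", "B", "1"])
        out = classify_empirical_rule(tbl)
        assert out["class"].iloc[-1] == "slow"


class TestHydrationNumber:
    def _classified(self, pops, classes, a):
        n = len(pops)
        df = pd.DataFrame(
            {
                "label": [f"L{i}" for i in range(n)],
                "a": a,
                "b": ["B"] * n,
                "c": ["B"] * n,
                "admissible": [True] * n,
                "population": pops,
                "pop_sigma": np.zeros(n),
                "tau_ps": np.ones(n),
                "tau_sigma": np.zeros(n),
                "n_origins": np.full(n, 10),
                "class": classes,
            }
        ).set_index("label")
        return df

    def test_all_bulk_gives_zero(self):
        df = self._classified([10, 20], ["bulk-like", "bulk-like"], ["B", "B"])
        assert hydration_number(df, 2).h == 0.0

    def test_first_shell_beyond_split(self):
        df = self._classified(
            [6.0, 9.0, 100.0], ["slow", "slow", "bulk-like"], ["1", "B", "B"]
        )
        res = hydration_number(df, 1)
        assert res.h == pytest.approx(15.0)
        assert res.slow_first_shell == pytest.approx(6.0)
        assert res.slow_beyond == pytest.approx(9.0)

    def test_intensive_under_doubling(self):
        df1 = self._classified([6.0, 100.0], ["slow", "bulk-like"], ["1", "B"])
        df2 = self._classified([12.0, 200.0], ["slow", "bulk-like"], ["1", "B"])
        assert hydration_number(df1, 1).h == hydration_number(df2, 2).h

    def test_requires_classification(self):
        df = self._classified([1.0], ["bulk-like"], ["B"]).drop(columns=["class"])
        with pytest.raises(ValueError, match="classified"):
            hydration_number(df, 1)


class TestPipelineRecovery:
    def test_designed_h_recovered(self, designed_solution, designed_shells):
        """Full chain on a designed box: 6 slow first-shell + 9 slow beyond
        per salt unit, recovered within one water."""
        spec, traj, topo, truth = designed_solution
        cat_sh, an_sh = designed_shells
        labels = label_trajectory(traj, topo, "Mg", "Cl", cat_sh, an_sh)
        table = subpopulation_taus(traj, topo, labels, window=16.0, fit_start=0.0)
        bulk_tau = bulk_reference_tau(table)
        table = retardation_factors(table, bulk_tau)
        table = classify_empirical_rule(table)
        res = hydration_number(table, truth["n_salt_units"], bulk_tau=bulk_tau)
        assert res.h == pytest.approx(truth["designed_h"], abs=1.0)
        assert res.slow_first_shell == pytest.approx(
            truth["slow_first_per_salt"], abs=0.5
        )
        # designed slow classes show retardation factors well above bulk
        slow_f = table.loc[table["class"] == "slow", "f"]
        assert (slow_f > 2).all()

    def test_all_identical_dynamics_classifies_bulk(self, designed_shells):
        from aquadyn.synthetic import SyntheticSolutionSpec, gen_rotational_trajectory

        spec = SyntheticSolutionSpec(
            n_waters=60, n_frames=400, dt=0.02, seed=3,
            cation_shell_occupancy=4, anion_shell_occupancy=(2, 2),
            D_by_class={"slow_first": 0.1, "slow_beyond": 0.1, "bulk": 0.1},
        )
        traj, topo, _ = gen_rotational_trajectory(spec)
        cat_sh, an_sh = designed_shells
        labels = label_trajectory(traj, topo, "Mg", "Cl", cat_sh, an_sh)
        table = subpopulation_taus(traj, topo, labels, window=6.0, fit_start=0.0)
        bulk_tau = bulk_reference_tau(table)
        table = retardation_factors(table, bulk_tau)
        table = classify_empirical_rule(table)
        # identical dynamics: every subpopulation with a meaningful
        # population (>= 1 water on average) is bulk-like, and whatever is
        # misclassified from sparsely-populated labels stays below the
        # one-water recovery tolerance
        solid = (table["class"] != "empty") & (table["population"] >= 1.0)
        assert (table.loc[solid, "class"] == "bulk-like").all()
        res = hydration_number(table, 1, bulk_tau=bulk_tau)
        assert res.h < 1.0
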