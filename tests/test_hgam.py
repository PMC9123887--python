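"""Grouped-model family and posterior smooth-difference contrasts."""

import numpy as np
import pandas as pd
import pytest

import whistlegam as wg
from whistlegam import gam, hgam
from whistlegam.errors import ValidationError


def _base_spec():
    return gam.ModelSpec(
        "y",
        smooths=[
            gam.BasisSpec("cyclic", ("hour",), k=8, period=(0, 24)),
            gam.BasisSpec("cubic", ("x",), k=6),
        ],
        linear=["effort"],
    )


def _two_group_data(seed=0, n=400, amp_a=1.0, amp_b=1.0, phase_b=5.0):
    rng = np.random.default_rng(seed)
    hour = rng.uniform(0, 24, n)
    grp = np.where(rng.uniform(size=n) < 0.5, "A", "B")
    x = rng.uniform(0, 10, n)
    fa = amp_a * np.cos(2 * np.pi * (hour - 5.0) / 24)
    fb = amp_b * np.cos(2 * np.pi * (hour - phase_b) / 24)
    eta = -0.1 + np.where(grp == "A", fa, fb) + 0.05 * (x - 5)
    return pd.DataFrame(
        {"y": rng.poisson(np.exp(eta)), "hour": hour, "x": x, "effort": 60.0, "cluster": grp}
    )


class TestBuildGrouped:
    def test_variant_g_is_base(self):
        base = _base_spec()
        g = hgam.build_grouped(base, "hour", "cluster", "G")
        assert [s.label for s in g.smooths] == [s.label for s in base.smooths]
        assert g.linear == base.linear

    def test_variant_i_penalty_per_group(self):
        df = _two_group_data()
        df["cluster"] = np.random.default_rng(0).choice(["a", "b", "c"], len(df))
        spec = hgam.build_grouped(_base_spec(), "hour", "cluster", "I")
        grouped = [s for s in spec.smooths if s.by_group == "cluster"][0]
        _, pens = wg.build_basis(grouped, df)
        assert len(pens) == 3  # one penalty block per cluster
        shared = [s for s in hgam.build_grouped(_base_spec(), "hour", "cluster", "S").smooths
                  if s.by_group][0]
        _, pens_s = wg.build_basis(shared, df)
        assert len(pens_s) == 1

    def test_gs_adds_global_smooth_and_gi_first_derivative(self):
        gs = hgam.build_grouped(_base_spec(), "hour", "cluster", "GS")
        gi = hgam.build_grouped(_base_spec(), "hour", "cluster", "GI")
        assert any(s.by_group is None and s.variables == ("hour",) for s in gs.smooths)
        glob = [s for s in gi.smooths if s.by_group is None and s.variables == ("hour",)][0]
        assert glob.penalty_order == 1

    def test_cluster_factor_added_once(self):
        spec = hgam.build_grouped(_base_spec(), "hour", "cluster", "S")
        assert spec.linear.count("cluster") == 1

    def test_sixteen_model_enumeration(self):
        base = gam.ModelSpec(
            "y",
            smooths=[
                gam.BasisSpec("cyclic", ("hour",), k=8, period=(0, 24)),
                gam.BasisSpec("cyclic", ("moon",), k=8, period=(0, 1)),
                gam.BasisSpec("thinplate", ("sst",), k=8),
                gam.BasisSpec("cubic", ("tide",), k=6),
            ],
            linear=["effort"],
        )
        fam = hgam.enumerate_grouped(base, ["hour", "moon", "sst", "tide"], "cluster")
        assert len(fam) == 16
        assert {(g.grouped_variable, g.variant) for g in fam} == {
            (v, var) for v in ("hour", "moon", "sst", "tide") for var in ("GS", "S", "GI", "I")
        }

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValidationError):
            hgam.build_grouped(_base_spec(), "hour", "cluster", "Z")


class TestCompareGrouped:
    def test_identical_fit_zero_delta_even_weights(self):
        df = _two_group_data(1)
        spec = gam.ModelSpec("y", smooths=[gam.BasisSpec("cyclic", ("hour",), k=6, period=(0, 24))])
        f = wg.fit(spec, df, lambdas=np.array([1.0]))
        comp = hgam.compare_grouped(f, {("hour", "S"): f})
        row = comp[comp["variant"] == "S"].iloc[0]
        assert row["delta_aic"] == pytest.approx(0.0)
        assert row["weight_row"] == pytest.approx(0.5)

    def test_mismatched_data_rejected(self):
        d1, d2 = _two_group_data(1), _two_group_data(2)
        spec = gam.ModelSpec("y", smooths=[gam.BasisSpec("cyclic", ("hour",), k=6, period=(0, 24))])
        f1 = wg.fit(spec, d1, lambdas=np.array([1.0]))
        f2 = wg.fit(spec, d2, lambdas=np.array([1.0]))
        with pytest.raises(ValidationError):
            hgam.compare_grouped(f1, {("hour", "S"): f2})

    def test_single_level_grouping_reproduces_global(self):
        """With one cluster level the factor-smooth design collapses to the
        global design: identical predictions at fixed λ."""
        df = _two_group_data(3)
        df["cluster"] = "only"
        spec_g = gam.ModelSpec("y", smooths=[gam.BasisSpec("cyclic", ("hour",), k=8, period=(0, 24))])
        spec_s = hgam.build_grouped(spec_g, "hour", "cluster", "S")
        fg = wg.fit(spec_g, df, lambdas=np.array([2.0]))
        fs = wg.fit(spec_s, df, lambdas=np.array([2.0]))
        assert np.allclose(fg.predict(df), fs.predict(df), atol=1e-6)


@pytest.fixture(scope="module")
def fit_s():
    df = _two_group_data(0, n=600, amp_a=1.2, amp_b=0.5, phase_b=14.0)
    spec = hgam.build_grouped(
        gam.ModelSpec("y", smooths=[gam.BasisSpec("cyclic", ("hour",), k=8, period=(0, 24))]),
        "hour", "cluster", "S",
    )
    return wg.fit(spec, df)


class TestSmoothDifference:

    def test_self_contrast_is_identically_zero(self, fit_s):
        # differencing a group's prediction rows against themselves cancels
        # exactly, so both the contrast and its variance vanish
        term = next(t.label for t in fit_s.design.terms)
        c = hgam.smooth_difference(fit_s, term, "A", "A")
        assert np.allclose(c.difference, 0.0)
        assert np.allclose(c.se, 0.0)
        assert c.significant_intervals == []

    def test_antisymmetry_exact(self, fit_s):
        term = next(t.label for t in fit_s.design.terms)
        ab = hgam.smooth_difference(fit_s, term, "A", "B")
        ba = hgam.smooth_difference(fit_s, term, "B", "A")
        assert np.allclose(ab.difference, -ba.difference, atol=1e-12)
        assert np.allclose(ab.se, ba.se, atol=1e-12)

    def test_transitivity_over_three_groups(self):
        df = _two_group_data(5, n=600)
        rng = np.random.default_rng(5)
        df["cluster"] = rng.choice(["A", "B", "C"], len(df))
        spec = hgam.build_grouped(
            gam.ModelSpec("y", smooths=[gam.BasisSpec("cyclic", ("hour",), k=6, period=(0, 24))]),
            "hour", "cluster", "I",
        )
        f = wg.fit(spec, df, maxfev=120)
        term = next(t.label for t in f.design.terms if t.spec.by_group)
        ac = hgam.smooth_difference(f, term, "A", "C").difference
        ab = hgam.smooth_difference(f, term, "A", "B").difference
        bc = hgam.smooth_difference(f, term, "B", "C").difference
        assert np.allclose(ac, ab + bc, atol=1e-10)

    def test_detects_known_shape_difference(self, fit_s):
        term = next(t.label for t in fit_s.design.terms)
        c = hgam.smooth_difference(fit_s, term, "A", "B")
        assert c.significant_intervals  # amplitudes/phases differ strongly

    def test_ungrouped_term_rejected(self):
        df = _two_group_data(1)
        f = wg.fit(
            gam.ModelSpec("y", smooths=[gam.BasisSpec("cyclic", ("hour",), k=6, period=(0, 24))]),
            df, lambdas=np.array([1.0]),
        )
        with pytest.raises(ValidationError):
            hgam.smooth_difference(f, "s(hour)", "A", "B")

    def test_null_groups_rarely_flagged(self):
        """No true group difference: ≤10% of grid points flagged at the 95%
        pointwise level (averaged over seeded replicates)."""
        fracs = []
        for seed in range(10):
            df = _two_group_data(100 + seed, n=500, amp_a=0.8, amp_b=0.8)
            spec = hgam.build_grouped(
                gam.ModelSpec("y", smooths=[gam.BasisSpec("cyclic", ("hour",), k=6, period=(0, 24))]),
                "hour", "cluster", "S",
            )
            f = wg.fit(spec, df, maxfev=80)
            term = next(t.label for t in f.design.terms if t.spec.by_group)
            c = hgam.smooth_difference(f, term, "A", "B", n_grid=96)
            flagged = sum(1 for lo, hi in zip(c.lower, c.upper) if lo > 0 or hi < 0)
            fracs.append(flagged / 96)
        assert np.mean(fracs) <= 0.10
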