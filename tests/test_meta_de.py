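"""Z-scoring, per-donor effects, DL pooling, BH, and the bootstrap."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stressmap as sm
from stressmap.meta_de import _dl_pool_arrays

from oracles import bh_oracle, dl_oracle


def _expr(values, donor="d1", standardized=False):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return sm.DonorExpression(
        donor_id=donor,
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{i}" for i in range(values.shape[1])],
        values=values,
        standardized=standardized,
    )


class TestZscore:
    def test_closed_form(self):
        z = sm.zscore_by_donor(_expr([[1.0, 2.0, 3.0]]), ["s0", "s1", "s2"])
        np.testing.assert_allclose(z.values, [[-1.0, 0.0, 1.0]])
        assert z.standardized

    def test_constant_gene_flagged(self):
        z = sm.zscore_by_donor(_expr([[5.0, 5.0, 5.0]]), ["s0", "s1", "s2"])
        np.testing.assert_array_equal(z.values, [[0.0, 0.0, 0.0]])
        assert z.constant_genes == ("g0",)

    def test_scope_too_small(self):
        with pytest.raises(ValueError):
            sm.zscore_by_donor(_expr([[1.0, 2.0]]), ["s0"])

    def test_moments_on_synthetic_donor(self, small_planted):
        _, donors, *_ = small_planted
        d = donors[0]
        z = sm.zscore_by_donor(d, d.sample_ids)
        assert np.abs(z.values.mean(axis=1)).max() < 1e-10
        assert np.abs(z.values.std(axis=1, ddof=1) - 1).max() < 1e-10


class TestDonorEffect:
    def test_simple_shift(self):
        e = sm.donor_effect(
            _expr([[1.0, 1.0, 0.0, 0.0]], standardized=True), ["s0", "s1"], ["s2", "s3"], "g0"
        )
        assert e.y == 1.0 and e.v == 0.0

    def test_symmetry_identical_groups(self):
        e = sm.donor_effect(
            _expr([[2.0, 3.0, 2.0, 3.0]], standardized=True), ["s0", "s1"], ["s2", "s3"], "g0"
        )
        assert e.y == 0.0

    def test_hand_computed_variance(self):
        # in=(0,2), out=(1,1,1,1): y = 1-1 = 0, v = 2/2 + 0/4 = 1
        e = sm.donor_effect(
            _expr([[0.0, 2.0, 1.0, 1.0, 1.0, 1.0]], standardized=True),
            ["s0", "s1"],
            ["s2", "s3", "s4", "s5"],
            "g0",
        )
        assert e.y == 0.0 and e.v == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            sm.donor_effect(_expr([[1.0, 2.0, 3.0]], standardized=True), ["s0"], ["s1", "s2"], "g0")


def _effects(y, v):
    return [
        sm.GeneEffect(gene_id="g", donor_id=f"d{i}", y=yy, v=vv, n_in=5, n_out=5)
        for i, (yy, vv) in enumerate(zip(y, v))
    ]


class TestDLMeta:
    def test_single_study(self):
        r = sm.dl_meta(_effects([0.5], [0.04]))
        assert r.mu_hat == 0.5 and r.tau2 == 0.0
        assert r.se == pytest.approx(0.2)

    def test_homogeneous_effects(self):
        r = sm.dl_meta(_effects([0.3, 0.3, 0.3], [0.1, 0.02, 0.5]))
        assert r.tau2 == 0.0 and r.q_stat == pytest.approx(0.0, abs=1e-14)
        assert r.mu_hat == pytest.approx(0.3)

    def test_against_step_by_step_oracle(self):
        y, v = [0.5, 0.3, 0.7], [0.04, 0.09, 0.01]
        r = sm.dl_meta(_effects(y, v))
        o = dl_oracle(y, v)
        for got, want in (
            (r.mu_hat, o["mu"]),
            (r.se, o["se"]),
            (r.tau2, o["tau2"]),
            (r.q_stat, o["q"]),
            (r.p, o["p"]),
            (r.ci_lo, o["ci_lo"]),
            (r.ci_hi, o["ci_hi"]),
        ):
            assert got == pytest.approx(want, abs=1e-10)

    def test_against_metafor_reference(self):
        # frozen rma(method="DL") outputs from the metafor R package;
        # agreement limited by the 7-digit printed precision of the inputs
        cases = [
            ([1.065339, 0.7779678], [0.1086282, 0.1499518],
             (0.944615515967, 0.250986111753, 0.0, 0.319367194497)),
            ([0.5021342, 0.2469377, 1.055761], [0.09783564, 0.1886028, 0.195863],
             (0.573563404054, 0.220171495832, 0.0, 1.804934521984)),
            ([0.268643, 0.9524348, 1.443323, -0.3944304, 0.1606056],
             [0.09492423, 0.1688408, 0.1501432, 0.1641005, 0.08374057],
             (0.471180668919, 0.293980252946, 0.302813784870, 13.738082134575)),
            ([0.7828764, -0.1072855, 0.4419789, 0.2191507],
             [0.1949726, 0.09203274, 0.1919396, 0.1786734],
             (0.239517890730, 0.194557319925, 0.001919671613, 3.036921505923)),
        ]
        for y, v, (mu, se, tau2, q) in cases:
            r = sm.dl_meta(_effects(y, v))
            assert r.mu_hat == pytest.approx(mu, abs=1e-5)
            assert r.se == pytest.approx(se, abs=1e-5)
            assert r.tau2 == pytest.approx(tau2, abs=1e-5)
            assert r.q_stat == pytest.approx(q, abs=1e-4)

    @given(
        st.lists(
            st.tuples(
                st.floats(-2, 2, allow_nan=False),
                st.floats(0.001, 1.0, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_pooled_effect_is_convex_combination(self, pairs):
        y = [p[0] for p in pairs]
        v = [p[1] for p in pairs]
        r = sm.dl_meta(_effects(y, v))
        assert min(y) - 1e-12 <= r.mu_hat <= max(y) + 1e-12
        assert r.tau2 >= 0.0
        assert r.ci_lo <= r.mu_hat <= r.ci_hi

    def test_tau2_invariant_to_donor_relabeling(self, rng):
        y = list(rng.normal(0, 1, 6))
        v = list(rng.uniform(0.01, 0.5, 6))
        r1 = sm.dl_meta(_effects(y, v))
        perm = rng.permutation(6)
        r2 = sm.dl_meta(_effects([y[i] for i in perm], [v[i] for i in perm]))
        assert r1.tau2 == pytest.approx(r2.tau2, abs=1e-12)
        assert r1.mu_hat == pytest.approx(r2.mu_hat, abs=1e-12)

    def test_equal_variances_mean_when_homogeneous(self):
        # Q <= k-1 forces tau2 = 0; equal v then weighs donors equally
        y = [0.10, 0.12, 0.11, 0.09]
        r = sm.dl_meta(_effects(y, [0.3] * 4))
        assert r.tau2 == 0.0
        assert r.mu_hat == pytest.approx(np.mean(y), abs=1e-12)

    def test_zero_variance_floored(self):
        r = sm.dl_meta(_effects([1.0, 1.0], [0.0, 0.0]))
        assert np.isfinite(r.se) and r.mu_hat == pytest.approx(1.0)

    def test_mixed_gene_ids_rejected(self):
        effs = [
            sm.GeneEffect(gene_id="g1", donor_id="d1", y=0.1, v=0.1, n_in=3, n_out=3),
            sm.GeneEffect(gene_id="g2", donor_id="d2", y=0.1, v=0.1, n_in=3, n_out=3),
        ]
        with pytest.raises(ValueError):
            sm.dl_meta(effs)


class TestBH:
    def test_closed_form(self):
        np.testing.assert_allclose(sm.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert sm.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 100))
            np.testing.assert_allclose(sm.bh_adjust(p), bh_oracle(list(p)), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sm.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_never_decreases_and_preserves_ranking(self, p):
        adj = sm.bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestRunDE:
    def test_duplicated_donor_equals_single_donor_effect(self):
        vals = np.array([[0.0, 1.0, 5.0, 4.0, 4.5, 5.5]])
        rows = []
        donors = []
        for donor in ("d1", "d2"):
            donors.append(
                sm.DonorExpression(
                    donor_id=donor,
                    gene_ids=["g0"],
                    sample_ids=[f"{donor}_s{i}" for i in range(6)],
                    values=vals,
                )
            )
            for i in range(6):
                rows.append((f"{donor}_s{i}", donor, i >= 4, "cortex", True))
        membership = pd.DataFrame(
            rows, columns=["sample_id", "donor_id", "in_network", "structure", "is_cortex"]
        )
        de = sm.run_de(donors, membership, sm.ContrastSpec("cortex"))
        z = sm.zscore_by_donor(donors[0], donors[0].sample_ids)
        single = sm.donor_effect(
            z, ["d1_s4", "d1_s5"], ["d1_s0", "d1_s1", "d1_s2", "d1_s3"], "g0"
        )
        assert de["mu_hat"].iloc[0] == pytest.approx(single.y, abs=1e-12)
        assert de["k"].iloc[0] == 2

    def test_planted_recovery_small(self, small_planted):
        _, donors, _, truth, _, membership = small_planted
        de = sm.run_de(donors, membership, sm.ContrastSpec("cortex"))
        planted = set(truth.planted_genes)
        sig = set(de.loc[de["significant"], "gene_id"])
        sensitivity = len(sig & planted) / len(planted)
        assert sensitivity >= 0.9
        # z-scoring attenuates the planted shift slightly (the shift itself
        # inflates the per-gene sd), so compare with a tolerant band
        mu_planted = de[de["gene_id"].isin(planted)]["mu_hat"].mean()
        assert mu_planted == pytest.approx(1.2, abs=0.2)

    def test_whole_brain_scope_applies_lfc_rule(self, small_planted):
        _, donors, _, _, _, membership = small_planted
        de = sm.run_de(
            donors, membership, sm.ContrastSpec("whole_brain_minus_cerebellum")
        )
        sig = de[de["significant"]]
        assert (sig["log2fc"].abs() > 1.0).all()
        assert (sig["p_bh"] < 0.05).all()

    def test_gene_order_preserved(self, small_planted):
        _, donors, _, _, _, membership = small_planted
        de = sm.run_de(donors, membership)
        assert list(de["gene_id"]) == donors[0].gene_ids


class TestSummarizeDirection:
    def test_positive_only_fixture_has_no_downregulated(self, small_planted):
        # strict alpha makes a BH false discovery (the only source of a
        # negative call under positive planted effects) vanishingly unlikely
        _, donors, _, _, _, membership = small_planted
        de = sm.run_de(donors, membership, alpha=0.005)
        n_up, n_down, n_sig = sm.summarize_direction(de)
        assert n_down == 0 and n_up == n_sig and n_sig > 0

    def test_null_fixture_mostly_empty(self, small_null):
        _, donors, _, _, _, membership = small_null
        de = sm.run_de(donors, membership)
        n_up, n_down, n_sig = sm.summarize_direction(de)
        assert n_up + n_down == n_sig


class TestBootstrap:
    def test_zero_iterations_empty_report(self, small_planted):
        _, donors, _, _, _, membership = small_planted
        rep = sm.bootstrap_stability(donors, membership, [], B=0, n_resample=10, seed=1)
        assert rep.per_gene_frequency == {} and rep.per_iteration_overlap == []
        assert rep.fraction_iterations_with_overlap == 0.0

    def test_fixed_seed_reproducible(self, small_planted):
        _, donors, _, _, _, membership = small_planted
        r1 = sm.bootstrap_stability(donors, membership, ["G00001"], B=5, n_resample=20, seed=42)
        r2 = sm.bootstrap_stability(donors, membership, ["G00001"], B=5, n_resample=20, seed=42)
        assert dataclasses.asdict(r1) == dataclasses.asdict(r2)

    def test_oversized_resample_rejected(self, small_planted):
        _, donors, _, _, _, membership = small_planted
        with pytest.raises(ValueError):
            sm.bootstrap_stability(donors, membership, [], B=1, n_resample=10**6, seed=1)


class TestLeaveOneDonorOut:
    def test_identical_donors_leave_mu_unchanged(self):
        vals = np.array([[0.0, 1.0, 5.0, 4.0, 4.5, 5.5]])
        donors, rows = [], []
        for donor in ("d1", "d2", "d3"):
            donors.append(
                sm.DonorExpression(
                    donor_id=donor,
                    gene_ids=["g0"],
                    sample_ids=[f"{donor}_s{i}" for i in range(6)],
                    values=vals,
                )
            )
            for i in range(6):
                rows.append((f"{donor}_s{i}", donor, i >= 4, "cortex", True))
        membership = pd.DataFrame(
            rows, columns=["sample_id", "donor_id", "in_network", "structure", "is_cortex"]
        )
        lodo = sm.leave_one_donor_out(donors, membership)
        assert np.abs(lodo["delta_mu"]).max() < 1e-12
        assert not lodo["flipped"].any()

    def test_outlier_donor_produces_largest_shift(self, small_planted):
        cfg, donors, samples, truth, mask, membership = small_planted
        shifted = []
        for d in donors:
            if d.donor_id == "donor1":
                in_ids = set(
                    membership.loc[
                        (membership["donor_id"] == "donor1") & membership["in_network"],
                        "sample_id",
                    ]
                )
                cols = [i for i, s in enumerate(d.sample_ids) if s in in_ids]
                vals = d.values.copy()
                vals[:, cols] += 3.0  # strong donor-specific in-network shift
                shifted.append(
                    sm.DonorExpression(d.donor_id, d.gene_ids, d.sample_ids, vals)
                )
            else:
                shifted.append(d)
        lodo = sm.leave_one_donor_out(shifted, membership)
        med = lodo.groupby("excluded_donor")["delta_mu"].apply(lambda s: s.abs().median())
        assert med.idxmax() == "donor1"

    def test_requires_two_donors(self, small_planted):
        _, donors, _, _, _, membership = small_planted
        with pytest.raises(ValueError):
            sm.leave_one_donor_out(donors[:1], membership)


class TestVectorizedPooling:
    def test_matches_scalar_oracle_with_missing_donors(self, rng):
        G, k = 50, 6
        Y = rng.normal(0, 1, (G, k))
        V = rng.uniform(0.01, 0.5, (G, k))
        drop = rng.random((G, k)) < 0.2
        drop[:, 0] = False  # keep >= 1 donor per gene
        Y[drop] = np.nan
        V[drop] = np.nan
        out = _dl_pool_arrays(Y, V)
        for g in range(G):
            ys = [y for y, d in zip(Y[g], drop[g]) if not d]
            vs = [v for v, d in zip(V[g], drop[g]) if not d]
            o = dl_oracle(ys, vs)
            assert out["mu_hat"][g] == pytest.approx(o["mu"], abs=1e-10)
            assert out["tau2"][g] == pytest.approx(o["tau2"], abs=1e-10)
            assert out["se"][g] == pytest.approx(o["se"], abs=1e-10)
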