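"""Pedigree algebra, BLUP, EM-REML and EBV deregression."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdgen.animal_model import (
    ModelSpec,
    PedigreeCycleError,
    PedigreeTable,
    VarianceComponents,
    deregress_ebv,
    em_reml_direct,
    pedigree_inbreeding_and_ainv,
    relationship_matrix,
    solve_mme,
)


def tabular_a(ped: PedigreeTable) -> np.ndarray:
    """Independent tabular-method oracle for the relationship matrix."""
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        A[i, i] = 1.0 + (0.5 * A[s[i], d[i]] if s[i] >= 0 and d[i] >= 0 else 0.0)
        for j in range(i):
            A[i, j] = A[j, i] = sum(
                0.5 * A[j, p] for p in (s[i], d[i]) if p >= 0
            )
    return A


class TestPedigree:
    def test_unrelated_founders_identity(self):
        ped = PedigreeTable(
            pd.DataFrame({"animal": ["a", "b", "c"], "sire": "0", "dam": "0"})
        )
        F, ainv = pedigree_inbreeding_and_ainv(ped)
        assert (F == 0).all()
        np.testing.assert_allclose(ainv.toarray(), np.eye(3))

    def test_full_sib_mating_offspring_f(self, toy_pedigree):
        F, _ = pedigree_inbreeding_and_ainv(toy_pedigree)
        assert F["e"] == pytest.approx(0.25)   # parents are full sibs
        assert F["c"] == 0 and F["d"] == 0

    def test_ainverse_matches_dense_inverse_oracle(self, toy_pedigree):
        _, ainv = pedigree_inbreeding_and_ainv(toy_pedigree)
        A = tabular_a(toy_pedigree)
        np.testing.assert_allclose(ainv.toarray(), np.linalg.inv(A), atol=1e-10)

    def test_ainverse_on_deeper_inbred_pedigree(self):
        rows = [("f1", "0", "0"), ("f2", "0", "0"), ("f3", "0", "0")]
        rows += [("x1", "f1", "f2"), ("x2", "f1", "f2"), ("x3", "f1", "f3")]
        rows += [("y1", "x1", "x2"), ("y2", "x1", "x3")]   # y1 inbred
        rows += [("z1", "y1", "y2"), ("z2", "y1", "x3")]
        ped = PedigreeTable(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))
        _, ainv = pedigree_inbreeding_and_ainv(ped)
        A = tabular_a(ped)
        np.testing.assert_allclose(ainv.toarray(), np.linalg.inv(A), atol=1e-10)
        np.testing.assert_allclose(relationship_matrix(ped), A, atol=1e-12)

    def test_cycle_detected(self):
        df = pd.DataFrame(
            {"animal": ["a", "b"], "sire": ["b", "a"], "dam": ["0", "0"]}
        )
        with pytest.raises(PedigreeCycleError, match="cycle"):
            PedigreeTable(df)

    def test_out_of_order_records_sorted(self):
        df = pd.DataFrame(
            {"animal": ["c", "a", "b"], "sire": ["a", "0", "0"], "dam": ["b", "0", "0"]}
        )
        ped = PedigreeTable(df)
        assert ped.animals.index("c") > ped.animals.index("a")
        assert ped.animals.index("c") > ped.animals.index("b")


class TestSolveMme:
    def _toy(self, toy_pedigree):
        rec = pd.DataFrame(
            {"animal": list("abcde"), "y": [1.0, 2.0, 1.5, 2.5, 3.0]}
        )
        return rec, toy_pedigree

    def test_matches_gls_oracle(self, toy_pedigree):
        rec, ped = self._toy(toy_pedigree)
        vc = VarianceComponents(sigma2_a=2.0, sigma2_e=1.0)
        res = solve_mme(ModelSpec(trait="y"), rec, ped, vc)
        A = tabular_a(ped)
        X = np.ones((5, 1))
        y = rec["y"].to_numpy()
        V = A * 2.0 + np.eye(5)
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        a = 2.0 * A @ Vi @ (y - X @ b)
        assert res.fixed_effects.iloc[0] == pytest.approx(b[0], abs=1e-8)
        np.testing.assert_allclose(res.ebv.to_numpy(), a, atol=1e-8)

    def test_shrinkage_limit_small_genetic_variance(self, toy_pedigree):
        rec, ped = self._toy(toy_pedigree)
        vc = VarianceComponents(sigma2_a=1e-10, sigma2_e=1.0)
        res = solve_mme(ModelSpec(trait="y"), rec, ped, vc)
        assert np.abs(res.ebv.to_numpy()).max() < 1e-6
        assert res.fixed_effects.iloc[0] == pytest.approx(np.mean(rec["y"]), abs=1e-6)

    def test_pev_and_reliability_ranges(self, toy_pedigree):
        rec, ped = self._toy(toy_pedigree)
        vc = VarianceComponents(sigma2_a=2.0, sigma2_e=1.0)
        res = solve_mme(ModelSpec(trait="y"), rec, ped, vc)
        assert (res.pev >= 0).all()
        assert res.reliability.between(0, 1).all()

    def test_maternal_model_matches_dense_joint_oracle(self):
        # direct + maternal with negative covariance, vs explicit GLS on V
        rows = [("s1", "0", "0"), ("d1", "0", "0"), ("d2", "0", "0")]
        rows += [(f"o{k}", "s1", f"d{1 + k % 2}") for k in range(6)]
        ped = PedigreeTable(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))
        rng = np.random.default_rng(0)
        rec = pd.DataFrame(
            {
                "animal": [f"o{k}" for k in range(6)],
                "dam": [f"d{1 + k % 2}" for k in range(6)],
                "y": rng.normal(10, 2, 6),
            }
        )
        vc = VarianceComponents(
            sigma2_a=1.0, sigma2_e=1.0, sigma2_m=0.5, sigma_am=-0.3
        )
        model = ModelSpec(trait="y", maternal=True, direct_maternal_cov=True)
        res = solve_mme(model, rec, ped, vc)

        A = tabular_a(ped)
        q = len(ped)
        n = 6
        Za = np.zeros((n, q))
        Zm = np.zeros((n, q))
        for r_i, row in rec.iterrows():
            Za[r_i, ped.index_of(row["animal"])] = 1
            Zm[r_i, ped.index_of(row["dam"])] = 1
        W = np.hstack([Za, Zm])
        G0 = np.array([[1.0, -0.3], [-0.3, 0.5]])
        G = np.kron(G0, A)
        V = W @ G @ W.T + np.eye(n) * 1.0
        X = np.ones((n, 1))
        y = rec["y"].to_numpy()
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = G @ W.T @ Vi @ (y - X @ b)
        np.testing.assert_allclose(res.ebv.to_numpy(), u[:q], atol=1e-8)
        np.testing.assert_allclose(res.maternal.to_numpy(), u[q:], atol=1e-8)

    def test_confounded_fixed_effect_rejected(self, toy_pedigree):
        rec, ped = self._toy(toy_pedigree)
        rec["herd"] = ["h1", "h1", "h2", "h2", "h2"]
        rec["herd2"] = rec["herd"]   # identical factor -> confounded dummies
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            solve_mme(ModelSpec(trait="y", fixed=("herd", "herd2")), rec, ped,
                      VarianceComponents(1.0, 1.0))

    def test_unknown_animal_rejected(self, toy_pedigree):
        rec = pd.DataFrame({"animal": ["ghost"], "y": [1.0]})
        with pytest.raises(ValueError, match="not in pedigree"):
            solve_mme(ModelSpec(trait="y"), rec, toy_pedigree,
                      VarianceComponents(1.0, 1.0))


class TestEmReml:
    def _simulate(self, seed, h2, n_founders=60, n_gen=2):
        from herdgen.simulate import SimConfig, sim_pedigree

        cfg = SimConfig(seed=seed, n_founders=n_founders, n_generations=n_gen,
                        mating="random")
        ped = sim_pedigree(cfg)
        n = len(ped)
        rng = np.random.default_rng(seed)
        A = relationship_matrix(ped)
        La = np.linalg.cholesky(A + np.eye(n) * 1e-10)
        a = La @ rng.standard_normal(n) * np.sqrt(h2)
        y = a + rng.normal(0, np.sqrt(1 - h2) if h2 < 1 else 0, n)
        rec = pd.DataFrame({"animal": ped.animals, "y": y})
        return rec, ped

    def test_loglik_nondecreasing(self):
        rec, ped = self._simulate(seed=4, h2=0.4, n_founders=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = em_reml_direct(rec, ped, VarianceComponents(0.5, 0.5),
                                 track_loglik=True, max_iter=150)
        ll = np.array(res.loglik_path)
        assert (np.diff(ll) >= -1e-8).all()

    def test_null_heritability_recovery(self):
        hits = 0
        for seed in range(8):
            rec, ped = self._simulate(seed=200 + seed, h2=0.0, n_founders=80, n_gen=3)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = em_reml_direct(rec, ped, VarianceComponents(0.3, 0.7))
            hits += res.h2 < 0.05
        assert hits >= 7

    def test_scale_equivariance(self):
        rec, ped = self._simulate(seed=9, h2=0.3, n_founders=40)
        rec2 = rec.copy()
        rec2["y"] = 2.0 * rec2["y"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = em_reml_direct(rec, ped, VarianceComponents(0.5, 0.5), max_iter=200)
            r2 = em_reml_direct(rec2, ped, VarianceComponents(2.0, 2.0), max_iter=200)
        assert r2.vc.sigma2_a == pytest.approx(4 * r1.vc.sigma2_a, rel=1e-3)
        assert r2.vc.sigma2_e == pytest.approx(4 * r1.vc.sigma2_e, rel=1e-3)
        assert r2.h2 == pytest.approx(r1.h2, abs=1e-6)

    def test_maternal_model_rejected(self, toy_pedigree):
        rec = pd.DataFrame({"animal": ["e"], "y": [1.0]})
        with pytest.raises(ValueError, match="direct-effects"):
            em_reml_direct(rec, toy_pedigree, VarianceComponents(1, 1),
                           model=ModelSpec(trait="y", maternal=True))


class TestDeregression:
    def test_full_reliability_identity(self):
        rec = pd.DataFrame({"animal": ["a"], "ebv": [2.5], "reliability": [1.0]})
        out = deregress_ebv(rec, c=0.10)
        assert out["debv"].iloc[0] == pytest.approx(2.5)
        assert out["weight"].iloc[0] == pytest.approx(9.0)

    def test_hand_arithmetic_case(self):
        rec = pd.DataFrame({"animal": ["a"], "ebv": [2.0], "reliability": [0.5]})
        out = deregress_ebv(rec, c=0.10)
        assert out["debv"].iloc[0] == pytest.approx(4.0, abs=1e-12)
        assert out["weight"].iloc[0] == pytest.approx(0.9 / 1.1, abs=1e-12)

    def test_low_reliability_excluded_with_warning(self):
        rec = pd.DataFrame(
            {"animal": ["a", "b"], "ebv": [1.0, 2.0], "reliability": [0.01, 0.5]}
        )
        with pytest.warns(UserWarning, match="excluded"):
            out = deregress_ebv(rec)
        assert list(out["animal"]) == ["b"]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.floats(min_value=0.06, max_value=0.99),
        st.floats(min_value=0.061, max_value=1.0),
    )
    def test_monotonicity_in_reliability(self, r_lo, r_hi):
        if r_lo >= r_hi:
            r_lo, r_hi = r_hi - 1e-3, r_lo
        rec = pd.DataFrame(
            {"animal": ["lo", "hi"], "ebv": [1.0, 1.0], "reliability": [r_lo, r_hi]}
        )
        out = deregress_ebv(rec).set_index("animal")
        assert out.loc["lo", "debv"] >= out.loc["hi", "debv"]
        assert out.loc["lo", "weight"] <= out.loc["hi", "weight"]

    def test_deshrinkage_on_simulated_breeding_values(self):
        # regression slope of TBV on DEBV closer to 1 than on shrunken EBV
        rng = np.random.default_rng(12)
        n = 400
        tbv = rng.normal(0, 1, n)
        r2 = rng.uniform(0.2, 0.6, n)
        # EBV = r2*TBV + noise so that corr(EBV, TBV)^2 = r2
        ebv = r2 * tbv + rng.normal(0, 1, n) * np.sqrt(r2 * (1 - r2))
        rec = pd.DataFrame({"animal": np.arange(n).astype(str),
                            "ebv": ebv, "reliability": r2})
        out = deregress_ebv(rec)
        # DEBV behaves like an observation of TBV: slope of DEBV on TBV ~ 1,
        # while shrunken EBV regresses on TBV with slope ~ mean reliability
        slope_ebv = np.polyfit(tbv, ebv, 1)[0]
        slope_debv = np.polyfit(tbv, out["debv"], 1)[0]
        assert abs(slope_debv - 1) < abs(slope_ebv - 1)
        assert slope_ebv < 1
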