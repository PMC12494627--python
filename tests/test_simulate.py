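import io

import numpy as np
import pytest

import sweetwin as sw


class TestSimulateCohort:
    def test_empirical_pair_correlations(self):
        spec = sw.SimulationSpec(
            n_pairs={"MZ": 20000, "DZ_SS": 20000},
            traits={"y": sw.TraitSpec(A=0.6, E=0.4)},
        )
        co = sw.simulate_cohort(spec, seed=2)
        pt = sw.pair_wide(co, "y")
        z = pt.zygosity_class()
        for zcls, expect in (("MZ", 0.60), ("DZ", 0.30)):
            sub = type(pt)(pt.frame[z == zcls].reset_index(drop=True),
                           pt.traits, ())
            assert sw.intraclass_pearson(sub).r == pytest.approx(expect,
                                                                 abs=0.01)

    def test_e_only_uncorrelated(self):
        spec = sw.SimulationSpec(
            n_pairs={"MZ": 8000, "DZ_SS": 8000},
            traits={"y": sw.TraitSpec(A=0.0, E=1.0)},
        )
        pt = sw.pair_wide(sw.simulate_cohort(spec, seed=3), "y")
        assert abs(sw.intraclass_pearson(pt).r) < 0.02

    def test_same_seed_byte_identical(self):
        spec = sw.preset("fin_like")
        bufs = []
        for _ in range(2):
            co = sw.simulate_cohort(spec, seed=9)
            buf = io.StringIO()
            sw.write_long_table(co, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_singleton_rate(self):
        spec = sw.SimulationSpec(
            n_pairs={"MZ": 4000},
            traits={"y": sw.TraitSpec(A=0.5, E=0.5)},
            incomplete_rate=0.3,
        )
        pt = sw.pair_wide(sw.simulate_cohort(spec, seed=4), "y")
        frac = 1 - pt.n_complete / len(pt)
        assert frac == pytest.approx(0.3, abs=0.03)

    def test_structure_tokens(self):
        co = sw.simulate_cohort(sw.preset("fin_like"), seed=5)
        df = co.data
        assert set(df["zygosity"]) == {"MZ", "DZ_SS", "DZ_OS"}
        os_pairs = df[df["zygosity"] == "DZ_OS"].groupby("family_id")["sex"]
        assert (os_pairs.nunique() == 2).all()
        # twins share age
        assert (df.groupby("family_id")["age"].nunique() == 1).all()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sw.SimulationSpec(n_pairs={"MZ": -1},
                              traits={"y": sw.TraitSpec(E=1.0)})
        with pytest.raises(ValueError):
            sw.SimulationSpec(n_pairs={"MZ": 10},
                              traits={"y": sw.TraitSpec(A=-0.5, E=1.0)})
        with pytest.raises(ValueError, match="PSD"):
            sw.SimulationSpec(
                n_pairs={"MZ": 10},
                traits={"x": sw.TraitSpec(A=0.1, E=0.9),
                        "y": sw.TraitSpec(A=0.1, E=0.9)},
                cross={"A12": 0.5, "E12": 0.0},
            )


class TestBivariateMoments:
    def test_within_person_cross_trait_correlation(self):
        # rg=0.31, re=0.06, h2 = (0.48, 0.52) imply rP ~= 0.185
        a1, e1, a2, e2 = 0.48, 0.52, 0.52, 0.48
        spec = sw.SimulationSpec(
            n_pairs={"MZ": 25000, "DZ_SS": 25000},
            traits={"x": sw.TraitSpec(A=a1, E=e1), "y": sw.TraitSpec(A=a2, E=e2)},
            cross={"A12": 0.31 * np.sqrt(a1 * a2), "E12": 0.06 * np.sqrt(e1 * e2)},
        )
        co = sw.simulate_bivariate_cohort(spec, seed=6)
        x = co.data["x"].to_numpy(float)
        y = co.data["y"].to_numpy(float)
        expect = sw.decompose_correlation(a1, e1, a2, e2, 0.31, 0.06)
        assert expect == pytest.approx(0.185, abs=0.001)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(expect, abs=0.01)

    def test_mz_cross_trait_twice_dz_when_pure_genetic(self):
        a = 0.5
        spec = sw.SimulationSpec(
            n_pairs={"MZ": 30000, "DZ_SS": 30000},
            traits={"x": sw.TraitSpec(A=a, E=0.5), "y": sw.TraitSpec(A=a, E=0.5)},
            cross={"A12": 0.4 * a, "E12": 0.0},
        )
        co = sw.simulate_bivariate_cohort(spec, seed=7)
        pt = sw.pair_wide(co, ["x", "y"])
        f, z = pt.frame, pt.zygosity_class()
        cc = {}
        for zcls in ("MZ", "DZ"):
            g = f[z == zcls]
            cc[zcls] = np.cov(g["x_1"], g["y_2"])[0, 1]
        assert cc["MZ"] == pytest.approx(2 * cc["DZ"], abs=0.02)


class TestDiscretizeStatus:
    def test_category_proportions_match_thresholds(self):
        spec = sw.SimulationSpec(
            n_pairs={"MZ": 50000}, traits={"y": sw.TraitSpec(A=0.4, E=0.6)},
        )
        co = sw.simulate_cohort(spec, seed=8)
        ts = sw.thresholds_from_proportions((0.42, 0.22, 0.36))
        out = sw.discretize_status(co, "y", ts)
        sp = sw.status_proportions(out.data["sweet_status"])
        assert sp.proportions["SD"] == pytest.approx(0.42, abs=0.01)
        assert sp.proportions["MSL"] == pytest.approx(0.22, abs=0.01)
        # round trip: proportions back to thresholds
        back = sw.thresholds_from_proportions(
            tuple(sp.proportions[k] for k in ("SD", "MSL", "ESL"))
        )
        assert back.tau1 == pytest.approx(ts.tau1, abs=0.02)
        assert back.tau2 == pytest.approx(ts.tau2, abs=0.02)

    def test_extreme_thresholds_all_msl(self):
        spec = sw.SimulationSpec(
            n_pairs={"MZ": 200}, traits={"y": sw.TraitSpec(E=1.0)},
        )
        co = sw.simulate_cohort(spec, seed=9)
        out = sw.discretize_status(co, "y", sw.ThresholdSet(-20.0, 20.0))
        assert set(out.data["sweet_status"]) == {"MSL"}

    def test_generated_data_recovers_components(self):
        # the generator feeds the fitter: bias check at one large size
        spec = sw.SimulationSpec(
            n_pairs={"MZ": 5000, "DZ_SS": 5000},
            traits={"y": sw.TraitSpec(A=0.48 * 384.6, E=0.52 * 384.6,
                                      intercept=52.62)},
        )
        pt = sw.pair_wide(sw.simulate_cohort(spec, seed=10), "y")
        h = sw.heritability(sw.fit_continuous(pt, "AE"))
        assert h["h2"] == pytest.approx(0.48, abs=0.02)
        assert h["total"] == pytest.approx(384.6, rel=0.03)
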