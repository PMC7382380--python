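import numpy as np
import pandas as pd
import pytest

import nuetrace as nt
from nuetrace.varcomp import DesignError


def vc(sg, sgc, sge, sce, sgce, se, n=4, k=6):
    return nt.VarianceComponents(sg, sgc, sge, sce, sgce, se, n_exp=n, k_cond=k)


class TestHeritabilityFormula:
    def test_zero_genetic_variance(self):
        assert nt.heritability(vc(0, 0, 0, 0, 0, 1)) == 0.0

    def test_pure_genetic_variance(self):
        assert nt.heritability(vc(1, 0, 0, 0, 0, 0)) == 1.0

    def test_plugin_worked_example(self):
        """σ = (2,1,1,1,1,4), n = 4, k = 6 → h² = 2 / (8/3) = 0.75."""
        assert nt.heritability(vc(2, 1, 1, 1, 1, 4, n=4, k=6)) == pytest.approx(0.75, abs=1e-12)

    def test_all_zero_components_undefined(self):
        assert np.isnan(nt.heritability(vc(0, 0, 0, 0, 0, 0)))

    def test_monotone_in_genetic_variance(self):
        h = [nt.heritability(vc(s, 1, 1, 1, 1, 4)) for s in (0.5, 1, 2, 4, 8)]
        assert all(a < b for a, b in zip(h, h[1:]))

    def test_divisor_conventions_differ_when_n_neq_k(self):
        paper = nt.heritability(vc(2, 3, 0, 0, 0, 0, n=4, k=6), "paper")
        conv = nt.heritability(vc(2, 3, 0, 0, 0, 0, n=4, k=6), "conventional")
        assert paper == pytest.approx(2 / (2 + 3 / 4))
        assert conv == pytest.approx(2 / (2 + 3 / 6))

    def test_single_stratum_reduces_to_raw_ratio(self):
        assert nt.heritability(vc(2, 0, 0, 0, 0, 4, n=1, k=1)) == pytest.approx(2 / 6)


def _balanced_layout(a=3, b=2, c=2, r=2):
    g, co, e, rep = np.meshgrid(
        np.arange(a), np.arange(b), np.arange(c), np.arange(r), indexing="ij"
    )
    return pd.DataFrame(
        {
            "genotype": (g + 1).astype(str).ravel(),
            "condition": np.char.add("c", (co + 1).astype(str).ravel()),
            "experiment": (e + 1).astype(str).ravel(),
        }
    )


def test_constant_trait_all_zero_with_flag():
    df = _balanced_layout()
    df["y"] = 3.14
    dec = nt.anova_components(df, "y")
    assert dec.components.sigma2_gen == 0.0
    assert dec.components.sigma2_err == 0.0
    assert (dec.anova_table["prop_explained"] == 0.0).all()
    assert any("constant trait" in f for f in dec.flags)
    assert np.isnan(dec.components.h2)


def test_pure_genotype_signal_explains_everything():
    df = _balanced_layout()
    df["y"] = df["genotype"].astype(int).astype(float) * 2.0
    dec = nt.anova_components(df, "y")
    assert dec.anova_table.loc["genotype", "prop_explained"] == pytest.approx(1.0)
    assert dec.components.h2 == pytest.approx(1.0)


def test_proportions_sum_to_one_on_balanced_data():
    rng = np.random.default_rng(0)
    df = _balanced_layout(4, 3, 2, 3)
    df["y"] = rng.normal(0, 1, len(df))
    dec = nt.anova_components(df, "y")
    assert dec.balanced
    assert dec.anova_table["prop_explained"].sum() == pytest.approx(1.0, abs=1e-9)


def test_ss_match_statsmodels_anova_lm():
    """Cell-mean SS equal statsmodels Type-I OLS ANOVA on balanced data."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(42)
    df = _balanced_layout(3, 3, 2, 2)
    df["y"] = rng.normal(0, 2, len(df))
    dec = nt.anova_components(df, "y")
    lm = smf.ols("y ~ C(genotype) * C(condition) * C(experiment)", data=df).fit()
    ref = sm.stats.anova_lm(lm, typ=1)
    mapping = {
        "genotype": "C(genotype)",
        "condition": "C(condition)",
        "experiment": "C(experiment)",
        "genotype:condition": "C(genotype):C(condition)",
        "genotype:experiment": "C(genotype):C(experiment)",
        "condition:experiment": "C(condition):C(experiment)",
        "genotype:condition:experiment": "C(genotype):C(condition):C(experiment)",
        "residual": "Residual",
    }
    for term, ref_term in mapping.items():
        assert dec.anova_table.loc[term, "ss"] == pytest.approx(
            ref.loc[ref_term, "sum_sq"], rel=1e-9
        ), term


def test_component_recovery_monte_carlo():
    """σ²_gen = 2, no interactions, σ²_err = 1 on the 8×6×4 design, 4 reps:
    the median estimate over 200 replicates lands within ±15% of truth."""
    rng = np.random.default_rng(99)
    truth = {"sigma2_gen": 2.0, "sigma2_err": 1.0}
    est = []
    for _ in range(200):
        df = nt.simulate_trait_components(8, 6, 4, 4, truth, rng)
        est.append(nt.anova_components(df, "trait").components.sigma2_gen)
    assert abs(np.median(est) - 2.0) / 2.0 < 0.15


def test_single_level_factor_rejected():
    df = _balanced_layout(3, 1, 2, 2)
    df["y"] = 1.0
    with pytest.raises(DesignError, match="single level"):
        nt.anova_components(df, "y")


def test_empty_cell_rejected():
    df = _balanced_layout()
    df["y"] = 1.0
    df = df[~((df.genotype == "1") & (df.condition == "c1"))]
    with pytest.raises(DesignError, match="empty cell"):
        nt.anova_components(df, "y")


def test_unbalanced_data_flagged_not_rejected():
    rng = np.random.default_rng(1)
    df = _balanced_layout(3, 2, 2, 3)
    df["y"] = rng.normal(0, 1, len(df))
    df = df.drop(df.index[:2])  # remove two replicates from one cell
    dec = nt.anova_components(df, "y")
    assert not dec.balanced
    assert any("unbalanced" in f for f in dec.flags)
    assert dec.components.sigma2_err >= 0


class TestContrasts:
    def _groups(self, rng, n=20, shift=0.0):
        half = pd.DataFrame(
            {
                "condition": "control",
                "genotype": np.tile(["A", "B"], n // 2),
                "experiment": np.repeat(["1", "2"], n // 2),
                "y": rng.normal(0, 1, n),
            }
        )
        other = half.copy()
        other["condition"] = "drought"
        other["y"] = rng.normal(shift, 1, n)
        return pd.concat([half, other], ignore_index=True)

    def test_identical_copy_gives_exact_zero(self):
        rng = np.random.default_rng(0)
        df = self._groups(rng)
        df.loc[df.condition == "drought", "y"] = df.loc[df.condition == "control", "y"].to_numpy()
        out = nt.contrast_vs_control(df, "y")
        assert out.loc[0, "estimate"] == pytest.approx(0.0, abs=1e-12)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        out = nt.contrast_vs_control(self._groups(rng, shift=3.0), "y")
        assert out.loc[0, "p"] < 1e-3
        assert out.loc[0, "estimate"] == pytest.approx(3.0, abs=1.0)

    def test_missing_control_rejected(self):
        rng = np.random.default_rng(2)
        df = self._groups(rng)
        with pytest.raises(DesignError, match="control"):
            nt.contrast_vs_control(df[df.condition != "control"], "y")

    def test_no_adjustment_is_declared(self):
        rng = np.random.default_rng(3)
        out = nt.contrast_vs_control(self._groups(rng), "y")
        assert (out["adjustment"] == "none").all()


def test_heritability_report_and_permutation_null(default_sim):
    """Genotype-persistent ΔSC beats N%/C% in h²; label permutation kills it."""
    ds, _ = default_sim
    seeds = ds.seeds()
    seeds = seeds[seeds["dw_mg"] >= 1.0]
    traits = nt.dsc_table(seeds, mode="per_experiment")
    report = nt.heritability_report(traits, ["n_pct", "c_pct", "dsc"]).set_index("trait")
    assert report.loc["dsc", "h2"] > report.loc["n_pct", "h2"]
    assert report.loc["dsc", "h2"] > report.loc["c_pct", "h2"]

    rng = np.random.default_rng(0)
    perm_h2 = []
    for _ in range(20):
        shuffled = traits.copy()
        shuffled["genotype"] = (
            shuffled.groupby(["condition", "experiment"])["genotype"]
            .transform(lambda s: rng.permutation(s.to_numpy()))
        )
        perm_h2.append(nt.anova_components(shuffled, "dsc").components.h2)
    assert np.median(perm_h2) < 0.05


def test_variance_decomposition_model_api(default_sim):
    ds, _ = default_sim
    traits = nt.dsc_table(ds.seeds()[ds.seeds()["dw_mg"] >= 1.0], mode="per_experiment")
    res = nt.VarianceDecomposition(traits, "dsc").fit()
    assert 0.0 <= res.heritability() <= 1.0
    # sterile heat plants are dropped, so the layout is mildly unbalanced
    assert res.proportions.sum() == pytest.approx(1.0, abs=0.01)
    assert "sigma2_gen" in res.summary()
    assert res.heritability("conventional") != res.heritability("paper")
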