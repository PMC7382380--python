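"""Three-way variance decomposition, broad-sense heritability, contrasts.

Trait values observed on replicated plants in a genotype × condition ×
experiment factorial are decomposed into sums of squares for the three
main effects, the three two-way interactions, the three-way interaction
and the residual.  Treating all factors as random, the six variance
components entering heritability (genotype, G×C, G×E, C×E, G×C×E,
residual) are solved from the expected-mean-squares equations by the
method of moments, which is closed-form and exactly unbiased on balanced
data; negative solutions are truncated to zero.

Broad-sense heritability is the genotype share of trait variance with the
interaction and residual components shrunk by design-size divisors:

    h² = σ²_G / (σ²_G + σ²_G×C/n + σ²_G×E/k + σ²_C×E/(n·k)
                 + σ²_G×C×E/(n·k) + σ²_E/(n·k))

with n the number of experiments and k the number of conditions — the
divisor placement implemented here follows the published equation this
pipeline reproduces; ``divisor_convention='conventional'`` instead divides
each interaction by the number of levels of the non-genotype factor(s)
crossed with it (G×C by k, G×E by n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import NuetraceError

_FACTORS = ("genotype", "condition", "experiment")

SS_TERMS = [
    "genotype", "condition", "experiment",
    "genotype:condition", "genotype:experiment", "condition:experiment",
    "genotype:condition:experiment", "residual",
]


class DesignError(NuetraceError):
    """The factorial layout cannot support the decomposition."""


@dataclass
class VarianceComponents:
    """Method-of-moments variance components and the design sizes.

    Components are in squared trait units, truncated at zero; ``n_exp``
    and ``k_cond`` are the numbers of experiments and conditions used as
    heritability divisors.
    """

    sigma2_gen: float
    sigma2_gxc: float
    sigma2_gxe: float
    sigma2_cxe: float
    sigma2_gxcxe: float
    sigma2_err: float
    n_exp: int
    k_cond: int
    h2: float = np.nan
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "sigma2_gen": self.sigma2_gen,
            "sigma2_gxc": self.sigma2_gxc,
            "sigma2_gxe": self.sigma2_gxe,
            "sigma2_cxe": self.sigma2_cxe,
            "sigma2_gxcxe": self.sigma2_gxcxe,
            "sigma2_err": self.sigma2_err,
            "n_exp": self.n_exp,
            "k_cond": self.k_cond,
            "h2": self.h2,
            "flags": ";".join(self.flags),
        }


def heritability(vc: VarianceComponents, divisor_convention: str = "paper") -> float:
    """Broad-sense h² from variance components and design sizes.

    Returns NaN when every component is zero (h² undefined).
    """
    n, k = vc.n_exp, vc.k_cond
    if divisor_convention == "paper":
        div_gxc, div_gxe = n, k
    elif divisor_convention == "conventional":
        div_gxc, div_gxe = k, n
    else:
        raise ValueError(f"unknown divisor_convention {divisor_convention!r}")
    denom = (
        vc.sigma2_gen
        + vc.sigma2_gxc / div_gxc
        + vc.sigma2_gxe / div_gxe
        + vc.sigma2_cxe / (n * k)
        + vc.sigma2_gxcxe / (n * k)
        + vc.sigma2_err / (n * k)
    )
    if denom == 0.0:
        return np.nan
    return vc.sigma2_gen / denom


def _cell_arrays(df: pd.DataFrame, trait: str):
    """Cell means/counts/within-SS on the (genotype, condition, experiment) grid."""
    levels = {f: sorted(df[f].unique()) for f in _FACTORS}
    for f, lv in levels.items():
        if len(lv) < 2:
            raise DesignError(f"factor {f!r} has a single level; need >= 2")
    idx = {f: {v: i for i, v in enumerate(lv)} for f, lv in levels.items()}
    a, b, c = (len(levels[f]) for f in _FACTORS)
    counts = np.zeros((a, b, c), dtype=int)
    sums = np.zeros((a, b, c))
    ss_within = 0.0
    for (g, co, e), grp in df.groupby(list(_FACTORS), sort=False):
        i, j, k = idx["genotype"][g], idx["condition"][co], idx["experiment"][e]
        y = grp[trait].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise DesignError(
                f"NaN trait values in cell ({g}, {co}, {e}); drop them upstream"
            )
        counts[i, j, k] = y.size
        sums[i, j, k] = y.sum()
        ss_within += float(((y - y.mean()) ** 2).sum()) if y.size else 0.0
    if (counts == 0).any():
        empty = np.argwhere(counts == 0)
        g, co, e = empty[0]
        raise DesignError(
            "empty cell(s) in the factorial, e.g. "
            f"({levels['genotype'][g]}, {levels['condition'][co]}, {levels['experiment'][e]})"
        )
    means = sums / counts
    return levels, means, counts, ss_within


@dataclass
class AnovaDecomposition:
    """SS/MS table, variance-explained proportions and MoM components."""

    trait: str
    anova_table: pd.DataFrame  # index: SS_TERMS; columns: ss, df, ms, prop_explained
    components: VarianceComponents
    balanced: bool
    flags: list[str]

    def summary(self) -> str:
        vc = self.components
        lines = [
            f"Three-way variance decomposition of {self.trait!r}",
            self.anova_table.to_string(float_format=lambda v: f"{v:.5g}"),
            "",
            "Method-of-moments components (random effects):",
            f"  sigma2_gen    {vc.sigma2_gen:.5g}",
            f"  sigma2_gxc    {vc.sigma2_gxc:.5g}",
            f"  sigma2_gxe    {vc.sigma2_gxe:.5g}",
            f"  sigma2_cxe    {vc.sigma2_cxe:.5g}",
            f"  sigma2_gxcxe  {vc.sigma2_gxcxe:.5g}",
            f"  sigma2_err    {vc.sigma2_err:.5g}",
            f"  h2 (n={vc.n_exp}, k={vc.k_cond})  {vc.h2:.4f}",
        ]
        if self.flags:
            lines.append("flags: " + "; ".join(self.flags))
        return "\n".join(lines)


def anova_components(
    df: pd.DataFrame,
    trait: str,
    divisor_convention: str = "paper",
) -> AnovaDecomposition:
    """Decompose a replicated three-way factorial trait table.

    Sums of squares come from the classical balanced-design cell-mean
    formulas (on balanced data these agree with every ANOVA type); the
    variance-explained proportion of each term is its SS over the total
    SS.  Components are solved from the expected mean squares of the
    fully random model.  Unbalanced data are handled by unweighted cell
    means with the harmonic-mean cell count and flagged
    ``"unbalanced: MoM approximate"``.
    """
    flags: list[str] = []
    work = df.dropna(subset=[trait])
    if len(work) < len(df):
        flags.append(f"dropped {len(df) - len(work)} NaN trait rows")
    levels, means, counts, ss_within = _cell_arrays(work, trait)
    a, b, c = means.shape
    balanced = bool((counts == counts.flat[0]).all())
    r = float(counts.flat[0]) if balanced else a * b * c / float((1.0 / counts).sum())
    if not balanced:
        flags.append("unbalanced: MoM approximate")

    mu = means.mean()
    g_i = means.mean(axis=(1, 2))
    c_j = means.mean(axis=(0, 2))
    e_k = means.mean(axis=(0, 1))
    gc_ij = means.mean(axis=2)
    ge_ik = means.mean(axis=1)
    ce_jk = means.mean(axis=0)

    ss = {}
    ss["genotype"] = r * b * c * float(((g_i - mu) ** 2).sum())
    ss["condition"] = r * a * c * float(((c_j - mu) ** 2).sum())
    ss["experiment"] = r * a * b * float(((e_k - mu) ** 2).sum())
    ss["genotype:condition"] = r * c * float(
        ((gc_ij - g_i[:, None] - c_j[None, :] + mu) ** 2).sum()
    )
    ss["genotype:experiment"] = r * b * float(
        ((ge_ik - g_i[:, None] - e_k[None, :] + mu) ** 2).sum()
    )
    ss["condition:experiment"] = r * a * float(
        ((ce_jk - c_j[:, None] - e_k[None, :] + mu) ** 2).sum()
    )
    interaction3 = (
        means
        - gc_ij[:, :, None]
        - ge_ik[:, None, :]
        - ce_jk[None, :, :]
        + g_i[:, None, None]
        + c_j[None, :, None]
        + e_k[None, None, :]
        - mu
    )
    ss["genotype:condition:experiment"] = r * float((interaction3**2).sum())
    ss["residual"] = ss_within

    dof = {
        "genotype": a - 1,
        "condition": b - 1,
        "experiment": c - 1,
        "genotype:condition": (a - 1) * (b - 1),
        "genotype:experiment": (a - 1) * (c - 1),
        "condition:experiment": (b - 1) * (c - 1),
        "genotype:condition:experiment": (a - 1) * (b - 1) * (c - 1),
        "residual": int(counts.sum()) - a * b * c,
    }
    if dof["residual"] <= 0:
        flags.append("no within-cell replication: residual component 0")

    y = work[trait].to_numpy(dtype=float)
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0.0:
        flags.append("constant trait: all components and proportions 0")
        props = {t: 0.0 for t in SS_TERMS}
    else:
        props = {t: ss[t] / ss_total for t in SS_TERMS}

    ms = {t: (ss[t] / dof[t] if dof[t] > 0 else 0.0) for t in SS_TERMS}

    # EMS (fully random, replication r):
    #   MS_err  = s2e
    #   MS_GCE  = s2e + r·s2gce
    #   MS_GC   = s2e + r·s2gce + r·c·s2gc          (c = #experiments)
    #   MS_GE   = s2e + r·s2gce + r·b·s2ge          (b = #conditions)
    #   MS_CE   = s2e + r·s2gce + r·a·s2ce          (a = #genotypes)
    #   MS_G    = MS_GC + MS_GE − MS_GCE + r·b·c·s2g
    s2e = ms["residual"]
    s2gce = max((ms["genotype:condition:experiment"] - s2e) / r, 0.0)
    s2gc = max((ms["genotype:condition"] - ms["genotype:condition:experiment"]) / (r * c), 0.0)
    s2ge = max((ms["genotype:experiment"] - ms["genotype:condition:experiment"]) / (r * b), 0.0)
    s2ce = max((ms["condition:experiment"] - ms["genotype:condition:experiment"]) / (r * a), 0.0)
    s2g = max(
        (
            ms["genotype"]
            - ms["genotype:condition"]
            - ms["genotype:experiment"]
            + ms["genotype:condition:experiment"]
        )
        / (r * b * c),
        0.0,
    )
    vc = VarianceComponents(
        sigma2_gen=s2g,
        sigma2_gxc=s2gc,
        sigma2_gxe=s2ge,
        sigma2_cxe=s2ce,
        sigma2_gxcxe=s2gce,
        sigma2_err=s2e,
        n_exp=c,
        k_cond=b,
        flags=flags,
    )
    vc.h2 = heritability(vc, divisor_convention)

    table = pd.DataFrame(
        {
            "ss": [ss[t] for t in SS_TERMS],
            "df": [dof[t] for t in SS_TERMS],
            "ms": [ms[t] for t in SS_TERMS],
            "prop_explained": [props[t] for t in SS_TERMS],
        },
        index=SS_TERMS,
    )
    return AnovaDecomposition(trait, table, vc, balanced, flags)


def contrast_vs_control(
    df: pd.DataFrame,
    trait: str,
    control: str = "control",
) -> pd.DataFrame:
    """Marginal mean difference of each stress condition vs control.

    An additive OLS model with genotype and experiment as blocking factors
    is fitted; under treatment coding the condition coefficients are the
    cell-balanced marginal differences stress − control, tested two-sided.
    No multiplicity adjustment is applied (flagged in the output).
    """
    import statsmodels.formula.api as smf

    work = df.dropna(subset=[trait]).copy()
    if control not in set(work["condition"]):
        raise DesignError(f"no data for the control condition {control!r}")
    if work["condition"].nunique() < 2:
        raise DesignError("need at least one non-control condition")
    work = work.rename(columns={trait: "_y"})
    terms = [f"C(condition, Treatment(reference={control!r}))"]
    for blocking in ("genotype", "experiment"):
        if blocking in work.columns and work[blocking].nunique() > 1:
            terms.append(f"C({blocking})")
    res = smf.ols("_y ~ " + " + ".join(terms), data=work).fit()

    prefix = terms[0] + "[T."
    rows = []
    for name in res.params.index:
        if name.startswith(prefix):
            cond = name[len(prefix):-1]
            rows.append(
                {
                    "condition": cond,
                    "estimate": res.params[name],
                    "se": res.bse[name],
                    "t": res.tvalues[name],
                    "p": res.pvalues[name],
                    "adjustment": "none",
                }
            )
    return pd.DataFrame(rows).sort_values("condition").reset_index(drop=True)


def heritability_report(
    traits: pd.DataFrame,
    trait_columns: list[str],
    divisor_convention: str = "paper",
) -> pd.DataFrame:
    """Per-trait variance components, h² and variance-explained shares.

    ``traits`` has one row per plant with factor labels plus the trait
    columns.  Traits whose layout cannot be decomposed (e.g. a whole cell
    lost to degenerate plants) are reported with NaN and the error message
    rather than aborting the whole report.
    """
    rows = []
    for trait in trait_columns:
        row = {"trait": trait}
        try:
            dec = anova_components(traits, trait, divisor_convention)
        except (DesignError, NuetraceError) as exc:
            warnings.warn(f"heritability of {trait!r} not computable: {exc}")
            row.update(h2=np.nan, error=str(exc))
        else:
            row.update(dec.components.as_dict())
            row["error"] = ""
            for term in SS_TERMS:
                row[f"prop_{term.replace(':', 'x')}"] = dec.anova_table.loc[
                    term, "prop_explained"
                ]
        rows.append(row)
    return pd.DataFrame(rows)


class VarianceDecompositionResults:
    """Fitted decomposition; exposes components, proportions, h²."""

    def __init__(self, model: "VarianceDecomposition", decomposition: AnovaDecomposition):
        self.model = model
        self._dec = decomposition

    @property
    def components(self) -> VarianceComponents:
        return self._dec.components

    @property
    def anova_table(self) -> pd.DataFrame:
        return self._dec.anova_table

    @property
    def proportions(self) -> pd.Series:
        return self._dec.anova_table["prop_explained"]

    @property
    def balanced(self) -> bool:
        return self._dec.balanced

    def heritability(self, divisor_convention: str | None = None) -> float:
        if divisor_convention is None:
            return self._dec.components.h2
        return heritability(self._dec.components, divisor_convention)

    def summary(self) -> str:
        return self._dec.summary()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<VarianceDecompositionResults trait={self._dec.trait!r} "
            f"h2={self._dec.components.h2:.3f}>"
        )


class VarianceDecomposition:
    """Random-effects variance-decomposition model for one trait."""

    def __init__(self, data: pd.DataFrame, trait: str, divisor_convention: str = "paper"):
        self.data = data
        self.trait = trait
        self.divisor_convention = divisor_convention

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str, **kwargs):
        return cls(data, trait, **kwargs)

    def fit(self) -> VarianceDecompositionResults:
        return VarianceDecompositionResults(
            self, anova_components(self.data, self.trait, self.divisor_convention)
        )
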