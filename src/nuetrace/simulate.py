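"""Synthetic factorial plant-organ datasets with known ground truth.

The generator emulates a multi-experiment glasshouse design: 8 genotypes ×
6 post-flowering conditions (control, drought, low N, defense, dark, heat)
× several experiments × 3–4 replicate plants, producing one rosette, stem
and seeds row per plant.  Every latent quantity — organ dry weights,
N-allocation fractions, the seed C:N trade-off line, genotype-persistent
ΔSC offsets, the ¹⁵N label distribution — is drawn from an explicit model
and returned as ground truth so each pipeline stage has a recovery test.

Key modelling choices:

* organ dry weights are log-normal around condition-specific means
  (biomass is positive and right-skewed), with genotype, experiment and
  genotype × condition effects on the log scale;
* the seed (N%, C%) point is placed on the condition's trade-off line at a
  genotype- and condition-dependent N%, then displaced orthogonally by the
  genotype's ΔSC offset plus Gaussian noise, so ΔSC heritability is built
  in by construction;
* N allocation is driven by per-condition target fractions: the seed N
  pool follows from seed DW × N%, the plant total is back-computed from
  the seed target fraction and the remainder split between rosette and
  stem — in the zero-noise limit the mass-balance module recovers the
  configured fractions exactly;
* a fixed excess-¹⁵N dose per plant is split across organs by
  condition-specific remobilisation fractions and the organ atom percents
  are back-computed, so the isotope bookkeeping is exact by construction
  rather than statistical (enrichment above a physical cap — reachable
  only for near-empty N pools of sterile plants — is treated as
  unrecovered tracer);
* the heat profile is near-sterile (seed DW ~2% of control) with a
  configurable probability of fully sterile plants that fall below the
  degenerate-seed guard, exercising every downstream guard path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .datasets import (
    CONDITIONS,
    DEFAULT_GENOTYPES,
    Dataset,
    NATURAL_ABUNDANCE_A15,
    ORGANS,
)

__all__ = [
    "ConditionProfile",
    "NoiseModel",
    "SyntheticConfig",
    "GroundTruth",
    "simulate",
    "simulate_trait_components",
    "fixture_small",
]


class ConditionProfile(BaseModel):
    """Latent effects of one growth condition.

    ``dw_mult`` multiplies the control organ dry weights (rosette, stem,
    seeds); ``n_alloc`` / ``n15_alloc`` are target allocation fractions of
    total N and of the ¹⁵N label; ``slope``/``intercept`` define the seed
    C%-vs-N% trade-off line; ``seed_n_center`` is the condition's mean
    seed N%; ``sterile_prob`` is the per-plant chance of a seed DW below
    the degenerate guard.
    """

    dw_mult: tuple[float, float, float]
    n_alloc: tuple[float, float, float]
    n15_alloc: tuple[float, float, float]
    slope: float
    intercept: float
    seed_n_center: float
    sterile_prob: float = 0.0

    @model_validator(mode="after")
    def _check(self):
        for name in ("dw_mult",):
            if any(v < 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_alloc", "n15_alloc"):
            fr = getattr(self, name)
            if any(not (0 <= v <= 1) for v in fr):
                raise ValueError(f"{name} fractions must lie in [0, 1]")
            if abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError(f"{name} fractions must sum to 1, got {sum(fr)}")
        if not (0 <= self.sterile_prob <= 1):
            raise ValueError("sterile_prob must lie in [0, 1]")
        if self.seed_n_center <= 0:
            raise ValueError("seed_n_center must be > 0")
        return self


class NoiseModel(BaseModel):
    """Standard deviations of every stochastic layer (0 ⇒ deterministic).

    Log-scale SDs apply to dry weights; seed-N% SDs are in percentage
    points; ``dsc_sd`` is orthogonal scatter in mixed % units; line jitter
    SDs perturb each experiment's trade-off line.
    """

    dw_sd: float = 0.15            # per-organ residual, log scale
    geno_dw_sd: float = 0.08       # genotype main effect, log scale
    exp_dw_sd: float = 0.10        # experiment main effect, log scale
    gxc_dw_sd: float = 0.05        # genotype x condition, log scale
    alloc_sd: float = 0.06         # lognormal jitter on N fractions
    alloc15_sd: float = 0.06       # lognormal jitter on 15N fractions
    seed_n_sd: float = 0.30        # plant residual on seed N%
    n_gxc_sd: float = 0.18
    n_gxe_sd: float = 0.15
    n_cxe_sd: float = 0.05
    n_gxcxe_sd: float = 0.10
    dsc_sd: float = 0.12           # orthogonal residual around genotype offset
    line_slope_sd: float = 0.30    # per-experiment line jitter
    line_intercept_sd: float = 1.2

    @model_validator(mode="after")
    def _nonneg(self):
        for name, v in self.model_dump().items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        return self

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(**{k: 0.0 for k in cls.model_fields})


def _default_profiles() -> dict[str, ConditionProfile]:
    # Control anchored at the printed means (DW 230/1590/840 mg; N alloc
    # 7/53/40%; 15N alloc 9/40/51%; line C = 70.7 - 4.0 N; seed N% 4.0);
    # stress profiles follow the reported directions of change.
    return {
        "control": ConditionProfile(
            dw_mult=(1.0, 1.0, 1.0), n_alloc=(0.07, 0.53, 0.40),
            n15_alloc=(0.09, 0.40, 0.51), slope=-4.0, intercept=70.7,
            seed_n_center=4.0,
        ),
        "drought": ConditionProfile(
            dw_mult=(1.0, 0.55, 0.50), n_alloc=(0.12, 0.40, 0.48),
            n15_alloc=(0.12, 0.33, 0.55), slope=-4.1, intercept=70.0,
            seed_n_center=4.4,
        ),
        "lowN": ConditionProfile(
            dw_mult=(0.40, 0.35, 0.45), n_alloc=(0.05, 0.42, 0.53),
            n15_alloc=(0.06, 0.32, 0.62), slope=-4.6, intercept=69.0,
            seed_n_center=3.4,
        ),
        "defense": ConditionProfile(
            dw_mult=(0.80, 1.0, 1.0), n_alloc=(0.07, 0.52, 0.41),
            n15_alloc=(0.08, 0.36, 0.56), slope=-3.7, intercept=71.8,
            seed_n_center=3.7,
        ),
        "dark": ConditionProfile(
            dw_mult=(0.70, 0.75, 0.85), n_alloc=(0.07, 0.47, 0.46),
            n15_alloc=(0.09, 0.33, 0.58), slope=-4.35, intercept=69.0,
            seed_n_center=3.9,
        ),
        "heat": ConditionProfile(
            dw_mult=(0.70, 0.90, 0.024), n_alloc=(0.01, 0.95, 0.04),
            n15_alloc=(0.14, 0.82, 0.04), slope=-3.5, intercept=73.0,
            seed_n_center=4.8, sterile_prob=0.10,
        ),
    }


def _default_genotype_dsc() -> dict[str, float]:
    # Three genotypes persistently above the line, three near it, two below.
    return {
        "7": -0.02, "63": 0.40, "83": 0.22, "134": -0.08,
        "359": 0.05, "397": 0.30, "401": -0.38, "442": -0.48,
    }


def _default_genotype_seed_n() -> dict[str, float]:
    # Genotype positions along the trade-off line (seed N% offsets).  The
    # assignment is deliberately uncorrelated with the ΔSC offsets: a
    # correlation between along-line and orthogonal genotype effects would
    # tilt the population major axis away from the configured line.
    return {
        "7": 0.0286, "63": -0.20, "83": -0.0286, "134": -0.0857,
        "359": 0.1429, "397": 0.20, "401": -0.1429, "442": 0.0857,
    }


class SyntheticConfig(BaseModel):
    """Full ground-truth specification of a synthetic factorial dataset."""

    genotypes: list[str] = Field(default_factory=lambda: list(DEFAULT_GENOTYPES))
    conditions: list[str] = Field(default_factory=lambda: list(CONDITIONS))
    n_experiments: int = 4
    reps: int = 4
    control_dw_mg: tuple[float, float, float] = (230.0, 1590.0, 840.0)
    a15_control_pct: float = NATURAL_ABUNDANCE_A15
    label_dose_mg: float = 0.05    # excess 15N taken up per plant, mg
    e_pct_cap: float = 5.0         # back-computed enrichment ceiling
    guard_dw_mg: float = 1.0
    profiles: dict[str, ConditionProfile] = Field(default_factory=_default_profiles)
    genotype_dsc: dict[str, float] = Field(default_factory=_default_genotype_dsc)
    genotype_seed_n: dict[str, float] | None = None  # default: decorrelated spread
    genotype_seed_n_span: float = 0.8   # fallback span for custom genotype lists
    noise: NoiseModel = Field(default_factory=NoiseModel)
    rng_seed: int | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.n_experiments < 1 or self.reps < 1:
            raise ValueError("n_experiments and reps must be >= 1")
        missing = [c for c in self.conditions if c not in self.profiles]
        if missing:
            raise ValueError(f"conditions without a profile: {missing}")
        missing = [g for g in self.genotypes if g not in self.genotype_dsc]
        if missing:
            raise ValueError(f"genotypes without a ΔSC offset: {missing}")
        if any(v <= 0 for v in self.control_dw_mg):
            raise ValueError("control_dw_mg must be > 0")
        if self.label_dose_mg < 0:
            raise ValueError("label_dose_mg must be >= 0")
        return self

    @classmethod
    def zero_noise(cls, **overrides) -> "SyntheticConfig":
        """A deterministic config: all noise layers and sterility off."""
        profiles = {
            k: v.model_copy(update={"sterile_prob": 0.0})
            for k, v in _default_profiles().items()
        }
        base = dict(noise=NoiseModel.zero(), profiles=profiles)
        base.update(overrides)
        return cls(**base)

    def genotype_seed_n_offsets(self) -> dict[str, float]:
        if self.genotype_seed_n is not None:
            missing = [g for g in self.genotypes if g not in self.genotype_seed_n]
            if missing:
                raise ValueError(f"genotypes without a seed-N offset: {missing}")
            return dict(self.genotype_seed_n)
        default = _default_genotype_seed_n()
        if all(g in default for g in self.genotypes):
            return {g: default[g] for g in self.genotypes}
        g = self.genotypes
        if len(g) == 1:
            return {g[0]: 0.0}
        offs = np.linspace(-self.genotype_seed_n_span / 2, self.genotype_seed_n_span / 2, len(g))
        return dict(zip(g, offs))


@dataclass
class GroundTruth:
    """Latent parameters behind a simulated dataset."""

    config: SyntheticConfig
    lines: pd.DataFrame       # experiment, condition, slope, intercept
    genotype_dsc: dict[str, float]
    per_plant: pd.DataFrame   # true ΔSC, seed N%, allocation fractions per plant


def _renormalised_fractions(target, jitter_sd, rng, size):
    """Lognormal jitter on a 3-vector of fractions, renormalised to sum 1."""
    t = np.asarray(target, dtype=float)
    if jitter_sd == 0.0:
        return np.tile(t, (size, 1))
    w = t * rng.lognormal(0.0, jitter_sd, size=(size, 3))
    return w / w.sum(axis=1, keepdims=True)


def simulate(config: SyntheticConfig, seed: int | None = None):
    """Draw a dataset from the generator.

    Returns ``(Dataset, GroundTruth)``.  ``seed`` overrides
    ``config.rng_seed``; the same config and seed give bit-identical
    output.
    """
    if seed is None:
        seed = config.rng_seed
    rng = np.random.default_rng(seed)
    nz = config.noise
    genos = config.genotypes
    conds = config.conditions
    exps = [str(i + 1) for i in range(config.n_experiments)]
    ng, nc, ne = len(genos), len(conds), len(exps)

    geno_dw = rng.normal(0.0, nz.geno_dw_sd, ng) if nz.geno_dw_sd else np.zeros(ng)
    exp_dw = rng.normal(0.0, nz.exp_dw_sd, ne) if nz.exp_dw_sd else np.zeros(ne)
    gxc_dw = rng.normal(0.0, nz.gxc_dw_sd, (ng, nc)) if nz.gxc_dw_sd else np.zeros((ng, nc))

    line_jit_slope = rng.normal(0.0, nz.line_slope_sd, ne) if nz.line_slope_sd else np.zeros(ne)
    line_jit_int = rng.normal(0.0, nz.line_intercept_sd, ne) if nz.line_intercept_sd else np.zeros(ne)

    n_gxc = rng.normal(0.0, nz.n_gxc_sd, (ng, nc)) if nz.n_gxc_sd else np.zeros((ng, nc))
    n_gxe = rng.normal(0.0, nz.n_gxe_sd, (ng, ne)) if nz.n_gxe_sd else np.zeros((ng, ne))
    n_cxe = rng.normal(0.0, nz.n_cxe_sd, (nc, ne)) if nz.n_cxe_sd else np.zeros((nc, ne))
    n_gxcxe = (
        rng.normal(0.0, nz.n_gxcxe_sd, (ng, nc, ne)) if nz.n_gxcxe_sd else np.zeros((ng, nc, ne))
    )

    seed_n_off = config.genotype_seed_n_offsets()
    dsc_off = config.genotype_dsc
    ctrl_dw = np.asarray(config.control_dw_mg)

    line_rows = []
    rows = []
    truth_rows = []
    for ke, exp in enumerate(exps):
        for kc, cond in enumerate(conds):
            prof = config.profiles[cond]
            b = prof.slope + line_jit_slope[ke]
            a = prof.intercept + line_jit_int[ke]
            line_rows.append(
                {"experiment": exp, "condition": cond, "slope": b, "intercept": a}
            )
            norm = float(np.hypot(1.0, b))
            for kg, geno in enumerate(genos):
                r = config.reps
                # organ DW, log-normal around the cell mean
                logmu = geno_dw[kg] + exp_dw[ke] + gxc_dw[kg, kc]
                dw_noise = rng.normal(0.0, nz.dw_sd, (r, 3)) if nz.dw_sd else np.zeros((r, 3))
                dw = ctrl_dw * np.asarray(prof.dw_mult) * np.exp(logmu + dw_noise)
                if prof.sterile_prob:
                    sterile = rng.random(r) < prof.sterile_prob
                    dw[sterile, 2] = rng.uniform(0.05, 0.5, int(sterile.sum()))

                # seed composition on the trade-off line + orthogonal ΔSC
                n_center = (
                    prof.seed_n_center
                    + seed_n_off[geno]
                    + n_gxc[kg, kc]
                    + n_gxe[kg, ke]
                    + n_cxe[kc, ke]
                    + n_gxcxe[kg, kc, ke]
                )
                n_seed = n_center + (
                    rng.normal(0.0, nz.seed_n_sd, r) if nz.seed_n_sd else np.zeros(r)
                )
                n_seed = np.clip(n_seed, 0.5, None)
                d_true = dsc_off[geno] + (
                    rng.normal(0.0, nz.dsc_sd, r) if nz.dsc_sd else np.zeros(r)
                )
                n_pt = n_seed - d_true * b / norm
                c_pt = (a + b * n_seed) + d_true / norm
                c_pt = np.clip(c_pt, 1.0, 95.0)

                # N pools from target allocation fractions
                frac_n = _renormalised_fractions(prof.n_alloc, nz.alloc_sd, rng, r)
                frac_15 = _renormalised_fractions(prof.n15_alloc, nz.alloc15_sd, rng, r)
                qty_n_seed = dw[:, 2] * n_pt / 100.0
                total_n = qty_n_seed / frac_n[:, 2]
                qty_n = frac_n * total_n[:, None]  # column 2 equals qty_n_seed

                # back-computed organ atom percents from the label split;
                # enrichment above the cap is treated as unrecovered tracer
                # (lost to the unharvested roots), keeping A% physical
                qty15 = config.label_dose_mg * frac_15
                qty15 = np.minimum(qty15, qty_n * config.e_pct_cap / 100.0)
                e_pct = 100.0 * qty15 / qty_n
                a15 = config.a15_control_pct + e_pct

                n_pct_organ = 100.0 * qty_n / dw
                for i in range(r):
                    pid = f"g{geno}_{cond}_e{exp}_r{i + 1}"
                    for o, organ in enumerate(ORGANS):
                        rows.append(
                            {
                                "plant_id": pid,
                                "genotype": geno,
                                "condition": cond,
                                "experiment": exp,
                                "organ": organ,
                                "dw_mg": dw[i, o],
                                "n_pct": n_pct_organ[i, o],
                                "c_pct": c_pt[i] if organ == "seeds" else 42.0,
                                "a15_pct": a15[i, o],
                            }
                        )
                    truth_rows.append(
                        {
                            "plant_id": pid,
                            "genotype": geno,
                            "condition": cond,
                            "experiment": exp,
                            "true_dsc": d_true[i],
                            "true_seed_n_pct": n_pt[i],
                            "true_seed_c_pct": c_pt[i],
                            "true_alloc_n_rosette": frac_n[i, 0],
                            "true_alloc_n_stem": frac_n[i, 1],
                            "true_alloc_n_seeds": frac_n[i, 2],
                            "true_alloc_15n_rosette": qty15[i, 0] / qty15[i].sum(),
                            "true_alloc_15n_stem": qty15[i, 1] / qty15[i].sum(),
                            "true_alloc_15n_seeds": qty15[i, 2] / qty15[i].sum(),
                        }
                    )

    records = pd.DataFrame(rows)
    dataset = Dataset(records, a15_control_pct=config.a15_control_pct)
    truth = GroundTruth(
        config=config,
        lines=pd.DataFrame(line_rows),
        genotype_dsc=dict(dsc_off),
        per_plant=pd.DataFrame(truth_rows),
    )
    return dataset, truth


def simulate_trait_components(
    n_genotypes: int,
    k_conditions: int,
    n_experiments: int,
    reps: int,
    components: dict[str, float],
    rng: np.random.Generator,
    mean: float = 0.0,
) -> pd.DataFrame:
    """Balanced factorial trait drawn from the random-effects model.

    ``components`` maps ``sigma2_gen, sigma2_gxc, sigma2_gxe, sigma2_cxe,
    sigma2_gxcxe, sigma2_err`` to variances; every effect is an i.i.d.
    Gaussian draw.  Returns a long DataFrame with factor labels and a
    ``trait`` column — the parameter-recovery oracle for the variance
    decomposition.
    """
    a, b, c, r = n_genotypes, k_conditions, n_experiments, reps

    def draw(var, shape):
        return rng.normal(0.0, np.sqrt(var), shape) if var > 0 else np.zeros(shape)

    g = draw(components.get("sigma2_gen", 0.0), (a, 1, 1, 1))
    gc = draw(components.get("sigma2_gxc", 0.0), (a, b, 1, 1))
    ge = draw(components.get("sigma2_gxe", 0.0), (a, 1, c, 1))
    ce = draw(components.get("sigma2_cxe", 0.0), (1, b, c, 1))
    gce = draw(components.get("sigma2_gxcxe", 0.0), (a, b, c, 1))
    err = draw(components.get("sigma2_err", 0.0), (a, b, c, r))
    y = mean + g + gc + ge + ce + gce + err

    gi, cj, ek, _ = np.meshgrid(np.arange(a), np.arange(b), np.arange(c), np.arange(r), indexing="ij")
    return pd.DataFrame(
        {
            "genotype": (gi + 1).astype(str).ravel(),
            "condition": np.char.add("cond", (cj + 1).astype(str).ravel()),
            "experiment": (ek + 1).astype(str).ravel(),
            "trait": y.ravel(),
        }
    )


def fixture_small() -> Dataset:
    """A deterministic, hand-checkable 2×2×1×2 dataset.

    Two genotypes × {control, heat} × one experiment × two replicates,
    with round-number pools (every allocation fraction is an exact
    decimal) and one fully sterile heat plant (seed DW 0) that exercises
    the degenerate-seed guard.  Atom percents encode a 0.2 mg label split
    so the ¹⁵N fractions recover exactly.
    """
    a0 = NATURAL_ABUNDANCE_A15
    dose = 0.2

    def plant(pid, geno, cond, dws, qty_n, frac15, seed_c):
        recs = []
        total15 = dose
        for o, organ in enumerate(ORGANS):
            dw = dws[o]
            qn = qty_n[o]
            n_pct = 100.0 * qn / dw if dw > 0 else 0.0
            q15 = total15 * frac15[o]
            e = 100.0 * q15 / qn if qn > 0 else 0.0
            recs.append(
                {
                    "plant_id": pid,
                    "genotype": geno,
                    "condition": cond,
                    "experiment": "1",
                    "organ": organ,
                    "dw_mg": dw,
                    "n_pct": n_pct,
                    "c_pct": seed_c if organ == "seeds" else 42.0,
                    "a15_pct": a0 + e,
                }
            )
        return recs

    rows = []
    # control plants: alloc_n (0.1, 0.5, 0.4), alloc_15n (0.1, 0.4, 0.5)
    rows += plant("p1", "gA", "control", (200.0, 1500.0, 800.0),
                  (8.0, 40.0, 32.0), (0.1, 0.4, 0.5), 54.0)
    rows += plant("p2", "gA", "control", (250.0, 1600.0, 900.0),
                  (10.0, 50.0, 40.0), (0.1, 0.4, 0.5), 55.0)
    rows += plant("p3", "gB", "control", (220.0, 1400.0, 760.0),
                  (9.0, 45.0, 36.0), (0.05, 0.45, 0.5), 53.5)
    rows += plant("p4", "gB", "control", (240.0, 1700.0, 840.0),
                  (8.0, 48.0, 24.0), (0.05, 0.45, 0.5), 56.0)
    # heat plants: stem-trapped N; p8 is fully sterile (seed DW 0)
    rows += plant("p5", "gA", "heat", (160.0, 1400.0, 20.0),
                  (0.5, 19.0, 0.5), (0.14, 0.82, 0.04), 52.0)
    rows += plant("p6", "gA", "heat", (150.0, 1450.0, 18.0),
                  (0.4, 19.2, 0.4), (0.14, 0.82, 0.04), 51.5)
    rows += plant("p7", "gB", "heat", (170.0, 1500.0, 22.0),
                  (0.5, 20.0, 0.5), (0.14, 0.82, 0.04), 52.5)
    rows += plant("p8", "gB", "heat", (165.0, 1480.0, 0.0),
                  (0.5, 19.5, 0.0), (0.10, 0.90, 0.0), 0.0)
    return Dataset(pd.DataFrame(rows), a15_control_pct=a0)
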