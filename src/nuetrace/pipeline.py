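"""End-to-end analysis: indices → stoichiometry → variance decomposition.

`run_pipeline` chains every stage on one dataset and returns (and
optionally writes) the full bundle of derived tables.  All outputs are
plain CSV; a JSON metadata sidecar records the package version, seed and
every design-decision switch in effect, so that identical inputs and
options reproduce byte-identical CSVs.
"""

from __future__ import annotations

import json
import os
import warnings
from importlib.metadata import PackageNotFoundError, version

import pandas as pd

from . import budget, stoichiometry, varcomp
from .datasets import Dataset, write_results

#: Index traits offered to the heritability report besides seed N%, C%, ΔSC.
INDEX_TRAITS = ["hi", "nhi", "nhi15", "nute", "nue", "nre"]


def _pkg_version() -> str:
    try:
        return version("nuetrace")
    except PackageNotFoundError:  # pragma: no cover - editable edge case
        return "unknown"


def seed_trait_table(dataset: Dataset, dsc_mode: str = "per_experiment") -> pd.DataFrame:
    """Per-plant seed traits (N%, C%, ΔSC) with factor labels."""
    seeds = dataset.seeds()
    return stoichiometry.dsc_table(seeds, mode=dsc_mode)


def run_pipeline(
    dataset: Dataset,
    out_dir: str | os.PathLike | None = None,
    dsc_mode: str = "per_experiment",
    guard_dw_mg: float = budget.DEFAULT_GUARD_DW_MG,
    divisor_convention: str = "paper",
    heterogeneity_deg: float = stoichiometry.DEFAULT_HETEROGENEITY_DEG,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every analysis stage; return the bundle of tables by name.

    When ``out_dir`` is given each table is written as ``<name>.csv``
    plus a single ``metadata.json`` sidecar.  Stages that need structure
    the data cannot provide (a single condition, a single experiment, a
    lost factorial cell) degrade to empty tables with a warning instead
    of failing the run.
    """
    tables: dict[str, pd.DataFrame] = {}

    res = budget.NitrogenBudget(dataset, guard_dw_mg=guard_dw_mg).fit()
    tables["plant_indices"] = res.indices
    tables["condition_summary"] = res.summary(by=("condition",))
    tables["genotype_condition_summary"] = res.summary(by=("condition", "genotype"))

    seeds = dataset.seeds()
    seeds = seeds[seeds["dw_mg"] >= guard_dw_mg]
    tables["stoich_fits"] = stoichiometry.fits_by_group(seeds)
    try:
        tables["dsc"] = stoichiometry.dsc_table(seeds, mode=dsc_mode)
    except Exception as exc:
        warnings.warn(f"ΔSC table not computable: {exc}")
        tables["dsc"] = pd.DataFrame(
            columns=["plant_id", "genotype", "condition", "experiment",
                     "n_pct", "c_pct", "diff_n", "diff_c", "dsc", "flagged"]
        )

    if seeds["condition"].nunique() > 1:
        per_exp, shift_summary = stoichiometry.condition_shifts(tables["stoich_fits"])
        vectors, homogeneity = stoichiometry.response_vectors(
            stoichiometry.seed_means(seeds), heterogeneity_deg=heterogeneity_deg
        )
    else:
        warnings.warn("only one condition present: shifts and response vectors are empty")
        per_exp = pd.DataFrame(columns=["experiment", "condition", "delta_slope", "delta_intercept"])
        shift_summary = pd.DataFrame(
            columns=["condition", "delta_slope_mean", "delta_slope_sd",
                     "delta_intercept_mean", "delta_intercept_sd", "n_experiments"]
        )
        vectors = pd.DataFrame(
            columns=["genotype", "condition", "delta_n", "delta_c", "length",
                     "angle_deg", "zero_vector"]
        )
        homogeneity = pd.DataFrame(
            columns=["condition", "mean_length", "circular_sd_deg", "heterogeneous", "n_genotypes"]
        )
    tables["shifts_by_experiment"] = per_exp
    tables["shifts_summary"] = shift_summary
    tables["response_vectors"] = vectors
    tables["vector_homogeneity"] = homogeneity

    traits = tables["dsc"].rename(columns={"dsc": "dsc_value"})
    traits = traits.merge(
        tables["plant_indices"][["plant_id"] + INDEX_TRAITS], on="plant_id", how="left"
    )
    trait_cols = ["n_pct", "c_pct", "dsc_value"] + INDEX_TRAITS
    enough_structure = (
        not traits.empty
        and traits["condition"].nunique() > 1
        and traits["experiment"].nunique() > 1
        and traits["genotype"].nunique() > 1
    )
    if enough_structure:
        tables["heritability"] = varcomp.heritability_report(
            traits, trait_cols, divisor_convention=divisor_convention
        )
        contrast_frames = []
        base = dataset.records.merge(
            tables["plant_indices"][["plant_id"] + INDEX_TRAITS], on="plant_id", how="inner"
        )
        base = base[base["organ"] == "seeds"]
        for trait in INDEX_TRAITS:
            try:
                ct = varcomp.contrast_vs_control(base, trait)
            except varcomp.DesignError as exc:
                warnings.warn(f"contrast for {trait!r} skipped: {exc}")
                continue
            ct.insert(0, "trait", trait)
            contrast_frames.append(ct)
        tables["contrasts"] = (
            pd.concat(contrast_frames, ignore_index=True)
            if contrast_frames
            else pd.DataFrame(columns=["trait", "condition", "estimate", "se", "t", "p", "adjustment"])
        )
    else:
        warnings.warn("factorial too small for variance decomposition; skipped")
        tables["heritability"] = pd.DataFrame(columns=["trait", "h2", "error"])
        tables["contrasts"] = pd.DataFrame(
            columns=["trait", "condition", "estimate", "se", "t", "p", "adjustment"]
        )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for name, table in tables.items():
            write_results(table, os.path.join(out_dir, f"{name}.csv"))
        meta = {
            "nuetrace_version": _pkg_version(),
            "seed": seed,
            "a15_control_pct": dataset.a15_control_pct,
            "guard_dw_mg": guard_dw_mg,
            "dsc_mode": dsc_mode,
            "divisor_convention": divisor_convention,
            "heterogeneity_deg": heterogeneity_deg,
            "multiplicity_adjustment": "none",
            "tables": sorted(tables),
        }
        with open(os.path.join(out_dir, "metadata.json"), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
    return tables
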