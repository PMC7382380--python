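"""Per-plant ¹⁵N / total-N mass balance and nitrogen-use indices.

A single tracer pulse (¹⁵NO₃⁻) applied before flowering labels the plant's
vegetative N pool; at maturity the distribution of ¹⁵N across rosette, stem
and seeds reads out how much of that stored N was remobilised into seeds.
From organ dry weights (DW), N concentrations and ¹⁵N atom percent this
module derives, per plant:

========  =============================================================
HI        seed DW / total aboveground DW
NHI       fraction of total aboveground N in seeds
¹⁵NHI     fraction of recovered ¹⁵N tracer in seeds
NUtE      total aboveground DW per unit total aboveground N (mg/mg)
NUE       NHI / HI — N delivery to seeds normalised by sink size
NRE       ¹⁵NHI / HI — remobilised-N delivery normalised by sink size
========  =============================================================

Indices are computed per plant and then averaged ("means of ratios"), which
is why a population-mean NUE generally differs from the ratio of the
population-mean NHI and HI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import (
    Dataset,
    IntegrityError,
    NuetraceError,
    ORGANS,
)

#: Seed dry weight (mg) below which seed-sink ratio indices are unreliable.
DEFAULT_GUARD_DW_MG = 1.0

INDEX_COLUMNS = [
    "plant_id", "genotype", "condition", "experiment",
    "dw_rosette_mg", "dw_stem_mg", "dw_seeds_mg", "dw_total_mg",
    "qty_n_rosette_mg", "qty_n_stem_mg", "qty_n_seeds_mg", "qty_n_total_mg",
    "e_pct_rosette", "e_pct_stem", "e_pct_seeds",
    "qty_15n_rosette_mg", "qty_15n_stem_mg", "qty_15n_seeds_mg", "qty_15n_total_mg",
    "alloc_n_rosette", "alloc_n_stem", "alloc_n_seeds",
    "alloc_15n_rosette", "alloc_15n_stem", "alloc_15n_seeds",
    "hi", "nhi", "nhi15", "nute", "nue", "nre", "degenerate_flag",
]

#: Ratio indices undefined for plants failing the seed-DW guard.
RATIO_INDICES = ("nue", "nre")


class DomainError(NuetraceError):
    """Inputs outside the physical domain (negative DW, zero biomass...)."""


def enrichment(a15_sample, a15_control, clamp_negative: bool = False):
    """¹⁵N enrichment E% = A%_sample − A%_control (percentage points).

    Slightly negative values occur for unlabelled tissue through
    measurement noise and are kept by default; ``clamp_negative`` floors
    the result at zero.
    """
    e = np.asarray(a15_sample, dtype=float) - np.asarray(a15_control, dtype=float)
    if clamp_negative:
        e = np.maximum(e, 0.0)
    return e if e.ndim else float(e)


def pools(dw_mg, n_pct, e_pct):
    """Absolute N and excess-¹⁵N masses of a sample, in mg.

    QtyN = DW · N%/100 and Qty¹⁵N = DW · (E%/100) · (N%/100); percentages
    are per 100 mg DW so both pools are true masses.
    """
    dw = np.asarray(dw_mg, dtype=float)
    if np.any(dw < 0):
        raise DomainError("dry weight must be >= 0")
    qty_n = dw * np.asarray(n_pct, dtype=float) / 100.0
    qty_15n = qty_n * np.asarray(e_pct, dtype=float) / 100.0
    if qty_n.ndim:
        return qty_n, qty_15n
    return float(qty_n), float(qty_15n)


def plant_indices(
    plant: pd.DataFrame,
    a15_control: float,
    guard_dw_mg: float = DEFAULT_GUARD_DW_MG,
) -> dict:
    """Full index record for one plant given its three organ rows.

    Excess-¹⁵N pools are floored at 0 before computing allocation fractions
    so the fractions stay in [0, 1] even when noise takes E% slightly
    negative.  When seed DW falls below ``guard_dw_mg`` the plant is
    flagged degenerate and the seed-sink ratios NUE and NRE are NaN (HI and
    the allocations are still computed).
    """
    organs = {row["organ"]: row for _, row in plant.iterrows()}
    missing = [o for o in ORGANS if o not in organs]
    if missing:
        raise IntegrityError(
            f"plant {plant['plant_id'].iloc[0]!r} is missing organ(s): {missing}"
        )

    first = plant.iloc[0]
    out = {
        "plant_id": first["plant_id"],
        "genotype": first["genotype"],
        "condition": first["condition"],
        "experiment": first["experiment"],
    }

    dw = {o: float(organs[o]["dw_mg"]) for o in ORGANS}
    dw_total = sum(dw.values())
    if dw_total <= 0:
        raise DomainError(f"plant {out['plant_id']!r}: total aboveground DW is 0")

    qty_n, qty_15n, e_pct = {}, {}, {}
    for o in ORGANS:
        a15 = float(organs[o]["a15_pct"])
        e = enrichment(a15, a15_control) if np.isfinite(a15) else np.nan
        qn, q15 = pools(dw[o], float(organs[o]["n_pct"]), 0.0 if np.isnan(e) else e)
        qty_n[o] = qn
        qty_15n[o] = q15 if np.isfinite(e) else np.nan
        e_pct[o] = e

    n_total = sum(qty_n.values())
    q15_pos = {o: max(qty_15n[o], 0.0) if np.isfinite(qty_15n[o]) else np.nan for o in ORGANS}
    q15_total = sum(q15_pos.values())  # NaN if any organ unlabelled

    for o in ORGANS:
        out[f"dw_{o}_mg"] = dw[o]
        out[f"qty_n_{o}_mg"] = qty_n[o]
        out[f"e_pct_{o}"] = e_pct[o]
        out[f"qty_15n_{o}_mg"] = qty_15n[o]
    out["dw_total_mg"] = dw_total
    out["qty_n_total_mg"] = n_total
    out["qty_15n_total_mg"] = q15_total

    for o in ORGANS:
        out[f"alloc_n_{o}"] = qty_n[o] / n_total if n_total > 0 else np.nan
        out[f"alloc_15n_{o}"] = (
            q15_pos[o] / q15_total if np.isfinite(q15_total) and q15_total > 0 else np.nan
        )

    hi = dw["seeds"] / dw_total
    nhi = out["alloc_n_seeds"]
    nhi15 = out["alloc_15n_seeds"]
    degenerate = dw["seeds"] < guard_dw_mg

    out["hi"] = hi
    out["nhi"] = nhi
    out["nhi15"] = nhi15
    out["nute"] = dw_total / n_total if n_total > 0 else np.nan
    out["nue"] = np.nan if degenerate else nhi / hi
    out["nre"] = np.nan if degenerate else nhi15 / hi
    out["degenerate_flag"] = bool(degenerate)
    return out


def indices_table(
    dataset: Dataset, guard_dw_mg: float = DEFAULT_GUARD_DW_MG
) -> pd.DataFrame:
    """Per-plant indices for every complete (three-organ) plant."""
    rows = [
        plant_indices(grp, dataset.a15_control_pct, guard_dw_mg)
        for _, grp in dataset.iter_plants()
    ]
    if not rows:
        return pd.DataFrame(columns=INDEX_COLUMNS)
    return pd.DataFrame(rows)[INDEX_COLUMNS]


_SUMMARY_INDICES = [
    "dw_rosette_mg", "dw_stem_mg", "dw_seeds_mg",
    "alloc_n_rosette", "alloc_n_stem", "alloc_n_seeds",
    "alloc_15n_rosette", "alloc_15n_stem", "alloc_15n_seeds",
    "hi", "nhi", "nhi15", "nute", "nue", "nre",
]


def condition_summary(
    indices: pd.DataFrame,
    by: tuple[str, ...] | list[str] = ("condition",),
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Mean ± SE of each index per group (condition, or condition × genotype).

    Degenerate plants carry NaN for the seed-sink ratio indices and are
    thereby excluded from those means; they are counted separately.  Empty
    cells and single-plant SEs are reported as missing, never as zero.
    """
    columns = columns or _SUMMARY_INDICES
    by = list(by)
    out_rows = []
    for keys, grp in indices.groupby(by, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(by, keys))
        row["n_plants"] = len(grp)
        row["n_degenerate"] = int(grp["degenerate_flag"].sum())
        for col in columns:
            vals = grp[col].dropna()
            row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{col}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
            row[f"{col}_n"] = len(vals)
        out_rows.append(row)
    return pd.DataFrame(out_rows)


@dataclass
class NitrogenBudgetResults:
    """Per-plant indices plus summaries, produced by :class:`NitrogenBudget`."""

    indices: pd.DataFrame
    a15_control_pct: float
    guard_dw_mg: float

    def summary(self, by=("condition",)) -> pd.DataFrame:
        return condition_summary(self.indices, by=by)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n = len(self.indices)
        d = int(self.indices["degenerate_flag"].sum()) if n else 0
        return f"<NitrogenBudgetResults: {n} plants, {d} degenerate>"


class NitrogenBudget:
    """Mass-balance model over a plant-organ dataset.

    ``fit()`` computes the per-plant index table; summaries by condition or
    condition × genotype hang off the results object.
    """

    def __init__(self, dataset: Dataset, guard_dw_mg: float = DEFAULT_GUARD_DW_MG):
        self.dataset = dataset
        self.guard_dw_mg = guard_dw_mg

    def fit(self) -> NitrogenBudgetResults:
        return NitrogenBudgetResults(
            indices_table(self.dataset, self.guard_dw_mg),
            self.dataset.a15_control_pct,
            self.guard_dw_mg,
        )
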