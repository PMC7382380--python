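"""Seed C:N stoichiometry: orthogonal regression and the ΔSC trait.

Seed protein and oil contents trade off against each other, which shows up
as a tight negative line when seed C% is plotted against seed N%.  Because
neither axis is an error-free predictor, the line is estimated by
orthogonal (total-least-squares / major-axis) regression: the direction of
the leading eigenvector of the 2×2 covariance of (N%, C%), passing through
the centroid, which minimises the sum of squared perpendicular distances.

The *delta seed composition* (ΔSC, ``dsc``) of a seed lot is its signed
perpendicular distance from that line — positive above (C-rich for its N),
negative below.  It isolates where a genotype sits relative to the shared
trade-off line, independently of where along the line the environment
pushed it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import NuetraceError


class DegenerateFitError(NuetraceError):
    """The major-axis direction is undefined (isotropic scatter)."""


@dataclass(frozen=True)
class StoichiometryFit:
    """A fitted orthogonal-regression line for seed (N%, C%) points.

    ``slope`` is C% per N%; ``intercept`` is C% at N% = 0 (NaN for a
    vertical line, whose position is carried by the centroid).  The line
    always passes through the centroid.
    """

    slope: float
    intercept: float
    centroid_n: float
    centroid_c: float
    n_points: int
    ss_orthogonal: float

    @property
    def is_vertical(self) -> bool:
        return math.isinf(self.slope)

    def predict_c(self, n_pct):
        return self.intercept + self.slope * np.asarray(n_pct, dtype=float)


@dataclass(frozen=True)
class DSCValue:
    """Signed orthogonal distance of one point from a stoichiometry line.

    ``diff_n`` and ``diff_c`` are the horizontal and vertical gaps between
    the point and the line; ``dsc`` is the signed perpendicular distance
    (the altitude of the right triangle those two gaps form).
    """

    diff_n: float
    diff_c: float
    dsc: float
    flagged: bool = False


def fit_orthogonal(n_pct, c_pct) -> StoichiometryFit:
    """Fit the major-axis (TLS) line to seed (N%, C%) points.

    With centred second moments S_nn, S_cc, S_nc the slope is
    ``(S_cc − S_nn + sqrt((S_cc − S_nn)² + 4 S_nc²)) / (2 S_nc)``; when
    S_nc = 0 the axes decouple: the line is horizontal (S_nn > S_cc),
    vertical (S_cc > S_nn), or undefined (isotropic), which raises
    :class:`DegenerateFitError` rather than silently picking a direction.
    """
    n = np.asarray(n_pct, dtype=float).ravel()
    c = np.asarray(c_pct, dtype=float).ravel()
    if n.size != c.size:
        raise ValueError("n_pct and c_pct must have the same length")
    if n.size < 3:
        raise DegenerateFitError(f"need at least 3 points, got {n.size}")
    if not (np.all(np.isfinite(n)) and np.all(np.isfinite(c))):
        raise ValueError("points must be finite")

    nbar, cbar = n.mean(), c.mean()
    dn, dc = n - nbar, c - cbar
    s_nn = float(dn @ dn)
    s_cc = float(dc @ dc)
    s_nc = float(dn @ dc)

    if s_nn == 0.0 and s_cc == 0.0:
        raise DegenerateFitError("all points coincide; no direction")

    if s_nc == 0.0:
        if s_nn == s_cc:
            raise DegenerateFitError(
                "isotropic scatter (S_nc = 0, S_nn = S_cc): major axis undefined"
            )
        slope = 0.0 if s_nn > s_cc else math.inf
    else:
        d = s_cc - s_nn
        slope = (d + math.hypot(d, 2.0 * s_nc)) / (2.0 * s_nc)

    if math.isinf(slope):
        intercept = math.nan
        ss = s_nn  # perpendicular distance to vertical line is the N-gap
    else:
        intercept = cbar - slope * nbar
        resid = (dc - slope * dn) / math.hypot(1.0, slope)
        ss = float(resid @ resid)
    return StoichiometryFit(
        slope=float(slope),
        intercept=float(intercept),
        centroid_n=float(nbar),
        centroid_c=float(cbar),
        n_points=int(n.size),
        ss_orthogonal=ss,
    )


def signed_distance(n_pct, c_pct, fit: StoichiometryFit):
    """Signed perpendicular distance via normal projection (oracle route).

    ``(C₀ − a − b·N₀) / sqrt(1 + b²)``: positive above the line.  This is
    the geometric definition the altitude formula in :func:`dsc` must
    reproduce; both are exposed so tests can hold one against the other.
    """
    n = np.asarray(n_pct, dtype=float)
    c = np.asarray(c_pct, dtype=float)
    if fit.is_vertical:
        return n - fit.centroid_n
    return (c - fit.intercept - fit.slope * n) / math.hypot(1.0, fit.slope)


def dsc(n_pct, c_pct, fit: StoichiometryFit):
    """ΔSC of point(s) against a fitted line, via the DiffN/DiffC altitude.

    DiffC = C₀ − (a + b·N₀) is the vertical gap, DiffN = N₀ − (C₀ − a)/b
    the horizontal gap; their altitude |DiffN·DiffC| / sqrt(DiffN² + DiffC²)
    equals the perpendicular point-line distance.  The sign is taken from
    DiffC (above the line ⇒ positive); for negatively sloped lines DiffN
    necessarily agrees.  Horizontal or vertical lines leave only one finite
    gap, which then supplies both magnitude and sign (flagged), as are
    points where the two gaps disagree in sign (possible only for
    positively sloped lines).

    Returns a :class:`DSCValue` for scalar input, else a DataFrame with
    columns ``diff_n, diff_c, dsc, flagged``.
    """
    scalar = np.isscalar(n_pct) and np.isscalar(c_pct)
    n = np.atleast_1d(np.asarray(n_pct, dtype=float))
    c = np.atleast_1d(np.asarray(c_pct, dtype=float))

    b, a = fit.slope, fit.intercept
    if fit.is_vertical:
        diff_n = n - fit.centroid_n
        diff_c = np.full_like(diff_n, np.nan)
        val = diff_n.copy()
        flagged = np.ones_like(val, dtype=bool)
    elif b == 0.0:
        diff_c = c - a
        diff_n = np.full_like(diff_c, np.nan)
        val = diff_c.copy()
        flagged = np.ones_like(val, dtype=bool)
    else:
        diff_c = c - (a + b * n)
        diff_n = n - (c - a) / b
        hyp = np.hypot(diff_n, diff_c)
        with np.errstate(invalid="ignore"):
            val = np.where(hyp > 0, np.abs(diff_n * diff_c) / np.where(hyp > 0, hyp, 1.0), 0.0)
        val = np.sign(diff_c) * val
        val = np.where((diff_c == 0) & (diff_n == 0), 0.0, val)
        flagged = (np.sign(diff_n) * np.sign(diff_c) < 0) & (np.abs(val) > 0)

    if scalar:
        return DSCValue(
            diff_n=float(diff_n[0]),
            diff_c=float(diff_c[0]),
            dsc=float(val[0]),
            flagged=bool(flagged[0]),
        )
    return pd.DataFrame({"diff_n": diff_n, "diff_c": diff_c, "dsc": val, "flagged": flagged})


# ---------------------------------------------------------------------------
# Model / Results wrappers


class OrthogonalRegressionResults:
    """Results of a TLS fit; carries the line and computes ΔSC values."""

    def __init__(self, model: "OrthogonalRegression", fit: StoichiometryFit):
        self.model = model
        self._fit = fit

    @property
    def slope(self) -> float:
        return self._fit.slope

    @property
    def intercept(self) -> float:
        return self._fit.intercept

    @property
    def centroid(self) -> tuple[float, float]:
        return (self._fit.centroid_n, self._fit.centroid_c)

    @property
    def nobs(self) -> int:
        return self._fit.n_points

    @property
    def ss_orthogonal(self) -> float:
        return self._fit.ss_orthogonal

    @property
    def line(self) -> StoichiometryFit:
        return self._fit

    def dsc(self, n_pct=None, c_pct=None):
        """ΔSC of given points (default: the fitted points themselves)."""
        if n_pct is None:
            n_pct, c_pct = self.model.n_pct, self.model.c_pct
        return dsc(n_pct, c_pct, self._fit)

    def summary(self) -> str:
        f = self._fit
        lines = [
            "Orthogonal regression (major axis), seed C% ~ N%",
            f"  n points        {f.n_points:>10d}",
            f"  slope           {f.slope:>10.4f}",
            f"  intercept       {f.intercept:>10.4f}",
            f"  centroid (N,C)  ({f.centroid_n:.4f}, {f.centroid_c:.4f})",
            f"  orthogonal SSE  {f.ss_orthogonal:>10.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of the fitted points with the TLS line and ΔSC segments."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        n, c = np.asarray(self.model.n_pct), np.asarray(self.model.c_pct)
        ax.scatter(n, c, s=18, zorder=3)
        if not self._fit.is_vertical:
            xs = np.linspace(n.min(), n.max(), 50)
            ax.plot(xs, self._fit.predict_c(xs), "k-", lw=1)
            b = self._fit.slope
            d = signed_distance(n, c, self._fit)
            foot_n = n + d * b / math.hypot(1.0, b)
            foot_c = c - d / math.hypot(1.0, b)
            for x0, y0, x1, y1 in zip(n, c, foot_n, foot_c):
                ax.plot([x0, x1], [y0, y1], color="0.6", lw=0.8, zorder=2)
        ax.set_xlabel("seed N%")
        ax.set_ylabel("seed C%")
        return ax

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        f = self._fit
        return (
            f"<OrthogonalRegressionResults slope={f.slope:.4g} "
            f"intercept={f.intercept:.4g} n={f.n_points}>"
        )


class OrthogonalRegression:
    """Total-least-squares line model for seed (N%, C%) points."""

    def __init__(self, n_pct, c_pct):
        self.n_pct = np.asarray(n_pct, dtype=float).ravel()
        self.c_pct = np.asarray(c_pct, dtype=float).ravel()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_col: str = "n_pct", c_col: str = "c_pct"):
        return cls(df[n_col].to_numpy(), df[c_col].to_numpy())

    def fit(self) -> OrthogonalRegressionResults:
        return OrthogonalRegressionResults(self, fit_orthogonal(self.n_pct, self.c_pct))


# ---------------------------------------------------------------------------
# Grouped fits, condition shifts, ΔSC tables, response vectors


def fits_by_group(
    seeds: pd.DataFrame,
    by: tuple[str, ...] = ("experiment", "condition"),
) -> pd.DataFrame:
    """One TLS fit per group of seed rows, pooling all genotypes in it."""
    rows = []
    for keys, grp in seeds.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(by, keys))
        try:
            f = fit_orthogonal(grp["n_pct"], grp["c_pct"])
        except DegenerateFitError as exc:
            row.update(
                slope=np.nan, intercept=np.nan, centroid_n=np.nan, centroid_c=np.nan,
                n_points=len(grp), ss_orthogonal=np.nan, error=str(exc),
            )
        else:
            row.update(
                slope=f.slope, intercept=f.intercept,
                centroid_n=f.centroid_n, centroid_c=f.centroid_c,
                n_points=f.n_points, ss_orthogonal=f.ss_orthogonal, error="",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def dsc_table(seeds: pd.DataFrame, mode: str = "per_experiment") -> pd.DataFrame:
    """ΔSC of every seed row against the line of its own stratum.

    ``mode='per_experiment'`` fits one line per (experiment, condition) and
    scores each plant against the line of its own experiment × condition;
    ``mode='pooled'`` pools experiments within each condition.
    """
    if mode == "per_experiment":
        by = ["experiment", "condition"]
    elif mode == "pooled":
        by = ["condition"]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pieces = []
    for keys, grp in seeds.groupby(by, sort=False):
        f = fit_orthogonal(grp["n_pct"], grp["c_pct"])
        vals = dsc(grp["n_pct"].to_numpy(), grp["c_pct"].to_numpy(), f)
        piece = grp[["plant_id", "genotype", "condition", "experiment", "n_pct", "c_pct"]].copy()
        piece[["diff_n", "diff_c", "dsc", "flagged"]] = vals.to_numpy()
        piece["flagged"] = piece["flagged"].astype(bool)
        pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)


def condition_shifts(
    fits: pd.DataFrame, control: str = "control"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-experiment slope/intercept deltas of each stress vs control.

    Returns ``(per_experiment, summary)``: the deltas Δslope and Δintercept
    for every (experiment, stress) pair, and their across-experiment
    mean ± SD per stress condition.  Experiments lacking a control fit are
    excluded with a warning.
    """
    import warnings

    deltas = []
    for exp, grp in fits.groupby("experiment", sort=True):
        ctrl = grp[grp["condition"] == control]
        if ctrl.empty or not np.isfinite(ctrl["slope"].iloc[0]):
            warnings.warn(f"experiment {exp!r} has no control fit; excluded from shifts")
            continue
        b0 = ctrl["slope"].iloc[0]
        a0 = ctrl["intercept"].iloc[0]
        for _, row in grp[grp["condition"] != control].iterrows():
            deltas.append(
                {
                    "experiment": exp,
                    "condition": row["condition"],
                    "delta_slope": row["slope"] - b0,
                    "delta_intercept": row["intercept"] - a0,
                }
            )
    per_exp = pd.DataFrame(deltas, columns=["experiment", "condition", "delta_slope", "delta_intercept"])
    if per_exp.empty:
        summary = pd.DataFrame(
            columns=["condition", "delta_slope_mean", "delta_slope_sd",
                     "delta_intercept_mean", "delta_intercept_sd", "n_experiments"]
        )
        return per_exp, summary
    g = per_exp.groupby("condition", sort=True)
    summary = pd.DataFrame(
        {
            "delta_slope_mean": g["delta_slope"].mean(),
            "delta_slope_sd": g["delta_slope"].std(ddof=1),
            "delta_intercept_mean": g["delta_intercept"].mean(),
            "delta_intercept_sd": g["delta_intercept"].std(ddof=1),
            "n_experiments": g.size(),
        }
    ).reset_index()
    return per_exp, summary


#: Circular SD of response-vector angles above which a condition's
#: genotype responses are called heterogeneous (degrees).
DEFAULT_HETEROGENEITY_DEG = 60.0


def response_vectors(
    seed_means: pd.DataFrame,
    control: str = "control",
    heterogeneity_deg: float = DEFAULT_HETEROGENEITY_DEG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genotype (ΔN%, ΔC%) displacement from the control baseline.

    ``seed_means`` has one row per genotype × condition with columns
    ``genotype, condition, n_pct, c_pct`` (cell means).  Returns the
    vector table (with length and angle, degrees, atan2(ΔC, ΔN)) and a
    per-condition homogeneity summary: mean vector length and the circular
    SD of angles, labelled heterogeneous above ``heterogeneity_deg``.
    Genotypes without a control cell are skipped with a warning; zero
    vectors have no angle and are flagged.
    """
    import warnings

    ctrl = seed_means[seed_means["condition"] == control].set_index("genotype")
    rows = []
    for _, row in seed_means[seed_means["condition"] != control].iterrows():
        g = row["genotype"]
        if g not in ctrl.index:
            warnings.warn(f"genotype {g!r} has no control mean; skipped")
            continue
        dn = row["n_pct"] - ctrl.loc[g, "n_pct"]
        dc = row["c_pct"] - ctrl.loc[g, "c_pct"]
        length = math.hypot(dn, dc)
        angle = math.degrees(math.atan2(dc, dn)) if length > 0 else np.nan
        rows.append(
            {
                "genotype": g,
                "condition": row["condition"],
                "delta_n": dn,
                "delta_c": dc,
                "length": length,
                "angle_deg": angle,
                "zero_vector": length == 0.0,
            }
        )
    vectors = pd.DataFrame(
        rows,
        columns=["genotype", "condition", "delta_n", "delta_c", "length", "angle_deg", "zero_vector"],
    )

    summaries = []
    for cond, grp in vectors.groupby("condition", sort=True):
        angles = np.radians(grp["angle_deg"].dropna().to_numpy())
        if angles.size:
            rbar = float(np.abs(np.exp(1j * angles).mean()))
            circ_sd = math.degrees(math.sqrt(max(-2.0 * math.log(max(rbar, 1e-300)), 0.0)))
        else:
            circ_sd = np.nan
        summaries.append(
            {
                "condition": cond,
                "mean_length": grp["length"].mean(),
                "circular_sd_deg": circ_sd,
                "heterogeneous": bool(np.isnan(circ_sd) or circ_sd > heterogeneity_deg),
                "n_genotypes": len(grp),
            }
        )
    return vectors, pd.DataFrame(summaries)


def seed_means(seeds: pd.DataFrame) -> pd.DataFrame:
    """Genotype × condition means of seed N% and C%."""
    return (
        seeds.groupby(["genotype", "condition"], sort=True)[["n_pct", "c_pct"]]
        .mean()
        .reset_index()
    )
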