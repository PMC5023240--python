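"""Growth-rate estimation and phenotype arithmetic.

The specific growth rate mu (1/h) is the slope of ln(OD600) against time in
the exponential phase. It is found by sliding-window ordinary least squares
over the log-transformed curve: among all contiguous windows of at least
``min_window`` points whose fit achieves r^2 >= ``r2_min`` AND whose fitted
rise spans at least ``min_rise`` log units (default two doublings), the
window with the maximum slope is reported. The rise requirement anchors the
fit to genuine growth: measurement noise cannot produce a sustained
two-doubling climb, so short spuriously steep windows never win, while the
r^2 gate keeps the window inside the log-linear phase. Curves with no
qualifying window yield an explicit no-fit (None), never a number.

Also here: relative growth (fold and percent benefit), pairwise epistasis
between two mutations from a four-genotype rate table, Welch's unequal-
variance t-test, and normalization of oxidative-stress inhibition halos to
each strain's ancestor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GrowthCurve:
    culture_id: str
    times: np.ndarray  # hours
    od600: np.ndarray
    strain: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.shape != self.od600.shape:
            raise ValueError("times and od600 differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time vector must be strictly increasing")
        if np.any(self.od600 <= 0):
            raise ValueError("OD600 must be positive")


@dataclass
class GrowthRateEstimate:
    culture_id: str
    mu: float  # 1/h
    window_start: float  # h
    window_end: float  # h
    r2: float
    n_points: int


#: Default minimum fitted rise of a qualifying window: two OD doublings.
MIN_RISE_LOG = 2.0 * math.log(2.0)


def estimate_growth_rate(
    curve: GrowthCurve,
    min_window: int = 5,
    r2_min: float = 0.99,
    min_rise: float = MIN_RISE_LOG,
) -> GrowthRateEstimate | None:
    """Maximum-slope log-linear fit over qualifying sliding windows.

    A window qualifies when it has >= ``min_window`` points, r^2 >=
    ``r2_min``, positive slope, and a fitted rise (slope x time span) of at
    least ``min_rise`` natural-log units. Returns None when no window
    qualifies.
    """
    t = curve.times
    y = np.log(curve.od600)
    n = t.size
    if n < min_window:
        raise ValueError(f"curve has {n} points; need at least {min_window}")
    # prefix sums give each window's OLS slope and r^2 in O(1)
    ct = np.concatenate(([0.0], np.cumsum(t)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    ctt = np.concatenate(([0.0], np.cumsum(t * t)))
    cty = np.concatenate(([0.0], np.cumsum(t * y)))
    cyy = np.concatenate(([0.0], np.cumsum(y * y)))
    best: GrowthRateEstimate | None = None
    for length in range(min_window, n + 1):
        for start in range(0, n - length + 1):
            end = start + length
            st, sy = ct[end] - ct[start], cy[end] - cy[start]
            stt, sty = ctt[end] - ctt[start], cty[end] - cty[start]
            syy = cyy[end] - cyy[start]
            sxx = stt - st * st / length
            sxy = sty - st * sy / length
            ss_tot = syy - sy * sy / length
            slope = sxy / sxx
            if ss_tot <= 0:
                r2 = 1.0
            else:
                r2 = min(1.0, (sxy * sxy) / (sxx * ss_tot))
            if slope <= 0 or r2 < r2_min:
                continue
            if slope * (t[end - 1] - t[start]) < min_rise:
                continue
            if best is None or slope > best.mu:
                best = GrowthRateEstimate(
                    culture_id=curve.culture_id,
                    mu=float(slope),
                    window_start=float(t[start]),
                    window_end=float(t[end - 1]),
                    r2=float(r2),
                    n_points=length,
                )
    return best


def estimate_rates(
    curves: Sequence[GrowthCurve],
    min_window: int = 5,
    r2_min: float = 0.99,
    min_rise: float = MIN_RISE_LOG,
) -> pd.DataFrame:
    """Rate table for many curves; no-fit curves get NaN mu."""
    rows = []
    for curve in curves:
        est = estimate_growth_rate(
            curve, min_window=min_window, r2_min=r2_min, min_rise=min_rise
        )
        rows.append(
            {
                "culture_id": curve.culture_id,
                "strain": curve.strain,
                "condition": curve.condition,
                "mu": est.mu if est else np.nan,
                "window_start": est.window_start if est else np.nan,
                "window_end": est.window_end if est else np.nan,
                "r2": est.r2 if est else np.nan,
                "n_points": est.n_points if est else 0,
                "fit": est is not None,
            }
        )
    return pd.DataFrame(rows)


def relative_rate(mu_strain: float, mu_reference: float) -> tuple[float, float]:
    """Fold change and benefit (fold - 1) of a strain's rate vs a reference."""
    if mu_reference <= 0:
        raise ValueError("reference growth rate must be positive")
    fold = mu_strain / mu_reference
    return fold, fold - 1.0


@dataclass(frozen=True)
class EpistasisResult:
    """Interaction between two mutations from a four-genotype rate table.

    ``benefit_alone`` is b(m1 | ancestor) = mu(anc+m1)/mu(anc) - 1;
    ``benefit_in_background`` is b(m1 | anc+m2). A negative interaction
    (benefit shrinks in the fitter background) is diminishing-returns
    epistasis; positive is synergy; zero matches multiplicative rates.
    """

    benefit_alone: float
    benefit_in_background: float
    interaction: float

    @property
    def classification(self) -> str:
        # float tolerance: exactly multiplicative rates give interaction ~1e-16
        if abs(self.interaction) < 1e-9:
            return "multiplicative"
        return "diminishing-returns" if self.interaction < 0 else "synergistic"


def epistasis_contrast(mu: Mapping[str, float]) -> EpistasisResult:
    """Epistasis of mutation m1 across backgrounds with/without m2.

    ``mu`` must map the four genotypes 'anc', 'm1', 'm2', 'm1m2' to growth
    rates.
    """
    required = {"anc", "m1", "m2", "m1m2"}
    missing = required - set(mu)
    if missing:
        raise ValueError(f"missing genotypes: {sorted(missing)}")
    if mu["anc"] <= 0 or mu["m2"] <= 0:
        raise ValueError("background growth rates must be positive")
    b_alone = mu["m1"] / mu["anc"] - 1.0
    b_background = mu["m1m2"] / mu["m2"] - 1.0
    return EpistasisResult(
        benefit_alone=b_alone,
        benefit_in_background=b_background,
        interaction=b_background - b_alone,
    )


def welch_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Two-tailed unpaired t-test assuming unequal variance.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def normalize_halo(
    measurements: pd.DataFrame, ancestor_map: Mapping[str, str]
) -> pd.DataFrame:
    """Normalize inhibition-halo diameters to each strain's ancestor.

    ``measurements`` is long-format with columns strain, diameter_cm (one row
    per replicate plate). Each strain's mean diameter is divided by its
    ancestor's mean; protection = 1 - ratio, so positive protection means a
    smaller dead zone than the ancestor. Returns per-strain mean, SEM, ratio
    and protection. Ancestor strains must be present in the table.
    """
    if not {"strain", "diameter_cm"} <= set(measurements.columns):
        raise ValueError("measurements need columns strain, diameter_cm")
    if (measurements["diameter_cm"] < 0).any():
        raise ValueError("diameters must be non-negative")
    per_strain = measurements.groupby("strain")["diameter_cm"].agg(["mean", "sem", "count"])
    rows = []
    for strain, ancestor in ancestor_map.items():
        if strain not in per_strain.index:
            raise KeyError(f"no measurements for strain {strain!r}")
        if ancestor not in per_strain.index:
            raise KeyError(f"no measurements for ancestor {ancestor!r}")
        anc_mean = per_strain.loc[ancestor, "mean"]
        if anc_mean <= 0:
            raise ValueError(f"ancestor {ancestor!r} has non-positive mean diameter")
        ratio = per_strain.loc[strain, "mean"] / anc_mean
        rows.append(
            {
                "strain": strain,
                "ancestor": ancestor,
                "mean_diameter_cm": per_strain.loc[strain, "mean"],
                "sem_diameter_cm": per_strain.loc[strain, "sem"],
                "n": int(per_strain.loc[strain, "count"]),
                "ratio": ratio,
                "protection": 1.0 - ratio,
            }
        )
    return pd.DataFrame(rows)


def curves_from_long_frame(frame: pd.DataFrame) -> list[GrowthCurve]:
    """Build curves from a long table with columns well, time_h, od600
    (optional strain, condition)."""
    required = {"well", "time_h", "od600"}
    if not required <= set(frame.columns):
        raise ValueError(f"long growth table needs columns {sorted(required)}")
    curves = []
    for well, block in frame.groupby("well", sort=True):
        block = block.sort_values("time_h")
        curves.append(
            GrowthCurve(
                culture_id=str(well),
                times=block["time_h"].to_numpy(),
                od600=block["od600"].to_numpy(),
                strain=str(block["strain"].iloc[0]) if "strain" in block else "",
                condition=str(block["condition"].iloc[0]) if "condition" in block else "",
            )
        )
    return curves


def curves_to_long_frame(curves: Sequence[GrowthCurve]) -> pd.DataFrame:
    rows = []
    for curve in curves:
        for t, od in zip(curve.times, curve.od600):
            rows.append(
                {
                    "well": curve.culture_id,
                    "strain": curve.strain,
                    "condition": curve.condition,
                    "time_h": t,
                    "od600": od,
                }
            )
    return pd.DataFrame(rows)
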