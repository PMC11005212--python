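"""Waterlogging-tolerance scoring and heterosis statistics for an F1 population.

Implements the membership-function evaluation pipeline used for germplasm
screening:

* tolerance index  WI = treatment mean / control mean, per line and trait;
* membership value X_i = (X - X_min) / (X_max - X_min), the min-max rescaling
  of a trait's WI across all entries (reported as a percentage);
* MFVW, the arithmetic mean of a line's membership values across traits —
  higher means more tolerant;
* five tolerance grades from SD thresholds around the population-mean MFVW
  (HWT / WT / MWT / WS / HWS, with the 1.64*SD and 1*SD cutoffs);
* mid-parent and high-parent heterosis (MPH / HPH, in percent) with
  one-sample t-tests of the offspring values against MPV / HPV.

Traits measured only under treatment (the morphological Score) have no
control group and hence no WI; their treatment value enters the membership
function directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "GRADES",
    "DomainError",
    "DegenerateScaleError",
    "waterlogging_index",
    "membership_values",
    "mfvw",
    "grade",
    "mid_parent_value",
    "high_parent_value",
    "heterosis",
    "coefficient_of_variation",
    "tolerance_report",
    "heterosis_report",
]

GRADES = ("HWT", "WT", "MWT", "WS", "HWS")


class DomainError(ValueError):
    """Input outside the operation's mathematical domain."""


class DegenerateScaleError(ValueError):
    """All values identical: the min-max scale is undefined."""


def waterlogging_index(treatment_mean: float, control_mean: float) -> float:
    """Tolerance index: treatment group value over control group value."""
    if control_mean <= 0:
        raise DomainError("control mean must be > 0")
    return treatment_mean / control_mean


def membership_values(values) -> np.ndarray:
    """Min-max rescale a vector of trait indices to [0, 1].

    The minimum maps to 0, the maximum to 1, affine in between.  Raises
    :class:`DegenerateScaleError` when all values coincide (callers drop the
    trait from the MFVW average with a logged warning).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError("need at least 2 values for min-max scaling")
    xmin, xmax = x.min(), x.max()
    if xmax == xmin:
        raise DegenerateScaleError("all values identical; membership undefined")
    return (x - xmin) / (xmax - xmin)


def mfvw(membership_by_trait) -> float:
    """Mean membership value across traits — the composite tolerance score."""
    x = np.asarray(membership_by_trait, dtype=float)
    if x.size == 0:
        raise DomainError("MFVW of an empty vector is undefined")
    return float(x.mean())


def grade(
    mfvw_i: float,
    population_mean: float,
    population_sd: float,
    k_inner: float = 1.0,
    k_outer: float = 1.64,
) -> str:
    """Five-grade tolerance classification around the population MFVW.

    HWT  x >= m + 1.64 s        (closed on the tolerant side)
    WT   m + s <= x < m + 1.64 s
    MWT  m - s <= x < m + s
    WS   m - 1.64 s <= x < m - s
    HWS  x < m - 1.64 s
    """
    if population_sd < 0:
        raise DomainError("population SD must be >= 0")
    m, s = population_mean, population_sd
    x = mfvw_i
    if x >= m + k_outer * s:
        return "HWT"
    if x >= m + k_inner * s:
        return "WT"
    if x >= m - k_inner * s:
        return "MWT"
    if x >= m - k_outer * s:
        return "WS"
    return "HWS"


def mid_parent_value(maternal_mean: float, paternal_mean: float) -> float:
    """MPV: the average of the two parental means."""
    return (maternal_mean + paternal_mean) / 2.0


def high_parent_value(maternal_mean: float, paternal_mean: float) -> float:
    """HPV: the better parent's mean."""
    return max(maternal_mean, paternal_mean)


@dataclass(frozen=True)
class HeterosisResult:
    mph: float  # mid-parent heterosis, percent
    hph: float  # high-parent heterosis, percent
    p_mph: float | None
    p_hph: float | None


def heterosis(values, maternal_mean: float, paternal_mean: float) -> HeterosisResult:
    """Mid- and high-parent heterosis of offspring values, in percent.

    MPH = (mean(values) - MPV) / MPV * 100, HPH likewise against HPV.
    For a vector of offspring values (n >= 2) the p-values come from
    two-sided one-sample t-tests against MPV and HPV; for a scalar input
    p-values are ``None``.
    """
    mpv = mid_parent_value(maternal_mean, paternal_mean)
    hpv = high_parent_value(maternal_mean, paternal_mean)
    if mpv == 0 or hpv == 0:
        raise DomainError("MPV and HPV must be nonzero")
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    mean = float(arr.mean())
    mph = (mean - mpv) / mpv * 100.0
    hph = (mean - hpv) / hpv * 100.0
    if arr.size >= 2:
        p_mph = float(stats.ttest_1samp(arr, mpv).pvalue)
        p_hph = float(stats.ttest_1samp(arr, hpv).pvalue)
    else:
        p_mph = p_hph = None
    return HeterosisResult(mph, hph, p_mph, p_hph)


def coefficient_of_variation(values) -> float:
    """Sample CV in percent: SD (n-1 denominator) over the mean, times 100."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError("CV needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise DomainError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean * 100.0)


def significance_stars(p: float | None) -> str:
    if p is None or math.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# table-level reports


def _group_means(table: pd.DataFrame) -> pd.DataFrame:
    required = {"line_id", "trait", "condition", "value"}
    missing = required - set(table.columns)
    if missing:
        raise DomainError(f"phenotype table missing columns: {sorted(missing)}")
    return (
        table.groupby(["line_id", "trait", "condition"], sort=False)["value"]
        .mean()
        .unstack("condition")
    )


def trait_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Per (line, trait) tolerance index, lines as rows, traits as columns.

    Traits with both conditions yield WI = treatment / control; treatment-only
    traits contribute their treatment mean directly.
    """
    means = _group_means(table)
    if "treatment" not in means.columns:
        raise DomainError("table has no treatment condition")
    if "control" in means.columns:
        wi = means["treatment"] / means["control"]
        wi = wi.where(means["control"].notna(), means["treatment"])
    else:
        wi = means["treatment"]
    out = wi.unstack("trait")
    # preserve input trait order
    order = [t for t in table["trait"].unique() if t in out.columns]
    return out[order]


def tolerance_report(
    table: pd.DataFrame,
    maternal_id: str = "maternal",
    paternal_id: str = "paternal",
    k_inner: float = 1.0,
    k_outer: float = 1.64,
    grade_on: str = "f1",
) -> pd.DataFrame:
    """Full tolerance evaluation: WI, membership values, MFVW and grade.

    Membership min-max scaling runs across all entries (parents included);
    the grade thresholds use the mean and SD of MFVW over the F1 lines only
    (``grade_on="all"`` includes the parents).  Returns one row per entry
    with ``WI_<trait>``, ``X_<trait>`` (membership), ``MFVW`` and ``grade``
    columns.
    """
    wi = trait_indices(table)
    for pid in (maternal_id, paternal_id):
        if pid not in wi.index:
            raise DomainError(f"designated parent {pid!r} not in table")

    memberships = {}
    for trait in wi.columns:
        col = wi[trait].dropna()
        try:
            memberships[trait] = pd.Series(
                membership_values(col.to_numpy()), index=col.index
            )
        except DegenerateScaleError:
            log.warning(
                "trait %s has a degenerate (constant) index; dropped from MFVW",
                trait,
            )
    x = pd.DataFrame(memberships).reindex(wi.index)
    composite = x.mean(axis=1, skipna=True)

    f1_mask = ~composite.index.isin([maternal_id, paternal_id])
    pop = composite if grade_on == "all" else composite[f1_mask]
    m, s = float(pop.mean()), float(pop.std(ddof=1))
    grades = composite.map(lambda v: grade(v, m, s, k_inner, k_outer))

    report = pd.concat(
        [wi.add_prefix("WI_"), x.add_prefix("X_")], axis=1
    )
    report["MFVW"] = composite
    report["grade"] = grades
    report.index.name = "line_id"
    return report


def heterosis_report(
    table: pd.DataFrame,
    maternal_id: str = "maternal",
    paternal_id: str = "paternal",
    include_mfvw: bool = True,
) -> pd.DataFrame:
    """Population heterosis per trait, on the tolerance-index scale.

    Each F1 line contributes one observation (its WI, or for treatment-only
    traits its treatment mean); MPH/HPH compare the F1 population mean with
    the parental index values, with one-sample t-tests for significance.
    A composite MFVW row is appended by default.
    """
    report = tolerance_report(table, maternal_id, paternal_id)
    wi_cols = [c for c in report.columns if c.startswith("WI_")]
    traits = [c[len("WI_"):] for c in wi_cols]
    f1 = report.index[~report.index.isin([maternal_id, paternal_id])]

    rows = []
    items = [(t, report[f"WI_{t}"]) for t in traits]
    if include_mfvw:
        items.append(("MFVW", report["MFVW"]))
    for trait, series in items:
        mm = float(series.loc[maternal_id])
        pm = float(series.loc[paternal_id])
        offspring = series.loc[f1].dropna().to_numpy()
        het = heterosis(offspring, mm, pm)
        rows.append(
            {
                "trait": trait,
                "maternal": mm,
                "paternal": pm,
                "MPV": mid_parent_value(mm, pm),
                "HPV": high_parent_value(mm, pm),
                "F1_mean": float(offspring.mean()),
                "CV_pct": coefficient_of_variation(offspring),
                "MPH_pct": het.mph,
                "HPH_pct": het.hph,
                "p_MPH": het.p_mph,
                "p_HPH": het.p_hph,
                "sig_MPH": significance_stars(het.p_mph),
                "sig_HPH": significance_stars(het.p_hph),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def round_display(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as printed summary tables conventionally do."""
    q = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)
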