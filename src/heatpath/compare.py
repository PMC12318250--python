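"""Method-comparison statistics: per-participant differences, cohort and
stratified summaries, and histogram exports.

The central contrasts are, per participant and indicator,

    difference_means    = mean_mobility    - mean_residence
    difference_maximums = maximum_mobility - maximum_residence

summarised over the cohort by mean, sample SD (n-1 denominator) and the
Pearson correlation between the two methods' means, overall and within
strata (tertiles of average daily distance travelled, and simulated
socio-demographic labels including a "Missing" level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import ExposureSummary

__all__ = [
    "participant_differences",
    "records_frame",
    "GroupSummary",
    "summarize_group",
    "tertiles",
    "stratified_table",
    "histogram_export",
]


def participant_differences(mobility: ExposureSummary,
                            residence: ExposureSummary) -> dict:
    """Signed mobility-minus-residence differences for one participant."""
    if mobility.participant_id != residence.participant_id:
        raise ValueError("summaries belong to different participants")
    if mobility.indicator != residence.indicator:
        raise ValueError("summaries describe different indicators")
    if mobility.method != "mobility" or residence.method != "residence":
        raise ValueError("expected one mobility and one residence summary")
    return {
        "participant_id": mobility.participant_id,
        "indicator": mobility.indicator,
        "mean_mobility": mobility.mean_incl_nonwear,
        "mean_residence": residence.mean_incl_nonwear,
        "mean_mobility_excl_nonwear": mobility.mean_excl_nonwear,
        "mean_residence_excl_nonwear": residence.mean_excl_nonwear,
        "maximum_mobility": mobility.maximum,
        "maximum_residence": residence.maximum,
        "difference_means": mobility.mean_incl_nonwear - residence.mean_incl_nonwear,
        "difference_means_excl_nonwear": (
            mobility.mean_excl_nonwear - residence.mean_excl_nonwear
        ),
        "difference_maximums": mobility.maximum - residence.maximum,
    }


def records_frame(records, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble ComparisonRecord dicts (plus optional covariates) into a table."""
    df = pd.DataFrame(list(records))
    if covariates is not None:
        df = df.merge(covariates, on="participant_id", how="left")
    return df


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean_difference_means: float
    sd_difference_means: float
    mean_difference_maximums: float
    sd_difference_maximums: float
    pearson_r_means: float        # NaN when undefined (n < 2 or zero variance)
    mean_mobility_mean: float
    sd_mobility_mean: float
    mean_residence_mean: float
    sd_residence_mean: float
    mean_mobility_maximum: float
    sd_mobility_maximum: float
    mean_residence_maximum: float
    sd_residence_maximum: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def summarize_group(records: pd.DataFrame, label: str = "overall") -> GroupSummary:
    """Mean, sample SD and Pearson r of the two methods' means for a group."""
    n = len(records)
    if n < 1:
        raise ValueError("cannot summarise an empty group")

    def _sd(col):
        return float(records[col].std(ddof=1)) if n > 1 else 0.0

    return GroupSummary(
        label=label,
        n=n,
        mean_difference_means=float(records["difference_means"].mean()),
        sd_difference_means=_sd("difference_means"),
        mean_difference_maximums=float(records["difference_maximums"].mean()),
        sd_difference_maximums=_sd("difference_maximums"),
        pearson_r_means=_pearson(
            records["mean_mobility"].to_numpy(dtype=float),
            records["mean_residence"].to_numpy(dtype=float),
        ),
        mean_mobility_mean=float(records["mean_mobility"].mean()),
        sd_mobility_mean=_sd("mean_mobility"),
        mean_residence_mean=float(records["mean_residence"].mean()),
        sd_residence_mean=_sd("mean_residence"),
        mean_mobility_maximum=float(records["maximum_mobility"].mean()),
        sd_mobility_maximum=_sd("maximum_mobility"),
        mean_residence_maximum=float(records["maximum_residence"].mean()),
        sd_residence_maximum=_sd("maximum_residence"),
    )


def tertiles(values) -> tuple:
    """Empirical tertile cut points and interval labels.

    Cuts at the 33⅓ and 66⅔ percentiles; the first interval is closed on
    the left and the rest on the right, labelled with the observed min and
    max as outer bounds, e.g. ``[5.63, 41.5]``, ``(41.5, 65]``,
    ``(65, 368]``.  Returns ``(cuts, labels, assignment)`` where
    ``assignment`` maps each value to its tertile label.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("tertiles need at least 3 values")
    # observed-value cut points, as in printed tertile boundaries
    q1, q2 = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0], method="lower")
    lo, hi = v.min(), v.max()

    def _fmt(x):
        return f"{x:.3g}"

    if q1 == q2 or lo == hi:
        warnings.warn("heavy ties: tertile groups are degenerate")
    labels = [
        f"[{_fmt(lo)}, {_fmt(q1)}]",
        f"({_fmt(q1)}, {_fmt(q2)}]",
        f"({_fmt(q2)}, {_fmt(hi)}]",
    ]
    assignment = np.where(v <= q1, labels[0], np.where(v <= q2, labels[1], labels[2]))
    return (float(q1), float(q2)), labels, assignment


def stratified_table(records: pd.DataFrame, strata: list) -> pd.DataFrame:
    """One GroupSummary row per (indicator, stratification variable, level).

    ``strata`` lists covariate column names; a special name
    ``"daily_distance_tertile"`` may be pre-assigned via :func:`tertiles`.
    Missing labels form their own level.  Rows with stratum "overall"
    summarise each indicator without stratification.
    """
    rows = []
    for indicator, sub in records.groupby("indicator", sort=True):
        g = summarize_group(sub, "overall")
        rows.append({"indicator": indicator, "stratum_variable": "overall",
                     **g.__dict__})
        for var in strata:
            if var not in records.columns:
                raise ValueError(f"unknown stratum variable {var!r}")
            levels = sub[var].fillna("Missing")
            for level in sorted(levels.unique()):
                grp = sub.loc[levels == level]
                gs = summarize_group(grp, str(level))
                rows.append({"indicator": indicator, "stratum_variable": var,
                             **gs.__dict__})
    return pd.DataFrame(rows)


def histogram_export(values, bin_width: float) -> pd.DataFrame:
    """Deterministic binned counts with edges anchored at 0.

    Bin k covers [k*w, (k+1)*w); counts always conserve the number of
    finite inputs.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return pd.DataFrame({"bin_left": [], "bin_right": [], "count": []})
    k = np.floor(v / bin_width).astype(np.int64)
    uniq, counts = np.unique(k, return_counts=True)
    return pd.DataFrame(
        {
            "bin_left": uniq * bin_width,
            "bin_right": (uniq + 1) * bin_width,
            "count": counts,
        }
    )
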