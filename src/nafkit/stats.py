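"""Condition comparison and clustering of subcellular distributions.

Replicated per-compartment percents (or absolute levels) are compared
between experimental conditions by one-way ANOVA; with more than two
conditions Tukey's HSD supplies pairwise p-values.  Significance is marked
with the conventional stars (* p<0.05, ** p<0.01, *** p<0.001) and an
arrow for the direction of change.  No family-wise correction is applied
across metabolites.

For the clustering view, variables (metabolite x compartment) are scaled to
zero mean / unit variance across condition means and clustered
agglomeratively on Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import ValidationError

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    """Conventional significance stars; thresholds are strict."""
    for threshold, mark in STAR_THRESHOLDS:
        if p < threshold:
            return mark
    return ""


@dataclass
class ConditionComparison:
    metabolite_id: str
    compartment: str
    p_value: float
    direction: str  # up | down | none
    stars: str
    tukey: pd.DataFrame | None = None  # pairwise table when > 2 conditions


@dataclass
class ClusterResult:
    scaled: pd.DataFrame
    linkage: np.ndarray  # scipy linkage matrix (merge order + heights)
    leaf_order: list[int]
    axis: str
    method: str


def compare_conditions(
    groups: dict[str, np.ndarray],
    metabolite_id: str = "",
    compartment: str = "",
) -> ConditionComparison:
    """One-way ANOVA across conditions with stars and direction.

    Direction is the sign of (last condition mean - first condition mean),
    i.e. up means the later-listed (e.g. acclimated) condition is higher.
    With all groups constant and equal, p = 1 and no stars.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two conditions to compare")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("need >= 2 replicates per condition")
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:
        p = 1.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            _f, p = sps.f_oneway(*arrays)
        if not np.isfinite(p):
            p = 1.0
    names = list(groups)
    diff = float(arrays[-1].mean() - arrays[0].mean())
    direction = "none" if (diff == 0 or p >= 0.05) else ("up" if diff > 0 else "down")
    tukey = None
    if len(groups) > 2:
        values = np.concatenate(arrays)
        labels = np.concatenate(
            [np.repeat(name, a.size) for name, a in zip(names, arrays)]
        )
        res = pairwise_tukeyhsd(values, labels)
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return ConditionComparison(
        metabolite_id, compartment, float(p), direction, stars_for_p(float(p)), tukey
    )


def annotate_conditions(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Condition comparison for every (metabolite, compartment).

    ``per_replicate`` needs columns metabolite, compartment, condition,
    sample_id (or replicate) and value.  Returns a tidy table with the
    per-condition mean +/- SD, ANOVA p, arrow and stars.
    """
    required = {"metabolite", "compartment", "condition", "value"}
    missing = required - set(per_replicate.columns)
    if missing:
        raise ValidationError(f"per-replicate table lacks column(s) {sorted(missing)}")
    rows = []
    arrow = {"up": "↑", "down": "↓", "none": ""}
    for (met, comp), grp in per_replicate.groupby(
        ["metabolite", "compartment"], sort=False
    ):
        groups = {
            str(cond): sub["value"].to_numpy()
            for cond, sub in grp.groupby("condition", sort=False)
        }
        if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
            continue
        cmp_res = compare_conditions(groups, met, comp)
        row = {
            "metabolite": met,
            "compartment": comp,
            "p_value": cmp_res.p_value,
            "direction": arrow[cmp_res.direction],
            "stars": cmp_res.stars,
        }
        for cond, vals in groups.items():
            row[f"mean_{cond}"] = float(vals.mean())
            row[f"sd_{cond}"] = float(vals.std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def zscore_scale(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Scale every row to zero mean / unit variance across columns.

    Constant rows carry no contrast and are dropped with a warning.  The
    sample SD (n-1) denominator matches the replicate-statistics convention;
    both are available via ``ddof``.
    """
    matrix = matrix.astype(float)
    sd = matrix.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.any():
        dropped = list(matrix.index[constant])
        logger.warning("dropping %d constant row(s): %s", len(dropped), dropped)
        matrix = matrix.loc[~constant]
        sd = sd.loc[~constant]
    return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)


def hierarchical_cluster(
    scaled: pd.DataFrame,
    axis: str = "rows",
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering on Euclidean distances.

    ``axis='rows'`` clusters the rows (variables), ``'columns'`` the
    columns.  Linkage method defaults to average (UPGMA); single, complete
    and ward are accepted.
    """
    if method not in ("single", "complete", "average", "ward"):
        raise ValidationError(f"unknown linkage method {method!r}")
    data = scaled.to_numpy(dtype=float)
    if axis == "columns":
        data = data.T
    elif axis != "rows":
        raise ValidationError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if data.shape[0] < 2:
        raise ValidationError("clustering needs at least two items")
    linkage = hierarchy.linkage(pdist(data, metric="euclidean"), method=method)
    leaf_order = hierarchy.leaves_list(linkage).tolist()
    return ClusterResult(scaled, linkage, leaf_order, axis, method)


def linkage_table(result: ClusterResult) -> pd.DataFrame:
    """Merge list (left, right, height, size) consumable by dendrogram tools."""
    z = result.linkage
    return pd.DataFrame(
        {
            "left": z[:, 0].astype(int),
            "right": z[:, 1].astype(int),
            "height": z[:, 2],
            "size": z[:, 3].astype(int),
        }
    )


def iqr_outlier_mask(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean mask of values outside the k*IQR fences.

    Offered as an optional screen; nothing in the pipeline applies it
    silently.
    """
    values = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)
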