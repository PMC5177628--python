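"""Hit-counting assignment of metabolites to subcellular compartments.

The method assumes that after non-aqueous fractionation each gradient
fraction is a mixture of compartment-derived particles, so a metabolite's
percent profile over fractions should track the marker-enzyme percent
profile of its home compartment.  Agreement is scored pairwise: for every
pair of detected fractions i < j the slope (percent difference) of the
metabolite is compared to each compartment marker's slope on the same pair,

    psi(comp, i, j) = | met_delta(i, j) - marker_delta(comp, i, j) |,

the compartment with minimal psi wins the pair, and compartments whose psi
exceeds the minimum by less than an uncertainty bound (default 5, 7.5 and
10 percentage points, reflecting technical error of the enzyme and GC-MS
measurements) also earn hits.  Hit totals over all pairs, normalized to
100%, are the metabolite's relative subcellular distribution; scaling by a
whole-tissue level gives absolute per-compartment levels.

Under the default "bound-loop" scheme every compartment, including the
arg-min one, is scored against every bound, so the arg-min compartment
earns exactly ``len(bounds)`` hits per pair and a full three-way tie
resolves to 33.3/33.3/33.3.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AbsoluteDistribution,
    AlgorithmConfig,
    DistanceSet,
    ExperimentTable,
    HitTable,
    MarkerProfiles,
    PercentProfile,
    RelativeDistribution,
    SlopeSet,
    UndetectableAnalyteError,
    ValidationError,
    marker_map_from_table,
    normalize_profile,
)

logger = logging.getLogger(__name__)


class SingleFractionCase(ValueError):
    """Signal: fewer than two detected fractions, no pairs can be built."""


def pairwise_slopes(
    profile: PercentProfile,
    fraction_densities: np.ndarray | None = None,
    density_normalized: bool = False,
) -> SlopeSet:
    """Percent differences between all ordered pairs of detected fractions.

    Returns C(k, 2) deltas for k detected fractions, keyed by 0-based
    (i, j) with i < j; delta = percent(j) - percent(i).  With
    ``density_normalized`` each delta is divided by the density spacing of
    its pair (requires densities).
    """
    idx = profile.detected_indices
    if idx.size < 2:
        raise SingleFractionCase(
            f"{profile.analyte_id!r}: {idx.size} detected fraction(s), "
            "pairwise slopes need at least two"
        )
    if density_normalized and fraction_densities is None:
        raise ValidationError("density-normalized slopes require densities")
    pairs: dict[tuple[int, int], float] = {}
    for i, j in combinations(idx.tolist(), 2):
        delta = float(profile.percents[j] - profile.percents[i])
        if density_normalized:
            spacing = float(fraction_densities[j] - fraction_densities[i])
            delta /= spacing
        pairs[(i, j)] = delta
    return SlopeSet(profile.analyte_id, pairs)


def psi_distances(
    met_slopes: SlopeSet,
    marker_slopes: Mapping[str, SlopeSet],
) -> DistanceSet:
    """Absolute slope distances of a metabolite to every compartment marker."""
    psi: dict[tuple[int, int], dict[str, float]] = {}
    for pair, met_delta in met_slopes.pairs.items():
        row: dict[str, float] = {}
        for comp, slopes in marker_slopes.items():
            if pair not in slopes.pairs:
                raise ValidationError(
                    f"marker slopes for {comp!r} lack fraction pair {pair}"
                )
            row[comp] = abs(met_delta - slopes.pairs[pair])
        psi[pair] = row
    return DistanceSet(met_slopes.analyte_id, psi)


def assign_pair_hits(
    psi_for_pair: Mapping[str, float],
    config: AlgorithmConfig = AlgorithmConfig(),
) -> dict[str, float]:
    """Hit increments of one fraction pair.

    The minimal-psi compartment wins the pair; each bound b additionally
    hits every compartment with (psi - min) below b.  Under the default
    bound-loop scheme the winner's hits come entirely from the bound loop
    (its excess is 0, below every bound); under "min-plus-bounds" the first
    arg-min compartment earns one extra hit on top.
    """
    if any(v < 0 for v in psi_for_pair.values()):
        raise ValidationError("psi distances must be non-negative")
    minimum = min(psi_for_pair.values())
    hits = {comp: 0.0 for comp in psi_for_pair}
    for comp, value in psi_for_pair.items():
        excess = value - minimum
        for bound in config.bounds:
            passed = excess < bound if config.strict_inequality else excess <= bound
            if passed:
                hits[comp] += 1.0
    if config.scheme == "min-plus-bounds":
        winner = next(c for c, v in psi_for_pair.items() if v == minimum)
        hits[winner] += 1.0
    return hits


def single_fraction_hits(
    fraction_index: int,
    markers: MarkerProfiles,
    config: AlgorithmConfig = AlgorithmConfig(),
    metabolite_id: str = "",
) -> HitTable:
    """Special case: metabolite detected in exactly one fraction.

    Only the compartment with the highest marker percent in that fraction
    is taken into account; it receives the configured weight.  Ties at the
    maximum follow the tie policy (all full weight, or split evenly).
    ``fraction_index`` is 0-based.
    """
    percent_at = markers.percent_at(fraction_index)
    top = max(percent_at.values())
    winners = [c for c, v in percent_at.items() if v == top]
    weight = float(config.single_fraction_hit_weight)
    counts = {c: 0.0 for c in percent_at}
    if config.tie_policy == "split":
        for c in winners:
            counts[c] = weight / len(winners)
    else:  # all-pass
        for c in winners:
            counts[c] = weight
    return HitTable(metabolite_id, counts, pair_count=0)


def hits_to_distribution(hits: HitTable) -> RelativeDistribution:
    total = hits.total
    if total <= 0:
        raise ValidationError(f"{hits.metabolite_id!r}: no hits to normalize")
    percents = {c: 100.0 * v / total for c, v in hits.counts.items()}
    return RelativeDistribution(hits.metabolite_id, percents)


def metabolite_distribution(
    met: PercentProfile,
    markers: MarkerProfiles,
    config: AlgorithmConfig = AlgorithmConfig(),
    fraction_densities: np.ndarray | None = None,
) -> tuple[HitTable, RelativeDistribution]:
    """Full per-replicate assignment of one metabolite."""
    k = met.n_detected
    if k == 0:
        raise UndetectableAnalyteError(
            f"{met.analyte_id!r}: detected in no fraction"
        )
    if k == 1:
        frac = int(met.detected_indices[0])
        hits = single_fraction_hits(frac, markers, config, met.analyte_id)
        return hits, hits_to_distribution(hits)

    met_slopes = pairwise_slopes(
        met, fraction_densities, config.density_normalized_slopes
    )
    marker_slopes: dict[str, SlopeSet] = {}
    for comp, prof in markers.profiles.items():
        full = pairwise_slopes(
            prof, fraction_densities, config.density_normalized_slopes
        )
        # restrict to the metabolite's detected pairs
        marker_slopes[comp] = SlopeSet(
            prof.analyte_id,
            {p: full.pairs[p] for p in met_slopes.pairs},
        )
    distances = psi_distances(met_slopes, marker_slopes)
    counts = {comp: 0.0 for comp in markers.compartments}
    for pair, psi_row in distances.psi.items():
        for comp, inc in assign_pair_hits(psi_row, config).items():
            counts[comp] += inc
    hits = HitTable(met.analyte_id, counts, pair_count=len(distances.psi))
    return hits, hits_to_distribution(hits)


def aggregate_replicates(
    distributions: Sequence[RelativeDistribution],
) -> RelativeDistribution:
    """Arithmetic mean and sample SD (n-1) across replicate distributions."""
    if not distributions:
        raise ValidationError("no replicate distributions to aggregate")
    met_ids = {d.metabolite_id for d in distributions}
    if len(met_ids) != 1:
        raise ValidationError(f"mixed metabolites in aggregation: {met_ids}")
    compartments = list(distributions[0].percents)
    n = len(distributions)
    stats: dict[str, tuple[float, float, int]] = {}
    means: dict[str, float] = {}
    for comp in compartments:
        vals = np.array([d.percents[comp] for d in distributions])
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        stats[comp] = (mean, sd, n)
        means[comp] = mean
    return RelativeDistribution(met_ids.pop(), means, replicate_stats=stats)


def absolute_subcellular_levels(
    rel: RelativeDistribution,
    whole_tissue_mean: float,
    whole_tissue_sd: float = 0.0,
    unit: str = "nmol g-1 DW",
) -> AbsoluteDistribution:
    """Scale a relative distribution by the whole-tissue metabolite level.

    level(comp) = rel_mean(comp)/100 * whole_mean, with the SD propagated
    for a product of independent means:
    sd = level * sqrt((rel_sd/rel_mean)^2 + (whole_sd/whole_mean)^2).
    """
    if whole_tissue_mean <= 0:
        raise ValidationError(
            f"{rel.metabolite_id!r}: whole-tissue mean must be positive"
        )
    stats = rel.replicate_stats or {
        c: (v, 0.0, 1) for c, v in rel.percents.items()
    }
    levels: dict[str, float] = {}
    sds: dict[str, float] = {}
    for comp, (mean, sd, _n) in stats.items():
        level = mean / 100.0 * whole_tissue_mean
        levels[comp] = level
        if mean == 0:
            sds[comp] = 0.0
        else:
            rel_cv = sd / mean
            whole_cv = whole_tissue_sd / whole_tissue_mean
            sds[comp] = level * math.sqrt(rel_cv**2 + whole_cv**2)
    return AbsoluteDistribution(rel.metabolite_id, levels, sds, unit)


def marker_profiles_for_sample(
    table: ExperimentTable,
    sample_id: str,
    marker_map: Mapping[str, str],
) -> MarkerProfiles:
    profiles = {
        comp: normalize_profile(table.profile(sample_id, analyte))
        for comp, analyte in marker_map.items()
    }
    return MarkerProfiles(profiles)


def run_assignment(
    table: ExperimentTable,
    config: AlgorithmConfig = AlgorithmConfig(),
    marker_map: Mapping[str, str] | None = None,
    whole_tissue: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, object]:
    """Assign every metabolite in every condition of an experiment table.

    Replicates (samples sharing a condition) are processed independently
    and aggregated to mean +/- SD per compartment.  With ``whole_tissue``
    (metabolite -> (mean, sd)) absolute levels are attached.

    Returns a dict with:

    ``relative`` : tidy DataFrame (metabolite, condition, compartment,
        mean_percent, sd_percent, n)
    ``absolute`` : same shape with level/sd columns (empty without
        whole-tissue input)
    ``hits`` : per-replicate hit tables as a tidy DataFrame
    ``skipped`` : list of (metabolite, condition) excluded for lack of data
    """
    if marker_map is None:
        marker_map = marker_map_from_table(table)
    meta = table.sample_meta()
    rel_rows: list[dict] = []
    abs_rows: list[dict] = []
    hit_rows: list[dict] = []
    skipped: list[tuple[str, str]] = []
    metabolites = table.analytes(kind="metabolite")
    for condition, cond_meta in meta.groupby("condition", sort=False):
        samples = list(cond_meta["sample_id"])
        markers = {
            s: marker_profiles_for_sample(table, s, marker_map) for s in samples
        }
        for met in metabolites:
            per_rep: list[RelativeDistribution] = []
            for s in samples:
                try:
                    raw = table.profile(s, met)
                    profile = normalize_profile(raw)
                except (KeyError, UndetectableAnalyteError):
                    continue
                hits, dist = metabolite_distribution(
                    profile, markers[s], config, raw.fraction_densities
                )
                per_rep.append(dist)
                for comp, count in hits.counts.items():
                    hit_rows.append(
                        {
                            "metabolite": met,
                            "condition": condition,
                            "sample_id": s,
                            "compartment": comp,
                            "hits": count,
                            "pair_count": hits.pair_count,
                        }
                    )
            if not per_rep:
                logger.warning(
                    "metabolite %r has no usable replicate in condition %r",
                    met,
                    condition,
                )
                skipped.append((met, str(condition)))
                continue
            agg = aggregate_replicates(per_rep)
            for comp, (mean, sd, n) in agg.replicate_stats.items():
                rel_rows.append(
                    {
                        "metabolite": met,
                        "condition": condition,
                        "compartment": comp,
                        "mean_percent": mean,
                        "sd_percent": sd,
                        "n": n,
                    }
                )
            if whole_tissue and met in whole_tissue:
                w_mean, w_sd = whole_tissue[met]
                absd = absolute_subcellular_levels(agg, w_mean, w_sd)
                for comp in absd.levels:
                    abs_rows.append(
                        {
                            "metabolite": met,
                            "condition": condition,
                            "compartment": comp,
                            "level": absd.levels[comp],
                            "sd": absd.sds[comp],
                            "unit": absd.unit,
                        }
                    )
            elif whole_tissue is not None and met not in whole_tissue:
                logger.warning("no whole-tissue level for %r; skipped", met)
    return {
        "relative": pd.DataFrame(rel_rows),
        "absolute": pd.DataFrame(abs_rows),
        "hits": pd.DataFrame(hit_rows),
        "skipped": skipped,
    }


def format_distribution_table(relative: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Presentation table: one row per metabolite, 'mean +/- SD' per
    (compartment, condition) column, percents rounded to one decimal."""
    df = relative.copy()
    df["cell"] = (
        df["mean_percent"].round(decimals).astype(str)
        + " ± "
        + df["sd_percent"].round(decimals).astype(str)
    )
    out = df.pivot_table(
        index="metabolite",
        columns=["compartment", "condition"],
        values="cell",
        aggfunc="first",
    )
    return out
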