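"""Domain types shared by all stages of the fractionation workflow.

The central objects are per-analyte profiles over the ordered gradient
fractions.  Fractions are numbered 1..f in all user-facing I/O (fraction 1
is the last, lightest supernatant; fraction f the densest pellet); internal
arrays are 0-based in that same order.  Missing metabolite measurements are
carried as NaN and treated as "not detected": they are excluded from
percent normalization and from pair building downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_COMPARTMENTS: tuple[str, ...] = ("plastid", "cytosol", "vacuole")

#: canonical marker enzymes proxying each compartment
DEFAULT_MARKER_ENZYMES: dict[str, str] = {
    "plastid": "alkaline_pyrophosphatase",
    "cytosol": "ugpase",
    "vacuole": "acid_phosphatase",
}

PERCENT_TOL = 1e-9


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class SchemaError(ValidationError):
    """A table does not match the declared schema (missing/extra columns)."""


class UndetectableAnalyteError(ValidationError):
    """All values of an analyte are missing or zero; no percent profile exists."""


def _as_float_array(values: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("profile values must be one-dimensional")
    return arr


@dataclass
class FractionProfile:
    """One analyte's raw values (activity or peak area) over the gradient.

    Parameters
    ----------
    analyte_id
        Identifier of the enzyme or metabolite.
    kind
        ``"marker_enzyme"`` or ``"metabolite"``.
    values
        Raw, non-negative values per fraction; NaN marks a metabolite that
        was not detected in that fraction.  Marker profiles must be complete.
    fraction_densities
        Optional gradient densities (g cm^-3) per fraction, strictly
        monotone along the fraction axis.
    """

    analyte_id: str
    kind: str
    values: np.ndarray
    fraction_densities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values)
        if self.kind not in ("marker_enzyme", "metabolite"):
            raise ValidationError(f"unknown analyte kind {self.kind!r}")
        if self.values.size < 1:
            raise ValidationError("a profile needs at least one fraction")
        finite = np.isfinite(self.values)
        if self.kind == "marker_enzyme" and not finite.all():
            raise ValidationError(
                f"marker profile {self.analyte_id!r} has missing values"
            )
        if np.any(self.values[finite] < 0):
            raise ValidationError(
                f"negative value in profile {self.analyte_id!r}"
            )
        if self.fraction_densities is not None:
            dens = _as_float_array(self.fraction_densities)
            if dens.size != self.values.size:
                raise ValidationError("densities and values differ in length")
            diffs = np.diff(dens)
            if dens.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ValidationError("fraction densities must be strictly monotone")
            self.fraction_densities = dens

    @property
    def n_fractions(self) -> int:
        return int(self.values.size)

    @property
    def detected(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class PercentProfile:
    """Percent-normalized profile: detected values sum to 100."""

    analyte_id: str
    percents: np.ndarray
    detected: np.ndarray

    def __post_init__(self) -> None:
        self.percents = _as_float_array(self.percents)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.percents.size != self.detected.size:
            raise ValidationError("percents and detection mask differ in length")
        if self.detected.any():
            total = float(self.percents[self.detected].sum())
            if not math.isclose(total, 100.0, rel_tol=0, abs_tol=1e-6):
                raise ValidationError(
                    f"percents of {self.analyte_id!r} sum to {total}, not 100"
                )

    @property
    def n_fractions(self) -> int:
        return int(self.percents.size)

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())

    @property
    def detected_indices(self) -> np.ndarray:
        """0-based indices of detected fractions, in gradient order."""
        return np.flatnonzero(self.detected)


def normalize_profile(profile: FractionProfile) -> PercentProfile:
    """Scale the detected values of a raw profile to percent of their sum.

    Undetected (NaN) fractions keep NaN and carry no percent.  Raises
    :class:`UndetectableAnalyteError` when nothing was detected or all
    detected values are zero, since no relative distribution exists then.
    """
    detected = profile.detected
    total = float(profile.values[detected].sum()) if detected.any() else 0.0
    if total <= 0:
        raise UndetectableAnalyteError(
            f"analyte {profile.analyte_id!r} has no positive detected value"
        )
    percents = np.full(profile.n_fractions, np.nan)
    percents[detected] = profile.values[detected] / total * 100.0
    return PercentProfile(profile.analyte_id, percents, detected)


@dataclass
class MarkerProfiles:
    """The three compartment marker percent profiles of one replicate."""

    profiles: dict[str, PercentProfile]

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValidationError("at least one marker profile required")
        sizes = {p.n_fractions for p in self.profiles.values()}
        if len(sizes) != 1:
            raise ValidationError("marker profiles must share the fraction axis")
        for comp, prof in self.profiles.items():
            if not prof.detected.all():
                raise ValidationError(
                    f"marker profile for {comp!r} has undetected fractions"
                )

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(self.profiles)

    @property
    def n_fractions(self) -> int:
        return next(iter(self.profiles.values())).n_fractions

    def percent_at(self, fraction_index: int) -> dict[str, float]:
        """Marker percents of every compartment in one 0-based fraction."""
        return {
            comp: float(prof.percents[fraction_index])
            for comp, prof in self.profiles.items()
        }


@dataclass
class SlopeSet:
    """Pairwise percent differences of one analyte over detected fractions.

    ``pairs[(i, j)]`` with 0-based ``i < j`` holds percent(j) - percent(i)
    in percentage points.
    """

    analyte_id: str
    pairs: dict[tuple[int, int], float]


@dataclass
class DistanceSet:
    """Per-pair, per-compartment distances between metabolite and marker slopes."""

    metabolite_id: str
    psi: dict[tuple[int, int], dict[str, float]]


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunables of the hit-counting assignment.

    bounds
        Percentage-point uncertainty thresholds; a compartment whose
        distance exceeds the minimum by less than a bound earns a hit for
        that bound.  Strictly increasing, positive.
    single_fraction_hit_weight
        Hits awarded in the single-detected-fraction special case; defaults
        to ``len(bounds)`` so the case weighs like one unanimous pair.
    tie_policy
        ``"all-pass"``: compartments tied at the maximum marker percent all
        receive the full weight; ``"split"``: the weight is divided among
        them.  Only the single-fraction case is affected.
    strict_inequality
        Compare (psi - min) to a bound with ``<`` (default) or ``<=``.
    scheme
        ``"bound-loop"`` (default): the minimum hit is realized through the
        bound loop, so the arg-min compartment earns ``len(bounds)`` hits
        per pair.  ``"min-plus-bounds"``: one extra hit for the (first)
        arg-min compartment on top of the bound hits.
    density_normalized_slopes
        Divide each pairwise slope by the density spacing of the pair; off
        by default since a common denominator cancels in the distances.
    """

    bounds: tuple[float, ...] = (5.0, 7.5, 10.0)
    single_fraction_hit_weight: float = 3.0
    tie_policy: str = "all-pass"
    strict_inequality: bool = True
    scheme: str = "bound-loop"
    density_normalized_slopes: bool = False

    def __post_init__(self) -> None:
        bounds = tuple(float(b) for b in self.bounds)
        object.__setattr__(self, "bounds", bounds)
        if not bounds or any(b <= 0 for b in bounds):
            raise ValidationError("bounds must be positive")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValidationError("bounds must be strictly increasing")
        if self.single_fraction_hit_weight <= 0:
            raise ValidationError("single_fraction_hit_weight must be positive")
        if self.tie_policy not in ("all-pass", "split"):
            raise ValidationError(f"unknown tie_policy {self.tie_policy!r}")
        if self.scheme not in ("bound-loop", "min-plus-bounds"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")


@dataclass
class HitTable:
    """Per-compartment hit counts of one metabolite in one replicate."""

    metabolite_id: str
    counts: dict[str, float]
    pair_count: int

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass
class RelativeDistribution:
    """Relative subcellular distribution of one metabolite (percent).

    ``replicate_stats`` maps compartment -> (mean, sd, n) once replicates
    have been aggregated; for a single replicate it is None and
    ``percents`` holds that replicate's values.
    """

    metabolite_id: str
    percents: dict[str, float]
    replicate_stats: dict[str, tuple[float, float, int]] | None = None

    def __post_init__(self) -> None:
        total = sum(self.percents.values())
        if self.percents and not math.isclose(total, 100.0, rel_tol=0, abs_tol=1e-6):
            raise ValidationError(
                f"relative distribution of {self.metabolite_id!r} sums to {total}"
            )


@dataclass
class AbsoluteDistribution:
    """Absolute subcellular levels in the whole-tissue unit."""

    metabolite_id: str
    levels: dict[str, float]
    sds: dict[str, float]
    unit: str = "nmol g-1 DW"


EXPERIMENT_COLUMNS = (
    "sample_id",
    "condition",
    "replicate",
    "fraction_index",
    "analyte_id",
    "kind",
    "value",
)


@dataclass
class ExperimentTable:
    """Long-format container of one fractionation experiment.

    One row per (sample, fraction, analyte).  ``fraction_index`` is 1-based.
    ``fraction_densities`` optionally maps fraction_index -> density.
    """

    data: pd.DataFrame
    fraction_densities: dict[int, float] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in EXPERIMENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"experiment table lacks column(s) {missing}")
        df = self.data.loc[:, list(EXPERIMENT_COLUMNS)].copy()
        df["fraction_index"] = df["fraction_index"].astype(int)
        df["value"] = df["value"].astype(float)
        bad = df["value"] < 0
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"negative value at row {row}")
        dup = df.duplicated(subset=["sample_id", "fraction_index", "analyte_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValidationError(f"duplicate (sample, fraction, analyte) at row {row}")
        for sample, grp in df.groupby("sample_id"):
            fr = np.sort(grp["fraction_index"].unique())
            if fr[0] != 1 or fr[-1] != fr.size:
                raise ValidationError(
                    f"sample {sample!r}: fractions must form a contiguous 1..f range"
                )
        self.data = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data["condition"]))

    def n_fractions(self, sample_id: str) -> int:
        sub = self.data[self.data["sample_id"] == sample_id]
        return int(sub["fraction_index"].max())

    def profile(self, sample_id: str, analyte_id: str) -> FractionProfile:
        """Extract one analyte's FractionProfile from one sample."""
        sub = self.data[
            (self.data["sample_id"] == sample_id)
            & (self.data["analyte_id"] == analyte_id)
        ]
        if sub.empty:
            raise KeyError(f"analyte {analyte_id!r} not in sample {sample_id!r}")
        f = self.n_fractions(sample_id)
        values = np.full(f, np.nan)
        for _, row in sub.iterrows():
            values[int(row["fraction_index"]) - 1] = row["value"]
        kind = str(sub["kind"].iloc[0])
        densities = None
        if self.fraction_densities:
            densities = np.array(
                [self.fraction_densities.get(i + 1, np.nan) for i in range(f)]
            )
            if not np.isfinite(densities).all():
                densities = None
        return FractionProfile(analyte_id, kind, values, densities)

    def analytes(self, kind: str | None = None) -> list[str]:
        df = self.data
        if kind is not None:
            df = df[df["kind"] == kind]
        return list(dict.fromkeys(df["analyte_id"]))

    def sample_meta(self) -> pd.DataFrame:
        """One row per sample: sample_id, condition, replicate."""
        return (
            self.data[["sample_id", "condition", "replicate"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )


def marker_map_from_table(
    table: ExperimentTable,
    compartments: Iterable[str] = DEFAULT_COMPARTMENTS,
) -> dict[str, str]:
    """Infer which marker-enzyme analyte proxies which compartment.

    Accepts analyte ids that equal the compartment label, ``marker_<label>``,
    or the canonical enzyme name for that compartment.
    """
    markers = table.analytes(kind="marker_enzyme")
    mapping: dict[str, str] = {}
    for comp in compartments:
        candidates = {comp, f"marker_{comp}", DEFAULT_MARKER_ENZYMES.get(comp, "")}
        found = [m for m in markers if m in candidates]
        if len(found) != 1:
            raise ValidationError(
                f"cannot infer marker analyte for compartment {comp!r}; "
                f"provide an explicit marker map (markers present: {markers})"
            )
        mapping[comp] = found[0]
    return mapping
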