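"""Synthetic fractionation experiments with known ground truth.

The generator emulates what a benchtop non-aqueous fractionation run
produces: three compartment marker-enzyme percent profiles with
characteristically shifted density optima (plastid material banding light,
vacuolar material dense, cytosol in between), and metabolite profiles that
are convex mixtures of those compartment profiles with known weights,
perturbed by multiplicative lognormal technical noise.  It does not model
the physics of the separation (particle sizes, centrifugation, wash
losses) — only the data the assignment algorithm consumes.

All randomness flows through numpy Generators derived from one master seed
via ``SeedSequence.spawn``, so a config is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_COMPARTMENTS,
    ExperimentTable,
    FractionProfile,
    MarkerProfiles,
    PercentProfile,
    ValidationError,
    normalize_profile,
)

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a simulated experiment.

    marker_centers / marker_width
        Relative positions (0 = lightest fraction, 1 = densest) and common
        width of the unimodal marker optima, per compartment in order.
        Defaults put the plastid optimum light, vacuole dense, cytosol
        intermediate, with enough overlap that neighbouring compartments
        compete on some fraction pairs.
    noise_cv
        Coefficient of variation of the multiplicative lognormal technical
        noise on raw metabolite abundances (GC-MS peak areas are positive
        and heteroscedastic).  Default 0.05, of the order of the technical
        error the uncertainty bounds are meant to absorb.
    missing_rate
        Probability that a metabolite is not detected in a fraction
        (default 0: complete profiles).
    """

    f: int = 6
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    marker_centers: tuple[float, ...] = (0.15, 0.50, 0.85)
    marker_width: float = 0.18
    density_range: tuple[float, float] = (1.20, 1.55)
    noise_cv: float = 0.05
    missing_rate: float = 0.0
    n_replicates: int = 3
    n_metabolites: int = 10
    conditions: tuple[str, ...] = ("non_acclimated",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f < 2:
            raise ValidationError("need at least two fractions")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        if len(self.marker_centers) != len(self.compartments):
            raise ValidationError("one marker center per compartment required")
        if self.marker_width <= 0:
            raise ValidationError("marker_width must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated experiment."""

    compartments: tuple[str, ...]
    #: (condition, metabolite_id) -> weight vector over compartments, sum 1
    weights: dict[tuple[str, str], np.ndarray]
    #: metabolite_id -> (whole-tissue mean, sd) in nmol g-1 DW
    whole_tissue: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "compartments": list(self.compartments),
            "weights": {
                f"{cond}::{met}": w.tolist() for (cond, met), w in self.weights.items()
            },
            "whole_tissue": {m: list(v) for m, v in self.whole_tissue.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        weights = {}
        for key, w in d["weights"].items():
            cond, met = key.split("::", 1)
            weights[(cond, met)] = np.asarray(w, dtype=float)
        whole = {m: (float(v[0]), float(v[1])) for m, v in d["whole_tissue"].items()}
        return cls(tuple(d["compartments"]), weights, whole)

    def dominant(self, condition: str, metabolite_id: str) -> str:
        w = self.weights[(condition, metabolite_id)]
        return self.compartments[int(np.argmax(w))]


def fraction_densities(config: SyntheticConfig) -> np.ndarray:
    lo, hi = config.density_range
    return np.linspace(lo, hi, config.f)


def generate_marker_profiles(config: SyntheticConfig) -> MarkerProfiles:
    """Deterministic compartment marker percent profiles.

    Each profile is a discretized Gaussian optimum over the relative
    fraction axis, normalized to sum 100.  Identical centers are allowed
    (full-tie regime) but flagged with a warning.
    """
    if len(set(config.marker_centers)) < len(config.marker_centers):
        logger.warning(
            "marker centers coincide: compartments are not separable (tie regime)"
        )
    x = (np.arange(config.f) + 0.5) / config.f
    profiles = {}
    for comp, center in zip(config.compartments, config.marker_centers):
        g = np.exp(-0.5 * ((x - center) / config.marker_width) ** 2)
        percents = g / g.sum() * 100.0
        profiles[comp] = PercentProfile(
            f"marker_{comp}", percents, np.ones(config.f, dtype=bool)
        )
    return MarkerProfiles(profiles)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative noise with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_metabolite_profile(
    true_weights: Sequence[float],
    markers: MarkerProfiles,
    noise_cv: float,
    rng: np.random.Generator | int,
    analyte_id: str = "metabolite",
    scale: float = 1.0,
    densities: np.ndarray | None = None,
) -> FractionProfile:
    """Raw metabolite profile as a noisy convex mixture of marker profiles.

    raw(i) = scale * sum_c w_c * marker_percent_c(i) * eps_i with eps_i
    i.i.d. lognormal, E[eps] = 1, CV = ``noise_cv``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    w = np.asarray(true_weights, dtype=float)
    if w.ndim != 1 or w.size != len(markers.compartments):
        raise ValidationError("one weight per compartment required")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValidationError("weights must be non-negative and sum to 1")
    mixed = np.zeros(markers.n_fractions)
    for weight, comp in zip(w, markers.compartments):
        mixed += weight * markers.profiles[comp].percents
    values = scale * mixed * _lognormal_factors(rng, noise_cv, mixed.size)
    return FractionProfile(analyte_id, "metabolite", values, densities)


def generate_experiment(
    config: SyntheticConfig,
) -> tuple[ExperimentTable, SyntheticTruth]:
    """Full multi-replicate (optionally multi-condition) synthetic dataset.

    Marker activities are written per replicate without noise (their percent
    profiles are the reference the algorithm conditions on); metabolite
    abundances carry the configured technical noise and per-metabolite
    peak-area scales.  Ground-truth mixture weights are drawn from a flat
    Dirichlet, independently per condition.
    """
    ss = np.random.SeedSequence(config.seed)
    weight_rng, scale_rng, noise_rng, missing_rng, tissue_rng = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    markers = generate_marker_profiles(config)
    densities = fraction_densities(config)
    met_ids = [f"met_{k:03d}" for k in range(1, config.n_metabolites + 1)]
    scales = 10 ** scale_rng.uniform(4, 7, size=config.n_metabolites)

    truth_weights: dict[tuple[str, str], np.ndarray] = {}
    whole_tissue: dict[str, tuple[float, float]] = {}
    for met in met_ids:
        mean = float(10 ** tissue_rng.uniform(0, 3))  # nmol g-1 DW
        whole_tissue[met] = (mean, 0.1 * mean)

    rows: list[dict] = []
    n_comp = len(config.compartments)
    for condition in config.conditions:
        for met in met_ids:
            truth_weights[(condition, met)] = weight_rng.dirichlet(np.ones(n_comp))
        for rep in range(1, config.n_replicates + 1):
            sample = f"{condition}_r{rep}"
            for comp in config.compartments:
                prof = markers.profiles[comp]
                for i in range(config.f):
                    rows.append(
                        {
                            "sample_id": sample,
                            "condition": condition,
                            "replicate": rep,
                            "fraction_index": i + 1,
                            "analyte_id": f"marker_{comp}",
                            "kind": "marker_enzyme",
                            "value": float(prof.percents[i]),
                        }
                    )
            for met, scale in zip(met_ids, scales):
                profile = generate_metabolite_profile(
                    truth_weights[(condition, met)],
                    markers,
                    config.noise_cv,
                    noise_rng,
                    analyte_id=met,
                    scale=float(scale),
                )
                detected = np.ones(config.f, dtype=bool)
                if config.missing_rate > 0:
                    detected = missing_rng.uniform(size=config.f) >= config.missing_rate
                    if not detected.any():
                        detected[int(missing_rng.integers(config.f))] = True
                for i in range(config.f):
                    if not detected[i]:
                        continue
                    rows.append(
                        {
                            "sample_id": sample,
                            "condition": condition,
                            "replicate": rep,
                            "fraction_index": i + 1,
                            "analyte_id": met,
                            "kind": "metabolite",
                            "value": float(profile.values[i]),
                        }
                    )
    table = ExperimentTable(
        pd.DataFrame(rows),
        fraction_densities={i + 1: float(d) for i, d in enumerate(densities)},
    )
    truth = SyntheticTruth(config.compartments, truth_weights, whole_tissue)
    return table, truth
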