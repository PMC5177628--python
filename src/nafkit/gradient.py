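"""Solvent-density arithmetic for planning non-aqueous density gradients.

The gradient is realized by stepwise dilution of a heavy organic phase
(tetrachlorethylene, TCE) with a light one (n-heptane).  Mixture densities
follow from mass balance under the assumption that the two solvent volumes
are additive:

    rho_mix = sum_i(rho_i * V_i) / sum_i(V_i)

All volumes are mL, densities g cm^-3.  Internal arithmetic is carried at
full precision; rounding to pipettable microlitres is presentation only.

The shipped TCE density constant is 1.60 g cm^-3: it is the unique value
consistent with a heptane density of 0.68 and a 0.484:1 heptane:TCE ratio
producing 1.3 g cm^-3.  Both constants are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd


class GradientError(ValueError):
    """A requested density cannot be reached with the given solvents."""


@dataclass(frozen=True)
class SolventComponent:
    name: str
    density: float  # g cm^-3

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise GradientError(f"solvent density must be positive: {self}")


HEPTANE = SolventComponent("heptane", 0.68)
TETRACHLORETHYLENE = SolventComponent("tetrachlorethylene", 1.60)


@dataclass(frozen=True)
class MixtureStep:
    """One dilution step of the supernatant loop."""

    target_density: float
    carried_volume: float  # mL brought into the step
    carried_density: float
    addition: float  # mL of diluent added
    diluent_density: float

    @property
    def total_volume(self) -> float:
        return self.carried_volume + self.addition

    @property
    def resulting_density(self) -> float:
        return mixture_density(
            [(self.carried_volume, self.carried_density),
             (self.addition, self.diluent_density)]
            if self.addition > 0
            else [(self.carried_volume, self.carried_density)]
        )


@dataclass
class GradientPlan:
    """Ordered dilution steps realizing a descending density ladder."""

    steps: list[MixtureStep] = field(default_factory=list)
    residual_supernatant_volume: float = 0.05  # mL left in the pellet

    def to_frame(self, decimals: int = 3) -> pd.DataFrame:
        """Pipetting table with volumes rounded to microlitre precision."""
        rows = []
        for k, s in enumerate(self.steps, start=1):
            rows.append(
                {
                    "step": k,
                    "target_density_g_cm3": round(s.target_density, decimals),
                    "carried_volume_mL": round(s.carried_volume, decimals),
                    "carried_density_g_cm3": round(s.carried_density, decimals),
                    "diluent_addition_mL": round(s.addition, decimals),
                    "total_volume_mL": round(s.total_volume, decimals),
                }
            )
        return pd.DataFrame(rows)


def mixture_density(components: Sequence[tuple[float, float]]) -> float:
    """Density of an ideal (volume-additive) mixture.

    ``components`` is a sequence of (volume mL, density g cm^-3) pairs with
    positive volumes.
    """
    if not components:
        raise GradientError("mixture needs at least one component")
    if any(v <= 0 for v, _ in components):
        raise GradientError("component volumes must be positive")
    mass = sum(v * rho for v, rho in components)
    volume = sum(v for v, _ in components)
    return mass / volume


def diluent_volume_for_target(
    current_volume: float,
    current_density: float,
    diluent_density: float,
    target_density: float,
) -> float:
    """Diluent volume x that brings the mixture to the target density.

    Solves rho_target = (rho_cur*V + rho_dil*x)/(V + x) for x:
    x = V * (rho_cur - rho_target) / (rho_target - rho_dil).
    Returns 0 when the target equals the current density.
    """
    if current_volume <= 0:
        raise GradientError("current volume must be positive")
    if target_density == current_density:
        return 0.0
    lo, hi = sorted((diluent_density, current_density))
    if not (lo < target_density < hi):
        raise GradientError(
            f"unreachable density {target_density} g cm^-3: must lie strictly "
            f"between diluent ({diluent_density}) and current ({current_density})"
        )
    return (
        current_volume
        * (current_density - target_density)
        / (target_density - diluent_density)
    )


def solvent_ratio_for_density(
    target_density: float,
    heavy: SolventComponent = TETRACHLORETHYLENE,
    light: SolventComponent = HEPTANE,
) -> float:
    """Volumetric ratio light:heavy (r : 1) giving the target density.

    Solves (rho_light*r + rho_heavy)/(r + 1) = rho_target.
    """
    if target_density == heavy.density:
        return 0.0
    lo, hi = sorted((light.density, heavy.density))
    if not (lo < target_density < hi):
        raise GradientError(
            f"unreachable density {target_density}: outside "
            f"({lo}, {hi}) for {light.name}/{heavy.name}"
        )
    return (heavy.density - target_density) / (target_density - light.density)


def plan_gradient(
    start_volume: float,
    start_density: float,
    targets: Sequence[float],
    diluent: SolventComponent = HEPTANE,
    residual_supernatant_volume: float = 0.05,
) -> GradientPlan:
    """Plan the supernatant dilution loop down a descending density ladder.

    Each step dilutes the full carried volume; the resulting mixture density
    is verified against the target before the next step.
    """
    targets = list(targets)
    if any(t2 >= t1 for t1, t2 in zip(targets, targets[1:])):
        raise GradientError("target densities must be strictly decreasing")
    plan = GradientPlan(residual_supernatant_volume=residual_supernatant_volume)
    volume, density = float(start_volume), float(start_density)
    for k, target in enumerate(targets, start=1):
        try:
            x = diluent_volume_for_target(volume, density, diluent.density, target)
        except GradientError as exc:
            raise GradientError(f"step {k} (target {target} g cm^-3): {exc}") from exc
        plan.steps.append(
            MixtureStep(
                target_density=target,
                carried_volume=volume,
                carried_density=density,
                addition=x,
                diluent_density=diluent.density,
            )
        )
        volume += x
        density = target
    return plan
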