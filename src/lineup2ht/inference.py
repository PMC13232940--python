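"""Likelihood-ratio (ΔG²) tests of equality constraints on 2-HT parameters.

Hypotheses about the latent processes — e.g. "culprit-presence detection does
not differ between presentation formats" — are tested by adding the
corresponding equality constraint to a general model and comparing fits:

    ΔG² = G²(restricted) − G²(general),   Δdf = df(restricted) − df(general),

with ΔG² asymptotically χ²(Δdf) under the restriction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import chi2

from .estimation import FitOptions, FitResult, FrequencyData, fit
from .model import ModelSpec, collapse_onto, with_equality

__all__ = [
    "NestedTestResult",
    "OptimizationQualityError",
    "test_equality",
    "test_grouped_vs_rest",
]

_NEG_TOL = 1e-6  # ΔG² below -_NEG_TOL indicates an optimization failure


class OptimizationQualityError(RuntimeError):
    """Raised when the restricted model fits better than the general one
    beyond numerical tolerance, which a correct nested fit cannot do."""


@dataclass(frozen=True)
class NestedTestResult:
    """Outcome of a restricted-vs-general model comparison."""

    delta_G2: float
    delta_df: int
    p_value: float
    general_fit: FitResult
    restricted_fit: FitResult

    def summary(self) -> str:
        return (
            f"dG2({self.delta_df}) = {self.delta_G2:.4f}, "
            f"p = {self.p_value:.4f}"
        )


def _compare(
    general: FitResult, restricted: FitResult
) -> tuple[float, int, float]:
    delta = restricted.G2 - general.G2
    if delta < -_NEG_TOL:
        raise OptimizationQualityError(
            f"restricted model fits better than general (dG2 = {delta:.3g}); "
            "the general fit did not reach its maximum"
        )
    delta = max(delta, 0.0)
    delta_df = restricted.df - general.df
    if delta_df < 1:
        raise ValueError(
            "restriction removes no free parameter (delta df = "
            f"{delta_df}); models are not properly nested"
        )
    return delta, delta_df, float(chi2.sf(delta, delta_df))


def _fit_pair(
    general_spec: ModelSpec,
    restricted_spec: ModelSpec,
    data: FrequencyData,
    options: FitOptions | None,
) -> tuple[FitResult, FitResult]:
    options = options or FitOptions()
    general = fit(general_spec, data, options)
    # Seed the restricted fit with the general solution collapsed onto the
    # constraint: guards against spurious positive dG2 from a failed start.
    seed_start = collapse_onto(
        general.free_estimates, general_spec, restricted_spec
    )
    restricted_options = FitOptions(
        n_starts=options.n_starts,
        seed=options.seed,
        extra_starts=options.extra_starts + (tuple(seed_start),),
        ftol=options.ftol,
        gtol=options.gtol,
        maxiter=options.maxiter,
        compute_se=options.compute_se,
    )
    restricted = fit(restricted_spec, data, restricted_options)
    return general, restricted


def test_equality(
    spec: ModelSpec,
    data: FrequencyData,
    parameter: str,
    condition_groups: Sequence[Iterable[str]],
    options: FitOptions | None = None,
) -> NestedTestResult:
    """Test equality of ``parameter`` within each group of conditions.

    The restricted model adds one equality constraint per group to ``spec``
    and is therefore nested in it. Returns ΔG², Δdf and the χ² upper-tail
    p-value.

    Parameters
    ----------
    spec
        The general model.
    data
        Observed frequencies.
    parameter
        One of dP, dA, b, g.
    condition_groups
        Groups of condition names; the parameter is equated within each
        group (typically a single group, giving Δdf = group size − 1).
    """
    restricted_spec = spec
    for group in condition_groups:
        restricted_spec = with_equality(restricted_spec, parameter, group)
    general, restricted = _fit_pair(spec, restricted_spec, data, options)
    delta, delta_df, p = _compare(general, restricted)
    return NestedTestResult(delta, delta_df, p, general, restricted)


def test_grouped_vs_rest(
    spec: ModelSpec,
    data: FrequencyData,
    parameter: str,
    focal_condition: str,
    rest_conditions: Sequence[str],
    options: FitOptions | None = None,
) -> NestedTestResult:
    """One-df test of a focal condition against an already-pooled rest.

    Requires that ``parameter`` already shares a single free index across
    ``rest_conditions`` in the general ``spec`` (i.e. the pooling step was
    performed first); the restricted model then equates the focal condition
    with that pooled value.
    """
    rest = list(rest_conditions)
    indices = {spec.constraint_map.get((parameter, cond)) for cond in rest}
    if len(indices) != 1 or None in indices:
        raise ValueError(
            f"parameter {parameter!r} must already share one free index "
            f"across {rest}; pool those conditions first"
        )
    restricted_spec = with_equality(spec, parameter, [focal_condition] + rest)
    general, restricted = _fit_pair(spec, restricted_spec, data, options)
    delta, delta_df, p = _compare(general, restricted)
    if delta_df != 1:
        raise ValueError(
            f"grouped-vs-rest test should free exactly one df, got {delta_df}"
        )
    return NestedTestResult(delta, delta_df, p, general, restricted)
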