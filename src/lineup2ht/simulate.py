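"""Synthetic response-frequency data from the 2-HT trees.

The generator draws pooled multinomial counts per (condition, tree) from the
model's category probabilities — exactly the independence assumption the
pooled MPT analysis makes. Each simulated participant contributes a fixed
number of culprit-present and culprit-absent lineup responses (four in total
in the designs emulated here: 2+2, or 3+1 / 1+3); responses are pooled at
the condition × tree level, so per-participant clustering is not modelled.

:func:`recovery_study` wraps simulate → fit replications and aggregates
bias, RMSE, empirical SE and Wald-interval coverage per parameter — the
standard validation harness for MPT estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .estimation import FitOptions, FrequencyData, fit
from .model import (
    DEFAULT_GUESS_SPLIT,
    PARAM_NAMES,
    ModelSpec,
    Params2HT,
    TreeKind,
    category_probs,
    expand,
)

__all__ = [
    "ConditionDesign",
    "DesignSpec",
    "RecoveryReport",
    "simulate",
    "recovery_study",
]


@dataclass(frozen=True)
class ConditionDesign:
    """Sampling plan and true parameters for one condition."""

    n_participants: int
    lineups_present: int
    lineups_absent: int
    params: Params2HT

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.lineups_present < 0 or self.lineups_absent < 0:
            raise ValueError("lineup counts must be non-negative")
        if self.lineups_present + self.lineups_absent == 0:
            raise ValueError("each participant must see at least one lineup")


@dataclass(frozen=True)
class DesignSpec:
    """A full simulated experiment: per-condition designs plus a seed."""

    conditions: Mapping[str, ConditionDesign]
    seed: int
    guess_split_c: float = DEFAULT_GUESS_SPLIT

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("design needs at least one condition")
        if not (0.0 < self.guess_split_c < 1.0):
            raise ValueError("guess_split_c must lie in (0, 1)")


def simulate(
    design: DesignSpec, rng: np.random.Generator | None = None
) -> FrequencyData:
    """Draw pooled multinomial response counts from the 2-HT trees.

    For each condition, N_present = n_participants × lineups_present
    responses are drawn from the culprit-present tree and analogously for
    the culprit-absent tree. Reproducible given the design's seed; pass an
    explicit ``rng`` to draw from a caller-managed stream instead (used for
    replicate substreams in :func:`recovery_study`).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    counts: dict[tuple[str, TreeKind], np.ndarray] = {}
    for name, cond in design.conditions.items():
        for tree, n_lineups in (
            (TreeKind.CULPRIT_PRESENT, cond.lineups_present),
            (TreeKind.CULPRIT_ABSENT, cond.lineups_absent),
        ):
            if n_lineups == 0:
                continue
            p = np.asarray(
                category_probs(cond.params, tree, design.guess_split_c)
            )
            n_tree = cond.n_participants * n_lineups
            counts[(name, tree)] = rng.multinomial(n_tree, p)
    return FrequencyData(counts)


@dataclass(frozen=True)
class RecoveryReport:
    """Estimator performance over simulated replicates.

    ``table`` is indexed by (parameter, condition) and reports the true
    value, mean estimate, bias, RMSE, empirical SE (SD of estimates across
    replicates, ddof=1), mean model-based SE, and coverage of the nominal
    95% Wald interval. RMSE uses the population variance, so
    RMSE² = bias² + var exactly. With a single replicate the variance
    columns are NaN and ``variance_defined`` is False.
    """

    table: pd.DataFrame
    n_replicates: int
    seed: int
    n_failures: int = 0
    misspecified: bool = False

    @property
    def failure_rate(self) -> float:
        return self.n_failures / self.n_replicates

    @property
    def variance_defined(self) -> bool:
        return self.n_replicates - self.n_failures > 1


def recovery_study(
    design: DesignSpec,
    n_replicates: int,
    fit_spec: ModelSpec,
    fit_options: FitOptions | None = None,
) -> RecoveryReport:
    """Simulate → fit → aggregate over seeded replicates.

    The design's master seed spawns one independent substream per replicate,
    so the study is reproducible and insensitive to execution order. True
    parameters that violate ``fit_spec``'s equality constraints are allowed
    (deliberate misspecification studies) but flagged in the report.
    Replicate-level fit failures are recorded as a failure rate, not fatal.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    fit_options = fit_options or FitOptions()

    truth = {
        name: cond.params.as_array()
        for name, cond in design.conditions.items()
    }
    misspecified = False
    for index, slots in fit_spec.slot_labels().items():
        values = {
            truth[cond][PARAM_NAMES.index(param)] for param, cond in slots
        }
        if len({round(v, 12) for v in values}) > 1:
            misspecified = True

    slots = [
        (param, cond)
        for param in PARAM_NAMES
        for cond in fit_spec.condition_names
        if (param, cond) in fit_spec.constraint_map
    ]
    estimates = np.full((n_replicates, len(slots)), np.nan)
    model_se = np.full((n_replicates, len(slots)), np.nan)
    n_failures = 0

    streams = np.random.SeedSequence(design.seed).spawn(n_replicates)
    for r, stream in enumerate(streams):
        data = simulate(design, rng=np.random.default_rng(stream))
        try:
            result = fit(fit_spec, data, fit_options)
            if not result.converged:
                raise RuntimeError("fit did not converge")
        except Exception:
            n_failures += 1
            continue
        for s, slot in enumerate(slots):
            estimates[r, s] = result.estimates[slot]
            model_se[r, s] = result.se[slot]

    rows = []
    for s, (param, cond) in enumerate(slots):
        true_value = float(truth[cond][PARAM_NAMES.index(param)])
        est = estimates[:, s]
        est = est[np.isfinite(est)]
        ses = model_se[:, s]
        ses = ses[np.isfinite(ses)]
        mean = float(est.mean()) if est.size else float("nan")
        bias = mean - true_value
        var = float(est.var(ddof=0)) if est.size else float("nan")
        rmse = float(np.sqrt(bias**2 + var))
        emp_se = float(est.std(ddof=1)) if est.size > 1 else float("nan")
        if est.size and ses.size == est.size:
            z = 1.959963984540054  # Phi^{-1}(0.975)
            covered = np.abs(estimates[:, s] - true_value) <= z * model_se[:, s]
            coverage = float(
                np.nanmean(np.where(np.isfinite(model_se[:, s]), covered, np.nan))
            )
        else:
            coverage = float("nan")
        rows.append(
            {
                "parameter": param,
                "condition": cond,
                "true": true_value,
                "mean": mean,
                "bias": bias,
                "rmse": rmse,
                "empirical_se": emp_se,
                "mean_model_se": float(ses.mean()) if ses.size else float("nan"),
                "coverage95": coverage,
            }
        )
    table = pd.DataFrame(rows).set_index(["parameter", "condition"])
    return RecoveryReport(
        table=table,
        n_replicates=n_replicates,
        seed=design.seed,
        n_failures=n_failures,
        misspecified=misspecified,
    )
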