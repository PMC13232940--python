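"""Constrained maximum-likelihood estimation for the multi-condition 2-HT model.

Counts per (condition, tree) are treated as pooled multinomial draws over the
three response categories. The log-likelihood kernel omits the multinomial
coefficient, which does not depend on the parameters. Fitting maximizes the
likelihood over the unit hypercube of free parameters with a multi-start
bounded quasi-Newton search; fit quality is summarized by the likelihood-ratio
goodness-of-fit statistic

    G² = 2 · Σ n · ln(n / (N · p̂)),

summed over cells with n > 0, which is asymptotically χ²-distributed with
df = (#cells) − (#trees) − (#free parameters). Standard errors come from the
inverse observed information (numerical Hessian of the negative
log-likelihood at the MLE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .model import PARAM_NAMES, ModelSpec, TreeKind, expand

__all__ = [
    "FrequencyData",
    "FitOptions",
    "FitResult",
    "log_likelihood",
    "fit",
    "degrees_of_freedom",
    "standard_errors",
    "gof_p_value",
]

_CATEGORIES = ("suspect", "filler", "rejection")
_BOUND_EPS = 1e-9  # optimizer box is [eps, 1-eps]
_BOUNDARY_TOL = 1e-6  # estimates this close to 0/1 are flagged


@dataclass(frozen=True)
class FrequencyData:
    """Observed response counts per (condition, tree).

    ``counts`` maps (condition name, :class:`TreeKind`) to the length-3
    integer array (n_suspect, n_filler, n_reject). This is the sufficient
    statistic for every analysis in the package.
    """

    counts: Mapping[tuple[str, TreeKind], np.ndarray]

    def __post_init__(self) -> None:
        cleaned = {}
        for key, values in self.counts.items():
            cond, tree = key
            tree = TreeKind(tree)
            arr = np.asarray(values)
            if arr.shape != (3,):
                raise ValueError(
                    f"counts for {key} must have three categories, got "
                    f"shape {arr.shape}"
                )
            if np.any(arr < 0) or not np.all(arr == np.floor(arr)):
                raise ValueError(
                    f"counts for {key} must be non-negative integers"
                )
            cleaned[(cond, tree)] = arr.astype(np.int64)
        object.__setattr__(self, "counts", cleaned)
        if not cleaned:
            raise ValueError("FrequencyData must contain at least one tree")

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for cond, _tree in self.counts:
            seen.setdefault(cond)
        return tuple(seen)

    def total(self, condition: str, tree: TreeKind) -> int:
        """Number of lineup responses N for one tree."""
        return int(self.counts[(condition, TreeKind(tree))].sum())

    @property
    def n_cells(self) -> int:
        return 3 * len(self.counts)

    @property
    def n_trees(self) -> int:
        return len(self.counts)

    @property
    def n_total(self) -> int:
        """Grand total of responses across all trees."""
        return int(sum(arr.sum() for arr in self.counts.values()))


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    ``n_starts`` points are tried: the first at 0.5 everywhere, the rest
    drawn uniformly from [0.05, 0.95] with ``seed``; ``extra_starts`` are
    appended (used to seed restricted fits with a collapsed general
    solution). The best converged solution is kept.
    """

    n_starts: int = 10
    seed: int = 0
    extra_starts: tuple[tuple[float, ...], ...] = ()
    ftol: float = 1e-14
    gtol: float = 1e-12
    maxiter: int = 2000
    compute_se: bool = True


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of a :class:`ModelSpec` to frequency data."""

    spec: ModelSpec
    free_estimates: np.ndarray
    estimates: Mapping[tuple[str, str], float]
    se: Mapping[tuple[str, str], float]  # NaN where unavailable
    log_likelihood: float
    G2: float
    df: int
    p_value: float
    converged: bool
    n_starts_used: int
    boundary_slots: tuple[tuple[str, str], ...] = ()

    def estimate(self, parameter: str, condition: str) -> float:
        return self.estimates[(parameter, condition)]

    def summary(self) -> str:
        lines = [
            f"G2({self.df}) = {self.G2:.4f}, p = {self.p_value:.4f}, "
            f"logL = {self.log_likelihood:.4f}",
        ]
        for index, slots in self.spec.slot_labels().items():
            label = " = ".join(f"{p}[{c}]" for p, c in slots)
            se = self.se[slots[0]]
            se_txt = f"{se:.4f}" if np.isfinite(se) else "n/a"
            flag = " (boundary)" if slots[0] in self.boundary_slots else ""
            lines.append(
                f"  {label} = {self.free_estimates[index]:.4f} "
                f"(SE = {se_txt}){flag}"
            )
        return "\n".join(lines)


def _check_match(spec: ModelSpec, data: FrequencyData) -> None:
    missing = set(data.conditions) - set(spec.condition_names)
    if missing:
        raise ValueError(f"data conditions {sorted(missing)} not in model spec")
    absent = set(spec.condition_names) - set(data.conditions)
    if absent:
        raise ValueError(f"model conditions {sorted(absent)} have no data")


def _build_kernel(
    spec: ModelSpec, data: FrequencyData
) -> tuple[Callable[[np.ndarray], np.ndarray], np.ndarray, np.ndarray]:
    """Vectorized category probabilities for all trees with data.

    Returns ``(probs_fn, counts, totals)`` where ``probs_fn(x)`` maps a free
    vector to an (n_trees, 3) probability matrix in the same row order as
    ``counts``.
    """
    rows = list(data.counts)
    counts = np.stack([data.counts[key] for key in rows]).astype(float)
    totals = counts.sum(axis=1)

    idx = np.full((len(rows), 4), -1, dtype=int)
    fixed = np.zeros((len(rows), 4))
    for r, (cond, _tree) in enumerate(rows):
        for p, param in enumerate(PARAM_NAMES):
            slot = (param, cond)
            if slot in spec.fixed_values:
                fixed[r, p] = spec.fixed_values[slot]
            else:
                idx[r, p] = spec.constraint_map[slot]
    present = np.array(
        [tree is TreeKind.CULPRIT_PRESENT for _cond, tree in rows]
    )
    c = spec.guess_split_c

    def probs_fn(x: np.ndarray) -> np.ndarray:
        P = np.where(idx >= 0, np.asarray(x)[idx], fixed)
        dP, dA, b, g = P.T
        d = np.where(present, dP, dA)
        miss = 1.0 - d
        guess_mass = miss * (1.0 - b) * g
        p_suspect = np.where(present, d, 0.0) + miss * b + guess_mass * c
        p_filler = guess_mass * (1.0 - c)
        p_reject = np.where(present, 0.0, d) + miss * (1.0 - b) * (1.0 - g)
        return np.stack([p_suspect, p_filler, p_reject], axis=1)

    return probs_fn, counts, totals


def log_likelihood(
    spec: ModelSpec, free_vector: Sequence[float], data: FrequencyData
) -> float:
    """Multinomial log-likelihood kernel Σ n·ln p (coefficient omitted).

    Cells with n = 0 contribute zero regardless of p; a cell with p = 0 and
    n > 0 yields −inf.
    """
    _check_match(spec, data)
    probs_fn, counts, _totals = _build_kernel(spec, data)
    p = probs_fn(np.asarray(free_vector, dtype=float))
    observed = counts > 0
    if np.any(observed & (p <= 0.0)):
        return float("-inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(observed, counts * np.log(p), 0.0)
    return float(terms.sum())


def degrees_of_freedom(spec: ModelSpec, data: FrequencyData) -> int:
    """df = (#cells) − (#trees) − (#free parameters).

    Each multinomial tree loses one cell to the sum-to-N constraint; each
    free parameter absorbs one further degree of freedom.
    """
    _check_match(spec, data)
    df = data.n_cells - data.n_trees - spec.n_free
    if df < 0:
        raise ValueError(
            f"model has more free parameters ({spec.n_free}) than the data "
            f"support ({data.n_cells - data.n_trees} identifiable df)"
        )
    return df


def gof_p_value(G2: float, df: int) -> float:
    """Upper-tail χ² probability of the goodness-of-fit statistic.

    A saturated model (df = 0) has p defined as 1.
    """
    if G2 < 0:
        raise ValueError(f"G2 must be non-negative, got {G2!r}")
    if df < 0:
        raise ValueError(f"df must be non-negative, got {df!r}")
    if df == 0:
        return 1.0  # saturated: the statistic is identically 0
    return float(chi2.sf(G2, df))


def _g_squared(counts: np.ndarray, totals: np.ndarray, p: np.ndarray) -> float:
    expected = totals[:, None] * p
    observed = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(observed, counts * np.log(counts / expected), 0.0)
    return float(2.0 * terms.sum())


def fit(
    spec: ModelSpec, data: FrequencyData, options: FitOptions | None = None
) -> FitResult:
    """Maximize the multinomial likelihood over [0, 1]^k.

    Runs L-BFGS-B from multiple deterministic-seeded starting points and
    keeps the best converged solution; non-convergence of every start is
    flagged in the result, never silent. Estimates within 1e-6 of a bound
    are flagged as boundary solutions (their SEs are approximate).
    """
    options = options or FitOptions()
    _check_match(spec, data)
    for cond in spec.condition_names:
        if all(data.total(cond, tree) == 0 for _c, tree in data.counts if _c == cond):
            raise ValueError(f"condition {cond!r} has no responses")
    probs_fn, counts, totals = _build_kernel(spec, data)
    k = spec.n_free

    observed = counts > 0

    def nll(x: np.ndarray) -> float:
        p = np.clip(probs_fn(x), 1e-300, 1.0)
        return -float(np.where(observed, counts * np.log(p), 0.0).sum())

    rng = np.random.default_rng(options.seed)
    starts = [np.full(k, 0.5)]
    starts += [
        rng.uniform(0.05, 0.95, size=k) for _ in range(options.n_starts - 1)
    ]
    starts += [
        np.clip(np.asarray(s, dtype=float), 0.05, 0.95)
        for s in options.extra_starts
    ]

    best = None
    any_converged = False
    bounds = [(_BOUND_EPS, 1.0 - _BOUND_EPS)] * k
    for x0 in starts:
        result = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "ftol": options.ftol,
                "gtol": options.gtol,
                "maxiter": options.maxiter,
            },
        )
        any_converged = any_converged or bool(result.success)
        if best is None or result.fun < best.fun:
            best = result
    assert best is not None

    x_hat = np.asarray(best.x)
    p_hat = probs_fn(x_hat)
    G2 = _g_squared(counts, totals, p_hat)
    df = degrees_of_freedom(spec, data)
    ll = log_likelihood(spec, x_hat, data)

    boundary = tuple(
        slot
        for slot in spec.constraint_map
        if min(
            x_hat[spec.constraint_map[slot]],
            1.0 - x_hat[spec.constraint_map[slot]],
        )
        < _BOUNDARY_TOL
    )
    if not any_converged:
        warnings.warn(
            "no optimizer start reported convergence; returning best point "
            "found",
            RuntimeWarning,
        )

    estimates = {
        slot: float(x_hat[index]) for slot, index in spec.constraint_map.items()
    }
    estimates.update({slot: v for slot, v in spec.fixed_values.items()})
    if options.compute_se:
        se = standard_errors(spec, data, x_hat)
    else:
        se = {slot: float("nan") for slot in estimates}

    return FitResult(
        spec=spec,
        free_estimates=x_hat,
        estimates=estimates,
        se=se,
        log_likelihood=ll,
        G2=max(G2, 0.0),
        df=df,
        p_value=gof_p_value(max(G2, 0.0), df),
        converged=any_converged,
        n_starts_used=len(starts),
        boundary_slots=boundary,
    )


def standard_errors(
    spec: ModelSpec, data: FrequencyData, mle: Sequence[float]
) -> dict[tuple[str, str], float]:
    """SEs from the inverse observed information at the MLE.

    The Hessian of the negative log-likelihood is approximated by central
    differences with step 1e-5; estimates closer than the step to a bound
    are nudged inward first so all evaluation points stay in the unit cube.
    A singular information matrix yields NaN SEs and a warning — the point
    estimates remain valid. Fixed slots have no sampling variability and
    get SE 0.
    """
    _check_match(spec, data)
    probs_fn, counts, _totals = _build_kernel(spec, data)
    observed = counts > 0

    def nll(x: np.ndarray) -> float:
        p = np.clip(probs_fn(x), 1e-300, 1.0)
        return -float(np.where(observed, counts * np.log(p), 0.0).sum())

    h = 1e-5
    x = np.clip(np.asarray(mle, dtype=float), 2 * h, 1.0 - 2 * h)
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                nll(x + ei + ej)
                - nll(x + ei - ej)
                - nll(x - ei + ej)
                + nll(x - ei - ej)
            ) / (4.0 * h * h)

    free_se = np.full(k, np.nan)
    eigenvalues = np.linalg.eigvalsh(H)
    # threshold sits above the finite-difference noise floor (~1e-7
    # relative) but far below any genuinely informative direction
    if eigenvalues.min() <= eigenvalues.max() * 1e-6:
        # rank-deficient or indefinite information: parameters are not
        # locally identified, so no finite SEs exist
        warnings.warn(
            "observed information matrix is singular or indefinite; SEs "
            "unavailable (point estimates remain valid)",
            RuntimeWarning,
        )
    else:
        diag = np.diag(np.linalg.inv(H))
        with np.errstate(invalid="ignore"):
            free_se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)

    se = {
        slot: float(free_se[index])
        for slot, index in spec.constraint_map.items()
    }
    se.update({slot: 0.0 for slot in spec.fixed_values})
    return se
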