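"""Core two-high-threshold (2-HT) eyewitness identification model.

The 2-HT model is a multinomial processing tree (MPT) model for simultaneous
lineups. A lineup presents one suspect among five fillers; the witness either
selects the suspect, selects a filler, or rejects the lineup. The model
explains these three observable outcomes through four latent processes:

``dP``
    probability of detecting the culprit's presence (culprit-present lineups
    only), which produces a culprit identification;
``dA``
    probability of detecting the culprit's absence (culprit-absent lineups
    only), which produces a lineup rejection;
``b``
    probability of biased suspect selection when detection fails — the
    witness is drawn to the suspect, e.g. because the lineup is unfair;
``g``
    probability of guessing-based selection when neither detection nor bias
    operates; a guess lands on the suspect with the random-sampling
    probability ``c`` = 1 / lineup size and on a filler with ``1 - c``.

A study typically fits several instances of these trees — one
culprit-present and one culprit-absent tree per experimental condition —
with equality constraints tying parameters across conditions.
:class:`ModelSpec` encodes that multi-condition structure as a mapping from
(parameter, condition) slots to shared free-parameter indices or fixed
constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_GUESS_SPLIT",
    "Params2HT",
    "TreeKind",
    "CategoryProbs",
    "ModelSpec",
    "category_probs",
    "build_model",
    "expand",
    "with_equality",
    "collapse_onto",
    "to_eqn",
]

#: Canonical parameter order; index assignment and reporting follow it.
PARAM_NAMES = ("dP", "dA", "b", "g")

#: Guessing split for a six-member lineup, stored as the literal decimal
#: approximation to 1/6 used in the reference analyses (not as 1/6 exactly).
DEFAULT_GUESS_SPLIT = 0.16667


class TreeKind(str, Enum):
    """Which of the two lineup trees a set of counts belongs to."""

    CULPRIT_PRESENT = "culprit_present"
    CULPRIT_ABSENT = "culprit_absent"


class CategoryProbs(NamedTuple):
    """Probabilities of the three observable lineup outcomes."""

    p_suspect: float
    p_filler: float
    p_reject: float


@dataclass(frozen=True)
class Params2HT:
    """The four 2-HT process probabilities for one condition.

    Raises
    ------
    ValueError
        If any field lies outside the closed unit interval. The error names
        the offending field.
    """

    dP: float
    dA: float
    b: float
    g: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(
                    f"parameter {name!r} must lie in [0, 1], got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.dP, self.dA, self.b, self.g], dtype=float)


def category_probs(
    params: Params2HT, tree: TreeKind, c: float = DEFAULT_GUESS_SPLIT
) -> CategoryProbs:
    """Category probabilities of one 2-HT tree.

    Culprit-present tree::

        p_suspect = dP + (1-dP)·b + (1-dP)·(1-b)·g·c
        p_filler  = (1-dP)·(1-b)·g·(1-c)
        p_reject  = (1-dP)·(1-b)·(1-g)

    Culprit-absent tree::

        p_suspect = (1-dA)·b + (1-dA)·(1-b)·g·c
        p_filler  = (1-dA)·(1-b)·g·(1-c)
        p_reject  = dA + (1-dA)·(1-b)·(1-g)

    The three probabilities sum to one by construction.

    Parameters
    ----------
    params
        Process probabilities.
    tree
        Which tree to evaluate.
    c
        Guessing split (1 / lineup size). Must lie strictly inside (0, 1):
        degenerate splits correspond to no real lineup and are rejected.
    """
    if not (0.0 < c < 1.0):
        raise ValueError(f"guessing split c must lie in (0, 1), got {c!r}")
    tree = TreeKind(tree)
    dP, dA, b, g = params.dP, params.dA, params.b, params.g
    if tree is TreeKind.CULPRIT_PRESENT:
        non_detect = 1.0 - dP
        p_suspect = dP + non_detect * b + non_detect * (1.0 - b) * g * c
        p_filler = non_detect * (1.0 - b) * g * (1.0 - c)
        p_reject = non_detect * (1.0 - b) * (1.0 - g)
    else:
        non_detect = 1.0 - dA
        p_suspect = non_detect * b + non_detect * (1.0 - b) * g * c
        p_filler = non_detect * (1.0 - b) * g * (1.0 - c)
        p_reject = dA + non_detect * (1.0 - b) * (1.0 - g)
    return CategoryProbs(p_suspect, p_filler, p_reject)


@dataclass(frozen=True)
class ModelSpec:
    """Multi-condition 2-HT model with equality constraints.

    Every (parameter, condition) slot resolves to exactly one free-parameter
    index (shared indices express equality constraints) or to one fixed
    constant. Free indices are contiguous from zero.
    """

    condition_names: tuple[str, ...]
    guess_split_c: float = DEFAULT_GUESS_SPLIT
    constraint_map: Mapping[tuple[str, str], int] = field(default_factory=dict)
    fixed_values: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.condition_names)) != len(self.condition_names):
            raise ValueError("condition names must be unique")
        if not (0.0 < self.guess_split_c < 1.0):
            raise ValueError(
                f"guess_split_c must lie in (0, 1), got {self.guess_split_c!r}"
            )
        indices = []
        for param in PARAM_NAMES:
            for cond in self.condition_names:
                slot = (param, cond)
                free = slot in self.constraint_map
                fixed = slot in self.fixed_values
                if free == fixed:
                    raise ValueError(
                        f"slot {slot} must resolve to exactly one free index "
                        "or one fixed constant"
                    )
                if free:
                    indices.append(self.constraint_map[slot])
        if sorted(set(indices)) != list(range(len(set(indices)))):
            raise ValueError("free-parameter indices must be contiguous from 0")
        for slot, value in self.fixed_values.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"fixed value for {slot} must lie in [0, 1]")

    @property
    def n_free(self) -> int:
        """Number of distinct free parameters."""
        return len(set(self.constraint_map.values()))

    @property
    def slots(self) -> list[tuple[str, str]]:
        """All (parameter, condition) slots in canonical order."""
        return [
            (param, cond)
            for param in PARAM_NAMES
            for cond in self.condition_names
        ]

    def slot_labels(self) -> dict[int, list[tuple[str, str]]]:
        """Free index -> the slots sharing it, in canonical order."""
        out: dict[int, list[tuple[str, str]]] = {}
        for slot in self.slots:
            if slot in self.constraint_map:
                out.setdefault(self.constraint_map[slot], []).append(slot)
        return out


def _normalize_groups(
    spec_entry, condition_names: Sequence[str]
) -> list[list[str]]:
    """Interpret an equality entry: 'all', one flat group, or many groups."""
    if spec_entry == "all":
        return [list(condition_names)]
    groups = list(spec_entry)
    if groups and all(isinstance(item, str) for item in groups):
        groups = [groups]
    return [list(group) for group in groups]


def build_model(
    condition_names: Sequence[str],
    equalities: Mapping[str, object] | None = None,
    fixed_values: Mapping[str, Mapping[str, float]] | None = None,
    c: float = DEFAULT_GUESS_SPLIT,
) -> ModelSpec:
    """Construct a :class:`ModelSpec` from equality constraints.

    Parameters
    ----------
    condition_names
        Experimental conditions, one pair of trees each. Order is preserved
        and determines index assignment.
    equalities
        Mapping from parameter name to either the string ``"all"``, a flat
        list of condition names forming one equality group, or a list of
        such groups. Conditions not named keep their own free parameter.
    fixed_values
        Mapping parameter name -> {condition: constant}. A fixed slot has no
        free index. Use the parameter-level mapping ``{"dA": {"all": 0.0}}``
        to fix a parameter in every condition.
    c
        Guessing split shared by all trees.

    Index assignment is deterministic: parameters in the order dP, dA, b, g;
    conditions in declaration order; a new index is allocated the first time
    an unconstrained slot or equality group is encountered.
    """
    condition_names = list(condition_names)
    equalities = dict(equalities or {})
    fixed_values = dict(fixed_values or {})
    known = set(condition_names)

    for source in (equalities, fixed_values):
        for param in source:
            if param not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {param!r} in constraints")

    group_of: dict[tuple[str, str], int] = {}  # slot -> group id within param
    groups_by_param: dict[str, list[list[str]]] = {}
    for param, entry in equalities.items():
        groups = _normalize_groups(entry, condition_names)
        for gi, group in enumerate(groups):
            for cond in group:
                if cond not in known:
                    raise ValueError(
                        f"equality for {param!r} references unknown "
                        f"condition {cond!r}"
                    )
                if (param, cond) in group_of:
                    raise ValueError(
                        f"condition {cond!r} appears in two equality groups "
                        f"for parameter {param!r}"
                    )
                group_of[(param, cond)] = gi
        groups_by_param[param] = groups

    fixed: dict[tuple[str, str], float] = {}
    for param, by_cond in fixed_values.items():
        for cond, value in by_cond.items():
            targets = condition_names if cond == "all" else [cond]
            for target in targets:
                if target not in known:
                    raise ValueError(
                        f"fixed value for {param!r} references unknown "
                        f"condition {target!r}"
                    )
                fixed[(param, target)] = float(value)

    constraint_map: dict[tuple[str, str], int] = {}
    next_index = 0
    group_index: dict[tuple[str, int], int] = {}  # (param, group id) -> index
    for param in PARAM_NAMES:
        for cond in condition_names:
            slot = (param, cond)
            if slot in fixed:
                if slot in group_of:
                    raise ValueError(
                        f"slot {slot} is both fixed and equality-constrained"
                    )
                continue
            if slot in group_of:
                key = (param, group_of[slot])
                if key not in group_index:
                    group_index[key] = next_index
                    next_index += 1
                constraint_map[slot] = group_index[key]
            else:
                constraint_map[slot] = next_index
                next_index += 1

    return ModelSpec(
        condition_names=tuple(condition_names),
        guess_split_c=c,
        constraint_map=constraint_map,
        fixed_values=fixed,
    )


def expand(
    free_vector: Sequence[float], spec: ModelSpec
) -> dict[str, Params2HT]:
    """Fill per-condition parameters from a free-parameter vector.

    Shared indices replicate their value into every slot of the equality
    group; fixed slots take their constant regardless of the vector.
    """
    free_vector = np.asarray(free_vector, dtype=float)
    if free_vector.shape != (spec.n_free,):
        raise ValueError(
            f"free_vector has length {free_vector.shape}, spec expects "
            f"{spec.n_free} free parameters"
        )
    out: dict[str, Params2HT] = {}
    for cond in spec.condition_names:
        values = {}
        for param in PARAM_NAMES:
            slot = (param, cond)
            if slot in spec.fixed_values:
                values[param] = spec.fixed_values[slot]
            else:
                values[param] = float(free_vector[spec.constraint_map[slot]])
        out[cond] = Params2HT(**values)
    return out


def with_equality(
    spec: ModelSpec, parameter: str, conditions: Iterable[str]
) -> ModelSpec:
    """Return a new spec with ``parameter`` equated across ``conditions``.

    The new model is nested in ``spec``: the named slots' free indices are
    merged into one and the remaining indices re-compacted in canonical
    order. Fixed slots cannot take part in an equality.
    """
    if parameter not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")
    conditions = list(conditions)
    for cond in conditions:
        if cond not in spec.condition_names:
            raise ValueError(f"unknown condition {cond!r}")
        if (parameter, cond) in spec.fixed_values:
            raise ValueError(
                f"slot ({parameter!r}, {cond!r}) is fixed and cannot be "
                "equality-constrained"
            )
    merged = {spec.constraint_map[(parameter, cond)] for cond in conditions}
    representative = min(merged)

    remapped: dict[tuple[str, str], int] = {}
    new_index: dict[int, int] = {}
    next_index = 0
    for param in PARAM_NAMES:
        for cond in spec.condition_names:
            slot = (param, cond)
            if slot in spec.fixed_values:
                continue
            old = spec.constraint_map[slot]
            if old in merged:
                old = representative
            if old not in new_index:
                new_index[old] = next_index
                next_index += 1
            remapped[slot] = new_index[old]

    return ModelSpec(
        condition_names=spec.condition_names,
        guess_split_c=spec.guess_split_c,
        constraint_map=remapped,
        fixed_values=dict(spec.fixed_values),
    )


def collapse_onto(
    free_vector: Sequence[float], general: ModelSpec, restricted: ModelSpec
) -> np.ndarray:
    """Project a general-model solution onto a nested restricted model.

    Each restricted free parameter takes the mean of the general values of
    the slots it pools. Used to seed the restricted fit with the general
    solution collapsed onto the constraint.
    """
    free_vector = np.asarray(free_vector, dtype=float)
    general_params = expand(free_vector, general)
    out = np.empty(restricted.n_free)
    for index, slots in restricted.slot_labels().items():
        values = [
            getattr(general_params[cond], param) for param, cond in slots
        ]
        out[index] = float(np.mean(values))
    return np.clip(out, 0.0, 1.0)


def to_eqn(spec: ModelSpec) -> str:
    """Export the instantiated model in EQN format.

    One line per branch product: ``<tree #> <category #> <term>``, preceded
    by a line giving the number of branch lines. Trees are numbered per
    (condition, tree kind) in canonical order; categories are 1 = suspect
    selection, 2 = filler selection, 3 = rejection. Shared parameters carry
    the same symbol across trees, fixed slots appear as numeric constants,
    so the constraint structure survives the export. Suitable for
    cross-checking against general-purpose MPT software.
    """
    c = repr(spec.guess_split_c)
    one_minus_c = repr(round(1.0 - spec.guess_split_c, 10))

    def symbol(param: str, cond: str) -> str:
        slot = (param, cond)
        if slot in spec.fixed_values:
            return repr(spec.fixed_values[slot])
        return f"x{spec.constraint_map[slot]}"

    lines: list[str] = []
    tree_no = 0
    for cond in spec.condition_names:
        for tree in (TreeKind.CULPRIT_PRESENT, TreeKind.CULPRIT_ABSENT):
            tree_no += 1
            b = symbol("b", cond)
            g = symbol("g", cond)
            if tree is TreeKind.CULPRIT_PRESENT:
                d = symbol("dP", cond)
                lines.append(f"{tree_no} 1 {d}")
                lines.append(f"{tree_no} 1 (1-{d})*{b}")
                lines.append(f"{tree_no} 1 (1-{d})*(1-{b})*{g}*{c}")
                lines.append(f"{tree_no} 2 (1-{d})*(1-{b})*{g}*{one_minus_c}")
                lines.append(f"{tree_no} 3 (1-{d})*(1-{b})*(1-{g})")
            else:
                d = symbol("dA", cond)
                lines.append(f"{tree_no} 1 (1-{d})*{b}")
                lines.append(f"{tree_no} 1 (1-{d})*(1-{b})*{g}*{c}")
                lines.append(f"{tree_no} 2 (1-{d})*(1-{b})*{g}*{one_minus_c}")
                lines.append(f"{tree_no} 3 {d}")
                lines.append(f"{tree_no} 3 (1-{d})*(1-{b})*(1-{g})")
    return "\n".join([str(len(lines))] + lines) + "\n"
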