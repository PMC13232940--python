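"""Reproduction of the two lineup-format experiments from their count tables.

The package ships the published response-frequency tables of both
experiments as CSV fixtures — counts of suspect selections, filler
selections and lineup rejections for culprit-present and culprit-absent
lineups per condition. Those counts are the sufficient statistic for the
pooled 2-HT analysis, so every model-based statistic of the original
analyses can be recomputed from them exactly:

Experiment 1 (N = 766; combined vs. separate presentation of four lineups,
two culprit-present): base model with b and dA equated across formats,
goodness of fit, parameter estimates with SEs, ΔG² tests of dP and g
equality across formats, and the sensitivity analysis (smallest detectable
w at α = β = .05 with 766 × 4 responses).

Experiment 2 (N = 781; format × number of culprit-present lineups): the
four-condition base model, the preliminary ΔG² test equating dP across the
three conditions where contextual cueing is theoretically impossible, the
augmented base model, the key one-df test of the combined/three-culprits
condition against the pooled rest, and the g-homogeneity test.

Each run emits a report comparing every recomputed statistic with its
published value at the printed precision (two decimals for estimates, SEs
and G² statistics; three for p-values), rounding half-up. Full-precision
values are retained alongside.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal

from .estimation import FitOptions, FitResult, FrequencyData, fit
from .inference import NestedTestResult, test_equality, test_grouped_vs_rest
from .io import load_frequencies, load_model_config
from .model import ModelSpec
from .power import sensitivity_w

__all__ = [
    "StudyReport",
    "load_experiment_data",
    "experiment_model",
    "run_experiment1",
    "run_experiment2",
    "write_report",
    "EXP1_CONDITIONS",
    "EXP2_CONDITIONS",
    "EXP2_CUE_FREE",
]

EXP1_CONDITIONS = ("combined", "separate")
EXP2_CONDITIONS = (
    "combined_three",
    "separate_three",
    "combined_one",
    "separate_one",
)
#: Experiment 2 conditions in which at most one culprit is visible at a
#: time, so contextual facial cueing is theoretically impossible.
EXP2_CUE_FREE = ("separate_three", "combined_one", "separate_one")

#: Participants per experiment; each contributed four lineup responses.
EXP1_N_PARTICIPANTS = 766
EXP2_N_PARTICIPANTS = 781
RESPONSES_PER_PARTICIPANT = 4

#: Published statistics at their printed precision, used only for the
#: pass/fail comparison columns of the reproduction report.
EXP1_REFERENCE: dict[str, float] = {
    "base_G2": 5.12,
    "base_p": 0.077,
    "b": 0.06,
    "se_b": 0.01,
    "dA": 0.03,
    "se_dA": 0.04,
    "g_combined": 0.44,
    "se_g_combined": 0.02,
    "g_separate": 0.42,
    "se_g_separate": 0.02,
    "dP_equality_dG2": 0.47,
    "dP_equality_p": 0.491,
    "g_equality_dG2": 0.60,
    "g_equality_p": 0.438,
    "sensitivity_w": 0.07,
}

EXP2_REFERENCE: dict[str, float] = {
    "base_G2": 4.01,
    "base_p": 0.675,
    "b": 0.06,
    "se_b": 0.01,
    "dA": 0.13,
    "se_dA": 0.05,
    "dP_cue_free_dG2": 0.99,
    "dP_cue_free_p": 0.609,
    "augmented_base_G2": 5.01,
    "augmented_base_p": 0.757,
    "key_grouped_dG2": 0.90,
    "key_grouped_p": 0.344,
    "g_homogeneity_dG2": 6.70,
    "g_homogeneity_p": 0.082,
    "g_combined_three": 0.45,
    "se_g_combined_three": 0.02,
    "g_separate_three": 0.44,
    "se_g_separate_three": 0.02,
    "g_combined_one": 0.42,
    "se_g_combined_one": 0.03,
    "g_separate_one": 0.50,
    "se_g_separate_one": 0.03,
    "sensitivity_w": 0.06,
}


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _data_path(name: str) -> Path:
    return Path(
        str(importlib.resources.files("lineup2ht").joinpath("data", name))
    )


def load_experiment_data(
    experiment: Literal["exp1", "exp2"]
) -> FrequencyData:
    """Load the packaged frequency table of one experiment."""
    return load_frequencies(_data_path(f"{experiment}_frequencies.csv"))


def experiment_model(experiment: Literal["exp1", "exp2"]) -> ModelSpec:
    """Load the packaged base-model configuration of one experiment."""
    return load_model_config(_data_path(f"{experiment}_model.yaml"))


@dataclass
class StudyReport:
    """Recomputed statistics with their published counterparts.

    ``entries`` maps statistic name to a dict with the full-precision
    computed value, the value rounded at the printed precision, the
    published reference, and whether they agree. ``extras`` carries
    full-precision quantities with no printed counterpart (the dP
    estimates, which the original report showed only graphically).
    """

    experiment: str
    entries: dict[str, dict] = field(default_factory=dict)
    extras: dict[str, float] = field(default_factory=dict)

    def add(
        self, name: str, computed: float, reference: float, decimals: int = 2
    ) -> None:
        rounded = round_half_up(computed, decimals)
        self.entries[name] = {
            "computed": float(computed),
            "rounded": rounded,
            "reference": reference,
            "match": abs(rounded - reference) < 10.0 ** (-decimals) / 2,
        }

    @property
    def passed(self) -> bool:
        return all(entry["match"] for entry in self.entries.values())

    @property
    def failures(self) -> list[str]:
        return [k for k, v in self.entries.items() if not v["match"]]

    def value(self, name: str) -> float:
        """Full-precision computed value of a tracked statistic."""
        return self.entries[name]["computed"]

    def rounded(self, name: str) -> float:
        return self.entries[name]["rounded"]

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "passed": self.passed,
            "entries": self.entries,
            "extras": self.extras,
        }

    def to_text(self) -> str:
        width = max(len(k) for k in self.entries)
        lines = [
            f"Reproduction report: {self.experiment}",
            f"{'statistic':<{width}}  {'computed':>10}  {'rounded':>8}  "
            f"{'published':>9}  ok",
        ]
        for name, entry in self.entries.items():
            lines.append(
                f"{name:<{width}}  {entry['computed']:>10.5f}  "
                f"{entry['rounded']:>8.3f}  {entry['reference']:>9.3f}  "
                f"{'yes' if entry['match'] else 'NO'}"
            )
        for name, value in self.extras.items():
            lines.append(f"{name:<{width}}  {value:>10.5f}  (not published)")
        lines.append("PASS" if self.passed else f"FAIL: {self.failures}")
        return "\n".join(lines)


def write_report(report: StudyReport, path: str | Path) -> None:
    """Write a reproduction report as JSON (deterministic key order)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=False)
        fh.write("\n")


def _add_fit_params(
    report: StudyReport,
    result: FitResult,
    names: dict[str, tuple[str, str]],
) -> None:
    for label, slot in names.items():
        reference = (
            EXP1_REFERENCE if report.experiment == "exp1" else EXP2_REFERENCE
        )
        report.add(label, result.estimates[slot], reference[label])
        report.add(f"se_{label}", result.se[slot], reference[f"se_{label}"])


def run_experiment1(options: FitOptions | None = None) -> StudyReport:
    """Recompute every model-based statistic of Experiment 1."""
    options = options or FitOptions()
    data = load_experiment_data("exp1")
    spec = experiment_model("exp1")
    report = StudyReport(experiment="exp1")

    base = fit(spec, data, options)
    report.add("base_G2", base.G2, EXP1_REFERENCE["base_G2"])
    report.add("base_p", base.p_value, EXP1_REFERENCE["base_p"], decimals=3)
    _add_fit_params(
        report,
        base,
        {
            "b": ("b", "combined"),
            "dA": ("dA", "combined"),
            "g_combined": ("g", "combined"),
            "g_separate": ("g", "separate"),
        },
    )
    for cond in EXP1_CONDITIONS:
        report.extras[f"dP_{cond}"] = base.estimates[("dP", cond)]
        report.extras[f"se_dP_{cond}"] = base.se[("dP", cond)]

    dp_test = test_equality(spec, data, "dP", [EXP1_CONDITIONS], options)
    report.add("dP_equality_dG2", dp_test.delta_G2, EXP1_REFERENCE["dP_equality_dG2"])
    report.add(
        "dP_equality_p", dp_test.p_value, EXP1_REFERENCE["dP_equality_p"], decimals=3
    )

    g_test = test_equality(spec, data, "g", [EXP1_CONDITIONS], options)
    report.add("g_equality_dG2", g_test.delta_G2, EXP1_REFERENCE["g_equality_dG2"])
    report.add(
        "g_equality_p", g_test.p_value, EXP1_REFERENCE["g_equality_p"], decimals=3
    )

    w = sensitivity_w(
        n_obs=EXP1_N_PARTICIPANTS * RESPONSES_PER_PARTICIPANT,
        df=1,
        alpha=0.05,
        power=0.95,
    )
    report.add("sensitivity_w", w, EXP1_REFERENCE["sensitivity_w"])
    report.extras["sensitivity_n_obs"] = float(
        EXP1_N_PARTICIPANTS * RESPONSES_PER_PARTICIPANT
    )
    return report


def run_experiment2(options: FitOptions | None = None) -> StudyReport:
    """Recompute every model-based statistic of Experiment 2.

    Follows the original two-step strategy: first equate dP across the
    three cue-free conditions (the preliminary ΔG²(2) test, yielding the
    augmented base model), then the key one-df test of the
    combined/three-culprits condition against the pooled rest. The
    g-homogeneity test is run from the fully-dP-pooled model.
    """
    options = options or FitOptions()
    data = load_experiment_data("exp2")
    spec = experiment_model("exp2")
    report = StudyReport(experiment="exp2")

    base = fit(spec, data, options)
    report.add("base_G2", base.G2, EXP2_REFERENCE["base_G2"])
    report.add("base_p", base.p_value, EXP2_REFERENCE["base_p"], decimals=3)
    _add_fit_params(
        report,
        base,
        {
            "b": ("b", "combined_three"),
            "dA": ("dA", "combined_three"),
            "g_combined_three": ("g", "combined_three"),
            "g_separate_three": ("g", "separate_three"),
            "g_combined_one": ("g", "combined_one"),
            "g_separate_one": ("g", "separate_one"),
        },
    )
    for cond in EXP2_CONDITIONS:
        report.extras[f"dP_{cond}"] = base.estimates[("dP", cond)]
        report.extras[f"se_dP_{cond}"] = base.se[("dP", cond)]

    cue_free = test_equality(spec, data, "dP", [EXP2_CUE_FREE], options)
    report.add(
        "dP_cue_free_dG2", cue_free.delta_G2, EXP2_REFERENCE["dP_cue_free_dG2"]
    )
    report.add(
        "dP_cue_free_p", cue_free.p_value, EXP2_REFERENCE["dP_cue_free_p"], decimals=3
    )
    augmented = cue_free.restricted_fit
    report.add(
        "augmented_base_G2", augmented.G2, EXP2_REFERENCE["augmented_base_G2"]
    )
    report.add(
        "augmented_base_p",
        augmented.p_value,
        EXP2_REFERENCE["augmented_base_p"],
        decimals=3,
    )

    key = test_grouped_vs_rest(
        augmented.spec,
        data,
        "dP",
        focal_condition="combined_three",
        rest_conditions=EXP2_CUE_FREE,
        options=options,
    )
    report.add("key_grouped_dG2", key.delta_G2, EXP2_REFERENCE["key_grouped_dG2"])
    report.add(
        "key_grouped_p", key.p_value, EXP2_REFERENCE["key_grouped_p"], decimals=3
    )

    pooled = key.restricted_fit  # dP shared by all four conditions
    g_hom = test_equality(pooled.spec, data, "g", [EXP2_CONDITIONS], options)
    report.add(
        "g_homogeneity_dG2", g_hom.delta_G2, EXP2_REFERENCE["g_homogeneity_dG2"]
    )
    report.add(
        "g_homogeneity_p", g_hom.p_value, EXP2_REFERENCE["g_homogeneity_p"], decimals=3
    )

    w = sensitivity_w(
        n_obs=EXP2_N_PARTICIPANTS * RESPONSES_PER_PARTICIPANT,
        df=1,
        alpha=0.05,
        power=0.95,
    )
    report.add("sensitivity_w", w, EXP2_REFERENCE["sensitivity_w"])
    report.extras["sensitivity_n_obs"] = float(
        EXP2_N_PARTICIPANTS * RESPONSES_PER_PARTICIPANT
    )
    return report
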