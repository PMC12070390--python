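"""Synthetic single-cell studies with known group structure.

Each subject's log-CSI distribution is a 2-component normal mixture whose
parameters carry subject-level random effects: a shared per-subject
brightness shift on both component means (emulating tissue-level staining
variability), small independent per-component mean perturbations, log-normal
perturbations of the component standard deviations, and a logit-normal
perturbation of the mixing weight.  Four scenarios define the high- vs
low-risk group contrast:

* A — the high-risk group has a distinctive high-expression component
  (bimodal), the low-risk mixture merges into a unimodal shape;
* B — groups differ in the first (low-expression) component: loss of
  expression marks high risk;
* C — groups differ in the second (high-expression) component: a fraction
  of cells with elevated expression marks high risk;
* D — null: identical mixtures in both groups.

Outcomes are either Bernoulli (event probability 0.61 in the high-risk
group, group odds ratio 2.5) or Weibull survival with administrative
censoring and a group log hazard ratio, drawn independently of the cells
given the group label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
import pandas as pd

from .models import BinaryOutcome, SurvivalOutcome

__all__ = [
    "MixtureParams",
    "ScenarioSpec",
    "SubjectParams",
    "Study",
    "SimulatedStudy",
    "scenario_spec",
    "draw_subject_params",
    "simulate_cells",
    "simulate_binary_outcome",
    "simulate_survival_outcome",
    "generate_study",
    "generate_pair",
]

#: default event probability in the high-risk group
P_EVENT_HIGH = 0.61
#: default high/low odds ratio of the binary outcome
ODDS_RATIO = 2.5


@dataclass(frozen=True)
class MixtureParams:
    """Group-level 2-component normal mixture (log-CSI scale)."""

    weight: float  # P(component 1)
    mean1: float
    mean2: float
    sd1: float
    sd2: float

    def __post_init__(self) -> None:
        if not 0.0 < self.weight < 1.0:
            raise ValueError("mixture weight must lie in (0, 1)")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("component sds must be positive")

    @property
    def mean(self) -> float:
        return self.weight * self.mean1 + (1 - self.weight) * self.mean2


# shared low-risk / null base mixture: components merge into a unimodal shape
_BASE = MixtureParams(weight=0.65, mean1=2.0, mean2=3.0, sd1=0.6, sd2=0.8)

_GROUP_PARAMS: dict[str, tuple[MixtureParams, MixtureParams]] = {
    # (low-risk, high-risk)
    "A": (_BASE, MixtureParams(0.65, 2.0, 4.8, 0.6, 0.6)),
    "B": (
        MixtureParams(0.65, 2.5, 3.0, 0.6, 0.8),
        MixtureParams(0.65, 1.2, 3.0, 0.6, 0.8),
    ),
    "C": (
        MixtureParams(0.65, 2.0, 4.0, 0.6, 0.6),
        MixtureParams(0.65, 2.0, 5.2, 0.6, 0.6),
    ),
    "D": (_BASE, _BASE),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one simulated study design."""

    scenario: str
    low: MixtureParams
    high: MixtureParams
    # subject random-effect scales
    tau_shift: float = 0.7      # shared brightness shift on both means
    tau_mean: float = 0.15      # independent per-component mean perturbation
    tau_logsd: float = 0.15
    tau_logitweight: float = 0.3
    # study size
    n_subjects_per_group: int = 120
    n_cells_per_subject: int = 100
    # outcome model
    outcome_kind: str = "binary"  # {"binary", "survival"}
    p_event_high: float = P_EVENT_HIGH
    odds_ratio: float = ODDS_RATIO
    weibull_shape: float = 1.5
    weibull_rate: float = 0.1
    log_hr: float = float(np.log(2.5))
    censor_time: float = 3.0

    def __post_init__(self) -> None:
        if self.outcome_kind not in ("binary", "survival"):
            raise ValueError("outcome_kind must be 'binary' or 'survival'")
        for tau in (self.tau_shift, self.tau_mean, self.tau_logsd,
                    self.tau_logitweight):
            if tau < 0:
                raise ValueError("random-effect scales must be >= 0")

    @property
    def p_event_low(self) -> float:
        """Low-risk event probability implied by the high-risk odds ratio."""
        odds_low = (self.p_event_high / (1 - self.p_event_high)) / self.odds_ratio
        return odds_low / (1 + odds_low)


def scenario_spec(
    scenario: str,
    n_subjects_per_group: int = 120,
    n_cells_per_subject: int = 100,
    outcome_kind: str = "binary",
    **overrides,
) -> ScenarioSpec:
    """Default specification for one of the scenarios A–D."""
    scenario = scenario.upper()
    if scenario not in _GROUP_PARAMS:
        raise ValueError(
            f"unknown scenario '{scenario}'; valid options: "
            f"{sorted(_GROUP_PARAMS)}"
        )
    low, high = _GROUP_PARAMS[scenario]
    return ScenarioSpec(
        scenario=scenario, low=low, high=high,
        n_subjects_per_group=n_subjects_per_group,
        n_cells_per_subject=n_cells_per_subject,
        outcome_kind=outcome_kind, **overrides,
    )


@dataclass
class SubjectParams:
    """Realized subject-level mixture parameters after random effects."""

    group: str  # {"high", "low"}
    weight: float
    mean1: float
    mean2: float
    sd1: float
    sd2: float

    @property
    def mean(self) -> float:
        return self.weight * self.mean1 + (1 - self.weight) * self.mean2


def draw_subject_params(
    spec: ScenarioSpec, group: str, rng: np.random.Generator
) -> SubjectParams:
    """Perturb the group mixture parameters with subject random effects."""
    base = spec.high if group == "high" else spec.low
    shift = rng.normal(0.0, spec.tau_shift)
    mean1 = base.mean1 + shift + rng.normal(0.0, spec.tau_mean)
    mean2 = base.mean2 + shift + rng.normal(0.0, spec.tau_mean)
    sd1 = base.sd1 * np.exp(rng.normal(0.0, spec.tau_logsd))
    sd2 = base.sd2 * np.exp(rng.normal(0.0, spec.tau_logsd))
    logit_w = np.log(base.weight / (1 - base.weight)) + rng.normal(
        0.0, spec.tau_logitweight
    )
    weight = 1.0 / (1.0 + np.exp(-logit_w))
    return SubjectParams(group=group, weight=float(weight), mean1=float(mean1),
                         mean2=float(mean2), sd1=float(sd1), sd2=float(sd2))


def simulate_cells(
    params: SubjectParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` log-scale CSI draws from the subject's 2-component mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    comp1 = rng.random(n) < params.weight
    out = np.where(
        comp1,
        rng.normal(params.mean1, params.sd1, size=n),
        rng.normal(params.mean2, params.sd2, size=n),
    )
    return out


def simulate_binary_outcome(
    group: str,
    rng: np.random.Generator,
    p_event_high: float = P_EVENT_HIGH,
    odds_ratio: float = ODDS_RATIO,
) -> int:
    """Bernoulli outcome with the high-risk event probability and group OR."""
    if group == "high":
        p = p_event_high
    else:
        odds = (p_event_high / (1 - p_event_high)) / odds_ratio
        p = odds / (1 + odds)
    return int(rng.random() < p)


def simulate_survival_outcome(
    group: str,
    rng: np.random.Generator,
    shape: float = 1.5,
    rate: float = 0.1,
    log_hr: float = float(np.log(2.5)),
    censor_time: float = 3.0,
) -> tuple[float, int]:
    """Weibull event time with administrative censoring, by inverse transform.

    The latent time is ``T = (−log U / (rate · e^{β·1{high}}))^{1/shape}``;
    the observed time is ``min(T, c)`` with event indicator ``1{T ≤ c}``.
    """
    if shape <= 0 or rate <= 0 or censor_time <= 0:
        raise ValueError("shape, rate and censor_time must be positive")
    u = rng.random()
    u = min(max(u, 1e-300), 1 - 1e-16)
    hazard_scale = rate * np.exp(log_hr * (group == "high"))
    latent = (-np.log(u) / hazard_scale) ** (1.0 / shape)
    t = min(latent, censor_time)
    return float(max(t, 1e-12)), int(latent <= censor_time)


Outcome = Union[BinaryOutcome, SurvivalOutcome]


@dataclass
class Study:
    """Cell table + outcome + group labels for one train or test half."""

    cells: pd.DataFrame
    outcome: Outcome
    groups: pd.Series  # subject_id -> {"high", "low"}
    subject_params: list[SubjectParams] = field(default_factory=list, repr=False)

    @property
    def subject_ids(self) -> list:
        return list(self.groups.index)


@dataclass
class SimulatedStudy:
    train: Study
    test: Study
    seed: int
    spec: ScenarioSpec


def generate_study(
    spec: ScenarioSpec, seed_seq: np.random.SeedSequence, prefix: str = "s"
) -> Study:
    """One study half from independent parameter / cell / outcome streams."""
    ss_params, ss_cells, ss_outcome = seed_seq.spawn(3)
    rng_params = np.random.default_rng(ss_params)
    rng_cells = np.random.default_rng(ss_cells)
    rng_outcome = np.random.default_rng(ss_outcome)

    groups = ["high"] * spec.n_subjects_per_group + ["low"] * spec.n_subjects_per_group
    sids = [f"{prefix}{i:04d}" for i in range(len(groups))]

    frames = []
    params_list = []
    times, events, ys = [], [], []
    for sid, group in zip(sids, groups):
        params = draw_subject_params(spec, group, rng_params)
        params_list.append(params)
        logs = simulate_cells(params, spec.n_cells_per_subject, rng_cells)
        frames.append(pd.DataFrame({"subject_id": sid, "csi": np.exp(logs)}))
        if spec.outcome_kind == "binary":
            ys.append(simulate_binary_outcome(
                group, rng_outcome, spec.p_event_high, spec.odds_ratio))
        else:
            t, e = simulate_survival_outcome(
                group, rng_outcome, spec.weibull_shape, spec.weibull_rate,
                spec.log_hr, spec.censor_time)
            times.append(t)
            events.append(e)
    cells = pd.concat(frames, ignore_index=True)
    if spec.outcome_kind == "binary":
        outcome: Outcome = BinaryOutcome(sids, np.array(ys, dtype=float))
    else:
        outcome = SurvivalOutcome(
            sids, np.array(times), np.array(events, dtype=float)
        )
    return Study(
        cells=cells, outcome=outcome,
        groups=pd.Series(groups, index=sids, name="group"),
        subject_params=params_list,
    )


def generate_pair(spec: ScenarioSpec, seed: int) -> SimulatedStudy:
    """Independent train and test halves, reproducible from (spec, seed)."""
    ss_train, ss_test = np.random.SeedSequence(seed).spawn(2)
    return SimulatedStudy(
        train=generate_study(spec, ss_train, prefix="tr"),
        test=generate_study(spec, ss_test, prefix="te"),
        seed=seed,
        spec=spec,
    )
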