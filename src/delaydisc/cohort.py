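"""Synthetic cohorts for the two-group x two-condition discounting design.

Each simulated participant carries a per-condition log discount rate, a
softmax choice temperature, power-law time-perception parameters (alpha:
overall contraction, beta: diminishing sensitivity to time), and attention
propensities.  Choices follow a logistic (softmax) rule on the difference of
hyperbolic present values, computed either on objective delays or on
subjective durations T = alpha * t**beta; line-scale time judgments follow
the same power law with multiplicative lognormal noise.

Two ready-made scenarios are provided:

``paper_scenario``
    The mechanistic account: both groups share one subjective-time discount
    rate, but the affect-positive group's alpha is twice the neutral group's.
    Fitted on objective delays this yields immediate-condition discount rates
    near 0.08 vs 0.04 per day; refitted on subjective durations the group
    difference disappears.

``direct_k_scenario``
    The descriptive account: group/condition differences injected directly
    into the objective discount rates (immediate 0.08 vs 0.04, non-immediate
    0.045 in both groups).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import task_engine as te
from .errors import ValidationError

CONDITIONS = ("immediate", "non_immediate")

#: The nine delay durations (days) probed by the line-scale judgment task.
MEASURED_DURATIONS: tuple[int, ...] = (7, 15, 22, 30, 45, 80, 95, 140, 155)

LINE_MAX_CM = 28.5
WEEK_ANCHOR_CM = 7.42


@dataclass(frozen=True)
class GroupSpec:
    """Generative hyper-parameters of one affect group.

    ``mu_log_k``/``sigma_log_k`` govern per-day log discount rates per
    condition (on the time basis named by ``time_basis`` of the scenario);
    ``k_condition_corr`` is the within-participant correlation of the two
    condition log-k draws.  ``alpha``/``beta`` are the power-law perception
    parameters, truncated to (0, 10] and (0, 2].
    """

    name: str
    n_participants: int
    mu_log_k: dict[str, float]
    sigma_log_k: float = 0.5
    mu_log_temp: float = math.log(0.3)
    sigma_log_temp: float = 0.4
    alpha_mean: float = 1.0
    alpha_sd: float = 0.2
    beta_mean: float = 0.4
    beta_sd: float = 0.05
    p_delay_first: float = 0.5
    p_delay_majority: float = 0.5
    judgment_noise_sd: float = 0.2
    k_condition_corr: float = 0.7

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        for p in (self.p_delay_first, self.p_delay_majority):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        for s in (
            self.sigma_log_k,
            self.sigma_log_temp,
            self.alpha_sd,
            self.beta_sd,
            self.judgment_noise_sd,
        ):
            if s < 0:
                raise ValidationError("standard deviations must be >= 0")
        if set(self.mu_log_k) != set(CONDITIONS):
            raise ValidationError(f"mu_log_k must map exactly {CONDITIONS}")
        if not -1.0 <= self.k_condition_corr <= 1.0:
            raise ValidationError("k_condition_corr must lie in [-1, 1]")


@dataclass(frozen=True)
class ParticipantParams:
    """Generative truth for one simulated participant."""

    participant_id: str
    group: str
    log_k: dict[str, float]
    log_temp: float
    alpha: dict[str, float]
    beta: dict[str, float]
    p_delay_first: float
    p_delay_majority: float

    @property
    def temp(self) -> float:
        return math.exp(self.log_temp)


def _log_mu_for_mean_k(k_mean: float, sigma: float = 0.5) -> float:
    # lognormal location giving arithmetic mean k_mean at scale sigma
    return math.log(k_mean) - 0.5 * sigma**2


def paper_scenario(n_per_group: int = 31) -> tuple[GroupSpec, GroupSpec]:
    """Shared subjective-time discount rate; group difference carried by alpha.

    Calibration: with beta near 0.4 and the five immediate-condition LL
    delays, a subjective-time rate of exp(-1.46) per subjective day combined
    with alpha of 2.0 (positive) vs 1.0 (neutral) yields objectively fitted
    immediate-condition discount rates near 0.08 vs 0.04 per day.  Keeping
    beta near 0.4 also keeps simulated line judgments inside the 28.5 cm
    scale for essentially all participants; steeper perception curves would
    saturate the line at long delays and censor the perception fits.
    """
    mu = {"immediate": -1.46, "non_immediate": -1.46}
    positive = GroupSpec(
        name="positive",
        n_participants=n_per_group,
        mu_log_k=dict(mu),
        alpha_mean=2.0,
        alpha_sd=0.3,
        p_delay_first=0.79,
        p_delay_majority=0.71,
        k_condition_corr=1.0,
    )
    neutral = GroupSpec(
        name="neutral",
        n_participants=n_per_group,
        mu_log_k=dict(mu),
        alpha_mean=1.0,
        alpha_sd=0.2,
        p_delay_first=0.38,
        p_delay_majority=0.49,
        k_condition_corr=1.0,
    )
    return positive, neutral


def direct_k_scenario(n_per_group: int = 31, sigma_log_k: float = 0.5) -> tuple[GroupSpec, GroupSpec]:
    """Group/condition differences injected directly into objective k."""
    positive = GroupSpec(
        name="positive",
        n_participants=n_per_group,
        mu_log_k={
            "immediate": _log_mu_for_mean_k(0.08, sigma_log_k),
            "non_immediate": _log_mu_for_mean_k(0.045, sigma_log_k),
        },
        sigma_log_k=sigma_log_k,
        p_delay_first=0.79,
        p_delay_majority=0.71,
    )
    neutral = GroupSpec(
        name="neutral",
        n_participants=n_per_group,
        mu_log_k={
            "immediate": _log_mu_for_mean_k(0.04, sigma_log_k),
            "non_immediate": _log_mu_for_mean_k(0.045, sigma_log_k),
        },
        sigma_log_k=sigma_log_k,
        p_delay_first=0.38,
        p_delay_majority=0.49,
    )
    return positive, neutral


def joint_k_spec(n_participants: int = 16, k_mean: float = 0.06) -> GroupSpec:
    """Single-group spec with equal discount rates across conditions."""
    mu = _log_mu_for_mean_k(k_mean)
    return GroupSpec(
        name="joint",
        n_participants=n_participants,
        mu_log_k={"immediate": mu, "non_immediate": mu},
        k_condition_corr=1.0,
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    """Rejection-sample Normal(mean, sd) restricted to (low, high]."""
    if sd == 0:
        if not low < mean <= high:
            raise ValidationError("degenerate truncated normal outside its support")
        return np.full(size, mean)
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, size=todo.size)
        ok = (draw > low) & (draw <= high)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _sample_group(spec: GroupSpec, rng: np.random.Generator) -> list[ParticipantParams]:
    n = spec.n_participants
    rho = spec.k_condition_corr
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    zc = rho * z1 + math.sqrt(max(0.0, 1.0 - rho**2)) * z2
    log_k_imm = spec.mu_log_k["immediate"] + spec.sigma_log_k * z1
    log_k_non = spec.mu_log_k["non_immediate"] + spec.sigma_log_k * zc
    log_temp = rng.normal(spec.mu_log_temp, spec.sigma_log_temp, size=n)
    alpha = _truncated_normal(rng, spec.alpha_mean, spec.alpha_sd, 0.0, 10.0, n)
    beta = _truncated_normal(rng, spec.beta_mean, spec.beta_sd, 0.0, 2.0, n)
    return [
        ParticipantParams(
            participant_id=f"{spec.name}_{i + 1:03d}",
            group=spec.name,
            log_k={"immediate": float(log_k_imm[i]), "non_immediate": float(log_k_non[i])},
            log_temp=float(log_temp[i]),
            alpha={c: float(alpha[i]) for c in CONDITIONS},
            beta={c: float(beta[i]) for c in CONDITIONS},
            p_delay_first=spec.p_delay_first,
            p_delay_majority=spec.p_delay_majority,
        )
        for i in range(n)
    ]


def sample_cohort(
    spec_positive: GroupSpec, spec_neutral: GroupSpec | None, seed: int
) -> list[ParticipantParams]:
    """Draw a full cohort (positive then neutral group) reproducibly."""
    rng = np.random.default_rng(seed)
    cohort = _sample_group(spec_positive, rng)
    if spec_neutral is not None:
        cohort += _sample_group(spec_neutral, rng)
    return cohort


def subjective_duration(t: np.ndarray | float, alpha: float, beta: float):
    """Power-law perceived duration; zero delay maps to zero perceived time."""
    t = np.asarray(t, dtype=float)
    return alpha * np.power(t, beta, where=t > 0, out=np.zeros_like(t))


def _pair_value_diff(
    pair: te.ChoicePair, participant: ParticipantParams, condition: str, time_basis: str
) -> float:
    k = math.exp(participant.log_k[condition])
    if time_basis == "objective":
        t_ss, t_ll = pair.ss_delay, pair.ll_delay
    elif time_basis == "subjective":
        a = participant.alpha[condition]
        b = participant.beta[condition]
        t_ss = a * pair.ss_delay**b if pair.ss_delay > 0 else 0.0
        t_ll = a * pair.ll_delay**b if pair.ll_delay > 0 else 0.0
    else:
        raise ValidationError(f"unknown time_basis {time_basis!r}")
    v_ss = pair.ss_amount / (1.0 + k * t_ss)
    v_ll = pair.ll_amount / (1.0 + k * t_ll)
    return v_ll - v_ss


def softmax_agent(
    participant: ParticipantParams,
    condition: str,
    rng: np.random.Generator,
    time_basis: str = "objective",
):
    """Stochastic agent: P(LL) = logistic(temp * (V_LL - V_SS))."""
    temp = participant.temp

    def agent(pair: te.ChoicePair) -> str:
        dv = _pair_value_diff(pair, participant, condition, time_basis)
        p_ll = 1.0 / (1.0 + math.exp(-min(700.0, max(-700.0, temp * dv))))
        return "LL" if rng.random() < p_ll else "SS"

    return agent


def simulate_choices(
    participant: ParticipantParams,
    battery: te.Battery,
    seed: int,
    time_basis: str = "objective",
) -> list[te.TrialRecord]:
    """Run one participant through a battery with softmax choice noise."""
    rng = np.random.default_rng(seed)
    condition = battery.condition
    agent = softmax_agent(participant, condition, rng, time_basis)
    records: list[te.TrialRecord] = []
    if battery.kind == "staircase":
        for blk in battery.blocks:
            if blk.practice:
                continue
            result = te.run_block(
                agent,
                ll_amount=blk.ll_amount,
                ll_delay=blk.ll_delay,
                ss_delay=blk.ss_delay,
                stop_width=blk.stop_width,
                start_ss=blk.start_ss,
                participant_id=participant.participant_id,
                group=participant.group,
                block_id=blk.block_id,
            )
            records.extend(result.records)
    else:
        for i, pair in enumerate(battery.pairs, start=1):
            records.append(
                te.TrialRecord(
                    participant_id=participant.participant_id,
                    group=participant.group,
                    condition=condition,
                    block_id=f"{condition}_fixed",
                    trial_index=i,
                    pair=pair,
                    choice=agent(pair),
                )
            )
    return records


def simulate_time_judgments(
    participant: ParticipantParams,
    durations=MEASURED_DURATIONS,
    line_length_max: float = LINE_MAX_CM,
    week_anchor: float = WEEK_ANCHOR_CM,
    seed: int = 0,
    noise_sd: float | None = None,
) -> list[tuple[float, float]]:
    """Line-scale judgments: (week_anchor/7) * alpha * t**beta with lognormal noise.

    Outputs are clipped to the physical line length [0, line_length_max].
    """
    durations = list(durations)
    if any(d <= 0 for d in durations):
        raise ValidationError("durations must be positive")
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = 0.2
    alpha = float(np.mean(list(participant.alpha.values())))
    beta = float(np.mean(list(participant.beta.values())))
    out = []
    for t in durations:
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        length = (week_anchor / 7.0) * alpha * t**beta * math.exp(eps)
        out.append((float(t), float(min(max(length, 0.0), line_length_max))))
    return out


def simulate_attention(
    participant: ParticipantParams, seed: int
) -> tuple[str, str]:
    """Independent Bernoulli draws of first-attended and majority attribute."""
    rng = np.random.default_rng(seed)
    first = "delay" if rng.random() < participant.p_delay_first else "reward"
    majority = "delay" if rng.random() < participant.p_delay_majority else "reward"
    return first, majority


def _participant_seed(base_seed: int, participant_id: str, tag: str) -> int:
    # stable per-participant stream, kept below 2**31 (crc32 is process-stable)
    label = zlib.crc32(f"{participant_id}/{tag}".encode())
    h = np.random.SeedSequence([base_seed, label])
    return int(h.generate_state(1)[0] % (2**31))


def simulate_study1(
    cohort: list[ParticipantParams],
    seed: int,
    time_basis: str = "subjective",
    judgment_noise_sd: float = 0.2,
) -> dict[str, pd.DataFrame]:
    """Choices (both conditions, titration battery) and time judgments for a cohort."""
    records: list[te.TrialRecord] = []
    judgment_rows = []
    batteries = {c: te.build_battery(1, c) for c in CONDITIONS}
    for p in cohort:
        for condition in CONDITIONS:
            s = _participant_seed(seed, p.participant_id, f"choice_{condition}")
            records.extend(simulate_choices(p, batteries[condition], s, time_basis))
        s = _participant_seed(seed, p.participant_id, "judgment")
        for t, length in simulate_time_judgments(
            p, seed=s, noise_sd=judgment_noise_sd
        ):
            judgment_rows.append(
                {
                    "participant_id": p.participant_id,
                    "group": p.group,
                    "duration_days": t,
                    "line_length_cm": length,
                }
            )
    return {
        "choices": te.records_table(records),
        "judgments": pd.DataFrame(judgment_rows),
        "truth": truth_table(cohort),
    }


def simulate_study2(
    cohort: list[ParticipantParams], seed: int, time_basis: str = "subjective"
) -> dict[str, pd.DataFrame]:
    """Fixed-battery choices plus the attribute-attention table for a cohort."""
    records: list[te.TrialRecord] = []
    attention_rows = []
    batteries = {c: te.build_battery(2, c) for c in CONDITIONS}
    for p in cohort:
        for condition in CONDITIONS:
            s = _participant_seed(seed, p.participant_id, f"s2_{condition}")
            records.extend(simulate_choices(p, batteries[condition], s, time_basis))
        s = _participant_seed(seed, p.participant_id, "attention")
        first, majority = simulate_attention(p, s)
        attention_rows.append(
            {
                "participant_id": p.participant_id,
                "group": p.group,
                "first_attention": first,
                "majority_attention": majority,
            }
        )
    return {
        "choices": te.records_table(records),
        "attention": pd.DataFrame(attention_rows),
        "truth": truth_table(cohort),
    }


def truth_table(cohort: list[ParticipantParams]) -> pd.DataFrame:
    """Generator truth per participant, for recovery tests."""
    return pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "group": p.group,
                "log_k_immediate": p.log_k["immediate"],
                "log_k_non_immediate": p.log_k["non_immediate"],
                "log_temp": p.log_temp,
                "alpha": p.alpha["immediate"],
                "beta": p.beta["immediate"],
                "p_delay_first": p.p_delay_first,
                "p_delay_majority": p.p_delay_majority,
            }
            for p in cohort
        ]
    )
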