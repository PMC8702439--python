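"""Intertemporal-choice task logic: bisection staircase titration and batteries.

The task presents a smaller-sooner (SS) against a larger-later (LL) monetary
option.  In the staircase (titration) battery the LL reward is fixed and the
SS reward is adjusted by bisection after every choice: choosing LL raises the
candidate SS interval's lower bound to the current SS amount, choosing SS
lowers the upper bound, and the next SS amount is the midpoint of the updated
interval.  A block terminates once the interval is no wider than
``stop_width`` (default CNY 5), which from an initial width of 200 always
happens after exactly six responses.  The midpoint of the terminal interval is
taken as the behavioral indifference point.

Two batteries are provided.  The titration battery has five blocks per
delay condition (immediate: SS today, LL at 7/15/30/80/140 days;
non-immediate: SS at 15 days, every delay shifted 15 days out) with the LL
reward fixed at CNY 200 and the SS starting at CNY 100.  The fixed battery
has ten preset pairs per condition (LL CNY 200 at 85 or 105 days, SS rewards
spanning CNY 100-194) and is scored as the proportion of SS choices.

An attribute-attention probe is also modelled: four information boxes
("shorter delay", "longer delay", "smaller reward", "larger reward") opened
either freely (classified by the first-opened attribute) or under a
three-box constraint (classified by the majority attribute).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Callable, Iterable, Literal, Sequence

import pandas as pd

from .errors import ConfigurationError, StaircaseStateError, ValidationError

Choice = Literal["SS", "LL"]
Condition = Literal["immediate", "non_immediate"]

#: LL delays (days) of the five titration blocks, immediate condition.
IMMEDIATE_LL_DELAYS: tuple[int, ...] = (7, 15, 30, 80, 140)
#: Non-immediate condition: SS delayed 15 days, every LL delay shifted +15.
NON_IMMEDIATE_SHIFT: int = 15
NON_IMMEDIATE_LL_DELAYS: tuple[int, ...] = tuple(
    d + NON_IMMEDIATE_SHIFT for d in IMMEDIATE_LL_DELAYS
)

LL_AMOUNT_DEFAULT: float = 200.0
START_SS_DEFAULT: float = 100.0
STOP_WIDTH_DEFAULT: float = 5.0

#: Fixed-battery (10-pair) SS rewards: ten equally spaced values on 100-194,
#: rounded to whole CNY.
FIXED_SS_AMOUNTS: tuple[int, ...] = (100, 110, 121, 131, 142, 152, 163, 173, 184, 194)
FIXED_LL_DELAY = {"immediate": 85, "non_immediate": 105}
SS_DELAY = {"immediate": 0, "non_immediate": NON_IMMEDIATE_SHIFT}

ATTENTION_BOXES: tuple[str, ...] = (
    "shorter_delay",
    "longer_delay",
    "smaller_reward",
    "larger_reward",
)
DELAY_BOXES = frozenset({"shorter_delay", "longer_delay"})
REWARD_BOXES = frozenset({"smaller_reward", "larger_reward"})


@dataclass(frozen=True)
class ChoicePair:
    """One SS/LL option pair (amounts in CNY, delays in days)."""

    ss_amount: float
    ss_delay: float
    ll_amount: float
    ll_delay: float

    def __post_init__(self) -> None:
        if self.ss_amount < 0 or self.ll_amount < 0:
            raise ValidationError("amounts must be non-negative")
        if self.ss_delay < 0 or self.ll_delay < 0:
            raise ValidationError("delays must be non-negative")
        if not self.ll_amount > self.ss_amount:
            raise ValidationError("LL amount must exceed SS amount")
        if not self.ll_delay > self.ss_delay:
            raise ValidationError("LL delay must exceed SS delay")


@dataclass(frozen=True)
class StaircaseState:
    """Bisection state of one titration block."""

    lower: float
    upper: float
    current_ss: float
    trial_index: int = 1
    terminated: bool = False

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class TrialRecord:
    """One presented pair and the recorded response, with condition labels."""

    participant_id: str
    group: str
    condition: str
    block_id: str
    trial_index: int
    pair: ChoicePair
    choice: Choice

    def __post_init__(self) -> None:
        expected = SS_DELAY.get(self.condition)
        if expected is not None and self.pair.ss_delay != expected:
            raise ValidationError(
                f"condition {self.condition!r} requires ss_delay {expected}, "
                f"got {self.pair.ss_delay}"
            )
        if self.choice not in ("SS", "LL"):
            raise ValidationError(f"choice must be 'SS' or 'LL', got {self.choice!r}")


@dataclass
class BlockResult:
    """All trials of one titration block plus the indifference-point estimate."""

    records: list[TrialRecord]
    indifference_point: float
    terminal_width: float

    def to_json(self) -> str:
        payload = {
            "indifference_point": self.indifference_point,
            "terminal_width": self.terminal_width,
            "records": [
                {**asdict(r), "pair": asdict(r.pair)} for r in self.records
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, payload: str) -> "BlockResult":
        data = json.loads(payload)
        records = [
            TrialRecord(
                participant_id=r["participant_id"],
                group=r["group"],
                condition=r["condition"],
                block_id=r["block_id"],
                trial_index=r["trial_index"],
                pair=ChoicePair(**r["pair"]),
                choice=r["choice"],
            )
            for r in data["records"]
        ]
        return cls(records, data["indifference_point"], data["terminal_width"])


@dataclass(frozen=True)
class BlockSpec:
    """Static description of one titration block."""

    block_id: str
    ss_delay: float
    ll_delay: float
    ll_amount: float = LL_AMOUNT_DEFAULT
    start_ss: float = START_SS_DEFAULT
    stop_width: float = STOP_WIDTH_DEFAULT
    practice: bool = False


@dataclass(frozen=True)
class Battery:
    """A task battery: either titration blocks or a fixed list of pairs."""

    study: int
    condition: Condition
    kind: Literal["staircase", "fixed"]
    blocks: tuple[BlockSpec, ...] = ()
    pairs: tuple[ChoicePair, ...] = ()


def staircase_init(
    ll_amount: float, start_ss: float = START_SS_DEFAULT, floor: float = 0.0
) -> StaircaseState:
    """Fresh titration state with bounds [floor, ll_amount] and SS at start_ss."""
    if ll_amount <= 0:
        raise ConfigurationError("ll_amount must be positive")
    if not floor < start_ss < ll_amount:
        raise ConfigurationError(
            f"start_ss {start_ss} must lie strictly inside ({floor}, {ll_amount})"
        )
    return StaircaseState(lower=floor, upper=ll_amount, current_ss=start_ss)


def staircase_update(
    state: StaircaseState, choice: Choice, stop_width: float = STOP_WIDTH_DEFAULT
) -> StaircaseState:
    """Apply one bisection step.

    An LL choice means the current SS was too small to tempt the participant,
    so it becomes the new lower bound; an SS choice caps the upper bound.  The
    next SS amount is the midpoint of the updated interval and the state
    terminates once the interval width is at most ``stop_width``.
    """
    if state.terminated:
        raise StaircaseStateError("cannot update a terminated staircase state")
    if choice == "LL":
        lower, upper = state.current_ss, state.upper
    elif choice == "SS":
        lower, upper = state.lower, state.current_ss
    else:
        raise ValidationError(f"choice must be 'SS' or 'LL', got {choice!r}")
    return StaircaseState(
        lower=lower,
        upper=upper,
        current_ss=(lower + upper) / 2.0,
        trial_index=state.trial_index + 1,
        terminated=(upper - lower) <= stop_width,
    )


def run_block(
    agent: Callable[[ChoicePair], Choice],
    ll_amount: float = LL_AMOUNT_DEFAULT,
    ll_delay: float = 30.0,
    ss_delay: float = 0.0,
    stop_width: float = STOP_WIDTH_DEFAULT,
    start_ss: float | None = None,
    floor: float = 0.0,
    participant_id: str = "anon",
    group: str = "none",
    block_id: str | None = None,
) -> BlockResult:
    """Run an agent through one titration block until termination.

    The agent is any callable mapping a ChoicePair to ``"SS"`` or ``"LL"``.
    Termination is guaranteed because the interval halves on every response.
    """
    if start_ss is None:
        start_ss = (floor + ll_amount) / 2.0
    condition = "immediate" if ss_delay == 0 else "non_immediate"
    if block_id is None:
        block_id = f"{condition}_ll{ll_delay:g}"
    state = staircase_init(ll_amount, start_ss, floor)
    records: list[TrialRecord] = []
    while not state.terminated:
        pair = ChoicePair(state.current_ss, ss_delay, ll_amount, ll_delay)
        choice = agent(pair)
        records.append(
            TrialRecord(
                participant_id=participant_id,
                group=group,
                condition=condition,
                block_id=block_id,
                trial_index=state.trial_index,
                pair=pair,
                choice=choice,
            )
        )
        state = staircase_update(state, choice, stop_width)
    return BlockResult(
        records=records,
        indifference_point=(state.lower + state.upper) / 2.0,
        terminal_width=state.width,
    )


def build_battery(
    study: int, condition: str, include_practice: bool = False
) -> Battery:
    """Battery for one study and delay condition.

    Study 1 returns five titration blocks (plus an optional practice block,
    flagged and excluded from analysis); study 2 returns the ten fixed pairs.
    """
    if condition not in ("immediate", "non_immediate"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    ss_delay = SS_DELAY[condition]
    if study == 1:
        delays = (
            IMMEDIATE_LL_DELAYS if condition == "immediate" else NON_IMMEDIATE_LL_DELAYS
        )
        blocks: list[BlockSpec] = []
        if include_practice:
            blocks.append(
                BlockSpec(
                    block_id=f"{condition}_practice",
                    ss_delay=ss_delay,
                    ll_delay=delays[0],
                    practice=True,
                )
            )
        blocks.extend(
            BlockSpec(
                block_id=f"{condition}_ll{d}", ss_delay=ss_delay, ll_delay=d
            )
            for d in delays
        )
        return Battery(study=1, condition=condition, kind="staircase", blocks=tuple(blocks))
    if study == 2:
        ll_delay = FIXED_LL_DELAY[condition]
        pairs = tuple(
            ChoicePair(float(a), float(ss_delay), LL_AMOUNT_DEFAULT, float(ll_delay))
            for a in FIXED_SS_AMOUNTS
        )
        return Battery(study=2, condition=condition, kind="fixed", pairs=pairs)
    raise ConfigurationError(f"unknown study {study!r}")


def battery_delays(study: int = 1) -> set[float]:
    """Distinct non-zero delays appearing across both conditions of a study."""
    delays: set[float] = set()
    for condition in ("immediate", "non_immediate"):
        battery = build_battery(study, condition)
        for blk in battery.blocks:
            delays.update({blk.ss_delay, blk.ll_delay})
        for pair in battery.pairs:
            delays.update({pair.ss_delay, pair.ll_delay})
    delays.discard(0.0)
    return delays


def battery_table(battery: Battery) -> pd.DataFrame:
    """Delimited-text-ready view: one row per block (staircase) or pair (fixed)."""
    rows = []
    if battery.kind == "staircase":
        for blk in battery.blocks:
            rows.append(
                {
                    "study": battery.study,
                    "condition": battery.condition,
                    "block_id": blk.block_id,
                    "ss_amount": blk.start_ss,
                    "ss_delay": blk.ss_delay,
                    "ll_amount": blk.ll_amount,
                    "ll_delay": blk.ll_delay,
                    "practice": blk.practice,
                }
            )
    else:
        for i, pair in enumerate(battery.pairs, start=1):
            rows.append(
                {
                    "study": battery.study,
                    "condition": battery.condition,
                    "block_id": f"{battery.condition}_fixed",
                    "ss_amount": pair.ss_amount,
                    "ss_delay": pair.ss_delay,
                    "ll_amount": pair.ll_amount,
                    "ll_delay": pair.ll_delay,
                    "practice": False,
                }
            )
    return pd.DataFrame(rows)


def records_table(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records into the analysis input schema."""
    rows = [
        {
            "participant_id": r.participant_id,
            "group": r.group,
            "condition": r.condition,
            "block_id": r.block_id,
            "trial_index": r.trial_index,
            "ss_amount": r.pair.ss_amount,
            "ss_delay": r.pair.ss_delay,
            "ll_amount": r.pair.ll_amount,
            "ll_delay": r.pair.ll_delay,
            "choice": r.choice,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def attention_options(condition: str) -> dict:
    """Structure of the attribute-attention probe for one condition."""
    if condition == "full":
        return {"boxes": ATTENTION_BOXES, "open": "all_in_order", "classify": "first_opened"}
    if condition == "constrained":
        return {"boxes": ATTENTION_BOXES, "open": "choose_exactly_3", "classify": "majority"}
    raise ConfigurationError(f"unknown attention condition {condition!r}")


def classify_first_attention(opening_order: Sequence[str]) -> str:
    """Attribute class (delay vs reward) of the first-opened box."""
    if sorted(opening_order) != sorted(ATTENTION_BOXES):
        raise ValidationError("full condition requires all four boxes opened once")
    return "delay" if opening_order[0] in DELAY_BOXES else "reward"


def classify_majority_attention(selection: Iterable[str]) -> str:
    """Majority attribute of a constrained three-box selection."""
    boxes = list(selection)
    if len(boxes) != 3 or len(set(boxes)) != 3:
        raise ValidationError("constrained condition requires exactly 3 distinct boxes")
    unknown = set(boxes) - set(ATTENTION_BOXES)
    if unknown:
        raise ValidationError(f"unknown boxes: {sorted(unknown)}")
    n_delay = sum(b in DELAY_BOXES for b in boxes)
    return "delay" if n_delay == 2 else "reward"


def threshold_agent(threshold: float) -> Callable[[ChoicePair], Choice]:
    """Deterministic agent choosing LL iff the SS amount is below a threshold."""

    def agent(pair: ChoicePair) -> Choice:
        return "LL" if pair.ss_amount < threshold else "SS"

    return agent
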