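"""Factorial designs, counterbalanced order enumeration, and trial schedules.

Two within-subjects designs are encoded:

* Experiment 1 — posture {upright, reclined} x alignment {aligned, misaligned}
  x speed {slow, fast}; 12 trials in 2 posture main blocks of 2 alignment
  sub-blocks, each sub-block opening with a stationary baseline trial.
* Experiment 2 — direction {forward, reverse, lateral} x speed {slow, fast};
  9 trials in 3 direction blocks, each opening with a stationary baseline.

Counterbalancing yields 16 order levels for Experiment 1 (posture-block order
x sub-block order within each main block x speed order: 2*2*2*2) and 12 for
Experiment 2 (3! direction permutations x 2 speed orders).  Speed order is
fixed within a participant.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigurationError

POSTURES = ("upright", "reclined")
ALIGNMENTS = ("aligned", "misaligned")
DIRECTIONS = ("forward", "reverse", "lateral")
SPEED_ORDERS = (("slow", "fast"), ("fast", "slow"))


@dataclass(frozen=True)
class DesignSpec:
    """A within-subjects factorial design with counterbalanced order components."""

    experiment: int | None
    within_factors: tuple[tuple[str, tuple[str, ...]], ...]
    #: names of factors whose presentation order is counterbalanced (generic designs)
    counterbalanced: tuple[str, ...] = ()

    def factor_levels(self, name: str) -> tuple[str, ...]:
        for factor, levels in self.within_factors:
            if factor == name:
                return levels
        raise KeyError(name)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.within_factors)


EXPERIMENT_1 = DesignSpec(
    experiment=1,
    within_factors=(
        ("posture", POSTURES),
        ("alignment", ALIGNMENTS),
        ("speed", ("slow", "fast")),
    ),
)

EXPERIMENT_2 = DesignSpec(
    experiment=2,
    within_factors=(
        ("direction", DIRECTIONS),
        ("speed", ("slow", "fast")),
    ),
)


@dataclass(frozen=True)
class OrderAssignment:
    """One enumerated counterbalancing order.

    ``components`` maps order-component names to level tuples, e.g. for
    Experiment 1: posture_block_order, subblock_order_block1,
    subblock_order_block2, speed_order.
    """

    order_index: int
    components: tuple[tuple[str, tuple[str, ...]], ...]

    def component(self, name: str) -> tuple[str, ...]:
        for key, value in self.components:
            if key == name:
                return value
        raise KeyError(name)


@dataclass(frozen=True)
class ScheduledTrial:
    """One slot of a session schedule; ``speed == "stationary"`` marks baselines."""

    trial_index: int
    block: int
    sub_block: int
    speed: str
    posture: str | None = None
    alignment: str | None = None
    direction: str | None = None

    @property
    def is_stationary(self) -> bool:
        return self.speed == "stationary"

    def condition(self) -> tuple:
        return (self.posture, self.alignment, self.direction, self.speed)


def enumerate_orders(design: DesignSpec) -> list[OrderAssignment]:
    """Every distinct realizable counterbalancing order, deterministically sorted.

    Experiment 1 -> 16 orders; Experiment 2 -> 12; generic designs -> the
    product of the level permutations of each factor named in
    ``design.counterbalanced``.
    """
    if design.experiment == 1:
        combos = itertools.product(
            itertools.permutations(POSTURES),
            itertools.permutations(ALIGNMENTS),
            itertools.permutations(ALIGNMENTS),
            SPEED_ORDERS,
        )
        return [
            OrderAssignment(
                order_index=i,
                components=(
                    ("posture_block_order", tuple(p)),
                    ("subblock_order_block1", tuple(a1)),
                    ("subblock_order_block2", tuple(a2)),
                    ("speed_order", tuple(s)),
                ),
            )
            for i, (p, a1, a2, s) in enumerate(combos)
        ]
    if design.experiment == 2:
        combos = itertools.product(itertools.permutations(DIRECTIONS), SPEED_ORDERS)
        return [
            OrderAssignment(
                order_index=i,
                components=(
                    ("direction_order", tuple(d)),
                    ("speed_order", tuple(s)),
                ),
            )
            for i, (d, s) in enumerate(combos)
        ]
    if design.counterbalanced:
        permuted = []
        for name in design.counterbalanced:
            levels = design.factor_levels(name)
            permuted.append([(name, tuple(p)) for p in itertools.permutations(levels)])
        return [
            OrderAssignment(order_index=i, components=tuple(combo))
            for i, combo in enumerate(itertools.product(*permuted))
        ]
    raise ConfigurationError(
        "unknown experiment id and no counterbalanced factors declared; "
        "cannot enumerate orders"
    )


def _check_order(design: DesignSpec, order: OrderAssignment, expected: tuple[str, ...]) -> None:
    names = tuple(name for name, _ in order.components)
    if names != expected:
        raise ConfigurationError(
            f"order {order.order_index} with components {names} does not match "
            f"experiment {design.experiment} (expected {expected})"
        )


def build_session_schedule(design: DesignSpec, order: OrderAssignment) -> list[ScheduledTrial]:
    """The ordered trial list one participant runs under a given order.

    Each (sub-)block is [stationary baseline, lap, lap] with the participant's
    fixed speed order; Experiment 1 yields 12 trials, Experiment 2 yields 9.
    """
    trials: list[ScheduledTrial] = []
    if design.experiment == 1:
        _check_order(
            design,
            order,
            ("posture_block_order", "subblock_order_block1", "subblock_order_block2", "speed_order"),
        )
        speed_order = order.component("speed_order")
        sub_orders = (
            order.component("subblock_order_block1"),
            order.component("subblock_order_block2"),
        )
        index = 0
        for block, posture in enumerate(order.component("posture_block_order")):
            for sub, alignment in enumerate(sub_orders[block]):
                for speed in ("stationary",) + tuple(speed_order):
                    trials.append(
                        ScheduledTrial(
                            trial_index=index,
                            block=block,
                            sub_block=sub,
                            posture=posture,
                            alignment=alignment,
                            speed=speed,
                        )
                    )
                    index += 1
        return trials
    if design.experiment == 2:
        _check_order(design, order, ("direction_order", "speed_order"))
        speed_order = order.component("speed_order")
        index = 0
        for block, direction in enumerate(order.component("direction_order")):
            for speed in ("stationary",) + tuple(speed_order):
                trials.append(
                    ScheduledTrial(
                        trial_index=index,
                        block=block,
                        sub_block=0,
                        direction=direction,
                        speed=speed,
                    )
                )
                index += 1
        return trials
    raise ConfigurationError(
        f"session schedules are defined for experiments 1 and 2, not {design.experiment!r}"
    )


def assign_orders(design: DesignSpec, n_participants: int) -> list[OrderAssignment]:
    """Round-robin order assignment by participant index.

    Balanced only when ``n_participants`` is a multiple of the order count;
    otherwise the assignment is as even as possible and a warning is issued.
    """
    orders = enumerate_orders(design)
    if n_participants % len(orders) != 0:
        warnings.warn(
            f"{n_participants} participants cannot be split evenly over "
            f"{len(orders)} order levels; assigning round-robin",
            stacklevel=2,
        )
    return [orders[i % len(orders)] for i in range(n_participants)]
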