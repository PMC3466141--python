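"""Recruitment funnel yields and interviewing cost arithmetic.

Cost per completed interview divides the call-center hourly rate by the
completes-per-hour productivity; multiplying back by the number of completed
interviews gives the arm's total interviewing cost. Yields divide completed
interviews by an arm-specific denominator: usable telephone numbers for the
survivor arm, nominees for the peer arm, and numbers dialed for the listed
arm.

Rounding dialects matter for bit-exact reproduction of published figures:
currency division truncates to cents by default (25/0.60 = 41.666… prints as
$41.66), while integer-percent yields round half-up (100/372 = 26.88% prints
as 27%). Both dialects are options.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import DomainError

ARMS = ("survivor", "peer", "listed")
ROUNDING_MODES = {"truncate": ROUND_DOWN, "half_up": ROUND_HALF_UP}

#: Which ledger field completions are divided by when reporting yield, per arm.
YIELD_DENOMINATORS = {
    "survivor": "n_usable_numbers",
    "peer": "n_candidates",
    "listed": "n_usable_numbers",
}


@dataclass
class RecruitmentLedger:
    """Funnel counts and rate parameters for one recruitment arm."""

    arm: str
    n_candidates: int
    n_usable_numbers: int
    n_completed: int
    completes_per_hour: float
    hourly_rate: float = 25.0
    stage_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DomainError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        counts = [self.n_candidates, self.n_usable_numbers, self.n_completed]
        if any(c < 0 for c in counts) or any(c < 0 for c in self.stage_counts.values()):
            raise DomainError(f"arm {self.arm}: negative counts are invalid")
        if not self.n_completed <= self.n_usable_numbers <= self.n_candidates:
            raise DomainError(
                f"arm {self.arm}: require completed <= usable <= candidates, got "
                f"{self.n_completed} / {self.n_usable_numbers} / {self.n_candidates}"
            )
        if self.n_completed + sum(self.stage_counts.values()) > self.n_candidates:
            raise DomainError(
                f"arm {self.arm}: stage counts plus completions exceed candidates"
            )


def _quantize_cents(x: Decimal, rounding: str) -> Decimal:
    try:
        mode = ROUNDING_MODES[rounding]
    except KeyError:
        raise DomainError(
            f"unknown rounding {rounding!r}; expected one of {tuple(ROUNDING_MODES)}"
        ) from None
    return x.quantize(Decimal("0.01"), rounding=mode)


def yield_rate(
    n_completed: int,
    n_denominator: int,
    decimals: int | None = 1,
    rounding: str = "truncate",
) -> float:
    """Percentage of completions over an arm-specific denominator.

    ``decimals=None`` returns the unrounded percentage; otherwise the value is
    rounded to that many decimals under the chosen dialect (default one
    decimal, truncated: 44/91 -> 48.3; with ``decimals=0, rounding='half_up'``
    100/372 -> 27).
    """
    if n_denominator <= 0:
        raise DomainError("yield denominator must be positive")
    if not 0 <= n_completed <= n_denominator:
        raise DomainError(
            f"completions must lie in [0, denominator]; got {n_completed}/{n_denominator}"
        )
    pct = Decimal(100) * Decimal(n_completed) / Decimal(n_denominator)
    if decimals is None:
        return float(pct)
    try:
        mode = ROUNDING_MODES[rounding]
    except KeyError:
        raise DomainError(
            f"unknown rounding {rounding!r}; expected one of {tuple(ROUNDING_MODES)}"
        ) from None
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=mode))


def cost_per_complete(
    hourly_rate: float, completes_per_hour: float, rounding: str = "truncate"
) -> Decimal:
    """Hourly rate divided by completes per hour, as currency.

    Defaults to truncation to cents, reproducing published cost tables where
    25/0.60 = 41.666… is printed as 41.66.
    """
    if completes_per_hour <= 0:
        raise DomainError("completes_per_hour must be positive")
    if hourly_rate < 0:
        raise DomainError("hourly_rate must be non-negative")
    raw = Decimal(str(hourly_rate)) / Decimal(str(completes_per_hour))
    return _quantize_cents(raw, rounding)


def total_cost(cost_per_complete_: Decimal | float, n_completed: int) -> Decimal:
    """Total interviewing cost for an arm, rounded half-up to cents."""
    if n_completed < 0:
        raise DomainError("n_completed must be non-negative")
    cpc = Decimal(str(cost_per_complete_))
    if cpc < 0:
        raise DomainError("cost per complete must be non-negative")
    return (cpc * n_completed).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


def accounting_report(
    ledgers: list[RecruitmentLedger],
    rounding: str = "truncate",
    yield_decimals: int = 0,
    yield_rounding: str = "half_up",
) -> pd.DataFrame:
    """Per-arm cost and yield table; funnel stage counts echoed for audit."""
    seen = set()
    rows = []
    for led in ledgers:
        if led.arm in seen:
            raise DomainError(f"duplicate arm {led.arm!r} in ledger list")
        seen.add(led.arm)
        denom = getattr(led, YIELD_DENOMINATORS[led.arm])
        cpc = cost_per_complete(led.hourly_rate, led.completes_per_hour, rounding)
        rows.append(
            {
                "arm": led.arm,
                "n_candidates": led.n_candidates,
                "n_usable_numbers": led.n_usable_numbers,
                "n_completed": led.n_completed,
                "completes_per_hour": led.completes_per_hour,
                "cost_per_complete": float(cpc),
                "total_cost": float(total_cost(cpc, led.n_completed)),
                "yield_pct": yield_rate(
                    led.n_completed, denom, decimals=yield_decimals, rounding=yield_rounding
                ),
                "stage_counts": dict(led.stage_counts),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "arm",
            "n_candidates",
            "n_usable_numbers",
            "n_completed",
            "completes_per_hour",
            "cost_per_complete",
            "total_cost",
            "yield_pct",
            "stage_counts",
        ],
    )


def read_ledgers(path) -> list[RecruitmentLedger]:
    """Read one-arm-per-row ledger CSV; ``stage_*`` columns become stage counts."""
    frame = pd.read_csv(path)
    required = {"arm", "n_candidates", "n_usable_numbers", "n_completed", "completes_per_hour"}
    missing = required - set(frame.columns)
    if missing:
        raise DomainError(f"{path}: missing ledger column(s): {', '.join(sorted(missing))}")
    stage_cols = [c for c in frame.columns if c.startswith("stage_")]
    ledgers = []
    for _, row in frame.iterrows():
        ledgers.append(
            RecruitmentLedger(
                arm=str(row["arm"]),
                n_candidates=int(row["n_candidates"]),
                n_usable_numbers=int(row["n_usable_numbers"]),
                n_completed=int(row["n_completed"]),
                completes_per_hour=float(row["completes_per_hour"]),
                hourly_rate=float(row.get("hourly_rate", 25.0)),
                stage_counts={
                    c[len("stage_"):]: int(row[c]) for c in stage_cols if pd.notna(row[c])
                },
            )
        )
    return ledgers


def write_ledgers(ledgers: list[RecruitmentLedger], path) -> None:
    """Write ledgers as CSV (inverse of :func:`read_ledgers`)."""
    stages = sorted({s for led in ledgers for s in led.stage_counts})
    rows = []
    for led in ledgers:
        row = {
            "arm": led.arm,
            "n_candidates": led.n_candidates,
            "n_usable_numbers": led.n_usable_numbers,
            "n_completed": led.n_completed,
            "completes_per_hour": led.completes_per_hour,
            "hourly_rate": led.hourly_rate,
        }
        for s in stages:
            row[f"stage_{s}"] = led.stage_counts.get(s, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
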