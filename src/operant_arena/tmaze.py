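"""Forced-choice T-maze indices and the participation-based exclusion rule.

A trial releases a group of flies to choose between an odor arm (A) and a
control arm (B); flies remaining in the elevator are recorded as DNP
("did not participate").  Deaths are subtracted before computing indices.
Two indices summarise a trial:

* conditioned preference index  CPI = (A - B) / (A + B), positive meaning
  preference for the odor arm;
* participation index = (A + B) / (A + B + DNP).

Trials with participation index <= 0.5 (at most half the flies chose) are
excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

ARMS = ("A", "B", "DNP")


@dataclass
class TmazeTrial:
    """Raw counts for one T-maze trial.

    ``dead_arm`` names where deaths occurred ("A", "B" or "DNP"); when the
    arm was not recorded, deaths are subtracted from DNP — the conservative
    choice, since it leaves the CPI unchanged.
    """

    n_a: int
    n_b: int
    n_dnp: int
    n_dead: int = 0
    dead_arm: str | None = None
    trial_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_a", "n_b", "n_dnp", "n_dead"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_dead > self.n_a + self.n_b + self.n_dnp:
            raise ValueError("more deaths than flies")
        if self.dead_arm is not None and self.dead_arm not in ARMS:
            raise ValueError(f"dead_arm must be one of {ARMS}")

    def effective_counts(self) -> tuple[int, int, int]:
        """(A, B, DNP) after death subtraction."""
        a, b, dnp = self.n_a, self.n_b, self.n_dnp
        if self.n_dead == 0:
            return a, b, dnp
        arm = self.dead_arm or "DNP"
        counts = {"A": a, "B": b, "DNP": dnp}
        if counts[arm] < self.n_dead:
            raise ValueError(
                f"trial {self.trial_id!r}: {self.n_dead} deaths exceed the "
                f"{counts[arm]} flies recorded in arm {arm}"
            )
        counts[arm] -= self.n_dead
        return counts["A"], counts["B"], counts["DNP"]


def cpi(trial: TmazeTrial) -> float | None:
    """(A - B) / (A + B) after death subtraction; None if no fly chose."""
    a, b, _ = trial.effective_counts()
    if a + b == 0:
        return None
    return (a - b) / (a + b)


def participation_index(trial: TmazeTrial) -> float:
    """(A + B) / (A + B + DNP) after death subtraction."""
    a, b, dnp = trial.effective_counts()
    total = a + b + dnp
    if total == 0:
        raise ValueError(f"trial {trial.trial_id!r}: no flies after death subtraction")
    return (a + b) / total


def filter_trials(
    trials: list[TmazeTrial], threshold: float = 0.5
) -> tuple[list[TmazeTrial], list[tuple[TmazeTrial, str]]]:
    """Partition trials into (kept, excluded-with-reason).

    A trial is excluded when its participation index is <= ``threshold``
    (inclusive: exactly half participating is not enough).
    """
    kept: list[TmazeTrial] = []
    excluded: list[tuple[TmazeTrial, str]] = []
    for t in trials:
        p = participation_index(t)
        if p <= threshold:
            excluded.append((t, f"participation index {p:.3f} <= {threshold}"))
        else:
            kept.append(t)
    return kept, excluded


def read_trials(path: str | Path) -> list[TmazeTrial]:
    """Read a trial CSV: trial_id, n_A, n_B, n_DNP[, n_dead, dead_arm]."""
    df = pd.read_csv(path)
    required = {"n_A", "n_B", "n_DNP"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    trials = []
    for _, row in df.iterrows():
        dead_arm = row.get("dead_arm")
        if pd.isna(dead_arm):
            dead_arm = None
        trials.append(
            TmazeTrial(
                n_a=int(row["n_A"]),
                n_b=int(row["n_B"]),
                n_dnp=int(row["n_DNP"]),
                n_dead=int(row["n_dead"]) if "n_dead" in df.columns else 0,
                dead_arm=dead_arm,
                trial_id=str(row.get("trial_id", "")),
            )
        )
    return trials


def summarize_trials(trials: list[TmazeTrial], threshold: float = 0.5) -> pd.DataFrame:
    """Per-trial CPI, participation and kept/excluded flag as a tidy table."""
    kept, excluded = filter_trials(trials, threshold)
    reasons = {id(t): reason for t, reason in excluded}
    rows = []
    for t in trials:
        rows.append(
            {
                "trial_id": t.trial_id,
                "cpi": cpi(t),
                "participation_index": participation_index(t),
                "kept": id(t) not in reasons,
                "exclusion_reason": reasons.get(id(t), ""),
            }
        )
    return pd.DataFrame(rows)
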