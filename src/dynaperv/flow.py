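"""Declarative, auditable inclusion/exclusion accounting.

The study screened 475 consecutive thrombectomy referrals and excluded
patients in seven labelled steps (unsuitable thrombus, MRI instead of CT,
external imaging, missing venous phase, missing unenhanced series,
motion/resolution, no consent), leaving 137.  The final count depends only
on the total removed; the audit trail records the running totals in order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import FlowConsistencyError

__all__ = ["ExclusionStep", "FlowAudit", "apply_exclusions", "apply_exclusion_predicates",
           "DEFAULT_EXCLUSIONS", "DEFAULT_N_INITIAL"]


@dataclass(frozen=True)
class ExclusionStep:
    """One exclusion reason and how many patients it removed."""

    label: str
    n_removed: int

    def __post_init__(self) -> None:
        if self.n_removed < 0:
            raise ValueError(f"n_removed must be >= 0 for step {self.label!r}")


#: The published screening flow: 475 referrals down to 137 analysed patients.
DEFAULT_N_INITIAL = 475
DEFAULT_EXCLUSIONS = (
    ExclusionStep("unsuitable thrombus (calcified/distal/extracranial)", 84),
    ExclusionStep("MRI performed instead of CT", 54),
    ExclusionStep("external imaging not stored in PACS", 81),
    ExclusionStep("no late/venous phase", 46),
    ExclusionStep("no unenhanced series", 9),
    ExclusionStep("motion artefacts or resolution below 0.8 mm", 43),
    ExclusionStep("no consent", 21),
)


@dataclass(frozen=True)
class FlowAudit:
    """Audit trail of an exclusion chain."""

    n_initial: int
    trail: pd.DataFrame  # columns: step, label, n_removed, n_remaining

    @property
    def final(self) -> int:
        if len(self.trail) == 0:
            return self.n_initial
        return int(self.trail["n_remaining"].iloc[-1])

    def to_csv(self, path) -> None:
        self.trail.to_csv(path, index=False)


def apply_exclusions(n_initial: int, steps: Sequence[ExclusionStep] = DEFAULT_EXCLUSIONS) -> FlowAudit:
    """Apply exclusion counts in order; raise if any running total goes negative.

    The final count is order-invariant; the audit trail is not.
    """
    if n_initial < 0:
        raise ValueError("n_initial must be >= 0")
    labels = [s.label for s in steps]
    if len(set(labels)) != len(labels):
        raise ValueError("exclusion step labels must be unique")
    rows = []
    remaining = int(n_initial)
    for i, step in enumerate(steps, start=1):
        remaining -= step.n_removed
        if remaining < 0:
            raise FlowConsistencyError(
                f"step {i} ({step.label!r}) removes {step.n_removed} but only "
                f"{remaining + step.n_removed} patients remain"
            )
        rows.append({"step": i, "label": step.label,
                     "n_removed": step.n_removed, "n_remaining": remaining})
    trail = pd.DataFrame(rows, columns=["step", "label", "n_removed", "n_remaining"])
    return FlowAudit(n_initial=int(n_initial), trail=trail)


def apply_exclusion_predicates(
    cohort: pd.DataFrame,
    steps: Iterable[tuple[str, Callable[[pd.DataFrame], pd.Series]]],
) -> tuple[pd.DataFrame, FlowAudit]:
    """Predicate-based variant for simulated cohorts.

    Each step is ``(label, predicate)`` where the predicate returns a boolean
    Series marking rows to *remove* from the patients still included.
    Returns the retained rows and the audit trail.
    """
    remaining = cohort
    audit_steps = []
    for label, predicate in steps:
        drop = predicate(remaining).astype(bool)
        audit_steps.append(ExclusionStep(label, int(drop.sum())))
        remaining = remaining[~drop]
    return remaining, apply_exclusions(len(cohort), audit_steps)
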