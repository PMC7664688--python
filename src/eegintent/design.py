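"""Experiment design: subjects x question trials with scenario type and answer.

Each subject sees ``n_insider`` insider-threat scenarios and ``n_conflict``
everyday-conflict scenarios in a random order.  The yes/no answer to each
question is drawn from a per-scenario-type probability; a small dropout
probability marks questions excluded from analysis (emulating over-time
responses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eegintent.seeding import STAGE, rng

#: default yes-answer rates: 96/242 for insider, 150/248 for conflict questions
DEFAULT_YES_PROB = {"insider": 96 / 242, "conflict": 150 / 248}
#: default per-question exclusion probability (10 of 500 in expectation)
DEFAULT_DROPOUT = 10 / 500

SCENARIO_TYPES = ("insider", "conflict")


@dataclass(frozen=True)
class QuestionTrial:
    subject: str
    question: int            # presentation order, 1-based, unique per subject
    scenario_type: str       # "insider" | "conflict"
    scenario_index: int      # 1..n within its scenario type
    answer: str              # "yes" | "no"
    responded: bool = True   # False -> excluded from analysis


@dataclass
class ExperimentDesign:
    trials: list[QuestionTrial] = field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.subject, None)
        return list(seen)

    def subject_trials(self, subject: str) -> list[QuestionTrial]:
        return [t for t in self.trials if t.subject == subject]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject": t.subject,
                    "question": t.question,
                    "scenario_type": t.scenario_type,
                    "scenario_index": t.scenario_index,
                    "answer": t.answer,
                    "responded": t.responded,
                }
                for t in self.trials
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExperimentDesign":
        trials = [
            QuestionTrial(
                subject=str(r.subject),
                question=int(r.question),
                scenario_type=str(r.scenario_type),
                scenario_index=int(r.scenario_index),
                answer=str(r.answer),
                responded=bool(r.responded),
            )
            for r in df.itertuples()
        ]
        return cls(trials)

    def __len__(self) -> int:
        return len(self.trials)


def make_design(
    n_subjects: int = 25,
    n_insider: int = 10,
    n_conflict: int = 10,
    yes_prob_by_type: dict[str, float] | None = None,
    dropout_prob: float = DEFAULT_DROPOUT,
    seed: int = 0,
) -> ExperimentDesign:
    """Build a seeded experiment design.

    Per subject, the ``n_insider + n_conflict`` scenarios are presented in a
    random order; each trial's answer label is Bernoulli with the
    scenario-type yes-probability.  Deterministic given ``seed``.
    """
    if n_subjects < 0 or n_insider < 0 or n_conflict < 0:
        raise ValueError("subject and question counts must be non-negative")
    probs = dict(DEFAULT_YES_PROB)
    if yes_prob_by_type:
        probs.update(yes_prob_by_type)
    for st, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"yes probability for {st!r} must be in [0, 1], got {p}")
    if not 0.0 <= dropout_prob <= 1.0:
        raise ValueError("dropout_prob must be in [0, 1]")

    trials: list[QuestionTrial] = []
    for si in range(n_subjects):
        g = rng(seed, STAGE["design"], si)
        slots = [("insider", k + 1) for k in range(n_insider)] + [
            ("conflict", k + 1) for k in range(n_conflict)
        ]
        order = g.permutation(len(slots))
        subject = f"S{si + 1:02d}"
        for q, idx in enumerate(order, start=1):
            stype, sidx = slots[idx]
            answer = "yes" if g.random() < probs[stype] else "no"
            responded = g.random() >= dropout_prob
            trials.append(
                QuestionTrial(
                    subject=subject,
                    question=q,
                    scenario_type=stype,
                    scenario_index=sidx,
                    answer=answer,
                    responded=responded,
                )
            )
    return ExperimentDesign(trials)
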