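"""Influence-diagram layer: expected-utility treatment recommendation.

A fitted outcome model becomes a decision model by promoting each binary
treatment cause to a decision node and attaching utility nodes: one for
the outcome (default: 1 if non-adverse, 0 if adverse) and one per
treatment with a nonzero quality-of-life disutility x, subtracted whenever
that treatment is taken.  Disutilities come from the standard gamble: a
patient indifferent between certain treatment and an untreated gamble with
probability p of the good outcome values treatment at 1 - x = p.

Recommendation enumerates every joint treatment assignment (at most 2^T)
and returns the one maximizing expected utility; ties break toward less
intervention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bn import CategoricalDistribution
from .camil import CamilModel, OrdinalCamil
from .errors import ConfigError, SchemaError

__all__ = [
    "UtilitySpec",
    "Recommendation",
    "InfluenceDiagram",
    "to_influence_diagram",
    "standard_gamble_disutility",
]


def standard_gamble_disutility(p: float) -> float:
    """Disutility x of a treatment from the standard-gamble indifference point.

    The patient is indifferent between taking the treatment with a certain
    good outcome (utility 1 - x) and forgoing it with probability *p* of
    the good outcome: 1 - x = 0*(1 - p) + 1*p, hence x = 1 - p.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"indifference probability must be in [0, 1], got {p}")
    return 1.0 - p


@dataclass
class UtilitySpec:
    """Outcome utilities per target state and per-treatment disutilities."""

    outcome_utilities: dict[str, float] | None = None
    treatment_disutilities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for t, x in self.treatment_disutilities.items():
            if not np.isfinite(x) or x < 0:
                raise ConfigError(f"disutility for {t!r} must be finite and >= 0")
        if self.outcome_utilities is not None:
            for s, u in self.outcome_utilities.items():
                if not np.isfinite(u):
                    raise ConfigError(f"outcome utility for {s!r} must be finite")

    def utilities_for(self, model) -> dict[str, float]:
        """Resolved per-state outcome utilities (default: adverse 0, else 1)."""
        if self.outcome_utilities is not None:
            missing = set(model.target.states) - set(self.outcome_utilities)
            if missing:
                raise ConfigError(f"no utility for target states {sorted(missing)}")
            return dict(self.outcome_utilities)
        adverse = getattr(model, "adverse_state", model.target.states[-1])
        return {s: (0.0 if s == adverse else 1.0) for s in model.target.states}


@dataclass
class Recommendation:
    decisions: dict[str, str]
    expected_utility: float
    all_utilities: dict[tuple[str, ...], float]
    p_adverse_chosen: float
    p_adverse_status_quo: float


class InfluenceDiagram:
    """A CAMIL model with treatments promoted to decisions plus utilities."""

    def __init__(
        self,
        model: CamilModel | OrdinalCamil,
        treatments: Sequence[str],
        utility: UtilitySpec | None = None,
    ):
        self.model = model
        self.utility = utility or UtilitySpec()
        self.treatments = tuple(treatments)
        cause_names = {v.name for v in model.causes}
        for t in self.treatments:
            if t not in cause_names:
                raise SchemaError(f"treatment {t!r} is not a cause of the model")
            if model.cause(t).n_states != 2:
                raise SchemaError(f"treatment {t!r} must be binary")
        for t in self.utility.treatment_disutilities:
            if t not in self.treatments:
                raise SchemaError(f"disutility names unknown treatment {t!r}")

    # -- structure ------------------------------------------------------
    @property
    def decision_nodes(self) -> tuple[str, ...]:
        return self.treatments

    @property
    def chance_nodes(self) -> tuple[str, ...]:
        return tuple(
            v.name for v in self.model.causes if v.name not in self.treatments
        )

    @property
    def utility_nodes(self) -> tuple[str, ...]:
        """The outcome-utility node plus one node per nonzero disutility."""
        extra = tuple(
            f"disutility[{t}]"
            for t in self.treatments
            if self.utility.treatment_disutilities.get(t, 0.0) > 0.0
        )
        return (f"utility[{self.model.target.name}]",) + extra

    @property
    def base_model(self) -> CamilModel | OrdinalCamil:
        """Strip the decision/utility annotations (inverse construction)."""
        return self.model

    # -- solution -------------------------------------------------------
    def _outcome(self, record: Mapping[str, str]) -> CategoricalDistribution:
        return self.model.predict(record)

    def expected_utility(
        self, features: Mapping[str, str], assignment: Mapping[str, str]
    ) -> float:
        """Utility expectation under the model, minus taken disutilities."""
        missing = set(self.treatments) - set(assignment)
        if missing:
            raise SchemaError(f"assignment misses decisions {sorted(missing)}")
        record = {**features, **assignment}
        dist = self._outcome(record)
        utils = self.utility.utilities_for(self.model)
        eu = sum(utils[s] * dist[s] for s in self.model.target.states)
        for t in self.treatments:
            x = self.utility.treatment_disutilities.get(t, 0.0)
            if assignment[t] == self._taken_state(t):
                eu -= x
        return float(eu)

    def _taken_state(self, t: str) -> str:
        return self.model.cause(t).states[-1]

    def _untaken_state(self, t: str) -> str:
        return self.model.cause(t).states[0]

    def _p_adverse(self, record: Mapping[str, str]) -> float:
        if isinstance(self.model, CamilModel):
            return self.model.predict_adverse(record)
        dist = self.model.predict(record)
        return 1.0 - dist[self.model.target.states[0]]

    def recommend(self, features: Mapping[str, str]) -> Recommendation:
        """Maximize expected utility over all joint treatment assignments.

        *features* must assign every non-treatment cause.  Ties break
        toward fewer treatments taken (less intervention), then
        lexicographically by which treatments are taken.
        """
        missing = set(self.chance_nodes) - set(features)
        if missing:
            raise SchemaError(f"features miss causes {sorted(missing)}")
        # assignments ordered so less intervention comes first; strict
        # improvement required to replace, which realizes the tie-break
        options = sorted(
            itertools.product((False, True), repeat=len(self.treatments)),
            key=lambda taken: (sum(taken), tuple(
                t for t, k in zip(self.treatments, taken) if k
            )),
        )
        best_eu, best_assignment, all_utilities = -np.inf, None, {}
        for taken in options:
            assignment = {
                t: (self._taken_state(t) if k else self._untaken_state(t))
                for t, k in zip(self.treatments, taken)
            }
            eu = self.expected_utility(features, assignment)
            all_utilities[tuple(assignment[t] for t in self.treatments)] = eu
            if eu > best_eu:
                best_eu, best_assignment = eu, assignment
        status_quo = {t: self._untaken_state(t) for t in self.treatments}
        return Recommendation(
            decisions=best_assignment,
            expected_utility=best_eu,
            all_utilities=all_utilities,
            p_adverse_chosen=self._p_adverse({**features, **best_assignment}),
            p_adverse_status_quo=self._p_adverse({**features, **status_quo}),
        )


def to_influence_diagram(
    model: CamilModel | OrdinalCamil,
    treatments: Sequence[str],
    utility: UtilitySpec | None = None,
) -> InfluenceDiagram:
    """Promote the model's treatment causes to decision nodes."""
    return InfluenceDiagram(model, treatments, utility)
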