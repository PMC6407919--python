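"""K-fold cross-validation of the full decision-support pipeline.

For each fold, the pipeline (interaction screening -> confounder check ->
noisy-OR fit -> influence diagram) is learned on the other folds and
applied to every held-out record.  Per treatment we tally

    n1: records whose actual treatment matched the recommendation
    k1: of those, how many avoided the adverse outcome
    n2/k2: the same for records that did not match

summed across folds into N1/K1/N2/K2.  K1/N1 estimates the probability of
a good outcome when following the recommendation (which, with 0/1 outcome
utilities, is also the average utility); K2/N2 the same when deviating.
Binomial confidence intervals are available in Wald and Wilson forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .bn import DataTable
from .camil import CamilModel, HiddenGroup, em_fit
from .errors import ConfigError, SchemaError
from .influence import InfluenceDiagram, UtilitySpec
from .tfi import confounder_check, rank_interactions

__all__ = [
    "kfold_split",
    "proportion_ci",
    "EvalCounts",
    "PipelineConfig",
    "fit_pipeline",
    "evaluate",
]

logger = logging.getLogger(__name__)


def kfold_split(n: int, k: int, seed: int | None = None) -> list[np.ndarray]:
    """Random partition of range(n) into k folds with sizes differing <= 1."""
    if k < 2:
        raise ConfigError("k must be >= 2")
    if k > n:
        raise ConfigError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Binomial proportion confidence interval (``wald`` or ``wilson``).

    The Wald (normal-approximation) interval is clipped to [0, 1]; the
    Wilson score interval lies in [0, 1] by construction.
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    if not 0 <= k <= n:
        raise ConfigError("k must be in [0, n]")
    sm_method = {"wald": "normal", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ConfigError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method=sm_method)
    return (float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))


@dataclass
class EvalCounts:
    """Per-fold and summed follow/deviate outcome tallies for one treatment."""

    treatment: str
    n1_folds: list[int] = field(default_factory=list)
    k1_folds: list[int] = field(default_factory=list)
    n2_folds: list[int] = field(default_factory=list)
    k2_folds: list[int] = field(default_factory=list)

    @classmethod
    def from_totals(cls, treatment: str, n1: int, k1: int, n2: int, k2: int):
        return cls(treatment, [n1], [k1], [n2], [k2])

    def add_fold(self, n1: int, k1: int, n2: int, k2: int) -> None:
        if k1 > n1 or k2 > n2:
            raise ConfigError("successes cannot exceed trials")
        self.n1_folds.append(n1)
        self.k1_folds.append(k1)
        self.n2_folds.append(n2)
        self.k2_folds.append(k2)

    @property
    def N1(self) -> int:
        return sum(self.n1_folds)

    @property
    def K1(self) -> int:
        return sum(self.k1_folds)

    @property
    def N2(self) -> int:
        return sum(self.n2_folds)

    @property
    def K2(self) -> int:
        return sum(self.k2_folds)

    @property
    def p_dec(self) -> float | None:
        """Good-outcome proportion among records that followed the advice."""
        return self.K1 / self.N1 if self.N1 > 0 else None

    @property
    def p_nodec(self) -> float | None:
        """Good-outcome proportion among records that deviated."""
        return self.K2 / self.N2 if self.N2 > 0 else None

    def ci_dec(self, level: float = 0.95, method: str = "wilson"):
        return proportion_ci(self.K1, self.N1, level, method) if self.N1 else None

    def ci_nodec(self, level: float = 0.95, method: str = "wilson"):
        return proportion_ci(self.K2, self.N2, level, method) if self.N2 else None


# ----------------------------------------------------------------------
# Pipeline
# ----------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed to learn and apply a decision-support system."""

    features: tuple[str, ...]
    treatments: tuple[str, ...]
    target: str
    adverse_state: str | None = None
    max_set_size: int = 2
    min_support: int = 10
    smoothing: float = 1.0
    run_confounder_check: bool = True
    max_candidate_sets: int = 20_000
    em_tol: float = 1e-6
    em_max_iter: int = 500
    utility: UtilitySpec = field(default_factory=UtilitySpec)
    ci_method: str = "wilson"
    bdeu_alpha: float = 1.0
    sig_level: float = 0.05

    def __post_init__(self):
        self.features = tuple(self.features)
        self.treatments = tuple(self.treatments)
        roles = [*self.features, *self.treatments, self.target]
        if len(set(roles)) != len(roles):
            raise ConfigError("feature/treatment/target roles must not overlap")


def select_interactions(
    data: DataTable, config: PipelineConfig
) -> dict[str, tuple[str, ...]]:
    """Top confounder-clean interaction set per treatment.

    Walks each treatment's ranking from the strongest set down, skipping
    sets that fail the confounder check; a treatment with no positive-
    strength set falls back to a singleton group containing only itself.
    """
    chosen: dict[str, tuple[str, ...]] = {}
    for t in config.treatments:
        ranked = rank_interactions(
            data, t, config.features, config.max_set_size, config.target,
            cap=config.max_candidate_sets,
            adverse_state=config.adverse_state,
            smoothing=config.smoothing,
            min_support=config.min_support,
        )
        selected: tuple[str, ...] = ()
        for cand in ranked:
            if cand.strength <= 0.0:
                break
            if config.run_confounder_check:
                report = confounder_check(
                    data, t, cand.features, config.target,
                    alpha=config.bdeu_alpha, sig_level=config.sig_level,
                    variables=[*config.features, t, config.target],
                )
                if not report.passed:
                    logger.info(
                        "pipeline: set %s for %s rejected by confounder "
                        "check (flagged: %s)",
                        cand.features, t, report.flagged_common_causes,
                    )
                    continue
            selected = cand.features
            break
        if not selected:
            logger.info(
                "pipeline: no positive-strength interaction for %s; "
                "using a singleton treatment group", t,
            )
        chosen[t] = selected
    return chosen


def fit_pipeline(
    data: DataTable, config: PipelineConfig, seed: int | None = None
) -> InfluenceDiagram:
    """Learn interactions, fit the noisy-OR model, build the decision model."""
    chosen = select_interactions(data, config)
    cause_names: list[str] = []
    groups: list[HiddenGroup] = []
    for t in config.treatments:
        parents = (t, *chosen[t])
        for p in parents:
            if p not in cause_names:
                cause_names.append(p)
        sizes = [data.variable(p).n_states for p in parents]
        groups.append(HiddenGroup(parents, np.full(int(np.prod(sizes)), 0.5)))
    causes = [data.variable(nm) for nm in cause_names]
    target = data.variable(config.target)
    structure = CamilModel(
        causes, groups, leak_q=1.0 - 1e-6, target=target,
        adverse_state=config.adverse_state,
    )
    result = em_fit(
        structure, data, tol=config.em_tol, max_iter=config.em_max_iter,
        seed=seed,
    )
    return InfluenceDiagram(result.model, config.treatments, config.utility)


def evaluate(
    config: PipelineConfig,
    data: DataTable,
    k: int = 5,
    seed: int | None = None,
) -> dict[str, EvalCounts]:
    """K-fold cross-validation; returns summed tallies per treatment.

    Deterministic given (data, k, seed, config).  Held-out records with a
    missing actual treatment value or target are excluded from that
    treatment's tally with a logged count.
    """
    folds = kfold_split(data.n_records, k, seed)
    counts = {t: EvalCounts(t) for t in config.treatments}
    adverse = config.adverse_state
    for fi, fold in enumerate(folds):
        train_rows = np.concatenate([f for j, f in enumerate(folds) if j != fi])
        train = data.subset(train_rows)
        test = data.subset(fold)
        diagram = fit_pipeline(train, config, seed=seed)
        model = diagram.model
        if adverse is None:
            adverse = model.adverse_state
        fold_tallies = {t: [0, 0, 0, 0] for t in config.treatments}
        n_skipped = 0
        for i in range(test.n_records):
            rec = test.record(i)
            if any(
                rec.get(c, data.missing_marker) == data.missing_marker
                for c in (*diagram.chance_nodes, *config.treatments,
                          config.target)
            ):
                n_skipped += 1
                continue
            recommendation = diagram.recommend(
                {c: rec[c] for c in diagram.chance_nodes}
            )
            good = rec[config.target] != adverse
            for t in config.treatments:
                tally = fold_tallies[t]
                if rec[t] == recommendation.decisions[t]:
                    tally[0] += 1
                    tally[1] += int(good)
                else:
                    tally[2] += 1
                    tally[3] += int(good)
        if n_skipped:
            logger.info(
                "evaluate: fold %d skipped %d records with missing cells",
                fi, n_skipped,
            )
        for t in config.treatments:
            counts[t].add_fold(*fold_tallies[t])
    return counts
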