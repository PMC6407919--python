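"""Treatment-feature interaction screening (TFI) and the confounder check.

A binary treatment R *interacts* with a feature set X (1-4 variables) to
affect a binary target T when R helps at some configurations of X and does
not help at others.  Per configuration x we compare P(T | x, treated) with
P(T | x, untreated) via the Hellinger distance and label the treatment
*effective* (adverse probability lower when treated), *deleterious*
(higher), or *neutral*.  The interaction strength is

    min( max distance over effective configurations,
         max distance over non-effective configurations )

and 0 when either class is empty — a treatment that helps everywhere (or
nowhere) carries no decision-relevant interaction with X.

The confounder check guards the top-ranked set S: it hill-climbs a BDeu-
scored DAG over all variables with edges R->T and S->T forced, and flags
any other variable that is structurally connected to both the treatment
and the target yet not conditionally independent of the target given S
(G-squared likelihood-ratio test).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.stats import chi2

from .bn import (
    BdeuConfig,
    CategoricalDistribution,
    DataTable,
    DiscreteVariable,
    _family_log_score,
    config_states,
    count_sufficient_stats,
)
from .errors import BudgetError, IncompleteDataError, SchemaError

__all__ = [
    "hellinger",
    "classify_effect",
    "tfi_strength",
    "rank_interactions",
    "confounder_check",
    "InteractionSet",
    "ConfigEffect",
    "ConfounderReport",
    "EFFECTIVE",
    "DELETERIOUS",
    "NEUTRAL",
]

logger = logging.getLogger(__name__)

EFFECTIVE = "effective"
DELETERIOUS = "deleterious"
NEUTRAL = "neutral"

#: probabilities equal within this tolerance are classified neutral
EFFECT_TOL = 1e-12


def hellinger(p: CategoricalDistribution, q: CategoricalDistribution) -> float:
    """Hellinger distance (1/sqrt(2))*||sqrt(p) - sqrt(q)||_2 in [0, 1].

    0 iff the distributions are identical; 1 iff their supports are
    disjoint (maximally dissimilar).
    """
    if p.variable.states != q.variable.states:
        raise SchemaError(
            f"distributions over different state sets: "
            f"{p.variable.states} vs {q.variable.states}"
        )
    diff = np.sqrt(p.probabilities) - np.sqrt(q.probabilities)
    return float(min(1.0, math.sqrt(float(np.dot(diff, diff)) / 2.0)))


def classify_effect(
    treated: CategoricalDistribution,
    untreated: CategoricalDistribution,
    adverse_state: str,
    tol: float = EFFECT_TOL,
) -> str:
    """Label a configuration by its adverse-outcome contrast."""
    pt, pu = treated[adverse_state], untreated[adverse_state]
    if abs(pt - pu) <= tol:
        return NEUTRAL
    return EFFECTIVE if pt < pu else DELETERIOUS


@dataclass
class ConfigEffect:
    """Per-configuration detail of an interaction set."""

    config: tuple[str, ...]
    treated: CategoricalDistribution
    untreated: CategoricalDistribution
    n_treated: int
    n_untreated: int
    distance: float
    label: str


@dataclass
class InteractionSet:
    """A treatment, a feature set, per-configuration effects, and a strength."""

    treatment: str
    features: tuple[str, ...]
    target: str
    per_config: list[ConfigEffect]
    excluded: list[tuple[str, ...]] = field(default_factory=list)
    strength: float = 0.0


def tfi_strength(
    data: DataTable,
    treatment: str,
    features: Sequence[str],
    target: str,
    adverse_state: str | None = None,
    *,
    treated_state: str | None = None,
    smoothing: float = 1.0,
    min_support: int = 10,
    require_deleterious: bool = False,
) -> InteractionSet:
    """Interaction strength of *treatment* with *features* on *target*.

    Conditional distributions P(target | configuration, arm) are estimated
    with additive (Laplace) smoothing ``smoothing`` (0 disables it).
    Configurations with fewer than *min_support* records in either arm are
    excluded from both maxima, with a logged warning.

    ``require_deleterious=True`` restricts the "non-effective" maximum to
    strictly deleterious configurations (the binary-feature reading);
    the default counts deleterious and neutral alike.
    """
    features = tuple(features)
    if not 1 <= len(features) <= 4:
        raise SchemaError("feature set must contain 1-4 variables")
    if treatment in features or target in features or treatment == target:
        raise SchemaError("treatment, features and target must be distinct")
    tvar = data.variable(treatment)
    yvar = data.variable(target)
    if tvar.n_states != 2 or yvar.n_states != 2:
        raise SchemaError("treatment and target must be binary")
    adverse_state = adverse_state if adverse_state is not None else yvar.states[-1]
    yvar.index(adverse_state)
    treated_state = (
        treated_state if treated_state is not None else tvar.states[-1]
    )
    t_code = tvar.index(treated_state)

    fvars = [data.variable(f) for f in features]
    sizes = [v.n_states for v in fvars]
    n_cfg = int(np.prod(sizes))

    codes = data.codes([*features, treatment, target])
    keep = (codes >= 0).all(axis=1)
    codes = codes[keep]
    j = np.ravel_multi_index(tuple(codes[:, : len(features)].T), tuple(sizes))
    flat = (j * 2 + codes[:, -2]) * 2 + codes[:, -1]
    counts = np.bincount(flat, minlength=n_cfg * 4).reshape(n_cfg, 2, 2)

    per_config: list[ConfigEffect] = []
    excluded: list[tuple[str, ...]] = []
    for cfg in range(n_cfg):
        labels = config_states(cfg, fvars)
        c_tr = counts[cfg, t_code, :]
        c_un = counts[cfg, 1 - t_code, :]
        n_tr, n_un = int(c_tr.sum()), int(c_un.sum())
        if n_tr < min_support or n_un < min_support:
            excluded.append(labels)
            logger.warning(
                "tfi: excluding configuration %s of %s (treated n=%d, "
                "untreated n=%d < min_support=%d)",
                labels, features, n_tr, n_un, min_support,
            )
            continue
        p_tr = (c_tr + smoothing) / (n_tr + 2 * smoothing)
        p_un = (c_un + smoothing) / (n_un + 2 * smoothing)
        d_tr = CategoricalDistribution(yvar, p_tr)
        d_un = CategoricalDistribution(yvar, p_un)
        per_config.append(
            ConfigEffect(
                labels, d_tr, d_un, n_tr, n_un,
                hellinger(d_tr, d_un),
                classify_effect(d_tr, d_un, adverse_state),
            )
        )

    eff = [c.distance for c in per_config if c.label == EFFECTIVE]
    if require_deleterious:
        non = [c.distance for c in per_config if c.label == DELETERIOUS]
    else:
        non = [c.distance for c in per_config if c.label != EFFECTIVE]
    strength = min(max(eff), max(non)) if eff and non else 0.0
    return InteractionSet(treatment, features, target, per_config, excluded, strength)


def rank_interactions(
    data: DataTable,
    treatment: str,
    candidates: Sequence[str],
    max_set_size: int,
    target: str,
    *,
    cap: int = 20_000,
    **kwargs,
) -> list[InteractionSet]:
    """Score every candidate subset of size 1..max_set_size, best first.

    Ties are broken toward smaller sets, then lexicographic feature names,
    so output order is deterministic.  Raises :class:`BudgetError` if the
    number of subsets exceeds *cap*.
    """
    if not 1 <= max_set_size <= 4:
        raise SchemaError("max_set_size must be in 1..4")
    candidates = sorted(set(candidates))
    if treatment in candidates or target in candidates:
        raise SchemaError("candidates must exclude treatment and target")
    total = sum(
        math.comb(len(candidates), s)
        for s in range(1, min(max_set_size, len(candidates)) + 1)
    )
    if total > cap:
        raise BudgetError(
            f"{total} candidate sets exceed the cap of {cap}"
        )
    results = [
        tfi_strength(data, treatment, combo, target, **kwargs)
        for s in range(1, min(max_set_size, len(candidates)) + 1)
        for combo in itertools.combinations(candidates, s)
    ]
    results.sort(key=lambda r: (-r.strength, len(r.features), r.features))
    return results


# ----------------------------------------------------------------------
# Confounder check: forced-edge hill climbing + conditional independence
# ----------------------------------------------------------------------

@dataclass
class ConfounderReport:
    candidate_set: tuple[str, ...]
    forced_edges: list[tuple[str, str]]
    learned_dag: nx.DiGraph
    flagged_common_causes: list[str]
    p_values: dict[str, float]
    passed: bool


def _hill_climb_bdeu(
    data: DataTable,
    variables: Sequence[str],
    forced_edges: Sequence[tuple[str, str]],
    alpha: float,
    max_rounds: int = 200,
) -> nx.DiGraph:
    """Greedy single-edge hill climbing maximizing the BDeu score.

    Starts from the forced-edge graph; forced edges are immutable.  Each
    round applies the best add/delete/reverse move; stops when no move
    improves the score.  Family scores are cached (the score decomposes).
    """
    order = list(variables)
    g = nx.DiGraph()
    g.add_nodes_from(order)
    g.add_edges_from(forced_edges)
    forced = set(forced_edges)
    cache: dict[tuple[str, frozenset], float] = {}

    def fam(node: str, parents: frozenset) -> float:
        key = (node, parents)
        if key not in cache:
            ps = [p for p in order if p in parents]
            cache[key] = _family_log_score(
                count_sufficient_stats(data, node, ps), alpha
            )
        return cache[key]

    def parents_of(node: str) -> frozenset:
        return frozenset(g.predecessors(node))

    for _ in range(max_rounds):
        best_delta, best_move = 1e-9, None
        for u, v in itertools.permutations(order, 2):
            pv = parents_of(v)
            if g.has_edge(u, v):
                if (u, v) in forced:
                    continue
                base = fam(v, pv)
                # deletion
                delta = fam(v, pv - {u}) - base
                if delta > best_delta:
                    best_delta, best_move = delta, ("del", u, v)
                # reversal: delete u->v, add v->u (only if still acyclic)
                g.remove_edge(u, v)
                if not nx.has_path(g, u, v):  # reversal keeps acyclicity
                    pu = parents_of(u)
                    delta = (
                        fam(v, pv - {u}) - base
                        + fam(u, pu | {v}) - fam(u, pu)
                    )
                    if delta > best_delta:
                        best_delta, best_move = delta, ("rev", u, v)
                g.add_edge(u, v)
            else:
                if nx.has_path(g, v, u):  # would create a cycle
                    continue
                delta = fam(v, pv | {u}) - fam(v, pv)
                if delta > best_delta:
                    best_delta, best_move = delta, ("add", u, v)
        if best_move is None:
            break
        op, u, v = best_move
        if op == "add":
            g.add_edge(u, v)
        elif op == "del":
            g.remove_edge(u, v)
        else:
            g.remove_edge(u, v)
            g.add_edge(v, u)
    return g


def g_squared_test(
    data: DataTable, x: str, y: str, given: Sequence[str]
) -> float:
    """P-value of the G-squared likelihood-ratio test of X _|_ Y | given."""
    cols = [*given, x, y]
    codes = data.codes(cols)
    if (codes < 0).any():
        raise IncompleteDataError("missing cells in CI test columns")
    xv, yv = data.variable(x), data.variable(y)
    gsizes = [data.variable(c).n_states for c in given]
    if given:
        strata = np.ravel_multi_index(tuple(codes[:, : len(given)].T), tuple(gsizes))
    else:
        strata = np.zeros(len(codes), dtype=np.int64)
    g2, df = 0.0, 0
    for s in np.unique(strata):
        sel = strata == s
        obs = np.zeros((xv.n_states, yv.n_states))
        np.add.at(obs, (codes[sel, -2], codes[sel, -1]), 1)
        obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
        if obs.shape[0] < 2 or obs.shape[1] < 2:
            continue
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        nz = obs > 0
        g2 += 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / exp[nz])))
        df += (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(chi2.sf(g2, df)) if df > 0 else 1.0


def _linked(g: nx.DiGraph, z: str, v: str) -> bool:
    """True if z is an ancestor of v or adjacent to v in the learned DAG.

    Greedy single-edge search cannot orient score-equivalent edges, so
    adjacency in either direction is treated as potential causation; the
    conditional-independence test is the decisive filter.
    """
    return (
        g.has_edge(z, v)
        or g.has_edge(v, z)
        or nx.has_path(g, z, v)
    )


def confounder_check(
    data: DataTable,
    treatment: str,
    s: Sequence[str],
    target: str,
    *,
    alpha: float = 1.0,
    sig_level: float = 0.05,
    variables: Sequence[str] | None = None,
) -> ConfounderReport:
    """Screen the candidate interaction set S for hidden common causes.

    Learns a DAG by BDeu hill climbing with edges treatment->target and
    S->target forced, then flags every other variable connected to both
    the treatment and the target whose G-squared test of independence from
    the target given S rejects at *sig_level*.  ``passed`` is True iff no
    variable is flagged.
    """
    s = tuple(s)
    if variables is None:
        variables = [v.name for v in data.variables]
    forced = [(treatment, target)] + [(f, target) for f in s]
    dag = _hill_climb_bdeu(data, variables, forced, alpha)
    flagged, pvals = [], {}
    for z in variables:
        if z in (treatment, target) or z in s:
            continue
        if _linked(dag, z, treatment) and _linked(dag, z, target):
            p = g_squared_test(data, z, target, s)
            pvals[z] = p
            if p < sig_level:
                flagged.append(z)
    return ConfounderReport(
        candidate_set=s,
        forced_edges=forced,
        learned_dag=dag,
        flagged_common_causes=flagged,
        p_values=pvals,
        passed=not flagged,
    )
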