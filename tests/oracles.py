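"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by exhaustive enumeration, staying
deliberately independent of the implementation paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from dpac import CamilModel, DataTable, DiscreteBayesNet, DiscreteVariable
from dpac.camil import OrdinalCamil


def enumerate_query(
    net: DiscreteBayesNet, target: str, evidence: dict[str, str]
) -> np.ndarray:
    """P(target | evidence) by summing the full joint over every outcome."""
    names = [v.name for v in net.variables]
    tvar = net.variable(target)
    acc = np.zeros(tvar.n_states)
    for combo in itertools.product(
        *(range(v.n_states) for v in net.variables)
    ):
        assign = dict(zip(names, combo))
        if any(
            net.variable(n).index(s) != assign[n] for n, s in evidence.items()
        ):
            continue
        p = 1.0
        for v in net.variables:
            parents = net.parents(v.name)
            if parents:
                sizes = tuple(pv.n_states for pv in parents)
                j = int(np.ravel_multi_index(
                    tuple(assign[pv.name] for pv in parents), sizes
                ))
            else:
                j = 0
            p *= net.cpts[v.name][j, assign[v.name]]
        acc[assign[target]] += p
    return acc / acc.sum()


def random_binary_net(
    rng: np.random.Generator, n_vars: int, p_edge: float = 0.4
) -> DiscreteBayesNet:
    """Random DAG over binary variables with Dirichlet CPT rows."""
    names = [f"v{i}" for i in range(n_vars)]
    variables = [DiscreteVariable(n, ("no", "yes")) for n in names]
    edges = [
        (names[i], names[j])
        for i in range(n_vars)
        for j in range(i + 1, n_vars)
        if rng.random() < p_edge
    ]
    parents = {n: [u for u, v in edges if v == n] for n in names}
    cpts = {}
    for n in names:
        q = 2 ** len(parents[n])
        cpts[n] = rng.dirichlet(np.ones(2), size=q)
    return DiscreteBayesNet(variables, edges, cpts)


def enumerate_camil_adverse(model: CamilModel, record: dict[str, str]) -> float:
    """P(adverse) by summing over every hidden-layer assignment of the
    explicit two-layer network (groups + leak, target = OR)."""
    activation = [
        1.0 - float(g.q[model.group_config(g, record)]) for g in model.groups
    ] + [1.0 - model.leak_q]
    total = 0.0
    for h in itertools.product((0, 1), repeat=len(activation)):
        p = 1.0
        for hi, a in zip(h, activation):
            p *= a if hi else 1.0 - a
        if any(h):
            total += p
    return total


def enumerate_ordinal(model: OrdinalCamil, record: dict[str, str]) -> np.ndarray:
    """Target distribution by enumerating all hidden level assignments."""
    m = model.target.n_states
    dists = [
        g.level_probs[model.group_config(g, record)] for g in model.groups
    ] + [np.asarray(model.leak_probs)]
    probs = np.zeros(m)
    for levels in itertools.product(range(m), repeat=len(dists)):
        p = 1.0
        for li, d in zip(levels, dists):
            p *= d[li]
        probs[max(levels)] += p
    return probs


def table_from_counts(
    variables: list[DiscreteVariable],
    counts: dict[tuple[str, ...], int],
) -> DataTable:
    """Materialize a table with exact per-row counts (deterministic order)."""
    rows = []
    for combo, n in counts.items():
        rows.extend([dict(zip((v.name for v in variables), combo))] * n)
    df = pd.DataFrame(rows, columns=[v.name for v in variables])
    return DataTable(variables, df)
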