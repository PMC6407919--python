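"""Discrete Bayesian networks: representation, exact inference, BDeu scoring.

Conventions used throughout the package
---------------------------------------
* A variable's *states* are an ordered tuple of labels; the first state is
  the baseline (e.g. ``("no", "yes")`` for a treatment).
* A node with parents ``(P1, ..., Pm)`` (in network declaration order) has
  one conditional distribution per joint parent configuration.  The
  configuration index is **row-major over the parents in declaration order,
  first parent slowest** — i.e. ``numpy.ravel_multi_index`` with C order.
  This ordering is shared by every module that exchanges flattened
  per-configuration parameter vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.special import gammaln

from .errors import (
    ImpossibleEvidenceError,
    IncompleteDataError,
    SchemaError,
)

__all__ = [
    "DiscreteVariable",
    "CategoricalDistribution",
    "DataTable",
    "DiscreteBayesNet",
    "BdeuConfig",
    "count_sufficient_stats",
    "bdeu_log_score",
    "config_index",
    "config_states",
]

DEFAULT_MISSING = "NULL"


@dataclass(frozen=True)
class DiscreteVariable:
    """A categorical variable with an ordered, finite state set."""

    name: str
    states: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        if len(self.states) < 2:
            raise SchemaError(f"variable {self.name!r} needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise SchemaError(f"variable {self.name!r} has duplicate states")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise SchemaError(
                f"{state!r} is not a state of variable {self.name!r} "
                f"(states: {self.states})"
            ) from None


@dataclass
class CategoricalDistribution:
    """A probability distribution over the states of one variable."""

    variable: DiscreteVariable
    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (self.variable.n_states,):
            raise SchemaError(
                f"distribution over {self.variable.name!r} needs "
                f"{self.variable.n_states} probabilities, got {p.shape}"
            )
        if (p < -1e-12).any():
            raise SchemaError("negative probability")
        if abs(p.sum() - 1.0) > 1e-9:
            raise SchemaError(f"probabilities sum to {p.sum()}, not 1")
        self.probabilities = np.clip(p, 0.0, None)

    def __getitem__(self, state: str) -> float:
        return float(self.probabilities[self.variable.index(state)])

    def __len__(self) -> int:
        return self.variable.n_states


def config_index(parent_codes: Sequence[int], parent_sizes: Sequence[int]) -> int:
    """Joint-configuration index: row-major, first parent slowest."""
    if not parent_sizes:
        return 0
    return int(np.ravel_multi_index(tuple(parent_codes), tuple(parent_sizes)))


def config_states(j: int, parents: Sequence[DiscreteVariable]) -> tuple[str, ...]:
    """Inverse of :func:`config_index`: state labels of configuration *j*."""
    if not parents:
        return ()
    codes = np.unravel_index(j, tuple(v.n_states for v in parents))
    return tuple(v.states[c] for v, c in zip(parents, codes))


class DataTable:
    """A rectangular table of categorical records with a missing marker.

    Backed by a pandas DataFrame of strings; missing cells hold the marker.
    """

    def __init__(
        self,
        variables: Sequence[DiscreteVariable],
        df: pd.DataFrame,
        missing_marker: str = DEFAULT_MISSING,
    ):
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names")
        if list(df.columns) != names:
            missing_cols = set(names) - set(df.columns)
            extra = set(df.columns) - set(names)
            if missing_cols or extra:
                raise SchemaError(
                    f"columns do not match schema (missing {sorted(missing_cols)}, "
                    f"unexpected {sorted(extra)})"
                )
            df = df[names]
        self.variables = list(variables)
        self.missing_marker = missing_marker
        self._by_name = {v.name: v for v in variables}
        self.df = df.reset_index(drop=True).astype(str)
        self._validate()

    def _validate(self) -> None:
        bad: list[tuple[int, str, str]] = []
        for v in self.variables:
            col = self.df[v.name]
            valid = col.isin(v.states) | (col == self.missing_marker)
            if not valid.all():
                for i in np.flatnonzero(~valid.to_numpy())[:10]:
                    bad.append((int(i), v.name, col.iloc[i]))
        if bad:
            detail = "; ".join(f"row {i} col {c}: {s!r}" for i, c, s in bad)
            raise SchemaError(f"cells with unknown state labels: {detail}")

    # ------------------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        variables: Sequence[DiscreteVariable],
        records: Iterable[Mapping[str, str]],
        missing_marker: str = DEFAULT_MISSING,
    ) -> "DataTable":
        df = pd.DataFrame(list(records), columns=[v.name for v in variables])
        return cls(variables, df.fillna(missing_marker), missing_marker)

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        schema: Sequence[DiscreteVariable] | None = None,
        missing_marker: str = DEFAULT_MISSING,
    ) -> "DataTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if schema is None:
            schema = [
                DiscreteVariable(
                    c,
                    tuple(sorted(set(df[c]) - {missing_marker})),
                )
                for c in df.columns
            ]
        return cls(schema, df, missing_marker)

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    # ------------------------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.df)

    def variable(self, name: str) -> DiscreteVariable:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None

    def codes(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Integer state codes, shape (n_records, len(names)); missing -> -1."""
        if names is None:
            names = [v.name for v in self.variables]
        cols = []
        for name in names:
            v = self.variable(name)
            cat = pd.Categorical(self.df[name], categories=list(v.states))
            cols.append(np.asarray(cat.codes, dtype=np.int64))
        return np.column_stack(cols) if cols else np.empty((self.n_records, 0), int)

    def has_missing(self, names: Sequence[str] | None = None) -> bool:
        if names is None:
            names = [v.name for v in self.variables]
        return bool((self.df[list(names)] == self.missing_marker).to_numpy().any())

    def subset(self, rows: Sequence[int]) -> "DataTable":
        return DataTable(
            self.variables, self.df.iloc[list(rows)], self.missing_marker
        )

    def record(self, i: int) -> dict[str, str]:
        return dict(self.df.iloc[i])


# ----------------------------------------------------------------------
# Sufficient statistics and the Bayesian (BDeu) structure score
# ----------------------------------------------------------------------

def count_sufficient_stats(
    data: DataTable, node: str, parents: Sequence[str]
) -> np.ndarray:
    """Counts ``s[j, k]``: node in state *k* while parents in configuration *j*.

    Configuration indexing follows the package convention (row-major over
    *parents* as given, first parent slowest).  Requires complete data for
    the involved columns.
    """
    v = data.variable(node)
    pvars = [data.variable(p) for p in parents]
    codes = data.codes([*parents, node])
    if (codes < 0).any():
        raise IncompleteDataError(
            f"missing cells in columns {[*parents, node]}"
        )
    sizes = [pv.n_states for pv in pvars]
    q = int(np.prod(sizes)) if sizes else 1
    if sizes:
        j = np.ravel_multi_index(tuple(codes[:, :-1].T), tuple(sizes))
    else:
        j = np.zeros(len(codes), dtype=np.int64)
    flat = j * v.n_states + codes[:, -1]
    return np.bincount(flat, minlength=q * v.n_states).reshape(q, v.n_states)


@dataclass(frozen=True)
class BdeuConfig:
    """Equivalent-sample-size prior: hyperparameters a_ijk = alpha/(r_i*q_i)."""

    alpha: float = 1.0

    def __post_init__(self):
        if not self.alpha > 0:
            raise SchemaError("alpha must be positive")


def _family_log_score(s: np.ndarray, alpha: float) -> float:
    q, r = s.shape
    a_ijk = alpha / (r * q)
    a_ij = alpha / q
    n_j = s.sum(axis=1)
    total = float(np.sum(gammaln(a_ij) - gammaln(a_ij + n_j)))
    total += float(np.sum(gammaln(a_ijk + s) - gammaln(a_ijk)))
    return total


def bdeu_log_score(
    dag: nx.DiGraph | Iterable[tuple[str, str]],
    data: DataTable,
    config: BdeuConfig = BdeuConfig(),
) -> float:
    """Log marginal likelihood log P(Data | G) under the BDeu prior.

    Computed in log-gamma arithmetic (the raw gamma-ratio product underflows
    at modest record counts).  The score decomposes over node families and is
    identical for Markov-equivalent DAGs.
    """
    g = dag if isinstance(dag, nx.DiGraph) else nx.DiGraph(list(dag))
    if not nx.is_directed_acyclic_graph(g):
        raise SchemaError("graph has a cycle")
    order = [v.name for v in data.variables]
    declared = set(order)
    for n in g.nodes:
        if n not in declared:
            raise SchemaError(f"graph node {n!r} not in data")
    total = 0.0
    for node in order:
        parents = [p for p in order if g.has_edge(p, node)] if node in g else []
        s = count_sufficient_stats(data, node, parents)
        total += _family_log_score(s, config.alpha)
    return total


# ----------------------------------------------------------------------
# The network and exact inference (variable elimination)
# ----------------------------------------------------------------------

@dataclass
class _Factor:
    vars: tuple[str, ...]
    table: np.ndarray  # one axis per variable, in `vars` order


class DiscreteBayesNet:
    """DAG over discrete variables plus per-node conditional tables.

    ``cpts[name]`` has shape ``(q_i, r_i)``: one row per joint parent
    configuration (package index convention), one column per state.
    Parents are ordered by the network's variable declaration order.
    """

    def __init__(
        self,
        variables: Sequence[DiscreteVariable],
        edges: Iterable[tuple[str, str]],
        cpts: Mapping[str, np.ndarray],
    ):
        self.variables = list(variables)
        self._by_name = {v.name: v for v in self.variables}
        if len(self._by_name) != len(self.variables):
            raise SchemaError("duplicate variable names")
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self._by_name)
        for u, v in edges:
            if u not in self._by_name or v not in self._by_name:
                raise SchemaError(f"edge ({u!r}, {v!r}) uses unknown variable")
            self.graph.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise SchemaError("graph has a cycle")
        self.cpts: dict[str, np.ndarray] = {}
        for v in self.variables:
            sizes = [p.n_states for p in self.parents(v.name)]
            q = int(np.prod(sizes)) if sizes else 1
            t = np.asarray(cpts[v.name], dtype=float)
            if t.shape != (q, v.n_states):
                raise SchemaError(
                    f"cpt for {v.name!r} must have shape ({q}, {v.n_states}), "
                    f"got {t.shape}"
                )
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise SchemaError(f"cpt rows for {v.name!r} do not sum to 1")
            self.cpts[v.name] = t

    def parents(self, name: str) -> list[DiscreteVariable]:
        """Parents in declaration order (the configuration-index order)."""
        return [v for v in self.variables if self.graph.has_edge(v.name, name)]

    def variable(self, name: str) -> DiscreteVariable:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None

    # -- inference ------------------------------------------------------
    def _node_factor(self, name: str) -> _Factor:
        v = self.variable(name)
        ps = self.parents(name)
        shape = tuple(p.n_states for p in ps) + (v.n_states,)
        return _Factor(
            tuple(p.name for p in ps) + (name,),
            self.cpts[name].reshape(shape),
        )

    def query(
        self, target: str, evidence: Mapping[str, str] | None = None
    ) -> CategoricalDistribution:
        """Exact conditional distribution of *target* given *evidence*.

        Variable elimination with a min-degree ordering.  Raises
        :class:`ImpossibleEvidenceError` if the evidence has probability 0.
        """
        evidence = dict(evidence or {})
        tv = self.variable(target)
        if target in evidence:
            raise SchemaError("target cannot appear in evidence")
        ev_codes = {
            n: self.variable(n).index(s) for n, s in evidence.items()
        }
        factors = []
        for v in self.variables:
            f = self._node_factor(v.name)
            for n, c in ev_codes.items():
                if n in f.vars:
                    ax = f.vars.index(n)
                    f = _Factor(
                        f.vars[:ax] + f.vars[ax + 1:],
                        np.take(f.table, c, axis=ax),
                    )
            factors.append(f)

        sizes = {v.name: v.n_states for v in self.variables}
        to_eliminate = {
            v.name for v in self.variables
        } - {target} - set(ev_codes)
        while to_eliminate:
            # min-degree: fewest distinct co-occurring variables
            neigh: dict[str, set[str]] = {x: set() for x in to_eliminate}
            for f in factors:
                fv = set(f.vars)
                for x in fv & to_eliminate:
                    neigh[x] |= fv - {x}
            x = min(to_eliminate, key=lambda n: (len(neigh[n]), n))
            involved = [f for f in factors if x in f.vars]
            rest = [f for f in factors if x not in f.vars]
            prod = involved[0]
            for f in involved[1:]:
                prod = _multiply(prod, f, sizes)
            ax = prod.vars.index(x)
            summed = _Factor(
                prod.vars[:ax] + prod.vars[ax + 1:], prod.table.sum(axis=ax)
            )
            factors = rest + [summed]
            to_eliminate.remove(x)

        result = factors[0]
        for f in factors[1:]:
            result = _multiply(result, f, sizes)
        if result.vars == ():
            raise SchemaError("degenerate query")
        ax_order = [result.vars.index(target)]
        table = np.transpose(result.table, ax_order) if result.table.ndim > 1 \
            else result.table
        total = float(table.sum())
        if total <= 0.0:
            raise ImpossibleEvidenceError(
                f"evidence {evidence} has probability 0 under the model"
            )
        return CategoricalDistribution(tv, table / total)

    # -- serialization --------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        """Plain-text serialization: nodes, edges, flattened CPT rows."""
        doc = {
            "variables": [
                {"name": v.name, "states": list(v.states)}
                for v in self.variables
            ],
            "edges": [[u, v] for u, v in self.graph.edges],
            "cpts": {
                name: [[float(x) for x in row] for row in table]
                for name, table in self.cpts.items()
            },
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "DiscreteBayesNet":
        text = Path(source).read_text() if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ) else str(source)
        doc = yaml.safe_load(text)
        variables = [
            DiscreteVariable(d["name"], tuple(d["states"]))
            for d in doc["variables"]
        ]
        cpts = {n: np.asarray(t, dtype=float) for n, t in doc["cpts"].items()}
        return cls(variables, [tuple(e) for e in doc["edges"]], cpts)


def _multiply(f1: _Factor, f2: _Factor, sizes: Mapping[str, int]) -> _Factor:
    allvars = f1.vars + tuple(v for v in f2.vars if v not in f1.vars)

    def align(f: _Factor) -> np.ndarray:
        order = [f.vars.index(v) for v in allvars if v in f.vars]
        t = np.transpose(f.table, order)
        shape = tuple(sizes[v] if v in f.vars else 1 for v in allvars)
        return t.reshape(shape)

    return _Factor(allvars, align(f1) * align(f2))
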