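"""Leaky noisy-OR outcome models with interacting, possibly non-binary causes.

The model (CAMIL: causal modelling with internal layers) places one hidden
binary variable H_g between each *group* of causes and the binary target.
A group is either a treatment-feature interaction set or a single
non-interacting cause.  Given the group's joint parent configuration j,
H_g stays off with *inhibition probability* q_g[j] = P(H_g = 0 | config j);
an always-present Leak cause covers everything unmodelled,
P(Leak off) = leak_q.  The target is the OR of the hidden layer, so

    P(target non-adverse | causes) = leak_q * prod_g q_g[j_g(causes)].

Parameters are learned by expectation-maximization over the hidden layer:
a non-adverse record certifies every hidden variable off; an adverse
record spreads responsibility across the hidden variables in proportion
to their activation probabilities.

Identifiability: multiplying every q of one group by c while dividing the
leak by c leaves the likelihood unchanged, so by default each group's
baseline configuration (all parents at their first state) is anchored at
q = 1 — the classic noisy-OR convention in which a cause at baseline
cannot trigger the effect.  Pass ``anchor_baseline=False`` to fit every
configuration freely (estimates are then unique only up to that rescaling).

The ordinal extension gives hidden variables levels 1..m matching an
ordered target; the target takes the maximum hidden level, so cumulative
probabilities multiply:  P(target <= k) = prod_g P(H_g <= k) * P(Leak <= k).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .bn import DataTable, DiscreteVariable, CategoricalDistribution, config_states
from .errors import ConfigError, NumericError, SchemaError

__all__ = [
    "HiddenGroup",
    "CamilModel",
    "OrdinalGroup",
    "OrdinalCamil",
    "estimate_q_direct",
    "em_fit",
    "EmResult",
]

Q_CLIP = 1e-6  # EM estimates kept inside [Q_CLIP, 1 - Q_CLIP]


@dataclass
class HiddenGroup:
    """One hidden variable: its parent causes and per-configuration inhibition."""

    parents: tuple[str, ...]
    q: np.ndarray  # P(H = 0 | parent configuration j), package index order

    def __post_init__(self):
        self.parents = tuple(self.parents)
        self.q = np.asarray(self.q, dtype=float)
        if ((self.q < 0) | (self.q > 1)).any():
            raise ConfigError("inhibition probabilities must lie in [0, 1]")


class CamilModel:
    """Binary-target leaky noisy-OR model over grouped causes."""

    def __init__(
        self,
        causes: Sequence[DiscreteVariable],
        groups: Sequence[HiddenGroup],
        leak_q: float,
        target: DiscreteVariable,
        adverse_state: str | None = None,
    ):
        self.causes = list(causes)
        self._by_name = {v.name: v for v in self.causes}
        if len(self._by_name) != len(self.causes):
            raise SchemaError("duplicate cause names")
        if target.name in self._by_name:
            raise SchemaError("target cannot also be a cause")
        if target.n_states != 2:
            raise SchemaError("CamilModel target must be binary")
        if not 0.0 <= leak_q <= 1.0:
            raise ConfigError("leak_q must lie in [0, 1]")
        self.groups = list(groups)
        covered = set()
        for g in self.groups:
            for p in g.parents:
                if p not in self._by_name:
                    raise SchemaError(f"group parent {p!r} is not a cause")
                covered.add(p)
            if g.q.shape != (self.group_n_configs(g),):
                raise ConfigError(
                    f"group {g.parents} needs {self.group_n_configs(g)} "
                    f"q entries, got {g.q.shape}"
                )
        uncovered = set(self._by_name) - covered
        if uncovered:
            raise SchemaError(f"causes in no group: {sorted(uncovered)}")
        self.leak_q = float(leak_q)
        self.target = target
        self.adverse_state = (
            adverse_state if adverse_state is not None else target.states[-1]
        )
        target.index(self.adverse_state)

    # ------------------------------------------------------------------
    def cause(self, name: str) -> DiscreteVariable:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown cause {name!r}") from None

    def group_sizes(self, g: HiddenGroup) -> tuple[int, ...]:
        return tuple(self.cause(p).n_states for p in g.parents)

    def group_n_configs(self, g: HiddenGroup) -> int:
        return int(np.prod(self.group_sizes(g)))

    def group_config(self, g: HiddenGroup, record: Mapping[str, str]) -> int:
        codes = []
        for p in g.parents:
            if p not in record:
                raise SchemaError(f"record is missing cause {p!r}")
            codes.append(self.cause(p).index(record[p]))
        return int(np.ravel_multi_index(tuple(codes), self.group_sizes(g)))

    def group_config_codes(self, g: HiddenGroup, codes: np.ndarray,
                           columns: Sequence[str]) -> np.ndarray:
        """Vectorized configuration index for a code matrix (complete rows)."""
        idx = [list(columns).index(p) for p in g.parents]
        return np.ravel_multi_index(
            tuple(codes[:, i] for i in idx), self.group_sizes(g)
        )

    # ------------------------------------------------------------------
    def predict_adverse(self, record: Mapping[str, str]) -> float:
        """P(target = adverse | full cause assignment), in closed form."""
        prod = self.leak_q
        for g in self.groups:
            prod *= float(g.q[self.group_config(g, record)])
        return 1.0 - prod

    def predict(self, record: Mapping[str, str]) -> CategoricalDistribution:
        p_adv = self.predict_adverse(record)
        probs = np.empty(2)
        ai = self.target.index(self.adverse_state)
        probs[ai] = p_adv
        probs[1 - ai] = 1.0 - p_adv
        return CategoricalDistribution(self.target, probs)

    # ------------------------------------------------------------------
    def copy(self) -> "CamilModel":
        return CamilModel(
            self.causes,
            [HiddenGroup(g.parents, g.q.copy()) for g in self.groups],
            self.leak_q,
            self.target,
            self.adverse_state,
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {
            "kind": "camil",
            "causes": [
                {"name": v.name, "states": list(v.states)} for v in self.causes
            ],
            "groups": [
                {"parents": list(g.parents), "q": [float(x) for x in g.q]}
                for g in self.groups
            ],
            "leak_q": float(self.leak_q),
            "target": {"name": self.target.name, "states": list(self.target.states)},
            "adverse_state": self.adverse_state,
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "CamilModel":
        text = (
            Path(source).read_text()
            if isinstance(source, Path)
            or ("\n" not in str(source) and Path(str(source)).exists())
            else str(source)
        )
        doc = yaml.safe_load(text)
        if doc.get("kind") != "camil":
            raise ConfigError("not a camil model file")
        return cls(
            [DiscreteVariable(d["name"], tuple(d["states"])) for d in doc["causes"]],
            [HiddenGroup(tuple(d["parents"]), np.asarray(d["q"], float))
             for d in doc["groups"]],
            float(doc["leak_q"]),
            DiscreteVariable(doc["target"]["name"], tuple(doc["target"]["states"])),
            doc["adverse_state"],
        )


# ----------------------------------------------------------------------
# Direct (closed-form) estimation and EM
# ----------------------------------------------------------------------

def estimate_q_direct(
    data: DataTable, model: CamilModel, group_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-configuration inhibition estimates for one group.

    For each non-baseline configuration j of the group, q_j is the fraction
    of non-adverse outcomes among records in which this group sits at j
    while **every other** group sits at its baseline configuration (all
    parents at their first state).  The baseline configuration keeps q = 1.

    Returns ``(q, defined)``: configurations with no qualifying records are
    left at the model's current value with ``defined=False`` — the
    data-starved case that motivates EM.
    """
    group = model.groups[group_index]
    names = [v.name for v in model.causes] + [model.target.name]
    codes = data.codes(names)
    if (codes < 0).any():
        raise SchemaError("estimate_q_direct requires complete data")
    adverse = codes[:, -1] == model.target.index(model.adverse_state)

    cfgs = [model.group_config_codes(g, codes, names) for g in model.groups]
    others_baseline = np.ones(len(codes), dtype=bool)
    for gi, g in enumerate(model.groups):
        if gi != group_index:
            others_baseline &= cfgs[gi] == 0

    q = group.q.copy()
    defined = np.zeros(model.group_n_configs(group), dtype=bool)
    q[0] = 1.0
    defined[0] = True
    for j in range(1, model.group_n_configs(group)):
        sel = others_baseline & (cfgs[group_index] == j)
        n = int(sel.sum())
        if n == 0:
            continue
        a0 = int((sel & ~adverse).sum())
        q[j] = a0 / n
        defined[j] = True
    return q, defined


@dataclass
class EmResult:
    model: CamilModel
    loglik_trace: list[float]
    n_iter: int
    converged: bool


def em_fit(
    structure: CamilModel,
    data: DataTable,
    *,
    init: Mapping[int, np.ndarray] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    anchor_baseline: bool = True,
    random_init: bool = False,
) -> EmResult:
    """Fit inhibition parameters and the leak by expectation-maximization.

    E-step: a non-adverse record fixes every hidden variable off; for an
    adverse record the posterior of H_g being off is
    (q_g - P(all off)) / P(adverse).  M-step: each q_g[j] becomes the mean
    posterior off-probability over records at configuration j, and the leak
    the mean over all records.  The log-likelihood trace is non-decreasing.

    ``init`` maps group index -> starting q vector (default all 0.5);
    ``random_init`` draws starting values uniformly using ``seed`` instead.
    Records with any missing cause or target value are excluded (impute
    upstream).  Estimates are clipped to [1e-6, 1 - 1e-6]; with
    ``anchor_baseline`` each group's configuration 0 is pinned at q = 1.
    """
    model = structure.copy()
    names = [v.name for v in model.causes] + [model.target.name]
    codes = data.codes(names)
    complete = (codes >= 0).all(axis=1)
    codes = codes[complete]
    n = len(codes)
    if n == 0:
        raise SchemaError("no complete records to fit on")
    d = (codes[:, -1] == model.target.index(model.adverse_state)).astype(float)

    rng = np.random.default_rng(seed)
    cfg = [model.group_config_codes(g, codes, names) for g in model.groups]
    n_cfg = [model.group_n_configs(g) for g in model.groups]
    for gi, g in enumerate(model.groups):
        if init is not None and gi in init:
            g.q = np.asarray(init[gi], float).copy()
        elif random_init:
            g.q = rng.uniform(0.2, 0.95, size=n_cfg[gi])
        else:
            g.q = np.full(n_cfg[gi], 0.5)
        if anchor_baseline:
            g.q[0] = 1.0
    model.leak_q = float(np.clip(1.0 - d.mean(), Q_CLIP, 1 - Q_CLIP))

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        qr = np.empty((n, len(model.groups)))
        for gi, g in enumerate(model.groups):
            qr[:, gi] = g.q[cfg[gi]]
        prod0 = model.leak_q * qr.prod(axis=1)  # P(target non-adverse | causes)
        p_adv = 1.0 - prod0
        with np.errstate(divide="ignore"):
            ll = float(np.sum(np.where(d == 1.0, np.log(p_adv), np.log(prod0))))
        if not np.isfinite(ll):
            raise NumericError("non-finite log-likelihood", iteration=it)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
            converged = True
            break

        # E-step: posterior P(H_g = 0 | record); 1 for non-adverse records
        safe_padv = np.where(d == 1.0, p_adv, 1.0)
        for gi, g in enumerate(model.groups):
            post0 = np.where(d == 1.0, (qr[:, gi] - prod0) / safe_padv, 1.0)
            # M-step for this group
            num = np.bincount(cfg[gi], weights=post0, minlength=n_cfg[gi])
            den = np.bincount(cfg[gi], minlength=n_cfg[gi]).astype(float)
            newq = g.q.copy()
            seen = den > 0
            newq[seen] = np.clip(num[seen] / den[seen], Q_CLIP, 1 - Q_CLIP)
            if anchor_baseline:
                newq[0] = 1.0
            g.q = newq
        post0_leak = np.where(d == 1.0, (model.leak_q - prod0) / safe_padv, 1.0)
        model.leak_q = float(np.clip(post0_leak.mean(), Q_CLIP, 1 - Q_CLIP))

    return EmResult(model=model, loglik_trace=trace, n_iter=it, converged=converged)


# ----------------------------------------------------------------------
# Ordinal-target extension
# ----------------------------------------------------------------------

@dataclass
class OrdinalGroup:
    """Hidden variable with ordered levels 1..m: P(H = level | configuration)."""

    parents: tuple[str, ...]
    level_probs: np.ndarray  # shape (n_configs, m), rows sum to 1

    def __post_init__(self):
        self.parents = tuple(self.parents)
        self.level_probs = np.asarray(self.level_probs, dtype=float)
        if self.level_probs.ndim != 2:
            raise ConfigError("level_probs must be 2-D (configs x levels)")
        if not np.allclose(self.level_probs.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("level_probs rows must sum to 1")


class OrdinalCamil:
    """CAMIL with an ordered m-level target: target = max hidden level."""

    def __init__(
        self,
        causes: Sequence[DiscreteVariable],
        groups: Sequence[OrdinalGroup],
        leak_probs: Sequence[float],
        target: DiscreteVariable,
    ):
        self.causes = list(causes)
        self._by_name = {v.name: v for v in self.causes}
        self.target = target
        m = target.n_states
        if m < 2:
            raise SchemaError("ordinal target needs >= 2 levels")
        self.leak_probs = np.asarray(leak_probs, dtype=float)
        if self.leak_probs.shape != (m,) or abs(self.leak_probs.sum() - 1) > 1e-9:
            raise ConfigError("leak_probs must be a distribution over levels")
        self.groups = list(groups)
        covered = set()
        for g in self.groups:
            sizes = tuple(self._by_name[p].n_states for p in g.parents)
            if g.level_probs.shape != (int(np.prod(sizes)), m):
                raise ConfigError(
                    f"group {g.parents} level_probs must have shape "
                    f"({int(np.prod(sizes))}, {m})"
                )
            covered.update(g.parents)
        if set(self._by_name) - covered:
            raise SchemaError("causes in no group")

    def cause(self, name: str) -> DiscreteVariable:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown cause {name!r}") from None

    def group_config(self, g: OrdinalGroup, record: Mapping[str, str]) -> int:
        sizes = tuple(self.cause(p).n_states for p in g.parents)
        codes = []
        for p in g.parents:
            if p not in record:
                raise SchemaError(f"record is missing cause {p!r}")
            codes.append(self.cause(p).index(record[p]))
        return int(np.ravel_multi_index(tuple(codes), sizes))

    def predict(self, record: Mapping[str, str]) -> CategoricalDistribution:
        """Distribution of the target: cumulative products over levels.

        P(target <= k) = prod_g P(H_g <= k | config) * P(Leak <= k);
        state probabilities are successive differences.
        """
        cum = np.cumsum(self.leak_probs)
        for g in self.groups:
            cum = cum * np.cumsum(g.level_probs[self.group_config(g, record)])
        probs = np.diff(np.concatenate(([0.0], cum)))
        probs[-1] += 1.0 - cum[-1]  # guard rounding; cum[-1] == 1 analytically
        return CategoricalDistribution(self.target, probs)
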