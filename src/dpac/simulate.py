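"""Synthetic patient-table generator with a known ground-truth process.

Emulates a breast-cancer registry table: categorical clinical features,
binary treatment indicators assigned by a configurable "physician policy"
(optionally depending on features, which is how confounding is planted),
and a binary (or ordinal) outcome drawn from a known leaky noisy-OR
(CAMIL) truth model.  Everything is synthetic: marginals default to
uniform and the truth models are hand-constructed, so recovery tests have
an exact reference.

Presets
-------
``preset_lsds_like``   23-variable schema mirroring a published registry
                       codebook, with planted HER2-inhibitor x HER2 x
                       node-status and chemo x node-status interactions
                       and a leak tuned so the marginal adverse rate sits
                       near 0.08.
``preset_beneficial``  small schema, one treatment effective only for a
                       biomarker-positive subgroup (deleterious otherwise).
``preset_confounded``/``preset_unconfounded``
                       a variable that drives both the treatment policy
                       and the outcome (or not) — fodder for the
                       confounder check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import itertools

import numpy as np

from .bn import DEFAULT_MISSING, DataTable, DiscreteVariable
from .camil import CamilModel, HiddenGroup, OrdinalCamil
from .errors import ConfigError
import pandas as pd

__all__ = [
    "TreatmentPolicy",
    "GeneratorConfig",
    "generate",
    "marginal_adverse_probability",
    "preset_lsds_like",
    "preset_beneficial",
    "preset_confounded",
    "preset_unconfounded",
]


@dataclass
class TreatmentPolicy:
    """P(treatment = taken-state | parent features), one entry per config."""

    parents: tuple[str, ...]
    p_taken: np.ndarray  # flat over parent configs (package index order)

    def __post_init__(self):
        self.parents = tuple(self.parents)
        self.p_taken = np.atleast_1d(np.asarray(self.p_taken, dtype=float))
        if ((self.p_taken < 0) | (self.p_taken > 1)).any():
            raise ConfigError("policy probabilities must lie in [0, 1]")


@dataclass
class GeneratorConfig:
    schema: list[DiscreteVariable]  # features + treatments (no target)
    truth: CamilModel | OrdinalCamil
    policies: dict[str, TreatmentPolicy]
    n: int = 1000
    missing_rate: float = 0.0
    feature_marginals: dict[str, np.ndarray] = field(default_factory=dict)
    missing_marker: str = DEFAULT_MISSING

    def __post_init__(self):
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        names = {v.name for v in self.schema}
        for t in self.policies:
            if t not in names:
                raise ConfigError(f"policy for unknown treatment {t!r}")
        for g in self.truth.groups:
            for p in g.parents:
                if p not in names:
                    raise ConfigError(f"truth model parent {p!r} not in schema")
        for f, m in self.feature_marginals.items():
            v = next(v for v in self.schema if v.name == f)
            m = np.asarray(m, dtype=float)
            if m.shape != (v.n_states,) or abs(m.sum() - 1) > 1e-9:
                raise ConfigError(f"bad marginal for {f!r}")
            self.feature_marginals[f] = m


def _marginal(config: GeneratorConfig, v: DiscreteVariable) -> np.ndarray:
    m = config.feature_marginals.get(v.name)
    if m is None:
        return np.full(v.n_states, 1.0 / v.n_states)
    return m


def generate(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[DataTable, dict]:
    """Sample a patient table from the ground-truth process.

    Features are drawn iid from their marginals, treatments from the
    policy given the realized features, each hidden group activates with
    probability 1 - q at its realized configuration, and the target is the
    OR (binary) or max level (ordinal) of the hidden layer and the leak.
    Missing cells are injected completely at random at ``missing_rate``.
    Deterministic under ``seed``.

    Returns the table (features, treatments, target) and an info dict with
    the truth model, the hidden-variable draws, and the realized adverse
    (or top-level) rate.
    """
    rng = np.random.default_rng(seed)
    n = config.n
    truth = config.truth
    columns: dict[str, np.ndarray] = {}
    code_cols: dict[str, np.ndarray] = {}
    for v in config.schema:
        if v.name in config.policies:
            continue
        codes = rng.choice(v.n_states, size=n, p=_marginal(config, v))
        code_cols[v.name] = codes
        columns[v.name] = np.asarray(v.states, dtype=object)[codes]
    for t, policy in config.policies.items():
        v = next(x for x in config.schema if x.name == t)
        if policy.parents:
            sizes = tuple(
                next(x for x in config.schema if x.name == p).n_states
                for p in policy.parents
            )
            cfg = np.ravel_multi_index(
                tuple(code_cols[p] for p in policy.parents), sizes
            )
            p_taken = policy.p_taken[cfg]
        else:
            p_taken = np.full(n, policy.p_taken[0])
        codes = (rng.random(n) < p_taken).astype(int)  # state 1 = taken
        code_cols[t] = codes
        columns[t] = np.asarray(v.states, dtype=object)[codes]

    names = [v.name for v in config.schema]
    code_mat = np.column_stack([code_cols[nm] for nm in names])

    if isinstance(truth, CamilModel):
        off = np.ones(n, dtype=bool)
        hidden = np.zeros((n, len(truth.groups) + 1), dtype=int)
        for gi, g in enumerate(truth.groups):
            cfg = truth.group_config_codes(g, code_mat, names)
            h = rng.random(n) >= g.q[cfg]  # activation prob 1 - q
            hidden[:, gi] = h
            off &= ~h
        leak_on = rng.random(n) >= truth.leak_q
        hidden[:, -1] = leak_on
        adverse = ~(off & ~leak_on)
        ai = truth.target.index(truth.adverse_state)
        t_codes = np.where(adverse, ai, 1 - ai)
    else:
        m = truth.target.n_states
        levels = np.zeros((n, len(truth.groups) + 1), dtype=int)
        for gi, g in enumerate(truth.groups):
            sizes = tuple(truth.cause(p).n_states for p in g.parents)
            cfg = np.ravel_multi_index(
                tuple(code_cols[p] for p in g.parents), sizes
            )
            cum = np.cumsum(g.level_probs, axis=1)
            u = rng.random(n)
            levels[:, gi] = (u[:, None] >= cum[cfg]).sum(axis=1)
        u = rng.random(n)
        levels[:, -1] = (u[:, None] >= np.cumsum(truth.leak_probs)[None, :]).sum(axis=1)
        hidden = levels
        t_codes = levels.max(axis=1)

    target_var = truth.target
    columns[target_var.name] = np.asarray(target_var.states, dtype=object)[t_codes]

    df = pd.DataFrame(columns, columns=names + [target_var.name])
    if config.missing_rate > 0:
        mask = rng.random(df.shape) < config.missing_rate
        arr = df.to_numpy(dtype=object)
        arr[mask] = config.missing_marker
        df = pd.DataFrame(arr, columns=df.columns)

    table = DataTable(
        list(config.schema) + [target_var], df, config.missing_marker
    )
    info = {
        "truth": truth,
        "hidden": hidden,
        "adverse_rate": float(np.mean(t_codes == (
            truth.target.index(truth.adverse_state)
            if isinstance(truth, CamilModel) else m - 1
        ))),
    }
    return table, info


def marginal_adverse_probability(config: GeneratorConfig) -> float:
    """Exact P(target adverse) by enumeration over the relevant variables.

    Enumerates the joint configurations of every variable entering the
    truth model or a relevant treatment policy; other variables do not
    affect the target.  Intended for small truth models.
    """
    truth = config.truth
    if not isinstance(truth, CamilModel):
        raise ConfigError("enumeration implemented for binary truth models")
    relevant: list[str] = []
    for g in truth.groups:
        for p in g.parents:
            if p not in relevant:
                relevant.append(p)
    for t in list(relevant):
        pol = config.policies.get(t)
        if pol is None:
            continue
        for p in pol.parents:
            if p not in relevant:
                relevant.append(p)
    by_name = {v.name: v for v in config.schema}
    vars_ = [by_name[nm] for nm in relevant]
    total = 0.0
    for combo in itertools.product(*(range(v.n_states) for v in vars_)):
        assign = dict(zip(relevant, combo))
        prob = 1.0
        for v, c in zip(vars_, combo):
            pol = config.policies.get(v.name)
            if pol is None:
                prob *= _marginal(config, v)[c]
            else:
                if pol.parents:
                    sizes = tuple(by_name[p].n_states for p in pol.parents)
                    j = int(np.ravel_multi_index(
                        tuple(assign[p] for p in pol.parents), sizes
                    ))
                else:
                    j = 0
                p_taken = pol.p_taken[j]
                prob *= p_taken if c == 1 else 1.0 - p_taken
        if prob == 0.0:
            continue
        record = {nm: by_name[nm].states[c] for nm, c in assign.items()}
        total += prob * truth.predict_adverse(record)
    return total


# ----------------------------------------------------------------------
# Presets
# ----------------------------------------------------------------------

def _bin(name: str, yes_no: bool = True) -> DiscreteVariable:
    return DiscreteVariable(name, ("no", "yes") if yes_no else ("neg", "pos"))


def preset_lsds_like(n: int = 20_000, missing_rate: float = 0.0) -> GeneratorConfig:
    """23-variable registry-style schema with a planted truth model.

    The variable names and state lists mirror a published breast-cancer
    registry codebook; the truth model, marginals, and policies are
    entirely synthetic.  Planted structure: a HER2-inhibitor x HER2 x
    node-status interaction (inhibitor helps HER2+/node+ patients, harms
    HER2- patients), a chemo x node-status interaction (chemo helps
    node-positive patients, slightly harms node-negative ones), a grade
    main effect, and a leak chosen so the marginal 5-year adverse rate
    lands near 0.08.
    """
    schema = [
        DiscreteVariable("Age", ("0-49", "50-64", ">64")),
        DiscreteVariable("menopause", ("pre", "post")),
        DiscreteVariable("size", ("0-38", "38-50.5", ">50.5")),
        DiscreteVariable("node_positive", ("0", "1-3", ">3")),
        DiscreteVariable("node_removed", ("0-2", "3-5", ">5")),
        _bin("node_status", yes_no=False),
        DiscreteVariable("grade", ("1", "2", "3")),
        _bin("invasive"),
        DiscreteVariable("stage", ("0", "1", "2", "3")),
        DiscreteVariable("histology", ("lobular", "duct")),
        _bin("ER", yes_no=False),
        _bin("PR", yes_no=False),
        _bin("HER2", yes_no=False),
        _bin("TNEG"),
        _bin("P53", yes_no=False),
        DiscreteVariable(
            "surgical_margins",
            ("no res. tumor", "res. tumor", "no primary site surgery"),
        ),
        DiscreteVariable("surgery", ("conservation", "mastectomy")),
        _bin("chemo"),
        _bin("breast_chest_radi"),
        _bin("nodal_radi"),
        _bin("antihormone"),
        _bin("HER2_Inhib"),
        _bin("neo"),
    ]
    target = _bin("metastasis")
    groups = [
        # (HER2_Inhib, HER2, node_status): q indexed inhibitor-slowest
        HiddenGroup(
            ("HER2_Inhib", "HER2", "node_status"),
            np.array([
                1.00,  # no,  neg, neg  (baseline, anchored)
                0.995,  # no,  neg, pos
                0.99,  # no,  pos, neg
                0.90,  # no,  pos, pos  <- untreated HER2+/node+ risk
                0.96,  # yes, neg, neg  <- deleterious in HER2-
                0.95,  # yes, neg, pos
                0.99,  # yes, pos, neg
                0.99,  # yes, pos, pos  <- inhibitor restores inhibition
            ]),
        ),
        HiddenGroup(
            ("chemo", "node_status"),
            np.array([
                1.00,  # no,  neg (baseline)
                0.92,  # no,  pos  <- untreated node+ risk
                0.96,  # yes, neg  <- mildly deleterious node-
                0.97,  # yes, pos  <- chemo helps node+
            ]),
        ),
        HiddenGroup(("grade",), np.array([1.00, 0.98, 0.95])),
    ]
    truth = CamilModel(
        [v for v in schema if v.name in
         ("HER2_Inhib", "HER2", "node_status", "chemo", "grade")],
        groups, leak_q=0.98, target=target, adverse_state="yes",
    )
    policies = {
        # inhibitor mostly given to HER2+ patients; chemo to node+ patients
        "HER2_Inhib": TreatmentPolicy(("HER2",), np.array([0.10, 0.70])),
        "chemo": TreatmentPolicy(("node_status",), np.array([0.30, 0.80])),
        "breast_chest_radi": TreatmentPolicy((), np.array([0.5])),
        "nodal_radi": TreatmentPolicy((), np.array([0.3])),
        "antihormone": TreatmentPolicy((), np.array([0.4])),
        "neo": TreatmentPolicy((), np.array([0.2])),
    }
    return GeneratorConfig(
        schema=schema, truth=truth, policies=policies, n=n,
        missing_rate=missing_rate,
    )


def preset_beneficial(n: int = 10_000) -> GeneratorConfig:
    """One treatment, effective only for biomarker-positive patients.

    The therapy x marker group makes the therapy strongly effective at
    marker=pos and deleterious at marker=neg; node status is an
    independent main effect; three noise features carry no signal.  The
    physician policy flips a fair coin, so roughly half the records
    deviate from the model's advice in each subgroup.
    """
    schema = [
        _bin("marker", yes_no=False),
        _bin("node_status", yes_no=False),
        DiscreteVariable("f3", ("a", "b")),
        DiscreteVariable("f4", ("a", "b")),
        DiscreteVariable("f5", ("a", "b")),
        _bin("therapy"),
    ]
    target = _bin("metastasis")
    truth = CamilModel(
        [v for v in schema if v.name in ("therapy", "marker", "node_status")],
        [
            HiddenGroup(
                ("therapy", "marker"),
                np.array([
                    1.00,  # no,  neg (baseline)
                    0.72,  # no,  pos  <- untreated marker+ risk
                    0.88,  # yes, neg  <- deleterious for marker-
                    0.97,  # yes, pos  <- therapy works for marker+
                ]),
            ),
            HiddenGroup(("node_status",), np.array([1.00, 0.86])),
        ],
        leak_q=0.96, target=target, adverse_state="yes",
    )
    policies = {"therapy": TreatmentPolicy((), np.array([0.5]))}
    return GeneratorConfig(schema=schema, truth=truth, policies=policies, n=n)


def _confounder_config(confounded: bool, n: int) -> GeneratorConfig:
    schema = [
        _bin("modifier", yes_no=False),
        DiscreteVariable("burden", ("low", "high")),
        DiscreteVariable("noise1", ("a", "b")),
        DiscreteVariable("noise2", ("a", "b")),
        _bin("therapy"),
    ]
    target = _bin("metastasis")
    truth = CamilModel(
        [v for v in schema if v.name in ("therapy", "modifier", "burden")],
        [
            HiddenGroup(
                ("therapy", "modifier"),
                np.array([1.00, 0.75, 0.88, 0.97]),
            ),
            HiddenGroup(("burden",), np.array([1.00, 0.80])),
        ],
        leak_q=0.97, target=target, adverse_state="yes",
    )
    policy = (
        TreatmentPolicy(("burden",), np.array([0.20, 0.80]))
        if confounded
        else TreatmentPolicy((), np.array([0.5]))
    )
    return GeneratorConfig(
        schema=schema, truth=truth, policies={"therapy": policy}, n=n
    )


def preset_confounded(n: int = 4000) -> GeneratorConfig:
    """Disease burden drives both the therapy decision and the outcome.

    With the candidate set S = ("modifier",), burden is a common cause of
    therapy and outcome outside S — the confounder check must fail unless
    burden is added to the conditioning set.
    """
    return _confounder_config(True, n)


def preset_unconfounded(n: int = 4000) -> GeneratorConfig:
    """Same process but therapy assigned by a fair coin (no confounding)."""
    return _confounder_config(False, n)
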