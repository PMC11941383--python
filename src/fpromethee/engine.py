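"""PROMETHEE I/II outranking core.

Given a resolved numeric grid, per-criterion preference functions, directions
and normalized weights, the engine computes:

* the aggregated preference index
  ``pi(a, b) = sum_k w_k * P_k(d_k(a, b))`` over all ordered pairs, where
  ``d_k`` is the signed advantage of ``a`` over ``b`` on criterion ``k``
  (negated for minimized criteria so larger always means better);
* positive and negative outranking flows
  ``Phi+(a) = (1/(n-1)) * sum_b pi(a, b)`` and
  ``Phi-(a) = (1/(n-1)) * sum_b pi(b, a)``;
* the PROMETHEE I partial preorder (preferred / indifferent / incomparable)
  from the two flows;
* the PROMETHEE II net flow ``Phi_net = Phi+ - Phi-`` and the complete
  descending ranking; and
* unicriterion net flows
  ``phi_k(a) = (1/(n-1)) * sum_b [P_k(d_k(a,b)) - P_k(d_k(b,a))]``, whose
  weighted sum recombines to ``Phi_net`` and which expose each alternative's
  per-criterion strengths (``phi_k > 0``) and weaknesses (``phi_k < 0``).

All six classical preference functions are available; the Gaussian type
``P(d) = 1 - exp(-d^2 / (2 s^2))`` with spread ``s`` estimated from the
criterion column's sample standard deviation is the default, giving graded,
scale-free preferences rather than a binary 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import (
    MAXIMIZE,
    MINIMIZE,
    DecisionMatrix,
    Direction,
    PreferenceFunctionSpec,
    resolve_cells,
    resolve_weights,
)

__all__ = [
    "InsufficientAlternativesError",
    "UnresolvedParameterError",
    "FLOW_TOLERANCE",
    "PreferenceFunctionSpec",
    "FlowTable",
    "PartialOrder",
    "signed_difference",
    "preference_value",
    "estimate_gaussian_spread",
    "resolve_spreads",
    "aggregated_preference",
    "positive_flow",
    "negative_flow",
    "net_flow",
    "partial_order",
    "complete_ranking",
    "unicriterion_net_flows",
    "compute_flows",
    "rank_matrix",
]

#: Tolerance for flow-equality tests in the partial preorder; exact float
#: equality would make indifference practically unreachable.
FLOW_TOLERANCE = 1e-9

# Partial-order relation labels.
SELF = "self"
PREFERRED = "preferred"
OUTRANKED = "outranked"  # converse of preferred, from the row's perspective
INDIFFERENT = "indifferent"
INCOMPARABLE = "incomparable"


class InsufficientAlternativesError(ValueError):
    """Flows divide by n - 1; fewer than two alternatives is undefined."""


class UnresolvedParameterError(ValueError):
    """A gaussian spec still carries s='auto' where a number is required."""


def signed_difference(value_a: float, value_b: float, direction: Direction) -> float:
    """Advantage of a over b on one criterion; positive means a is better.

    Minimized criteria are negated internally so downstream preference
    functions never need to know the direction.
    """
    d = value_a - value_b
    return d if direction == MAXIMIZE else -d


def preference_value(d: Union[float, np.ndarray], spec: PreferenceFunctionSpec):
    """Preference degree P(d) in [0, 1]; 0 for d <= 0 under every kind.

    Accepts scalars or arrays (vectorized).  Kinds:

    * ``usual``    — 1 for any d > 0 (strict jump);
    * ``u_shape``  — 1 for d > q, else 0;
    * ``v_shape``  — min(d / p, 1) for d > 0;
    * ``level``    — 0 for d <= q, 0.5 for q < d <= p, 1 for d > p;
    * ``linear``   — ramp (d - q) / (p - q) clipped to [0, 1] (q defaults 0,
      reducing to v_shape);
    * ``gaussian`` — 1 - exp(-d^2 / (2 s^2)); s must be resolved to a number
      (use :func:`resolve_spreads` for s='auto'); s == 0 (constant column)
      yields 0 everywhere.
    """
    d = np.asarray(d, dtype=float)
    pos = d > 0
    kind = spec.kind
    if kind == "usual":
        out = np.where(pos, 1.0, 0.0)
    elif kind == "u_shape":
        out = np.where(d > spec.q, 1.0, 0.0)
    elif kind == "v_shape":
        out = np.where(pos, np.minimum(d / spec.p, 1.0), 0.0)
    elif kind == "level":
        out = np.where(d > spec.p, 1.0, np.where(d > spec.q, 0.5, 0.0))
    elif kind == "linear":
        ramp = np.clip((d - spec.q) / (spec.p - spec.q), 0.0, 1.0)
        out = np.where(d > spec.q, ramp, 0.0)
    elif kind == "gaussian":
        s = spec.s
        if isinstance(s, str):
            raise UnresolvedParameterError(
                "gaussian spread is 'auto'; resolve it from the data first")
        if s == 0:
            out = np.zeros_like(d)
        else:
            out = np.where(pos, 1.0 - np.exp(-np.square(d) / (2.0 * s * s)), 0.0)
    else:  # pragma: no cover - spec validation forbids this
        raise ValueError(f"unknown preference kind {kind!r}")
    return float(out) if out.ndim == 0 else out


def estimate_gaussian_spread(column: Sequence[float]) -> float:
    """Sample standard deviation (divisor n - 1) of one resolved column.

    A constant column returns 0; the engine then yields zero preference on
    that criterion, consistent with all pairwise differences being zero.
    """
    col = np.asarray(column, dtype=float)
    if col.size < 2:
        raise InsufficientAlternativesError("spread estimation needs at least 2 values")
    return float(np.std(col, ddof=1))


def resolve_spreads(
    resolved: np.ndarray, specs: Sequence[PreferenceFunctionSpec]
) -> List[PreferenceFunctionSpec]:
    """Replace s='auto' in gaussian specs with each column's sample std."""
    out = []
    for j, spec in enumerate(specs):
        if spec.kind == "gaussian" and spec.s == "auto":
            spec = PreferenceFunctionSpec(
                kind="gaussian", q=spec.q, p=spec.p,
                s=estimate_gaussian_spread(resolved[:, j]))
        out.append(spec)
    return out


def _pairwise_preferences(
    resolved: np.ndarray,
    specs: Sequence[PreferenceFunctionSpec],
    directions: Sequence[Direction],
) -> np.ndarray:
    """(K, n, n) stack of per-criterion preference matrices P_k(d_k(a, b))."""
    n, k = resolved.shape
    if len(specs) != k or len(directions) != k:
        raise ValueError("specs/directions length must match the number of criteria")
    specs = resolve_spreads(resolved, specs)
    stack = np.empty((k, n, n), dtype=float)
    for j in range(k):
        col = resolved[:, j]
        d = col[:, None] - col[None, :]
        if directions[j] == MINIMIZE:
            d = -d
        stack[j] = preference_value(d, specs[j])
        np.fill_diagonal(stack[j], 0.0)
    return stack


def aggregated_preference(
    resolved: np.ndarray,
    weights: Sequence[float],
    specs: Sequence[PreferenceFunctionSpec],
    directions: Sequence[Direction],
) -> np.ndarray:
    """Aggregated preference index pi(a, b) for all ordered pairs.

    ``pi(a, b) = sum_k w_k * P_k(d_k(a, b))`` with zero diagonal; values lie
    in [0, 1] when the weights are normalized.
    """
    weights = np.asarray(weights, dtype=float)
    stack = _pairwise_preferences(resolved, specs, directions)
    if weights.shape[0] != stack.shape[0]:
        raise ValueError("weight vector length must match the number of criteria")
    return np.tensordot(weights, stack, axes=(0, 0))


def positive_flow(pi: np.ndarray) -> np.ndarray:
    """Phi+(a): mean strength with which a outranks the other n-1 alternatives."""
    n = pi.shape[0]
    if n < 2:
        raise InsufficientAlternativesError("flows need at least 2 alternatives")
    return (pi.sum(axis=1) - np.diag(pi)) / (n - 1)


def negative_flow(pi: np.ndarray) -> np.ndarray:
    """Phi-(a): mean strength with which a is outranked; positive_flow of pi^T."""
    return positive_flow(pi.T)


def net_flow(phi_plus: Sequence[float], phi_minus: Sequence[float]) -> np.ndarray:
    """Phi_net = Phi+ - Phi-; sums to 0 when both come from the same pi."""
    plus = np.asarray(phi_plus, dtype=float)
    minus = np.asarray(phi_minus, dtype=float)
    if plus.shape != minus.shape:
        raise ValueError("flow vectors must have equal length")
    return plus - minus


@dataclass(frozen=True)
class PartialOrder:
    """PROMETHEE I relation grid over ordered pairs.

    ``relation[i][j]`` is 'preferred' (i outranks j), 'indifferent',
    'incomparable', or 'self' on the diagonal.  Preference uses both flows:
    i outranks j when it is at least as strong AND at most as weak, strictly
    better on one side; flows that disagree in direction are incomparable.
    """

    relations: Tuple[Tuple[str, ...], ...]

    def relation(self, i: int, j: int) -> str:
        return self.relations[i][j]

    def edges(self, ids: Optional[Sequence[str]] = None) -> List[Tuple[str, str, str]]:
        """Flat (a, relation, b) list over distinct ordered pairs."""
        n = len(self.relations)
        names = list(ids) if ids is not None else [str(i) for i in range(n)]
        return [
            (names[i], self.relations[i][j], names[j])
            for i in range(n) for j in range(n) if i != j
        ]


def partial_order(
    phi_plus: Sequence[float],
    phi_minus: Sequence[float],
    tol: float = FLOW_TOLERANCE,
) -> PartialOrder:
    """Classify every ordered pair from the two flows (PROMETHEE I).

    Equality of flows is tested within ``tol``.
    """
    plus = np.asarray(phi_plus, dtype=float)
    minus = np.asarray(phi_minus, dtype=float)
    n = plus.shape[0]
    rels = [[SELF] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            p_eq = abs(plus[i] - plus[j]) <= tol
            m_eq = abs(minus[i] - minus[j]) <= tol
            p_gt = not p_eq and plus[i] > plus[j]
            p_lt = not p_eq and plus[i] < plus[j]
            m_lt = not m_eq and minus[i] < minus[j]
            m_gt = not m_eq and minus[i] > minus[j]
            if p_eq and m_eq:
                rels[i][j] = INDIFFERENT
            elif ((p_gt or p_eq) and m_lt) or (p_gt and m_eq):
                rels[i][j] = PREFERRED
            elif ((p_lt or p_eq) and m_gt) or (p_lt and m_eq):
                rels[i][j] = OUTRANKED
            else:
                # flows disagree in direction: (p_gt and m_gt) or (p_lt and m_lt)
                rels[i][j] = INCOMPARABLE
    return PartialOrder(tuple(tuple(r) for r in rels))


@dataclass(frozen=True)
class FlowTable:
    """Per-alternative flows, ranks, and the unicriterion decomposition."""

    alternative_ids: Tuple[str, ...]
    phi_plus: np.ndarray
    phi_minus: np.ndarray
    phi_net: np.ndarray
    ranks: Tuple[int, ...]
    unicriterion: pd.DataFrame  # n x K, indexed by alternative id
    weights: np.ndarray

    def ranking(self) -> List[Tuple[int, str]]:
        """(rank, alternative id) pairs in ranking order (ties in input order)."""
        order = sorted(range(len(self.ranks)), key=lambda i: (self.ranks[i], i))
        return [(self.ranks[i], self.alternative_ids[i]) for i in order]

    @property
    def has_ties(self) -> bool:
        return len(set(self.ranks)) < len(self.ranks)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "rank": self.ranks,
            "alternative": self.alternative_ids,
            "phi_net": self.phi_net,
            "phi_plus": self.phi_plus,
            "phi_minus": self.phi_minus,
        })
        # stable sort keeps input order within tied ranks
        return df.sort_values("rank", kind="stable").reset_index(drop=True)


def complete_ranking(phi_net: Sequence[float], tol: float = FLOW_TOLERANCE) -> List[int]:
    """Competition ranks from net flows, descending; ties share the best rank.

    With flows (0.4, -0.4) the ranks are (1, 2); four equal flows all get
    rank 1.  Tie detection uses ``tol``.
    """
    net = np.asarray(phi_net, dtype=float)
    order = sorted(range(net.size), key=lambda i: (-net[i], i))
    ranks = [0] * net.size
    for pos, idx in enumerate(order):
        if pos > 0 and abs(net[idx] - net[order[pos - 1]]) <= tol:
            ranks[idx] = ranks[order[pos - 1]]
        else:
            ranks[idx] = pos + 1
    return ranks


def unicriterion_net_flows(
    resolved: np.ndarray,
    specs: Sequence[PreferenceFunctionSpec],
    directions: Sequence[Direction],
) -> np.ndarray:
    """Per-criterion net flows phi_k(a); weighted sum recombines to Phi_net.

    Positive entries are the criteria on which an alternative beats the
    field (its strengths), negative entries its weaknesses.
    """
    n = resolved.shape[0]
    if n < 2:
        raise InsufficientAlternativesError("flows need at least 2 alternatives")
    stack = _pairwise_preferences(resolved, specs, directions)
    # (K, n): row sums of P_k minus column sums, / (n-1)
    return ((stack.sum(axis=2) - stack.sum(axis=1)) / (n - 1)).T


def compute_flows(
    resolved: np.ndarray,
    weights: Sequence[float],
    specs: Sequence[PreferenceFunctionSpec],
    directions: Sequence[Direction],
    alternative_ids: Optional[Sequence[str]] = None,
    criterion_ids: Optional[Sequence[str]] = None,
) -> FlowTable:
    """Full PROMETHEE II computation from a resolved numeric grid."""
    resolved = np.asarray(resolved, dtype=float)
    n, k = resolved.shape
    ids = tuple(alternative_ids) if alternative_ids is not None \
        else tuple(f"A{i + 1}" for i in range(n))
    cids = list(criterion_ids) if criterion_ids is not None \
        else [f"C{j + 1}" for j in range(k)]
    pi = aggregated_preference(resolved, weights, specs, directions)
    plus = positive_flow(pi)
    minus = negative_flow(pi)
    net = net_flow(plus, minus)
    uni = unicriterion_net_flows(resolved, specs, directions)
    return FlowTable(
        alternative_ids=ids,
        phi_plus=plus,
        phi_minus=minus,
        phi_net=net,
        ranks=tuple(complete_ranking(net)),
        unicriterion=pd.DataFrame(uni, index=list(ids), columns=cids),
        weights=np.asarray(weights, dtype=float),
    )


def rank_matrix(matrix: DecisionMatrix) -> FlowTable:
    """Resolve a decision matrix and run the full outranking pipeline."""
    if matrix.n_alternatives < 2:
        raise InsufficientAlternativesError("ranking needs at least 2 alternatives")
    resolved = resolve_cells(matrix)
    weights = resolve_weights(matrix.criteria, matrix.scale)
    specs = [c.preference for c in matrix.criteria]
    directions = [c.direction for c in matrix.criteria]
    return compute_flows(
        resolved, weights, specs, directions,
        alternative_ids=matrix.alternative_ids(),
        criterion_ids=matrix.criterion_ids(),
    )
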