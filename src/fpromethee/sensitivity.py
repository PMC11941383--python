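"""Weight-change sensitivity analysis for outranking rankings.

Criterion weights in an outranking model are expert judgments, so the
robustness of a ranking under weight perturbation is part of the result.
This module supports three experiments:

* targeted re-weighting (``apply_weight_changes``): replace the weights of
  named criteria — e.g. demoting a block of Very-High criteria to High — and
  re-rank;
* ranking comparison (``compare_rankings``): per-alternative rank
  displacement, the list of pairwise rank reversals, and Kendall's tau-b
  concordance between the two net-flow orderings; and
* Monte Carlo stability (``monte_carlo_weight_stability``): multiplicative
  uniform noise on the normalized weights, renormalize, re-rank, and tabulate
  how often each alternative lands at each rank.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .engine import FlowTable, compute_flows, complete_ranking, rank_matrix
from .fuzzy import LinguisticTerm
from .model import DecisionMatrix, resolve_cells, resolve_weights

__all__ = [
    "WeightChange",
    "SensitivityReport",
    "STUDY_DEMOTED_CRITERIA",
    "apply_weight_changes",
    "compare_rankings",
    "run_weight_change_experiment",
    "monte_carlo_weight_stability",
    "study_weight_changes",
]

#: Criterion labels demoted to High in the packaged replication experiment:
#: accuracy, diagnostic sensitivity, instrument cost, cost per run, throughput
#: and loading volume are all set to High regardless of their baseline weight.
STUDY_DEMOTED_CRITERIA = (
    "accuracy",
    "diagnostic sensitivity",
    "cost per instrument",
    "cost/run",
    "throughput",
    "loading volume",
)


@dataclass(frozen=True)
class WeightChange:
    """Replace one criterion's weight (linguistic term or positive number)."""

    criterion_id: str
    new_weight: Union[LinguisticTerm, float]


@dataclass(frozen=True)
class SensitivityReport:
    """Baseline vs modified ranking with displacement and concordance."""

    baseline: FlowTable
    modified: FlowTable
    displacement: pd.Series          # rank_after - rank_before, per alternative
    reversals: Tuple[Tuple[str, str], ...]  # ordered pairs whose relative order flipped
    concordance: float               # Kendall tau-b of the two phi_net orderings

    def summary(self) -> pd.DataFrame:
        ids = list(self.baseline.alternative_ids)
        return pd.DataFrame({
            "alternative": ids,
            "rank_before": self.baseline.ranks,
            "rank_after": self.modified.ranks,
            "displacement": self.displacement.values,
            "phi_net_before": self.baseline.phi_net,
            "phi_net_after": self.modified.phi_net,
        }).sort_values("rank_before", kind="stable").reset_index(drop=True)


def apply_weight_changes(
    matrix: DecisionMatrix, changes: Sequence[WeightChange]
) -> DecisionMatrix:
    """Return a copy of the model with the listed weights replaced.

    The input model is untouched; renormalization happens downstream in
    ``resolve_weights``.  Unknown criterion ids raise ``KeyError``.
    """
    by_id = {ch.criterion_id: ch.new_weight for ch in changes}
    known = set(m.id for m in matrix.criteria)
    unknown = set(by_id) - known
    if unknown:
        raise KeyError(f"unknown criterion id(s): {sorted(unknown)}")
    new_criteria = [
        dc_replace(c, weight=by_id[c.id]) if c.id in by_id else c
        for c in matrix.criteria
    ]
    return matrix.with_criteria(new_criteria)


def compare_rankings(before: FlowTable, after: FlowTable) -> SensitivityReport:
    """Quantify how a modified ranking departs from the baseline.

    Displacement is ``rank_after - rank_before`` per alternative; a reversal
    is an unordered pair whose strict net-flow order flipped; concordance is
    Kendall's tau-b on the two net-flow vectors (1 for identical order, -1
    for a full reversal, ties handled).
    """
    if before.alternative_ids != after.alternative_ids:
        raise ValueError("flow tables cover different alternative sets")
    ids = list(before.alternative_ids)
    disp = pd.Series(
        np.asarray(after.ranks) - np.asarray(before.ranks), index=ids,
        name="displacement")
    reversals: List[Tuple[str, str]] = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            d_before = before.phi_net[i] - before.phi_net[j]
            d_after = after.phi_net[i] - after.phi_net[j]
            if d_before * d_after < 0:
                reversals.append((ids[i], ids[j]))
    tau, _ = kendalltau(before.phi_net, after.phi_net)
    if np.isnan(tau):  # all-tied degenerate input
        tau = 1.0
    return SensitivityReport(
        baseline=before, modified=after, displacement=disp,
        reversals=tuple(reversals), concordance=float(tau))


def run_weight_change_experiment(
    matrix: DecisionMatrix, changes: Sequence[WeightChange]
) -> SensitivityReport:
    """Re-rank under modified weights and compare with the baseline.

    An empty change list reproduces the baseline exactly (zero displacement,
    concordance 1).
    """
    before = rank_matrix(matrix)
    after = rank_matrix(apply_weight_changes(matrix, changes))
    return compare_rankings(before, after)


def monte_carlo_weight_stability(
    matrix: DecisionMatrix,
    relative_noise: float,
    n_draws: int,
    seed: int,
) -> pd.DataFrame:
    """Rank-frequency table under multiplicative weight noise.

    Each draw perturbs every normalized weight by ``(1 + u)`` with ``u``
    uniform on ``[-relative_noise, +relative_noise]``, renormalizes, and
    re-ranks.  Returns an ``n x n`` DataFrame of rank frequencies (rows:
    alternatives, columns: ranks 1..n, each row summing to 1).  The same
    seed always produces the same table; noise 0 reproduces the baseline
    ranking in every draw.
    """
    if relative_noise < 0:
        raise ValueError("relative_noise must be >= 0")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    resolved = resolve_cells(matrix)
    base_weights = resolve_weights(matrix.criteria, matrix.scale)
    specs = [c.preference for c in matrix.criteria]
    directions = [c.direction for c in matrix.criteria]
    ids = matrix.alternative_ids()
    n = len(ids)
    counts = np.zeros((n, n), dtype=int)
    for _ in range(n_draws):
        u = rng.uniform(-relative_noise, relative_noise, size=base_weights.size)
        w = base_weights * (1.0 + u)
        w = w / w.sum()
        table = compute_flows(resolved, w, specs, directions, alternative_ids=ids)
        for i, r in enumerate(table.ranks):
            counts[i, r - 1] += 1
    freq = counts / n_draws
    return pd.DataFrame(freq, index=ids, columns=[r for r in range(1, n + 1)])


def study_weight_changes(matrix: DecisionMatrix) -> List[WeightChange]:
    """The packaged replication experiment: set the six named criteria
    (matched by label) to High.

    Raises ``KeyError`` if any of the six labels is absent from the model.
    """
    by_label = {c.label.strip().lower(): c.id for c in matrix.criteria}
    changes = []
    for label in STUDY_DEMOTED_CRITERIA:
        if label not in by_label:
            raise KeyError(f"criterion labelled {label!r} not present in the model")
        changes.append(WeightChange(by_label[label], LinguisticTerm.HIGH))
    return changes
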