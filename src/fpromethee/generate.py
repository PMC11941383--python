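"""Synthetic decision matrices emulating the sequencing-platform study design.

The study compares 15 sequencing technologies on 20 criteria whose importance
weights follow the distribution 10 Very-High / 7 High / 3 Moderate, with a
mix of quantitative cells (costs, error rates, run output) and qualitative
cells on the five-level linguistic scale, and with five minimized criteria
(costs, error rate, processing time, loading volume).  The underlying
platform-by-criterion measurements were compiled from vendor specifications
and are not public, so this module generates matrices with the same
*structure* for testing and demonstration; all cell values are synthetic and
no claim is made of reproducing the study's exact flows.

``plant_dominant_alternative`` upgrades one alternative to be weakly better
everywhere and strictly better somewhere — by the dominance property of
outranking flows it must rank first under any positive weights, which gives
the package a recoverable ground truth (the analog of parameter recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .fuzzy import DEFAULT_SCALE, LinguisticTerm, yager_index
from .model import (
    MAXIMIZE,
    MINIMIZE,
    Alternative,
    CellValue,
    Criterion,
    DecisionMatrix,
    PreferenceFunctionSpec,
)

__all__ = [
    "GeneratorConfig",
    "generate_matrix",
    "plant_dominant_alternative",
    "paper_fixture",
    "FIXTURE_ALTERNATIVES",
    "FIXTURE_CRITERIA",
]

#: Ordered linguistic terms, worst to best.
_TERM_ORDER = (
    LinguisticTerm.VERY_LOW,
    LinguisticTerm.LOW,
    LinguisticTerm.MODERATE,
    LinguisticTerm.HIGH,
    LinguisticTerm.VERY_HIGH,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-structure defaults: 15 alternatives, 20 criteria, 10 VH + 7 H +
    3 M weights, 5 minimized criteria, roughly half the criteria linguistic.

    ``fraction_linguistic_cells`` is applied at the criterion level — a
    criterion's column is either wholly numeric or wholly linguistic, as in
    real decision tables where a qualitative attribute is qualitative for
    every alternative.  ``seed`` fully determines the output.
    """

    n_alternatives: int = 15
    weight_distribution: Dict[LinguisticTerm, int] = field(
        default_factory=lambda: {
            LinguisticTerm.VERY_HIGH: 10,
            LinguisticTerm.HIGH: 7,
            LinguisticTerm.MODERATE: 3,
        })
    fraction_linguistic_cells: float = 0.5
    n_minimize: int = 5
    lognormal_sigma: float = 1.0   # dispersion of cost/rate-like numeric columns
    uniform_range: Tuple[float, float] = (0.0, 100.0)  # score-like numeric columns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alternatives < 2:
            raise ValueError("need at least 2 alternatives")
        if not 0.0 <= self.fraction_linguistic_cells <= 1.0:
            raise ValueError("fraction_linguistic_cells must be in [0, 1]")
        if any(v < 0 for v in self.weight_distribution.values()):
            raise ValueError("weight counts must be non-negative")
        if self.n_criteria < 1:
            raise ValueError("weight distribution must cover at least one criterion")
        if not 0 <= self.n_minimize <= self.n_criteria:
            raise ValueError("n_minimize must lie in [0, number of criteria]")

    @property
    def n_criteria(self) -> int:
        return sum(self.weight_distribution.values())


def generate_matrix(config: Optional[GeneratorConfig] = None) -> DecisionMatrix:
    """Draw a complete decision matrix with the configured structure.

    Numeric columns alternate between lognormal draws (heavy-tailed, like
    instrument costs or error rates) and uniform draws (bounded scores like
    accuracy percentages); linguistic columns draw uniformly from the five
    terms.  Deterministic in ``config.seed``.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_alternatives, cfg.n_criteria

    weight_terms: List[LinguisticTerm] = []
    for term, count in cfg.weight_distribution.items():
        weight_terms.extend([term] * count)

    n_linguistic = int(round(cfg.fraction_linguistic_cells * k))
    is_linguistic = np.zeros(k, dtype=bool)
    is_linguistic[rng.choice(k, size=n_linguistic, replace=False)] = True
    # minimized criteria are drawn from the numeric ones first (cost-like),
    # spilling into linguistic ones only if there are not enough
    numeric_idx = list(np.nonzero(~is_linguistic)[0])
    linguistic_idx = list(np.nonzero(is_linguistic)[0])
    minimize_set = set((numeric_idx + linguistic_idx)[: cfg.n_minimize])

    criteria = []
    for j in range(k):
        criteria.append(Criterion(
            id=f"C{j + 1}",
            label=f"criterion {j + 1}" + (" (linguistic)" if is_linguistic[j] else ""),
            direction=MINIMIZE if j in minimize_set else MAXIMIZE,
            weight=weight_terms[j],
            preference=PreferenceFunctionSpec(kind="gaussian", s="auto"),
        ))
    alternatives = [Alternative(id=f"A{i + 1}", label=f"alternative {i + 1}")
                    for i in range(n)]

    columns: List[List[CellValue]] = []
    for j in range(k):
        if is_linguistic[j]:
            draws = rng.integers(0, len(_TERM_ORDER), size=n)
            columns.append([CellValue(linguistic=_TERM_ORDER[d]) for d in draws])
        elif j % 2 == 0:
            vals = rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=n)
            columns.append([CellValue(numeric=float(v)) for v in vals])
        else:
            lo, hi = cfg.uniform_range
            vals = rng.uniform(lo, hi, size=n)
            columns.append([CellValue(numeric=float(v)) for v in vals])

    cells = [[columns[j][i] for j in range(k)] for i in range(n)]
    return DecisionMatrix(alternatives=alternatives, criteria=criteria, cells=cells)


def plant_dominant_alternative(
    matrix: DecisionMatrix, target_id: str
) -> DecisionMatrix:
    """Make ``target_id`` weakly best on every criterion, strictly on some.

    Numeric cells are pushed strictly beyond the current column optimum by a
    margin of 5% of the column spread (or 1.0 for a constant column);
    linguistic cells get the best term in the matrix's scale for the
    criterion direction.  Dominance makes the target rank 1 under any
    positive weights and any monotone preference functions.
    """
    ids = matrix.alternative_ids()
    if target_id not in ids:
        raise KeyError(f"unknown alternative id {target_id!r}")
    t = ids.index(target_id)
    # best/worst available terms under the matrix's own scale
    scale_terms = sorted(matrix.scale.terms(), key=lambda tm: yager_index(matrix.scale[tm]))
    worst_term, best_term = scale_terms[0], scale_terms[-1]

    new_rows = [list(row) for row in matrix.cells]
    for j, crit in enumerate(matrix.criteria):
        col = [row[j] for row in matrix.cells]
        if any(c.is_linguistic for c in col):
            term = best_term if crit.direction == MAXIMIZE else worst_term
            new_rows[t][j] = CellValue(linguistic=term)
        else:
            vals = np.array([c.numeric for c in col], dtype=float)
            spread = float(np.ptp(vals))
            margin = 0.05 * spread if spread > 0 else 1.0
            if crit.direction == MAXIMIZE:
                new_rows[t][j] = CellValue(numeric=float(vals.max() + margin))
            else:
                new_rows[t][j] = CellValue(numeric=float(vals.min() - margin))
    return DecisionMatrix(
        alternatives=matrix.alternatives, criteria=matrix.criteria,
        cells=new_rows, scale=matrix.scale)


# --- packaged study-structure fixture -------------------------------------

#: The 15 platforms of the study's ranking table.
FIXTURE_ALTERNATIVES: Tuple[Tuple[str, str, dict], ...] = (
    ("ABC", "Avidite Base Chemistry Sequencing", {"generation": "third", "read": "short"}),
    ("ONT", "Oxford Nanopore Sequencing", {"generation": "third", "read": "long"}),
    ("ILM", "Illumina NextSeq 2000", {"generation": "second", "read": "short"}),
    ("SMF", "Single Molecule Fluorescent Sequencing", {"generation": "second", "read": "short"}),
    ("SOL", "ABI SOLiD Sequencing", {"generation": "second", "read": "short"}),
    ("SMR", "Single-Molecule Real-Time Sequencing", {"generation": "third", "read": "long"}),
    ("ION", "Ion Torrent Semiconductor Sequencing", {"generation": "second", "read": "short"}),
    ("MFS", "Microfluidic Sanger Sequencing", {"generation": "second", "read": "short"}),
    ("MPS", "Massively Parallel Signature Sequencing", {"generation": "second", "read": "short"}),
    ("CRC", "CRISPR Cas Sequencing", {"generation": "second", "read": "short"}),
    ("PLY", "Polony Sequencing", {"generation": "second", "read": "short"}),
    ("GNP", "GenapSys Sequencing", {"generation": "second", "read": "short"}),
    ("PYR", "Qiagen PyroMark Q48 Autoprep", {"generation": "second", "read": "short"}),
    ("MXG", "Maxam-Gilbert Method", {"generation": "first", "read": "short"}),
    ("AB3", "Applied Biosystems 3730", {"generation": "first", "read": "short"}),
)

#: (id, label, weight term, direction, cell kind) for the 20 study criteria.
#: The published criterion legend labels both C10 and C12 "cost per
#: instrument" and omits "mutation detection"; this fixture resolves the
#: duplication by assigning C12 to mutation detection ability, which recovers
#: exactly the 20 distinct weighted criteria of the study's weight table.
FIXTURE_CRITERIA: Tuple[Tuple[str, str, str, str, str], ...] = (
    ("C1", "machine design", "H", MAXIMIZE, "linguistic"),
    ("C2", "type of sequencing", "VH", MAXIMIZE, "linguistic"),
    ("C3", "generation type", "H", MAXIMIZE, "linguistic"),
    ("C4", "DNA or RNA sequencing", "M", MAXIMIZE, "linguistic"),
    ("C5", "max read length/run", "VH", MAXIMIZE, "numeric"),
    ("C6", "max output data/run", "VH", MAXIMIZE, "numeric"),
    ("C7", "processing time/run", "VH", MINIMIZE, "numeric"),
    ("C8", "accuracy", "VH", MAXIMIZE, "numeric"),
    ("C9", "diagnostic sensitivity", "VH", MAXIMIZE, "numeric"),
    ("C10", "cost per instrument", "VH", MINIMIZE, "numeric"),
    ("C11", "cost/run", "H", MINIMIZE, "numeric"),
    ("C12", "mutation detection", "H", MAXIMIZE, "linguistic"),
    ("C13", "error rate", "VH", MINIMIZE, "numeric"),
    ("C14", "throughput", "H", MAXIMIZE, "linguistic"),
    ("C15", "large whole-genome sequencing", "H", MAXIMIZE, "linguistic"),
    ("C16", "small whole-genome sequencing", "M", MAXIMIZE, "linguistic"),
    ("C17", "exome and large panel sequencing", "H", MAXIMIZE, "linguistic"),
    ("C18", "loading volume", "M", MINIMIZE, "numeric"),
    ("C19", "whole genome with single-stranded sequencing", "VH", MAXIMIZE, "linguistic"),
    ("C20", "single-stranded sequencing accuracy", "VH", MAXIMIZE, "numeric"),
)

#: Plausible units and draw ranges for the numeric fixture columns.
_FIXTURE_NUMERIC: Dict[str, Tuple[str, float, float]] = {
    # criterion id -> (unit, low, high) for uniform draws
    "C5": ("kb", 0.5, 4000.0),       # max read length per run
    "C6": ("Gb", 0.1, 300.0),        # max output per run
    "C7": ("h", 4.0, 96.0),          # processing time per run
    "C8": ("%", 85.0, 99.9),         # accuracy
    "C9": ("%", 80.0, 99.9),         # diagnostic sensitivity
    "C10": ("kUSD", 20.0, 1000.0),   # instrument cost
    "C11": ("USD", 50.0, 2000.0),    # cost per run
    "C13": ("%", 0.1, 15.0),         # error rate
    "C18": ("uL", 5.0, 100.0),       # minimum loading volume
    "C20": ("%", 70.0, 99.9),        # single-stranded sequencing accuracy
}

_FIXTURE_SEED = 20250310


def paper_fixture(seed: int = _FIXTURE_SEED) -> DecisionMatrix:
    """Synthetic study-structure fixture: 15 platforms x 20 criteria.

    Alternative labels, criterion labels, weight terms (10 VH / 7 H / 3 M)
    and optimization directions follow the published study design; the cell
    values are SYNTHETIC draws (fixed seed) within plausible vendor-spec
    ranges, because the study's underlying measurements were never published.
    The fixture therefore reproduces the problem's structure, not its
    numerical ranking.
    """
    rng = np.random.default_rng(seed)
    alternatives = [Alternative(id=a, label=lbl, metadata=dict(meta))
                    for a, lbl, meta in FIXTURE_ALTERNATIVES]
    criteria = []
    for cid, label, wterm, direction, _kind in FIXTURE_CRITERIA:
        criteria.append(Criterion(
            id=cid, label=label, direction=direction,
            weight=LinguisticTerm.parse(wterm),
            preference=PreferenceFunctionSpec(kind="gaussian", s="auto")))

    n = len(alternatives)
    columns: List[List[CellValue]] = []
    for cid, _label, _w, _d, kind in FIXTURE_CRITERIA:
        if kind == "linguistic":
            draws = rng.integers(0, len(_TERM_ORDER), size=n)
            columns.append([CellValue(linguistic=_TERM_ORDER[d]) for d in draws])
        else:
            unit, lo, hi = _FIXTURE_NUMERIC[cid]
            vals = rng.uniform(lo, hi, size=n)
            columns.append([CellValue(numeric=round(float(v), 3), unit=unit)
                            for v in vals])
    cells = [[columns[j][i] for j in range(len(criteria))] for i in range(n)]
    return DecisionMatrix(alternatives=alternatives, criteria=criteria,
                          cells=cells, scale=DEFAULT_SCALE)
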