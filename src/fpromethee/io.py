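"""Reading and writing decision matrices, criteria configs, and reports.

File formats (all plain text):

* decision matrix — CSV, UTF-8, one header row of criterion ids, first
  column the alternative id, cells either numbers or linguistic tokens
  (``VH/H/M/L/VL`` or full words, case-insensitive, whitespace-tolerant);
* criteria config — YAML or JSON with per-criterion ``id``, ``label``,
  ``direction``, ``weight`` (term or number), ``preference`` (kind and
  parameters), optional ``scale`` block of term -> [lower, mode, upper]
  triples, and optional alternative labels/metadata;
* ranking report — CSV with columns rank, alternative, phi_net, phi_plus,
  phi_minus rounded (half-even) to the requested precision at the report
  layer only, plus a companion full-precision CSV, the unicriterion flow
  matrix, and the partial order as an (a, relation, b) edge list.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .engine import FlowTable, PartialOrder
from .fuzzy import (
    DEFAULT_SCALE,
    FuzzyScale,
    LinguisticTerm,
    make_tfn,
)
from .model import (
    Alternative,
    CellValue,
    Criterion,
    DecisionMatrix,
    PreferenceFunctionSpec,
)

__all__ = [
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "read_criteria_config",
    "write_criteria_config",
    "write_report",
]


class MatrixParseError(ValueError):
    """A malformed matrix cell or header; carries row/column coordinates."""


_TERM_TO_TOKEN = {
    LinguisticTerm.VERY_HIGH: "VH",
    LinguisticTerm.HIGH: "H",
    LinguisticTerm.MODERATE: "M",
    LinguisticTerm.LOW: "L",
    LinguisticTerm.VERY_LOW: "VL",
}


def _parse_cell(token: str, row: int, col: str) -> CellValue:
    text = token.strip()
    if not text:
        raise MatrixParseError(f"empty cell at row {row}, column {col}")
    try:
        return CellValue(numeric=float(text))
    except ValueError:
        pass
    try:
        return CellValue(linguistic=LinguisticTerm.parse(text))
    except ValueError:
        raise MatrixParseError(
            f"cannot parse cell {token!r} at row {row}, column {col}: "
            "neither a number nor a linguistic term") from None


def _scale_from_config(block: Optional[Dict]) -> FuzzyScale:
    if not block:
        return DEFAULT_SCALE
    mapping = {}
    for token, triple in block.items():
        term = LinguisticTerm.parse(str(token))
        lo, mode, hi = (float(v) for v in triple)
        mapping[term] = make_tfn(lo, mode, hi)
    return FuzzyScale(mapping)


def _preference_from_config(block: Optional[Dict]) -> PreferenceFunctionSpec:
    if not block:
        return PreferenceFunctionSpec(kind="gaussian", s="auto")
    return PreferenceFunctionSpec(
        kind=block.get("kind", "gaussian"),
        q=float(block.get("q", 0.0)),
        p=None if block.get("p") is None else float(block["p"]),
        s=block.get("s", "auto"),
    )


def _parse_weight(value: Union[str, float, int]) -> Union[LinguisticTerm, float]:
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            return LinguisticTerm.parse(value)
    return float(value)


def read_criteria_config(path: Union[str, Path]) -> Dict:
    """Load a YAML/JSON criteria config into criterion objects plus extras.

    Returns a dict with keys ``criteria`` (list of :class:`Criterion`),
    ``scale`` (:class:`FuzzyScale`), and ``alternatives`` (optional id ->
    (label, metadata) mapping).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict) or "criteria" not in raw:
        raise MatrixParseError(f"{path}: config must contain a 'criteria' list")
    scale = _scale_from_config(raw.get("scale"))
    criteria = []
    for entry in raw["criteria"]:
        criteria.append(Criterion(
            id=str(entry["id"]),
            label=str(entry.get("label", "")),
            direction=str(entry.get("direction", "maximize")),
            weight=_parse_weight(entry.get("weight", 1.0)),
            preference=_preference_from_config(entry.get("preference")),
        ))
    alt_info = {}
    for entry in raw.get("alternatives", []) or []:
        alt_info[str(entry["id"])] = (
            str(entry.get("label", "")), dict(entry.get("metadata", {}) or {}))
    return {"criteria": criteria, "scale": scale, "alternatives": alt_info}


def read_matrix(
    csv_path: Union[str, Path], config_path: Union[str, Path]
) -> DecisionMatrix:
    """Parse a matrix CSV against its criteria config into a validated model.

    The CSV's criterion columns must match the config's criterion ids
    exactly (order taken from the config); parse errors report row and
    column coordinates.
    """
    cfg = read_criteria_config(config_path)
    criteria: List[Criterion] = cfg["criteria"]
    scale: FuzzyScale = cfg["scale"]
    csv_path = Path(csv_path)

    with csv_path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise MatrixParseError(f"{csv_path}: empty file")
    header = [h.strip() for h in rows[0]]
    if len(header) < 2:
        raise MatrixParseError(f"{csv_path}: header needs an id column plus criteria")
    wanted = [c.id for c in criteria]
    present = header[1:]
    missing = [c for c in wanted if c not in present]
    if missing:
        raise MatrixParseError(f"{csv_path}: missing criterion column(s) {missing}")
    extra = [c for c in present if c not in wanted]
    if extra:
        raise MatrixParseError(f"{csv_path}: unknown criterion column(s) {extra}")
    col_of = {cid: present.index(cid) + 1 for cid in wanted}

    alternatives: List[Alternative] = []
    cells: List[List[CellValue]] = []
    for r, row in enumerate(rows[1:], start=2):
        if not row or all(not t.strip() for t in row):
            continue
        if len(row) != len(header):
            raise MatrixParseError(
                f"{csv_path}: row {r} has {len(row)} fields, expected {len(header)}")
        aid = row[0].strip()
        label, meta = cfg["alternatives"].get(aid, (aid, {}))
        alternatives.append(Alternative(id=aid, label=label, metadata=meta))
        cells.append([_parse_cell(row[col_of[cid]], r, cid) for cid in wanted])
    return DecisionMatrix(alternatives=alternatives, criteria=criteria,
                          cells=cells, scale=scale)


def _format_number(x: float) -> str:
    return repr(float(x))  # round-trips exactly


def write_matrix(
    matrix: DecisionMatrix,
    csv_path: Union[str, Path],
    config_path: Union[str, Path],
) -> None:
    """Serialize a model to the same CSV + config formats ``read_matrix``
    accepts; linguistic cells are written as term abbreviations, numerics
    with full round-trip precision."""
    csv_path, config_path = Path(csv_path), Path(config_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    with csv_path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["alternative"] + matrix.criterion_ids())
        for alt, row in zip(matrix.alternatives, matrix.cells):
            out = [alt.id]
            for cell in row:
                out.append(_TERM_TO_TOKEN[cell.linguistic] if cell.is_linguistic
                           else _format_number(cell.numeric))
            w.writerow(out)
    write_criteria_config(matrix, config_path)


def write_criteria_config(matrix: DecisionMatrix, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scale_block = {
        _TERM_TO_TOKEN[t]: [tfn.lower, tfn.mode, tfn.upper]
        for t, tfn in sorted(matrix.scale.mapping.items(), key=lambda kv: kv[0].value)
    }
    crit_block = []
    for c in matrix.criteria:
        pref = {"kind": c.preference.kind}
        if c.preference.q:
            pref["q"] = c.preference.q
        if c.preference.p is not None:
            pref["p"] = c.preference.p
        if c.preference.kind == "gaussian":
            pref["s"] = c.preference.s
        crit_block.append({
            "id": c.id,
            "label": c.label,
            "direction": c.direction,
            "weight": _TERM_TO_TOKEN[c.weight] if isinstance(c.weight, LinguisticTerm)
                      else float(c.weight),
            "preference": pref,
        })
    alt_block = [
        {"id": a.id, "label": a.label, "metadata": dict(a.metadata)}
        for a in matrix.alternatives
    ]
    doc = {"scale": scale_block, "criteria": crit_block, "alternatives": alt_block}
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def write_report(
    flow_table: FlowTable,
    partial: Optional[PartialOrder],
    out_dir: Union[str, Path],
    precision: int = 4,
) -> Dict[str, Path]:
    """Write the ranking and companion files; returns the paths written.

    ``ranking.csv`` holds the presentation table (round-half-even at
    ``precision`` decimals); ``ranking_full.csv`` keeps full precision for
    machine consumption; ``unicriterion_flows.csv`` the per-criterion
    decomposition; ``partial_order.csv`` the PROMETHEE I edge list.
    """
    if precision < 0:
        raise ValueError("precision must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    full = flow_table.to_frame()
    pretty = full.copy()
    for col in ("phi_net", "phi_plus", "phi_minus"):
        pretty[col] = [f"{_round_half_even(v, precision):.{precision}f}"
                       for v in full[col]]
    paths["ranking"] = out_dir / "ranking.csv"
    pretty.to_csv(paths["ranking"], index=False)
    paths["ranking_full"] = out_dir / "ranking_full.csv"
    full.to_csv(paths["ranking_full"], index=False)

    paths["unicriterion"] = out_dir / "unicriterion_flows.csv"
    flow_table.unicriterion.to_csv(paths["unicriterion"], index_label="alternative")

    if partial is not None:
        paths["partial_order"] = out_dir / "partial_order.csv"
        edges = partial.edges(flow_table.alternative_ids)
        pd.DataFrame(edges, columns=["a", "relation", "b"]).to_csv(
            paths["partial_order"], index=False)
    return paths


def _round_half_even(x: float, ndigits: int) -> float:
    return float(np.round(x, ndigits))  # numpy rounds half to even
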