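"""Three-level evaluation indicator hierarchy: types, loading, validation.

The hierarchy has four level-1 indexes, each owning level-2 sub-indexes,
each owning leaf (level-3) indicators.  Every node carries a weight; within
a sibling group the weights are expected to sum to one.  Leaf indicators
additionally carry a tendency attribute (benefit ``+``, cost ``-`` or
interval ``0``) and an optional reference value used by the tendency
treatment.

The bundled configuration (:func:`default_hierarchy`) transcribes the
published 4/11/41 public-hospital evaluation system with its printed,
2-decimal weights; sibling sums are therefore validated with a +/-0.01
tolerance (see :data:`PRINTED_WEIGHT_TOL`).
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Attribute",
    "IndicatorSpec",
    "Level2Node",
    "Level1Node",
    "IndicatorHierarchy",
    "WeightSet",
    "HierarchyError",
    "load_hierarchy",
    "default_hierarchy",
    "validate_hierarchy",
    "comprehensive_weights",
    "serialize_hierarchy",
    "hierarchy_to_flat_csv",
]

#: tolerance for sibling-group weight sums when weights come from a printed,
#: 2-decimal-place table
PRINTED_WEIGHT_TOL = 0.01

#: tolerance for full-precision (programmatically built) hierarchies
EXACT_WEIGHT_TOL = 1e-12

_ATTRIBUTE_CODES = {
    "+": "benefit",
    "-": "cost",
    "−": "cost",  # unicode minus, common in extracted tables
    "0": "interval",
    "benefit": "benefit",
    "cost": "cost",
    "interval": "interval",
}

_ATTRIBUTE_TO_CODE = {"benefit": "+", "cost": "-", "interval": "0"}


class HierarchyError(ValueError):
    """Raised for malformed or invalid hierarchy configurations."""


def _parse_attribute(code: object, node: str) -> str:
    try:
        return _ATTRIBUTE_CODES[str(code).strip()]
    except KeyError:
        raise HierarchyError(
            f"leaf {node!r}: unknown attribute code {code!r} "
            f"(expected one of +, -, 0)"
        ) from None


def _parse_reference(raw: object, attribute: str, node: str):
    if raw is None or raw == "":
        return None
    if isinstance(raw, (list, tuple)):
        if len(raw) != 2:
            raise HierarchyError(
                f"leaf {node!r}: interval reference must have two values"
            )
        low, high = float(raw[0]), float(raw[1])
        if low > high:
            raise HierarchyError(
                f"leaf {node!r}: interval reference must be ordered low <= high"
            )
        return (low, high)
    value = float(raw)
    if attribute == "interval":
        # scalar target for an interval indicator: degenerate [v, v] band
        return (value, value)
    return value


@dataclass(frozen=True)
class IndicatorSpec:
    """A leaf (level-3) indicator."""

    id: str
    name: str
    attribute: str  # "benefit" | "cost" | "interval"
    weight: float
    reference: float | tuple[float, float] | None = None
    unit: str = ""

    @property
    def attribute_code(self) -> str:
        return _ATTRIBUTE_TO_CODE[self.attribute]


@dataclass(frozen=True)
class Level2Node:
    name: str
    weight: float
    leaves: tuple[IndicatorSpec, ...]


@dataclass(frozen=True)
class Level1Node:
    name: str
    weight: float
    children: tuple[Level2Node, ...]


@dataclass(frozen=True)
class IndicatorHierarchy:
    """Validated three-level indicator tree."""

    level1: tuple[Level1Node, ...]
    name: str = "hierarchy"

    def iter_leaves(self) -> Iterator[tuple[Level1Node, Level2Node, IndicatorSpec]]:
        for l1 in self.level1:
            for l2 in l1.children:
                for leaf in l2.leaves:
                    yield l1, l2, leaf

    @property
    def leaves(self) -> tuple[IndicatorSpec, ...]:
        return tuple(leaf for _, _, leaf in self.iter_leaves())

    @property
    def leaf_ids(self) -> tuple[str, ...]:
        return tuple(leaf.id for leaf in self.leaves)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf(self, leaf_id: str) -> IndicatorSpec:
        for lf in self.leaves:
            if lf.id == leaf_id:
                return lf
        raise KeyError(leaf_id)

    def branch_slices(self) -> dict[tuple[str, str], slice]:
        """Leaf-index slice of every (level-1, level-2) sibling group."""
        out: dict[tuple[str, str], slice] = {}
        start = 0
        for l1 in self.level1:
            for l2 in l1.children:
                out[(l1.name, l2.name)] = slice(start, start + len(l2.leaves))
                start += len(l2.leaves)
        return out


@dataclass(frozen=True)
class WeightSet:
    """Per-leaf comprehensive weights, in hierarchy leaf order."""

    leaf_ids: tuple[str, ...]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or len(w) != len(self.leaf_ids):
            raise ValueError("weights must be 1-d and aligned with leaf_ids")
        if np.any(w <= 0):
            raise ValueError("comprehensive weights must be positive")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.leaf_ids)

    def __getitem__(self, leaf_id: str) -> float:
        return float(self.weights[self.leaf_ids.index(leaf_id)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.leaf_ids, self.weights.tolist()))


# ---------------------------------------------------------------------------
# loading / serialization


def _build_hierarchy(doc: dict) -> IndicatorHierarchy:
    if not isinstance(doc, dict) or "level1" not in doc:
        raise HierarchyError("config must be a mapping with a 'level1' list")
    l1_nodes = []
    seen_ids: set[str] = set()
    for i1, raw1 in enumerate(doc["level1"]):
        try:
            name1 = str(raw1["name"])
            w1 = float(raw1["weight"])
            raw_children = raw1["level2"]
        except (KeyError, TypeError, ValueError) as exc:
            raise HierarchyError(f"level-1 node #{i1}: {exc}") from exc
        l2_nodes = []
        for i2, raw2 in enumerate(raw_children):
            try:
                name2 = str(raw2["name"])
                w2 = float(raw2["weight"])
                raw_leaves = raw2["leaves"]
            except (KeyError, TypeError, ValueError) as exc:
                raise HierarchyError(
                    f"level-2 node #{i2} under {name1!r}: {exc}"
                ) from exc
            leaves = []
            for raw_leaf in raw_leaves:
                try:
                    leaf_id = str(raw_leaf["id"])
                    leaf_name = str(raw_leaf["name"])
                    w3 = float(raw_leaf["weight"])
                except (KeyError, TypeError, ValueError) as exc:
                    raise HierarchyError(
                        f"leaf under {name1!r}/{name2!r}: {exc}"
                    ) from exc
                if leaf_id in seen_ids:
                    raise HierarchyError(f"duplicate leaf id {leaf_id!r}")
                seen_ids.add(leaf_id)
                attribute = _parse_attribute(raw_leaf.get("attribute", "+"), leaf_id)
                reference = _parse_reference(
                    raw_leaf.get("reference"), attribute, leaf_id
                )
                leaves.append(
                    IndicatorSpec(
                        id=leaf_id,
                        name=leaf_name,
                        attribute=attribute,
                        weight=w3,
                        reference=reference,
                        unit=str(raw_leaf.get("unit", "") or ""),
                    )
                )
            l2_nodes.append(Level2Node(name=name2, weight=w2, leaves=tuple(leaves)))
        l1_nodes.append(Level1Node(name=name1, weight=w1, children=tuple(l2_nodes)))
    return IndicatorHierarchy(
        level1=tuple(l1_nodes), name=str(doc.get("name", "hierarchy"))
    )


def load_hierarchy(
    source: str | Path | dict | io.TextIOBase,
    *,
    weight_tol: float = PRINTED_WEIGHT_TOL,
) -> IndicatorHierarchy:
    """Load and validate a hierarchy from JSON/YAML path, text stream or dict.

    Raises :class:`HierarchyError` naming the offending node on malformed
    input or invariant violations.
    """
    if isinstance(source, dict):
        doc = source
    else:
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        doc = _parse_config_text(text)
    h = _build_hierarchy(doc)
    violations = validate_hierarchy(h, weight_tol=weight_tol)
    if violations:
        raise HierarchyError("invalid hierarchy: " + "; ".join(violations))
    return h


def _parse_config_text(text: str) -> dict:
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        pass
    try:
        import yaml

        doc = yaml.safe_load(text)
    except Exception as exc:  # noqa: BLE001 - surfaced as parse error
        raise HierarchyError(f"could not parse config as JSON or YAML: {exc}")
    if not isinstance(doc, dict):
        raise HierarchyError("config document must be a mapping")
    return doc


def default_hierarchy() -> IndicatorHierarchy:
    """The bundled 4/11/41 public-hospital evaluation hierarchy."""
    text = (
        resources.files("hospeval").joinpath("data/hierarchy.json").read_text()
    )
    return load_hierarchy(json.loads(text))


def serialize_hierarchy(h: IndicatorHierarchy) -> dict:
    """Inverse of :func:`load_hierarchy` (round-trips up to key order)."""

    def ser_ref(ref):
        if ref is None:
            return None
        if isinstance(ref, tuple):
            return [ref[0], ref[1]]
        return ref

    return {
        "name": h.name,
        "level1": [
            {
                "name": l1.name,
                "weight": l1.weight,
                "level2": [
                    {
                        "name": l2.name,
                        "weight": l2.weight,
                        "leaves": [
                            {
                                "id": leaf.id,
                                "name": leaf.name,
                                "weight": leaf.weight,
                                "attribute": leaf.attribute_code,
                                "reference": ser_ref(leaf.reference),
                                "unit": leaf.unit,
                            }
                            for leaf in l2.leaves
                        ],
                    }
                    for l2 in l1.children
                ],
            }
            for l1 in h.level1
        ],
    }


_FLAT_COLUMNS = ["l1", "l1_w", "l2", "l2_w", "id", "name", "l3_w", "attribute", "reference"]


def hierarchy_to_flat_csv(
    h: IndicatorHierarchy,
    path: str | Path | None = None,
    *,
    extra_columns: dict[str, Sequence[float]] | None = None,
) -> str:
    """Flat one-row-per-leaf CSV export; returns the CSV text."""
    buf = io.StringIO()
    cols = list(_FLAT_COLUMNS) + sorted(extra_columns or {})
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(cols)
    for i, (l1, l2, leaf) in enumerate(h.iter_leaves()):
        if isinstance(leaf.reference, tuple):
            ref = f"{leaf.reference[0]}..{leaf.reference[1]}"
        else:
            ref = "" if leaf.reference is None else str(leaf.reference)
        row = [
            l1.name, l1.weight, l2.name, l2.weight,
            leaf.id, leaf.name, leaf.weight, leaf.attribute_code, ref,
        ]
        for key in sorted(extra_columns or {}):
            row.append(extra_columns[key][i])
        writer.writerow(row)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# validation / weights


def _check_sibling_sum(
    weights: Sequence[float], label: str, tol: float, report: list[str]
) -> None:
    total = float(np.sum(weights))
    if abs(total - 1.0) > tol + 1e-9:  # epsilon guards printed sums of 0.99
        report.append(
            f"{label}: sibling weights sum to {total:.4f}, expected 1 +/- {tol}"
        )


def validate_hierarchy(
    h: IndicatorHierarchy, *, weight_tol: float = PRINTED_WEIGHT_TOL
) -> list[str]:
    """Return a list of invariant violations (empty means valid)."""
    report: list[str] = []
    if not h.level1:
        return ["hierarchy: no level-1 nodes"]
    for l1 in h.level1:
        if not 0 < l1.weight <= 1:
            report.append(f"level-1 {l1.name!r}: weight must be in (0, 1]")
        if not l1.children:
            report.append(f"level-1 {l1.name!r}: no level-2 children")
        for l2 in l1.children:
            if not 0 < l2.weight <= 1:
                report.append(f"level-2 {l2.name!r}: weight must be in (0, 1]")
            if not l2.leaves:
                report.append(f"level-2 {l2.name!r}: no leaves")
            for leaf in l2.leaves:
                if not 0 < leaf.weight <= 1:
                    report.append(f"leaf {leaf.id!r}: weight must be positive (0, 1]")
                if leaf.attribute == "interval" and isinstance(leaf.reference, tuple):
                    low, high = leaf.reference
                    if low > high:
                        report.append(
                            f"leaf {leaf.id!r}: interval reference low > high"
                        )
            if l2.leaves:
                _check_sibling_sum(
                    [leaf.weight for leaf in l2.leaves],
                    f"leaves of {l1.name!r}/{l2.name!r}",
                    weight_tol,
                    report,
                )
        if l1.children:
            _check_sibling_sum(
                [l2.weight for l2 in l1.children],
                f"level-2 group under {l1.name!r}",
                weight_tol,
                report,
            )
    _check_sibling_sum(
        [l1.weight for l1 in h.level1], "level-1 group", weight_tol, report
    )
    ids = [leaf.id for leaf in h.leaves]
    if len(set(ids)) != len(ids):
        report.append("duplicate leaf ids present")
    return report


def comprehensive_weights(h: IndicatorHierarchy) -> WeightSet:
    """Per-leaf weight as the exact product of its three ancestral weights."""
    ids: list[str] = []
    weights: list[float] = []
    for l1, l2, leaf in h.iter_leaves():
        ids.append(leaf.id)
        weights.append(l1.weight * l2.weight * leaf.weight)
    return WeightSet(leaf_ids=tuple(ids), weights=np.asarray(weights))
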