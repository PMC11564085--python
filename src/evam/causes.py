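"""Cause-of-death hierarchy.

The analysis uses a mutually exclusive, collectively exhaustive (MECE) tree
of causes of death condensed from the WHO Global Health Estimates cause
list: a level-0 root (all causes), three level-1 groups (communicable/
maternal/perinatal/nutritional conditions, NCDs, injuries), eleven level-2
causes and seventeen level-3 causes.  Every death assigned to a parent
cause belongs to exactly one of its children, which is what makes the
nested, level-wise frontier rescaling well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CauseNode",
    "CauseTree",
    "ValidationReport",
    "build_default_tree",
    "validate_tree",
    "map_source_causes",
    "rollup_tree",
    "SEX_SPECIFIC_CAUSES",
    "ROOT_CODE",
]

ROOT_CODE = "all_causes"

#: Causes whose frontier is estimated separately by sex (female-specific
#: epidemiology; male rates are structurally zero).
SEX_SPECIFIC_CAUSES = frozenset({"breast_cancer", "cervix_uteri_cancer"})


@dataclass(frozen=True)
class CauseNode:
    """A single cause of death in the hierarchy."""

    code: str
    name: str
    level: int
    parent: str | None = None


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff valid
        return self.ok


class CauseTree:
    """MECE cause-of-death tree rooted at ``all_causes``.

    Parameters
    ----------
    nodes:
        Iterable of :class:`CauseNode`.  Duplicate codes are kept (and
        reported by :func:`validate_tree`) but only the first occurrence is
        addressable.
    """

    def __init__(self, nodes: Iterable[CauseNode]):
        self.nodes: list[CauseNode] = list(nodes)
        self._by_code: dict[str, CauseNode] = {}
        for n in self.nodes:
            self._by_code.setdefault(n.code, n)
        self._children: dict[str, list[str]] = {}
        for n in self.nodes:
            if n.parent is not None:
                self._children.setdefault(n.parent, []).append(n.code)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, code: str) -> CauseNode:
        return self._by_code[code]

    @property
    def root(self) -> CauseNode:
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        return roots[0]

    def children(self, code: str) -> list[str]:
        return list(self._children.get(code, []))

    def parents_with_children(self) -> list[str]:
        return [c for c in self._children if c in self._by_code]

    @property
    def codes(self) -> list[str]:
        return [n.code for n in self.nodes]

    @property
    def leaves(self) -> list[str]:
        return [n.code for n in self.nodes if n.code not in self._children]

    def level_codes(self, level: int) -> list[str]:
        return [n.code for n in self.nodes if n.level == level]

    def max_level(self) -> int:
        return max(n.level for n in self.nodes)

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [n.code for n in self.nodes],
                "name": [n.name for n in self.nodes],
                "level": [n.level for n in self.nodes],
                "parent": [n.parent if n.parent is not None else "" for n in self.nodes],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CauseTree":
        nodes = [
            CauseNode(
                code=str(r.code),
                name=str(r.name),
                level=int(r.level),
                parent=(str(r.parent) if str(r.parent) not in ("", "nan") else None),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(nodes)


def _slug(name: str) -> str:
    out = name.lower()
    for ch in ",()/":
        out = out.replace(ch, "")
    return "_".join(out.split())


# Table rows: (level, display name, parent code).  "Other" residuals are
# explicit nodes so exhaustiveness stays checkable.
_DEFAULT_ROWS: list[tuple[int, str, str | None]] = [
    (0, "All causes", None),
    (1, "Communicable, maternal, perinatal and nutritional conditions", ROOT_CODE),
    (2, "Infectious and parasitic diseases", "communicable_maternal_perinatal_and_nutritional_conditions"),
    (2, "Maternal and neonatal conditions", "communicable_maternal_perinatal_and_nutritional_conditions"),
    (2, "Nutritional deficiencies", "communicable_maternal_perinatal_and_nutritional_conditions"),
    (1, "NCDs", ROOT_CODE),
    (2, "CVDs", "ncds"),
    (3, "Ischemic heart disease", "cvds"),
    (3, "Stroke", "cvds"),
    (3, "Other CVDs", "cvds"),
    (2, "Diabetes mellitus", "ncds"),
    (2, "Digestive diseases", "ncds"),
    (3, "Cirrhosis of the liver", "digestive_diseases"),
    (3, "Other digestive diseases", "digestive_diseases"),
    (2, "Malignant neoplasms", "ncds"),
    (3, "Breast cancer", "malignant_neoplasms"),
    (3, "Cervix uteri cancer", "malignant_neoplasms"),
    (3, "Liver cancer", "malignant_neoplasms"),
    (3, "Mouth and oropharynx cancers", "malignant_neoplasms"),
    (3, "Esophagus cancer", "malignant_neoplasms"),
    (3, "Stomach cancer", "malignant_neoplasms"),
    (3, "Trachea, bronchus and lung cancers", "malignant_neoplasms"),
    (3, "Other malignant neoplasms", "malignant_neoplasms"),
    (2, "Respiratory diseases", "ncds"),
    (3, "Chronic obstructive pulmonary disease", "respiratory_diseases"),
    (3, "Other respiratory diseases", "respiratory_diseases"),
    (2, "Other NCDs", "ncds"),
    (1, "Injuries", ROOT_CODE),
    (2, "Intentional injuries", "injuries"),
    (2, "Unintentional injuries", "injuries"),
    (3, "Road injury", "unintentional_injuries"),
    (3, "Other unintentional injuries", "unintentional_injuries"),
]


def build_default_tree() -> CauseTree:
    """Return the default cause-of-death tree used throughout the analysis."""
    nodes = []
    for level, name, parent in _DEFAULT_ROWS:
        code = ROOT_CODE if level == 0 else _slug(name)
        nodes.append(CauseNode(code=code, name=name, level=level, parent=parent))
    return CauseTree(nodes)


def validate_tree(tree: CauseTree) -> ValidationReport:
    """Check structural invariants; violations are reported, not raised."""
    report = ValidationReport()
    if not tree.nodes:
        raise ValueError("tree is empty")

    seen: set[str] = set()
    for n in tree.nodes:
        if n.code in seen:
            report.violations.append(f"duplicate code: {n.code}")
        seen.add(n.code)

    roots = [n for n in tree.nodes if n.parent is None]
    if len(roots) != 1:
        report.violations.append(f"expected exactly one root, found {len(roots)}")
    for n in tree.nodes:
        if n.parent is None:
            if n.level != 0:
                report.violations.append(f"root {n.code} must be level 0, got {n.level}")
            continue
        if n.parent not in tree:
            report.violations.append(f"orphan node: {n.code} (parent {n.parent} missing)")
            continue
        plevel = tree.node(n.parent).level
        if n.level != plevel + 1:
            report.violations.append(
                f"level gap: {n.code} is level {n.level} under level-{plevel} parent {n.parent}"
            )
    return report


def map_source_causes(
    tree: CauseTree,
    mapping: pd.DataFrame | Mapping[str, str],
    records: pd.DataFrame,
    label_col: str = "cause",
    value_col: str = "deaths",
) -> pd.DataFrame:
    """Regroup a source-labelled death table onto analysis cause codes.

    ``mapping`` has columns ``source_label, code`` (or is a plain dict).
    Deaths are conserved exactly: multiple source labels mapped to one
    analysis cause are summed within each remaining index cell.
    """
    if isinstance(mapping, pd.DataFrame):
        lut = dict(zip(mapping["source_label"], mapping["code"]))
    else:
        lut = dict(mapping)

    labels = records[label_col]
    unmapped = sorted(set(labels) - set(lut))
    if unmapped:
        raise ValueError(f"unmapped cause label(s): {', '.join(map(str, unmapped))}")
    bad = sorted({c for c in lut.values() if c not in tree})
    if bad:
        raise ValueError(f"mapped code(s) not in tree: {', '.join(bad)}")

    out = records.copy()
    out[label_col] = labels.map(lut)
    keys = [c for c in out.columns if c != value_col]
    return out.groupby(keys, as_index=False, sort=False)[value_col].sum()


def rollup_tree(
    df: pd.DataFrame,
    tree: CauseTree,
    cause_col: str = "cause",
    value_col: str = "rate",
) -> pd.DataFrame:
    """Add internal-node rows to a leaf-level table by summing children.

    Input rows must cover exactly the tree's leaves; the returned frame
    contains every node of the tree, with each parent equal to the sum of
    its children within every other-index cell.  Summation is associative,
    so aggregating level by level equals aggregating leaves directly.
    """
    present = set(df[cause_col].unique())
    missing = set(tree.leaves) - present
    if missing:
        raise ValueError(f"leaf cause(s) missing from table: {sorted(missing)}")
    extra = present - set(tree.leaves)
    if extra:
        raise ValueError(f"non-leaf cause(s) in leaf table: {sorted(extra)}")

    # leaf -> every internal ancestor; each internal node is then the sum of
    # its descendant leaves, which is identical to level-by-level summation.
    pairs: list[tuple[str, str]] = []
    for leaf in tree.leaves:
        node = tree.node(leaf)
        while node.parent is not None:
            pairs.append((leaf, node.parent))
            node = tree.node(node.parent)
    lut = pd.DataFrame(pairs, columns=[cause_col, "_ancestor"])

    keys = [c for c in df.columns if c not in (cause_col, value_col)]
    merged = df.merge(lut, on=cause_col, how="inner")
    internal = (
        merged.drop(columns=[cause_col])
        .rename(columns={"_ancestor": cause_col})
        .groupby(keys + [cause_col], as_index=False, sort=False)[value_col]
        .sum()
    )
    return pd.concat([df, internal[df.columns.tolist()]], ignore_index=True)
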