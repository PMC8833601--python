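"""Declarative marker-combination rules mapping cells to lymphocyte subsets.

Each subset is a boolean rule over the marker panel: a set of markers that
must be positive (``require``) and a set that must be negative (``forbid``).
A cell may satisfy several rules at once (e.g. a CD4+CD45RO+ cell is both
``CD4_total`` and ``CD4_memory``), so assignments are sets of subset names.

The shipped default panel covers {CD4, CD8, CD20, CD45RO, FoxP3} and the
eight subsets quantified in the study design this package supports:
total and single-positive CD8 and CD4 populations, CD4 memory
(CD4+CD45RO+), regulatory T cells (CD4+FoxP3+), CD45RO+ cells, and CD20+
B cells.  "Single positive" forbids all other panel markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cell_table_io import SampleTable, Tissue

__all__ = [
    "PhenotypeRule",
    "PhenotypeAssignment",
    "RuleConfigError",
    "default_rules",
    "classify_cells",
    "subset_mask",
]

PANEL = ("CD4", "CD8", "CD20", "CD45RO", "FoxP3")


class RuleConfigError(ValueError):
    """A phenotype rule is inconsistent or references an unknown marker."""


@dataclass(frozen=True)
class PhenotypeRule:
    subset_name: str
    require: frozenset[str]
    forbid: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.require & self.forbid
        if overlap:
            raise RuleConfigError(
                f"rule {self.subset_name!r} both requires and forbids {sorted(overlap)}"
            )
        if not self.require:
            raise RuleConfigError(f"rule {self.subset_name!r} requires no marker")


@dataclass
class PhenotypeAssignment:
    """Per-cell subset memberships, plus a boolean membership matrix."""

    subsets: list[str]
    #: boolean DataFrame indexed like the sample's cell table, one column
    #: per subset
    membership: pd.DataFrame = field(repr=False)

    def subsets_of(self, idx: int) -> set[str]:
        row = self.membership.iloc[idx]
        return {s for s in self.subsets if row[s]}

    def counts(self) -> pd.Series:
        return self.membership.sum(axis=0)


def default_rules() -> list[PhenotypeRule]:
    """The shipped eight-subset rule set over the five-marker panel."""
    others = lambda *keep: frozenset(PANEL) - frozenset(keep)  # noqa: E731
    return [
        PhenotypeRule("CD8_total", frozenset({"CD8"})),
        PhenotypeRule("CD8_single", frozenset({"CD8"}), others("CD8")),
        PhenotypeRule("CD4_total", frozenset({"CD4"})),
        PhenotypeRule("CD4_single", frozenset({"CD4"}), others("CD4")),
        PhenotypeRule("CD4_memory", frozenset({"CD4", "CD45RO"})),
        PhenotypeRule("CD4_Treg", frozenset({"CD4", "FoxP3"})),
        PhenotypeRule("CD45RO_total", frozenset({"CD45RO"})),
        PhenotypeRule("CD20_total", frozenset({"CD20"})),
    ]


def rules_from_config(blocks: dict) -> list[PhenotypeRule]:
    """Build rules from config mapping subset name -> {require: [...], forbid: [...]}."""
    rules = []
    for name, block in blocks.items():
        rules.append(
            PhenotypeRule(
                subset_name=name,
                require=frozenset(block.get("require", [])),
                forbid=frozenset(block.get("forbid", [])),
            )
        )
    names = [r.subset_name for r in rules]
    if len(set(names)) != len(names):
        raise RuleConfigError("duplicate subset names in rule set")
    return rules


def classify_cells(
    table: SampleTable, rules: list[PhenotypeRule] | None = None
) -> PhenotypeAssignment:
    """Assign every cell all subsets whose rule its marker map satisfies.

    EXCLUDED cells are assigned no subset regardless of markers.
    """
    if rules is None:
        rules = default_rules()
    names = [r.subset_name for r in rules]
    if len(set(names)) != len(names):
        raise RuleConfigError("duplicate subset names in rule set")
    known = set(table.markers)
    for rule in rules:
        unknown = (rule.require | rule.forbid) - known
        if unknown:
            raise RuleConfigError(
                f"rule {rule.subset_name!r} references unknown markers {sorted(unknown)}"
            )

    df = table.cells
    not_excluded = (df["tissue"] != Tissue.EXCLUDED.value).to_numpy()
    membership = pd.DataFrame(index=df.index)
    for rule in rules:
        ok = not_excluded.copy()
        for m in rule.require:
            ok &= df[m].to_numpy(dtype=bool)
        for m in rule.forbid:
            ok &= ~df[m].to_numpy(dtype=bool)
        membership[rule.subset_name] = ok
    return PhenotypeAssignment(subsets=names, membership=membership)


def subset_mask(assignment: PhenotypeAssignment, subset: str) -> pd.Series:
    """Boolean membership vector for one subset (aligned to the cell table)."""
    if subset not in assignment.subsets:
        raise KeyError(f"unknown subset {subset!r}")
    return assignment.membership[subset]
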