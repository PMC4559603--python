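"""Workspace: named tables, filter-derived subsets, output application,
and app chaining.

Tables live in a flat namespace; *subsets* are child tables defined by a
persistent filter over a parent and form a forest (a subset of a subset is
fine, a cycle is not). Filters persist: whenever a table's data changes —
an app writes an output column, a calculated column is re-derived — every
filter on it re-evaluates and the subset hierarchy is rebuilt recursively,
so a child's membership always equals parent membership ∧ filter predicate.

Reactivity is explicit: the mutating operations call :meth:`Workspace.refresh`
themselves, which makes the propagation contract deterministic and testable
rather than event-driven.

Workflows chain apps: each step runs one app on one table and applies its
outputs (new or overwritten columns/tables) before the next step, so a later
step can consume an earlier step's product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .appspec import AppSpec
from .backends import Backend
from .datatable import Table
from .engine import ExecutionResult, run_app
from .errors import SchemaError, ShapeError, WorkflowError

logger = logging.getLogger(__name__)


@dataclass
class SubsetNode:
    """Hierarchy record: a subset table, its parent, and its defining filter."""

    name: str
    parent: str
    filter: Any  # RangeFilter | Region2DFilter | anything with .mask(table)


@dataclass
class WorkflowStep:
    app: AppSpec
    table: str
    bindings: dict[str, Any] = field(default_factory=dict)


class Workspace:
    """Named tables plus their subset hierarchy and persistent filters."""

    def __init__(self):
        self.tables: dict[str, Table] = {}
        self.subsets: dict[str, SubsetNode] = {}  # subset name -> node

    # -- introspection -----------------------------------------------------

    def table(self, name: str) -> Table:
        if name not in self.tables:
            raise KeyError(f"no table named {name!r}")
        return self.tables[name]

    def children(self, name: str) -> list[str]:
        return [s.name for s in self.subsets.values() if s.parent == name]

    def roots(self) -> list[str]:
        return [n for n in self.tables if n not in self.subsets]

    def parent_of(self, name: str) -> str | None:
        node = self.subsets.get(name)
        return node.parent if node else None

    # -- mutation ----------------------------------------------------------

    def add_table(self, name: str, table: Table) -> None:
        """Register a table; re-using a name replaces the table (with a
        warning) and refreshes everything derived from it."""
        if not name:
            raise ValueError("table name must be non-empty")
        replacing = name in self.tables
        if replacing:
            logger.warning("table %r replaced", name)
        self.tables[name] = table
        if replacing:
            self.refresh(name)

    def create_subset(self, table_name: str, filt, subset_name: str) -> Table:
        """Materialize the rows of ``table_name`` passing ``filt`` as a new
        child table; the filter persists and re-applies on refresh."""
        parent = self.table(table_name)
        for col in getattr(filt, "columns", []):
            if col not in parent:
                raise SchemaError(f"filter references unknown column {col!r}")
        if subset_name in self.subsets or subset_name == table_name:
            # re-defining a subset re-parents it; guard against cycles below
            pass
        node = SubsetNode(subset_name, table_name, filt)
        self._check_acyclic(node)
        child = self._materialize(parent, filt)
        self.tables[subset_name] = child
        self.subsets[subset_name] = node
        return child

    def create_segmented_subsets(
        self, table_name: str, base_filter, names: Sequence[str]
    ) -> list[Table]:
        """One subset per segment of a segmented range filter."""
        from dataclasses import replace

        if len(names) != base_filter.segments:
            raise ValueError("need one subset name per segment")
        return [
            self.create_subset(table_name, replace(base_filter, segment=i), nm)
            for i, nm in enumerate(names)
        ]

    def apply_output(self, table_name: str, output_name: str, payload) -> None:
        """Attach one app output to the workspace.

        A column payload (1-D) becomes a column of ``table_name`` — created
        under a new name, replaced in place under an existing one — and a
        tabular payload becomes a workspace table under the same
        new-vs-overwrite rule. Dependent filters and subsets refresh.
        """
        if isinstance(payload, pd.DataFrame):
            self.add_table(output_name, Table(payload))
            return
        if isinstance(payload, Table):
            self.add_table(output_name, payload)
            return
        table = self.table(table_name)
        vec = np.atleast_1d(np.asarray(payload))
        if len(vec) != table.n:
            raise ShapeError(
                f"output {output_name!r} has length {len(vec)},"
                f" table {table_name!r} has {table.n} rows"
            )
        table.set_column(output_name, vec, kind="output")
        self.refresh(table_name)

    def refresh(self, table_name: str) -> None:
        """Re-derive calculated columns and rebuild every descendant subset
        from its parent's current data, recursively."""
        table = self.table(table_name)
        table.recompute_calculated()
        for child_name in self.children(table_name):
            node = self.subsets[child_name]
            self.tables[child_name] = self._materialize(table, node.filter)
            self.refresh(child_name)

    # -- workflows ---------------------------------------------------------

    def run_workflow(
        self, steps: Sequence[WorkflowStep], backend_factory
    ) -> list[ExecutionResult]:
        """Run steps sequentially, applying each step's outputs before the
        next; a failing step halts the workflow, keeping earlier outputs.

        ``backend_factory`` is called once per step (fresh session per run);
        passing a Backend instance instead reuses it for every step.
        """
        results: list[ExecutionResult] = []
        for i, step in enumerate(steps):
            if step.table not in self.tables:
                raise WorkflowError(
                    f"step {i}: input table {step.table!r} does not exist", i
                )
            backend = backend_factory() if callable(backend_factory) else backend_factory
            try:
                with backend:
                    result = run_app(step.app, self.table(step.table),
                                     step.bindings, backend)
            except Exception as exc:
                raise WorkflowError(f"step {i}: {exc}", i) from exc
            results.append(result)
            if result.status != "ok":
                break
            for out_name, payload in result.outputs.items():
                if isinstance(payload, str):  # file output: path, already written
                    continue
                self.apply_output(step.table, out_name, payload)
        return results

    # -- internals ---------------------------------------------------------

    def _materialize(self, parent: Table, filt) -> Table:
        mask = np.asarray(filt.mask(parent), dtype=bool)
        child = Table(parent.df.loc[mask].reset_index(drop=True))
        child.meta = {
            k: type(v)(v.name, v.kind, v.formula) for k, v in parent.meta.items()
        }
        return child

    def _check_acyclic(self, node: SubsetNode) -> None:
        seen = {node.name}
        current = node.parent
        while current is not None:
            if current in seen:
                raise ValueError(f"subset {node.name!r} would create a cycle")
            seen.add(current)
            current = self.parent_of(current)
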