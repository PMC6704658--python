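"""Map-reduce execution of compiled query plans over a record store.

Records are processed in chunks (one chunk per store block). Each chunk
produces mergeable partial aggregator states; partial states are merged in
ascending chunk order, so floating-point results are bit-stable regardless
of the worker count, and finalized into an :class:`OutputTable`.

Aggregator semantics:

* ``sum`` — running total.
* ``mean`` — (n, running sum); final value sum/n.
* ``stdev`` — Welford (n, mean, M2) updated online and merged with the
  pairwise-combination formulas; final value is the SAMPLE standard
  deviation sqrt(M2/(n-1)), defined as 0 when n < 2.
* ``maximum`` / ``minimum`` — best (value, weight) by weight; ties keep the
  lexicographically smaller value.
* ``top(k)`` — exact value -> count table; final ranking by count
  descending, then value ascending, truncated to k.
"""

from __future__ import annotations

import math
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .dsl.compiler import Emission, QueryPlan
from .dsl.nodes import OutputDecl
from .schema import GenomeRecord
from .store import read_store_blocks

__all__ = [
    "AggregatorState", "OutputRow", "OutputTable",
    "new_state", "agg_update", "agg_merge", "finalize",
    "run_query", "run_query_records", "aggregate_emissions",
]


class EngineError(RuntimeError):
    """Raised when query evaluation fails on a record."""


@dataclass
class AggregatorState:
    """Mergeable partial state for one (output, index tuple) cell."""

    kind: str
    # sum
    total: Union[int, float] = 0
    # mean / stdev
    n: int = 0
    acc: float = 0.0   # running sum (mean) or running mean (stdev)
    m2: float = 0.0
    # maximum / minimum
    best_value: object = None
    best_weight: object = None
    # top
    counts: dict = field(default_factory=dict)


def new_state(kind: str) -> AggregatorState:
    return AggregatorState(kind=kind)


def _better(kind: str, value, weight, cur_value, cur_weight) -> bool:
    if cur_weight is None:
        return True
    if weight != cur_weight:
        return weight > cur_weight if kind == "maximum" else weight < cur_weight
    return value < cur_value  # tie: lexicographically smaller value wins


def agg_update(state: AggregatorState, value, weight=None) -> AggregatorState:
    """Fold one emission into a state (in place; returns the state)."""
    kind = state.kind
    if kind == "sum":
        state.total += value
    elif kind == "mean":
        state.n += 1
        state.acc += value
    elif kind == "stdev":
        state.n += 1
        delta = value - state.acc
        state.acc += delta / state.n
        state.m2 += delta * (value - state.acc)
    elif kind in ("maximum", "minimum"):
        if _better(kind, value, weight, state.best_value, state.best_weight):
            state.best_value = value
            state.best_weight = weight
    elif kind == "top":
        state.counts[value] = state.counts.get(value, 0) + 1
    else:
        raise ValueError(f"unknown aggregator kind {kind!r}")
    return state


def agg_merge(a: AggregatorState, b: AggregatorState) -> AggregatorState:
    """Merge two partial states of the same kind (associative on counts)."""
    if a.kind != b.kind:
        raise ValueError(f"cannot merge {a.kind!r} state with {b.kind!r} state")
    kind = a.kind
    out = AggregatorState(kind=kind)
    if kind == "sum":
        out.total = a.total + b.total
    elif kind == "mean":
        out.n = a.n + b.n
        out.acc = a.acc + b.acc
    elif kind == "stdev":
        n = a.n + b.n
        out.n = n
        if n == 0:
            return out
        delta = b.acc - a.acc
        out.acc = (a.n * a.acc + b.n * b.acc) / n
        out.m2 = a.m2 + b.m2 + delta * delta * a.n * b.n / n
    elif kind in ("maximum", "minimum"):
        out.best_value, out.best_weight = a.best_value, a.best_weight
        if b.best_weight is not None and _better(
                kind, b.best_value, b.best_weight, out.best_value, out.best_weight):
            out.best_value, out.best_weight = b.best_value, b.best_weight
    elif kind == "top":
        out.counts = dict(a.counts)
        for v, c in b.counts.items():
            out.counts[v] = out.counts.get(v, 0) + c
    else:
        raise ValueError(f"unknown aggregator kind {kind!r}")
    return out


def finalize(state: Optional[AggregatorState], decl: OutputDecl):
    """Turn a final state into the row value for its declaration.

    For mean/stdev with no emissions the row value is the string "n=0".
    """
    kind = decl.agg_kind
    if kind in ("mean", "stdev") and (state is None or state.n == 0):
        return "n=0"
    assert state is not None
    if kind == "sum":
        return state.total
    if kind == "mean":
        return state.acc / state.n
    if kind == "stdev":
        if state.n < 2:
            return 0.0
        return math.sqrt(state.m2 / (state.n - 1))
    if kind in ("maximum", "minimum"):
        return (state.best_value, state.best_weight)
    if kind == "top":
        ranked = sorted(state.counts.items(), key=lambda vc: (-vc[1], vc[0]))
        return ranked[:decl.agg_arg]
    raise ValueError(f"unknown aggregator kind {kind!r}")


@dataclass(frozen=True)
class OutputRow:
    name: str
    indices: tuple
    value: object

    def render(self) -> str:
        idx = "".join(f"[{_render_scalar(i)}]" for i in self.indices)
        return f"{self.name}{idx} = {_render_value(self.value)}"


def _render_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _render_value(v) -> str:
    if isinstance(v, tuple):  # maximum/minimum: (value, weight)
        return f"{_render_scalar(v[0])}, {_render_scalar(v[1])}"
    if isinstance(v, list):  # top: [(value, count), ...]
        return ", ".join(f"{_render_scalar(x)}:{c}" for x, c in v)
    return _render_scalar(v)


@dataclass(frozen=True)
class OutputTable:
    """Finalized query result: rows sorted by (output name, index tuple)."""

    rows: tuple[OutputRow, ...]

    def to_tsv(self) -> str:
        return "".join(row.render() + "\n" for row in self.rows)

    def by_name(self, name: str) -> dict[tuple, object]:
        return {r.indices: r.value for r in self.rows if r.name == name}


States = dict[tuple[str, tuple], AggregatorState]


def _fold_emissions(emissions: Iterable[Emission],
                    decls: dict[str, OutputDecl],
                    states: States) -> None:
    for em in emissions:
        key = (em.output, em.indices)
        state = states.get(key)
        if state is None:
            state = states[key] = new_state(decls[em.output].agg_kind)
        agg_update(state, em.value, em.weight)


def _chunk_states(plan: QueryPlan, records: list[GenomeRecord]) -> States:
    decls = {d.name: d for d in plan.output_decls}
    states: States = {}
    for record in records:
        try:
            emissions = plan.record_fn(record)
        except Exception as exc:
            raise EngineError(
                f"query failed on record {record.refseq_accession!r}: {exc}") from exc
        _fold_emissions(emissions, decls, states)
    return states


def _merge_states(parts: list[States]) -> States:
    merged: States = {}
    for part in parts:  # ascending chunk order: caller guarantees ordering
        for key, state in part.items():
            if key in merged:
                merged[key] = agg_merge(merged[key], state)
            else:
                merged[key] = state
    return merged


def _finalize_table(plan: QueryPlan, states: States) -> OutputTable:
    rows: list[OutputRow] = []
    seen_outputs = {key[0] for key in states}
    for decl in plan.output_decls:
        if decl.agg_kind in ("mean", "stdev") and decl.name not in seen_outputs:
            rows.append(OutputRow(decl.name, (), "n=0"))
    for (name, indices), state in states.items():
        decl = next(d for d in plan.output_decls if d.name == name)
        rows.append(OutputRow(name, indices, finalize(state, decl)))
    rows.sort(key=lambda r: (r.name, r.indices))
    return OutputTable(rows=tuple(rows))


def aggregate_emissions(plan: QueryPlan, emissions: Iterable[Emission]) -> OutputTable:
    """Aggregate a flat emission list in one pass (single chunk)."""
    decls = {d.name: d for d in plan.output_decls}
    states: States = {}
    _fold_emissions(emissions, decls, states)
    return _finalize_table(plan, states)


def run_query_records(plan: QueryPlan,
                      chunks: Iterable[list[GenomeRecord]],
                      workers: int = 1) -> OutputTable:
    """Run a plan over pre-chunked records; merge in ascending chunk order."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if workers == 1:
        parts = [_chunk_states(plan, chunk) for chunk in chunks]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            parts = list(pool.map(lambda c: _chunk_states(plan, c), chunks))
    return _finalize_table(plan, _merge_states(parts))


def run_query(plan: QueryPlan,
              store_path: Union[str, os.PathLike],
              workers: int = 1) -> OutputTable:
    """Execute a compiled plan over a store file.

    One chunk per store block; the result is identical for any worker count.
    """
    return run_query_records(plan, read_store_blocks(store_path), workers=workers)
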