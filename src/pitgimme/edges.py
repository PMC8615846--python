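"""Path (edge) bookkeeping for euSEM network structures.

A network structure is the set of free paths of the extended unified SEM:

* ``contemporaneous`` — ROI -> ROI at the same scan (the A matrix; diagonal forbidden),
* ``lagged``          — ROI at t-1 -> ROI at t (the phi matrix; the diagonal entries are
  the autoregressive paths and form the never-removed null-model base),
* ``direct``          — convolved task input -> ROI (the gamma matrix),
* ``bilinear``        — (input x source ROI) -> target ROI (the tau tensor): the degree to
  which a contemporaneous influence is modulated by the task input.

Edges carry a ``level`` flag ("group" or "individual") so the iterative group/individual
model search can distinguish which paths it may prune.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "ROI_ORDER",
    "INPUT_NAMES",
    "Edge",
    "NetworkStructure",
    "StructureError",
]

#: Fixed analysis column order for the five regions of interest.
ROI_ORDER = ("putamen_l", "putamen_r", "insula_l", "insula_r", "cingulate_r")

#: The two task-input columns: specific transfer (CS1 u CS2) and general transfer (CS3).
INPUT_NAMES = ("specific", "general")

_KIND_ORDER = {"lagged": 0, "contemporaneous": 1, "direct": 2, "bilinear": 3}


class StructureError(ValueError):
    """Raised for malformed network structures."""


@dataclass(frozen=True, order=False)
class Edge:
    """One free path of the euSEM.

    Parameters
    ----------
    kind : {"contemporaneous", "lagged", "direct", "bilinear"}
    source : str
        Source ROI name, or input name for ``direct`` edges.
    target : str
        Target ROI name.
    input : str, optional
        Input name; required for ``bilinear`` edges, otherwise None.
    level : {"group", "individual"}
    """

    kind: str
    source: str
    target: str
    input: str | None = None
    level: str = "group"

    def __post_init__(self):
        if self.kind not in _KIND_ORDER:
            raise StructureError(f"unknown edge kind {self.kind!r}")
        if self.kind == "contemporaneous" and self.source == self.target:
            raise StructureError("self-loops are not allowed among contemporaneous paths")
        if self.kind == "bilinear" and self.input is None:
            raise StructureError("bilinear edges require an input name")
        if self.kind != "bilinear" and self.input is not None:
            raise StructureError(f"{self.kind} edges take no input name")
        if self.level not in ("group", "individual"):
            raise StructureError(f"unknown edge level {self.level!r}")

    @property
    def is_ar(self) -> bool:
        """True for the autoregressive (lagged self) base paths."""
        return self.kind == "lagged" and self.source == self.target

    def key(self):
        """Deterministic sort/identity key (ignores level)."""
        return (_KIND_ORDER[self.kind], self.source, self.target, self.input or "")

    def presence_key(self):
        """Identity up to direction for contemporaneous/lagged pairs."""
        if self.kind in ("contemporaneous", "lagged") and not self.is_ar:
            pair = tuple(sorted((self.source, self.target)))
            return (self.kind, pair[0], pair[1], "")
        return (self.kind, self.source, self.target, self.input or "")

    def label(self) -> str:
        if self.kind == "bilinear":
            return f"{self.input}*{self.source}->{self.target}"
        arrow = "=>" if self.kind == "lagged" else "->"
        return f"{self.source}{arrow}{self.target}"

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "source": self.source,
            "target": self.target,
            "input": self.input,
            "level": self.level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Edge":
        return cls(d["kind"], d["source"], d["target"], d.get("input"), d.get("level", "group"))


@dataclass(frozen=True)
class NetworkStructure:
    """A duplicate-free set of euSEM paths over a fixed ROI/input node set."""

    edges: tuple[Edge, ...]
    roi_names: tuple[str, ...] = ROI_ORDER
    input_names: tuple[str, ...] = INPUT_NAMES

    def __post_init__(self):
        object.__setattr__(self, "edges", tuple(sorted(self.edges, key=Edge.key)))
        keys = [e.key() for e in self.edges]
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate edges in structure")
        rois = set(self.roi_names)
        inputs = set(self.input_names)
        for e in self.edges:
            if e.target not in rois:
                raise StructureError(f"unknown target ROI {e.target!r}")
            if e.kind == "direct":
                if e.source not in inputs:
                    raise StructureError(f"direct edge source {e.source!r} is not an input")
            elif e.source not in rois:
                raise StructureError(f"unknown source ROI {e.source!r}")
            if e.kind == "bilinear" and e.input not in inputs:
                raise StructureError(f"unknown bilinear input {e.input!r}")
        for r in self.roi_names:
            if not any(e.is_ar and e.target == r for e in self.edges):
                raise StructureError(f"autoregressive path for {r!r} missing (null-model base)")

    # -- construction ----------------------------------------------------------------
    @classmethod
    def null_model(
        cls,
        roi_names: Sequence[str] = ROI_ORDER,
        input_names: Sequence[str] = INPUT_NAMES,
    ) -> "NetworkStructure":
        """The AR-only base model: one lagged self path per ROI, nothing else."""
        ar = tuple(Edge("lagged", r, r, level="group") for r in roi_names)
        return cls(ar, tuple(roi_names), tuple(input_names))

    def with_edge(self, edge: Edge) -> "NetworkStructure":
        if self.contains(edge):
            raise StructureError(f"edge {edge.label()} already present")
        return replace(self, edges=self.edges + (edge,))

    def without_edge(self, edge: Edge) -> "NetworkStructure":
        if edge.is_ar:
            raise StructureError("autoregressive base paths cannot be removed")
        kept = tuple(e for e in self.edges if e.key() != edge.key())
        if len(kept) == len(self.edges):
            raise StructureError(f"edge {edge.label()} not present")
        return replace(self, edges=kept)

    def contains(self, edge: Edge) -> bool:
        k = edge.key()
        return any(e.key() == k for e in self.edges)

    # -- views ----------------------------------------------------------------------
    def of_kind(self, kind: str) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.kind == kind)

    def non_ar_edges(self) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if not e.is_ar)

    def group_edges(self) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.level == "group")

    def individual_edges(self) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.level == "individual")

    def predictors_of(self, target: str) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.target == target)

    def contemporaneous_adjacency(self) -> dict[str, set[str]]:
        """source -> set of targets over contemporaneous edges."""
        adj: dict[str, set[str]] = {r: set() for r in self.roi_names}
        for e in self.of_kind("contemporaneous"):
            adj[e.source].add(e.target)
        return adj

    def contemporaneous_cycles(self) -> list[list[str]]:
        """Strongly connected components of size > 1 in the contemporaneous graph."""
        adj = self.contemporaneous_adjacency()
        index: dict[str, int] = {}
        lowlink: dict[str, int] = {}
        on_stack: dict[str, bool] = {}
        stack: list[str] = []
        counter = [0]
        sccs: list[list[str]] = []

        def strongconnect(v: str):
            index[v] = lowlink[v] = counter[0]
            counter[0] += 1
            stack.append(v)
            on_stack[v] = True
            for w in sorted(adj[v]):
                if w not in index:
                    strongconnect(w)
                    lowlink[v] = min(lowlink[v], lowlink[w])
                elif on_stack.get(w):
                    lowlink[v] = min(lowlink[v], index[w])
            if lowlink[v] == index[v]:
                comp = []
                while True:
                    w = stack.pop()
                    on_stack[w] = False
                    comp.append(w)
                    if w == v:
                        break
                if len(comp) > 1:
                    sccs.append(sorted(comp))

        for v in self.roi_names:
            if v not in index:
                strongconnect(v)
        return sccs

    def is_acyclic(self) -> bool:
        return not self.contemporaneous_cycles()

    # -- serialization ---------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "roi_names": list(self.roi_names),
            "input_names": list(self.input_names),
            "edges": [e.to_dict() for e in self.edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkStructure":
        return cls(
            tuple(Edge.from_dict(e) for e in d["edges"]),
            tuple(d["roi_names"]),
            tuple(d["input_names"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NetworkStructure":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def candidate_universe(
    structure: NetworkStructure,
    classes: Iterable[str] = ("contemporaneous", "lagged", "direct", "bilinear"),
) -> list[Edge]:
    """All absent candidate edges of the enabled classes, in deterministic order.

    Bilinear candidates pair each input with each ordered ROI pair (source != target),
    i.e. input-modulation of a contemporaneous influence.
    """
    classes = set(classes)
    cands: list[Edge] = []
    rois = structure.roi_names
    if "contemporaneous" in classes:
        cands += [Edge("contemporaneous", s, t) for s in rois for t in rois if s != t]
    if "lagged" in classes:
        cands += [Edge("lagged", s, t) for s in rois for t in rois if s != t]
    if "direct" in classes:
        cands += [Edge("direct", u, t) for u in structure.input_names for t in rois]
    if "bilinear" in classes:
        cands += [
            Edge("bilinear", s, t, input=u)
            for u in structure.input_names
            for s in rois
            for t in rois
            if s != t
        ]
    present = {e.key() for e in structure.edges}
    return sorted((e for e in cands if e.key() not in present), key=Edge.key)
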