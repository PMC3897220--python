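"""Hierarchical interactome shells, term enrichment and graph export.

A focus protein's interactome (typed physical/genetic undirected edges,
BioGRID-style) is decomposed into concentric shells:

* level 1 — proteins physically binding the focus;
* level 2 — genetic interactors of the focus with a physical edge to a
  level-1 protein;
* level 3 — genetic interactors of the focus with a physical edge to a
  level-2 protein (and no qualifying edge to level 1);
* outer — remaining genetic interactors of the focus.

A protein that is both a physical and a genetic partner of the focus is
level 1 (physical wins), and each interactor receives the minimum level it
can justify. Term enrichment over any shell (or the whole interactor set)
is the upper-tail hypergeometric test with Benjamini–Hochberg correction —
a standard substitute for GUI enrichment tools. Graphs are exported as SIF
and GraphML for Cytoscape-style viewers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected typed interaction; (a, b) and (b, a) are one edge."""

    a: str
    b: str
    etype: str  # "physical" or "genetic"
    source: str = ""

    def __post_init__(self) -> None:
        if self.etype not in ("physical", "genetic"):
            raise ValueError(f"edge type must be physical|genetic, got {self.etype!r}")

    @property
    def key(self) -> tuple[frozenset, str]:
        return frozenset((self.a, self.b)), self.etype


def dedupe_edges(edges: Iterable[InteractionEdge]) -> list[InteractionEdge]:
    """Drop self-loops (with a warning) and collapse duplicate edges."""
    seen = set()
    out = []
    n_self = 0
    for e in edges:
        if e.a == e.b:
            n_self += 1
            continue
        if e.key in seen:
            continue
        seen.add(e.key)
        out.append(e)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop edge(s)", stacklevel=2)
    return out


@dataclass
class ShellAssignment:
    """Partition of a focus protein's interactors into shells."""

    focus: str
    levels: dict[str, str]  # protein -> "1" | "2" | "3" | "outer"
    provenance: dict[str, list[InteractionEdge]] = field(default_factory=dict)

    def shell(self, level: str) -> set[str]:
        return {p for p, lv in self.levels.items() if lv == level}

    @property
    def counts(self) -> dict[str, int]:
        return {lv: len(self.shell(lv)) for lv in ("1", "2", "3", "outer")}


def assign_shells(edges: Iterable[InteractionEdge], focus: str) -> ShellAssignment:
    """Decompose the focus protein's interactome into hierarchical shells."""
    edges = dedupe_edges(edges)
    nodes = {e.a for e in edges} | {e.b for e in edges}
    if focus not in nodes:
        raise ValueError(f"focus protein {focus!r} absent from the edge table")

    phys: dict[str, set[str]] = {}
    for e in edges:
        if e.etype == "physical":
            phys.setdefault(e.a, set()).add(e.b)
            phys.setdefault(e.b, set()).add(e.a)

    genetic_partners = set()
    for e in edges:
        if e.etype == "genetic" and focus in (e.a, e.b):
            genetic_partners.add(e.b if e.a == focus else e.a)

    level1 = set(phys.get(focus, ()))
    levels: dict[str, str] = {p: "1" for p in level1}
    provenance: dict[str, list[InteractionEdge]] = {}
    for e in edges:
        for p in level1:
            if e.etype == "physical" and {e.a, e.b} == {focus, p}:
                provenance.setdefault(p, []).append(e)

    candidates = genetic_partners - level1
    level2 = {p for p in candidates if phys.get(p, set()) & level1}
    for p in level2:
        levels[p] = "2"
    level3 = {p for p in candidates - level2 if phys.get(p, set()) & level2}
    for p in level3:
        levels[p] = "3"
    for p in candidates - level2 - level3:
        levels[p] = "outer"

    for e in edges:
        a_in, b_in = e.a in levels, e.b in levels
        if a_in and e.a not in provenance and (e.b == focus or b_in):
            provenance.setdefault(e.a, []).append(e)
        if b_in and e.b not in provenance and (e.a == focus or a_in):
            provenance.setdefault(e.b, []).append(e)

    return ShellAssignment(focus=focus, levels=levels, provenance=provenance)


# ---------------------------------------------------------------------------
# enrichment


def enrich_terms(
    foreground: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    background: Iterable[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric term enrichment with Benjamini–Hochberg correction.

    For each term with K annotated proteins in a background of N, the
    p-value is P(X ≥ k) for X ~ Hypergeom(N, K, n) where k of the n
    foreground proteins are annotated. Returns a DataFrame with columns
    term, k, n, K, N, p, q, significant, sorted by p (ties by term id).
    """
    bg = set(background)
    fg = set(foreground)
    if not fg:
        raise ValueError("empty foreground")
    if not fg <= bg:
        warnings.warn(
            f"{len(fg - bg)} foreground protein(s) absent from the background "
            "were dropped",
            stacklevel=2,
        )
        fg &= bg
        if not fg:
            raise ValueError("foreground and background are disjoint")
    N, n = len(bg), len(fg)
    rows = []
    for term in sorted(annotation):
        annotated = set(annotation[term])
        if not annotated <= bg:
            warnings.warn(
                f"term {term}: {len(annotated - bg)} annotated protein(s) "
                "outside the background were ignored",
                stacklevel=2,
            )
            annotated &= bg
        K = len(annotated)
        k = len(annotated & fg)
        p = float(hypergeom.sf(k - 1, N, K, n))  # upper tail P(X >= k)
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q=[], significant=[])
    _, q, _, _ = multipletests(df["p"], method="fdr_bh")
    df["q"] = q
    df["significant"] = df["q"] <= fdr
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# export


def export_graph(
    assignment: ShellAssignment,
    edges: Iterable[InteractionEdge],
    classes: Mapping[str, str] | None = None,
    sif_path: str | Path | None = None,
    graphml_path: str | Path | None = None,
) -> nx.Graph:
    """Export the shelled interactome as SIF and/or GraphML.

    Node attributes: ``level`` (focus/1/2/3/outer) and ``function`` (from
    ``classes``; empty when unknown). Edge attribute: ``etype``. Output is
    byte-stable for a fixed input: nodes and edges are written sorted.
    """
    classes = dict(classes or {})
    edges = dedupe_edges(edges)
    known = {assignment.focus} | set(assignment.levels)
    unknown_classes = set(classes) - known
    if unknown_classes:
        warnings.warn(
            f"{len(unknown_classes)} class label(s) refer to unknown proteins",
            stacklevel=2,
        )
    g = nx.Graph()
    for node in sorted(known):
        level = "focus" if node == assignment.focus else assignment.levels[node]
        g.add_node(node, level=level, function=classes.get(node, ""))
    for e in sorted(edges, key=lambda e: (min(e.a, e.b), max(e.a, e.b), e.etype)):
        if e.a in known and e.b in known:
            a, b = sorted((e.a, e.b))
            g.add_edge(a, b, etype=e.etype)
    if sif_path is not None:
        lines = [
            f"{a}\t{d['etype']}\t{b}"
            for a, b, d in sorted(g.edges(data=True), key=lambda x: (x[0], x[1]))
        ]
        Path(sif_path).write_text("\n".join(lines) + "\n")
    if graphml_path is not None:
        nx.write_graphml(g, str(graphml_path), named_key_ids=True)
    return g
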