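"""Diagnosis ontology: hierarchy loading, depth-based semantic similarity,
and distances between diagnosis lists.

The diagnosis space of congenital heart disease (CHD) is organised as a
rooted hierarchy (possibly a DAG: a term may have several parents).  The
similarity of two diagnosis terms is measured with the Wu–Palmer formula

    sim(a, b) = 2 * depth(LCA(a, b)) / (depth(a) + depth(b))

with ``depth(root) = 1`` and, on a DAG, ``depth(t)`` the minimum number of
nodes on a root-to-t path.  The lowest common ancestor (LCA) is the deepest
term that is an ancestor-or-self of both arguments; ties are broken by
lexicographic term id so the result is deterministic.

A patient carries a *list* of diagnoses, some flagged as primary ("basic")
diagnoses.  Two list-distance modes are provided:

* ``ungrade`` treats all diagnoses equally: a symmetric best-match average
  of pairwise similarities, turned into a distance.
* ``grade`` distinguishes primary from secondary diagnoses: the primary
  sub-lists and the secondary sub-lists are compared separately and blended
  with weight ``alpha`` (default 0.7) on the primary part.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import OntologyStructureError, TermNotFoundError

__all__ = [
    "OntologyTerm",
    "Ontology",
    "DiagnosisAssignment",
    "load_ontology",
    "load_obo",
    "lowest_common_ancestor",
    "pair_similarity",
    "diagnosis_list_distance",
]


@dataclass(frozen=True)
class OntologyTerm:
    """One diagnosis concept: an opaque id, a human label and parent ids."""

    term_id: str
    label: str = ""
    parents: tuple[str, ...] = ()


@dataclass(frozen=True)
class DiagnosisAssignment:
    """A diagnosis attached to a patient; ``is_primary`` marks a basic
    (principal) diagnosis used by the ``grade`` list-distance mode."""

    term_id: str
    is_primary: bool = False


class Ontology:
    """A validated rooted hierarchy of diagnosis terms.

    Invariants enforced at construction: exactly one root, no cycles,
    every parent id resolves, every term reachable from the root.  Depths
    are precomputed: ``depth(root) = 1`` and ``depth(t) = 1 + min`` over
    parents.
    """

    def __init__(self, terms: Mapping[str, OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        self._validate_references()
        self.root_id = self._find_root()
        self._graph = nx.DiGraph()  # edges parent -> child
        self._graph.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                self._graph.add_edge(p, t.term_id)
        self._validate_acyclic()
        self.depths: dict[str, int] = self._compute_depths()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- validation -------------------------------------------------------

    def _validate_references(self) -> None:
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    raise TermNotFoundError(
                        f"term {t.term_id!r} names unknown parent {p!r}"
                    )

    def _find_root(self) -> str:
        roots = sorted(t.term_id for t in self.terms.values() if not t.parents)
        if len(roots) != 1:
            raise OntologyStructureError(
                f"expected exactly one root, found {len(roots)}: {roots}"
            )
        return roots[0]

    def _validate_acyclic(self) -> None:
        try:
            cycle = nx.find_cycle(self._graph)
        except nx.NetworkXNoCycle:
            pass
        else:
            u, v = cycle[0][0], cycle[0][1]
            raise OntologyStructureError(
                f"cycle detected involving edge {v!r} -> parent {u!r}"
            )
        unreachable = set(self.terms) - {self.root_id} - nx.descendants(
            self._graph, self.root_id
        )
        if unreachable:
            raise OntologyStructureError(
                f"terms not reachable from root {self.root_id!r}: "
                f"{sorted(unreachable)}"
            )

    def _compute_depths(self) -> dict[str, int]:
        lengths = nx.single_source_shortest_path_length(self._graph, self.root_id)
        return {t: d + 1 for t, d in lengths.items()}

    # -- queries ----------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def depth(self, term_id: str) -> int:
        self._require(term_id)
        return self.depths[term_id]

    def ancestors_or_self(self, term_id: str) -> frozenset[str]:
        self._require(term_id)
        cached = self._ancestor_cache.get(term_id)
        if cached is None:
            cached = frozenset(nx.ancestors(self._graph, term_id)) | {term_id}
            self._ancestor_cache[term_id] = cached
        return cached

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise TermNotFoundError(f"unknown ontology term {term_id!r}")


# -- loading ---------------------------------------------------------------


def load_ontology(source: str | Iterable[str],
                  labels: Mapping[str, str] | None = None) -> Ontology:
    """Build an ontology from a child–parent edge list.

    ``source`` is TSV text (or an iterable of lines) with two columns,
    ``child_id<TAB>parent_id``.  Lines starting with ``#`` are skipped.
    A line with a single column declares an isolated term (used for the
    degenerate single-term ontology).
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = list(source)
    parents: dict[str, list[str]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) == 1:
            parents.setdefault(cols[0], [])
            continue
        child, parent = cols[0].strip(), cols[1].strip()
        if not child or not parent:
            raise OntologyStructureError(f"empty id on line {lineno}: {raw!r}")
        parents.setdefault(parent, [])
        parents.setdefault(child, [])
        if parent not in parents[child]:
            parents[child].append(parent)
    if not parents:
        raise OntologyStructureError("empty ontology source")
    labels = labels or {}
    terms = {
        tid: OntologyTerm(tid, labels.get(tid, tid), tuple(ps))
        for tid, ps in parents.items()
    }
    return Ontology(terms)


def load_obo(source: str) -> Ontology:
    """Read an OBO-flavoured file: ``[Term]`` stanzas with ``id:``,
    ``name:`` and ``is_a:`` tags.  Anything else is ignored."""
    terms: dict[str, OntologyTerm] = {}
    cur_id: str | None = None
    cur_name = ""
    cur_parents: list[str] = []
    in_term = False

    def flush() -> None:
        nonlocal cur_id, cur_name, cur_parents
        if cur_id is not None:
            terms[cur_id] = OntologyTerm(cur_id, cur_name or cur_id,
                                         tuple(cur_parents))
        cur_id, cur_name, cur_parents = None, "", []

    for raw in source.splitlines():
        line = raw.strip()
        if line == "[Term]":
            flush()
            in_term = True
        elif line.startswith("["):
            flush()
            in_term = False
        elif in_term and line.startswith("id:"):
            cur_id = line[3:].strip()
        elif in_term and line.startswith("name:"):
            cur_name = line[5:].strip()
        elif in_term and line.startswith("is_a:"):
            # "is_a: PARENT ! label" -- keep the id only
            cur_parents.append(line[5:].split("!")[0].strip())
    flush()
    if not terms:
        raise OntologyStructureError("no [Term] stanzas found")
    return Ontology(terms)


# -- semantic similarity ---------------------------------------------------


def lowest_common_ancestor(a: str, b: str, onto: Ontology) -> str:
    """Deepest ancestor-or-self shared by ``a`` and ``b``; ties broken by
    lexicographic term id."""
    common = onto.ancestors_or_self(a) & onto.ancestors_or_self(b)
    # root is a common ancestor of everything, so common is never empty
    return min(common, key=lambda t: (-onto.depths[t], t))


def pair_similarity(a: str, b: str, onto: Ontology) -> float:
    """Wu–Palmer similarity: 2*depth(LCA) / (depth(a) + depth(b))."""
    lca = lowest_common_ancestor(a, b, onto)
    return 2.0 * onto.depths[lca] / (onto.depths[a] + onto.depths[b])


def _best_match_distance(terms_a: Iterable[str], terms_b: Iterable[str],
                         onto: Ontology) -> float:
    """Symmetric best-match-average distance between two term sets."""
    ta, tb = list(terms_a), list(terms_b)
    fwd = sum(max(pair_similarity(a, b, onto) for b in tb) for a in ta) / len(ta)
    bwd = sum(max(pair_similarity(a, b, onto) for a in ta) for b in tb) / len(tb)
    sim = 0.5 * (fwd + bwd)
    return min(max(1.0 - sim, 0.0), 1.0)


def diagnosis_list_distance(
    list_a: Iterable[DiagnosisAssignment],
    list_b: Iterable[DiagnosisAssignment],
    onto: Ontology,
    mode: str = "ungrade",
    alpha: float = 0.7,
) -> float:
    """Distance in [0, 1] between two diagnosis lists.

    ``ungrade`` ignores the primary flags.  ``grade`` compares primary and
    secondary sub-lists separately and blends them as
    ``alpha * d_primary + (1 - alpha) * d_secondary``; when either record
    lacks secondary terms the primary part takes full weight (and vice
    versa), and when either record has no primary-flagged diagnosis at all
    the pair falls back to ``ungrade``.
    """
    A = list(list_a)
    B = list(list_b)
    if not A or not B:
        raise ValueError("diagnosis lists must be non-empty")
    for d in (*A, *B):
        if d.term_id not in onto:
            raise TermNotFoundError(f"unknown ontology term {d.term_id!r}")
    if mode not in ("grade", "ungrade"):
        raise ValueError(f"unknown diagnosis distance mode {mode!r}")

    if mode == "ungrade":
        return _best_match_distance((d.term_id for d in A),
                                    (d.term_id for d in B), onto)

    prim_a = [d.term_id for d in A if d.is_primary]
    prim_b = [d.term_id for d in B if d.is_primary]
    sec_a = [d.term_id for d in A if not d.is_primary]
    sec_b = [d.term_id for d in B if not d.is_primary]
    if not prim_a or not prim_b:
        return _best_match_distance((d.term_id for d in A),
                                    (d.term_id for d in B), onto)
    d_primary = _best_match_distance(prim_a, prim_b, onto)
    if not sec_a or not sec_b:
        return d_primary
    d_secondary = _best_match_distance(sec_a, sec_b, onto)
    return alpha * d_primary + (1.0 - alpha) * d_secondary


# -- serialisation ---------------------------------------------------------


def ontology_to_tsv(onto: Ontology) -> str:
    """Child–parent edge list round-trippable through :func:`load_ontology`."""
    lines = []
    for tid in sorted(onto.terms):
        t = onto.terms[tid]
        if not t.parents:
            lines.append(tid)
        for p in t.parents:
            lines.append(f"{tid}\t{p}")
    return "\n".join(lines) + "\n"


def labels_to_tsv(onto: Ontology) -> str:
    return "\n".join(
        f"{tid}\t{onto.terms[tid].label}" for tid in sorted(onto.terms)
    ) + "\n"
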