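"""Phenotype-ontology representation, information content and term scoring.

A phenotype ontology (HPO, MP, ZP, ...) is held as a rooted DAG of terms
linked by ``is_a`` edges.  Every term carries its reflexive-transitive
ancestor closure, which is the basis of the Jaccard term similarity (simJ)
and of the most-informative-common-ancestor (MICA) lookup used by the
cross-species profile score.

Cross-ontology comparison goes through a :class:`BridgeMap`: a table of
exact term equivalences (in real data derived from logical definitions).
Terms without an exact entry fall back to the images of their nearest
mapped ancestors — the mechanism that turns a specific clinical phenotype
into a generic model-organism match when its logical definition is missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: identifier given to the synthetic root inserted above multi-rooted inputs
SYNTHETIC_ROOT_ID = "SYNTH:0000000"

EXACT = "exact"
ANCESTOR_FALLBACK = "ancestor-fallback"


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or unknown terms."""


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    ``parents`` holds direct ``is_a`` parents only; obsolete terms carry no
    parents and never enter ancestor closures.
    """

    id: str
    label: str = ""
    parents: frozenset[str] = frozenset()
    obsolete: bool = False


class Ontology:
    """A rooted is_a DAG with precomputed reflexive ancestor closures."""

    def __init__(self, terms: Iterable[Term], species: str = "") -> None:
        self.species = species
        self.terms: dict[str, Term] = {}
        for t in terms:
            if t.id in self.terms:
                raise OntologyError(f"duplicate term id {t.id!r}")
            if t.id in t.parents:
                raise OntologyError(f"term {t.id!r} is its own parent")
            self.terms[t.id] = t
        self._resolve_parents()
        self.root = self._find_root()
        self._closure = self._compute_closures()

    # -- construction helpers -------------------------------------------------

    def _resolve_parents(self) -> None:
        """Drop parent references to unknown (e.g. obsolete) terms."""
        for tid, t in list(self.terms.items()):
            missing = {p for p in t.parents if p not in self.terms}
            if missing:
                logger.warning(
                    "term %s: dropping unknown parent(s) %s", tid, sorted(missing)
                )
                self.terms[tid] = Term(
                    t.id, t.label, t.parents - missing, t.obsolete
                )

    def _find_root(self) -> str:
        roots = sorted(t.id for t in self.terms.values() if not t.parents)
        if not roots:
            raise OntologyError("no root term (every term has a parent: cycle?)")
        if len(roots) == 1:
            return roots[0]
        # multi-rooted input: insert a synthetic top element
        logger.info(
            "inserting synthetic root above %d parent-less terms", len(roots)
        )
        self.terms[SYNTHETIC_ROOT_ID] = Term(SYNTHETIC_ROOT_ID, "synthetic root")
        for r in roots:
            t = self.terms[r]
            self.terms[r] = Term(t.id, t.label, frozenset({SYNTHETIC_ROOT_ID}))
        return SYNTHETIC_ROOT_ID

    def _compute_closures(self) -> dict[str, frozenset[str]]:
        closure: dict[str, frozenset[str]] = {}
        # iterative post-order over the parent graph, with cycle detection
        GREY, BLACK = 0, 1
        state: dict[str, int] = {}
        for start in self.terms:
            if start in closure:
                continue
            stack = [start]
            while stack:
                tid = stack[-1]
                if tid in closure:
                    stack.pop()
                    continue
                if state.get(tid) is GREY:
                    acc: set[str] = {tid}
                    for p in self.terms[tid].parents:
                        acc |= closure[p]
                    closure[tid] = frozenset(acc)
                    state[tid] = BLACK
                    stack.pop()
                    continue
                state[tid] = GREY
                for p in self.terms[tid].parents:
                    if p in closure:
                        continue
                    if state.get(p) is GREY:
                        raise OntologyError(
                            f"cycle detected in is_a graph involving {p!r}"
                        )
                    stack.append(p)
        return closure

    # -- queries --------------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive-transitive ancestor set of ``term_id``."""
        try:
            return self._closure[term_id]
        except KeyError:
            raise OntologyError(
                f"unknown term {term_id!r} in {self.species or 'ontology'}"
            ) from None

    def parents(self, term_id: str) -> frozenset[str]:
        if term_id not in self.terms:
            raise OntologyError(f"unknown term {term_id!r}")
        return self.terms[term_id].parents

    def label(self, term_id: str) -> str:
        return self.terms[term_id].label

    def non_root_terms(self) -> list[str]:
        return sorted(t for t in self.terms if t != self.root)


def ancestors(ontology: Ontology, term_id: str) -> frozenset[str]:
    """Module-level alias for :meth:`Ontology.ancestors`."""
    return ontology.ancestors(term_id)


# ---------------------------------------------------------------------------
# OBO reading (1.2 subset: [Term] stanzas with id / name / is_a / is_obsolete)
# ---------------------------------------------------------------------------

def load_obo(path: str, species: str = "") -> Ontology:
    """Read an OBO file (``[Term]`` stanzas; ``id``, ``name``, ``is_a``,
    ``is_obsolete``) into an :class:`Ontology`.

    Obsolete terms are excluded.  A stanza without an ``id`` is a hard error
    reported with its line number; other tags are ignored.
    """
    stanzas: list[tuple[int, dict[str, object]]] = []
    current: dict[str, object] | None = None
    in_term = False
    start_line = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                if in_term and current is not None:
                    stanzas.append((start_line, current))
                in_term = line == "[Term]"
                current = {"parents": set()} if in_term else None
                start_line = lineno
                continue
            if not in_term or current is None:
                continue
            if ":" not in line:
                continue
            tag, value = (s.strip() for s in line.split(":", 1))
            if tag == "id":
                current["id"] = value
            elif tag == "name":
                current["label"] = value
            elif tag == "is_a":
                current["parents"].add(value.split()[0])  # type: ignore[union-attr]
            elif tag == "is_obsolete":
                current["obsolete"] = value.lower() == "true"
            else:
                logger.debug("ignoring OBO tag %r at line %d", tag, lineno)
        if in_term and current is not None:
            stanzas.append((start_line, current))

    terms: list[Term] = []
    for lineno, st in stanzas:
        if "id" not in st:
            raise OntologyError(f"{path}: [Term] stanza at line {lineno} has no id")
        if st.get("obsolete"):
            continue  # obsolete terms carry no parents and are dropped entirely
        terms.append(
            Term(
                str(st["id"]),
                str(st.get("label", "")),
                frozenset(st["parents"]),  # type: ignore[arg-type]
            )
        )
    if not terms:
        raise OntologyError(f"{path}: no non-obsolete [Term] stanzas found")
    return Ontology(terms, species=species)


def write_obo(ontology: Ontology, path: str) -> None:
    """Serialize an ontology back to the OBO subset read by :func:`load_obo`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for tid in sorted(ontology.terms):
            t = ontology.terms[tid]
            fh.write(f"\n[Term]\nid: {t.id}\n")
            if t.label:
                fh.write(f"name: {t.label}\n")
            for p in sorted(t.parents):
                fh.write(f"is_a: {p}\n")


# ---------------------------------------------------------------------------
# Information content
# ---------------------------------------------------------------------------

@dataclass
class ICTable:
    """Annotation-corpus information content in natural-log units.

    ``counts[t]`` is the number of distinct entities annotated to *t* or any
    of its descendants; ``ic[t] = -ln(counts[t] / corpus_size)``.  Terms that
    annotate nothing (directly or via descendants) are absent — there are no
    pseudo-counts, so MICA maximisation is restricted to corpus-covered
    ancestors, with the root as guaranteed floor.
    """

    corpus_size: int
    counts: dict[str, int]
    ic: dict[str, float]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic


def information_content(
    ontology: Ontology,
    annotations: Sequence[tuple[str, Iterable[str]]],
) -> ICTable:
    """Build an :class:`ICTable` from an annotation corpus.

    ``annotations`` lists ``(entity_id, term_ids)`` pairs; repeated entity
    ids are merged.  Every annotated term must exist in the ontology.
    """
    if not annotations:
        raise OntologyError("empty annotation corpus")
    per_entity: dict[str, set[str]] = {}
    for entity, term_ids in annotations:
        closure = per_entity.setdefault(entity, set())
        for t in term_ids:
            closure |= ontology.ancestors(t)
    n = len(per_entity)
    counts: dict[str, int] = {}
    for closure in per_entity.values():
        for t in closure:
            counts[t] = counts.get(t, 0) + 1
    ic = {t: -math.log(c / n) for t, c in counts.items()}
    return ICTable(corpus_size=n, counts=counts, ic=ic)


# ---------------------------------------------------------------------------
# Term-pair scoring
# ---------------------------------------------------------------------------

def sim_jaccard(ontology: Ontology, t1: str, t2: str) -> float:
    """Jaccard similarity of the two terms' reflexive ancestor closures."""
    a, b = ontology.ancestors(t1), ontology.ancestors(t2)
    return len(a & b) / len(a | b)


def term_pair_score(ontology: Ontology, ic: ICTable, t1: str, t2: str) -> float:
    """Geometric mean of simJ and the IC of the most informative common
    ancestor: ``sqrt(simJ(t1,t2) * IC(MICA(t1,t2)))``.

    MICA is taken over common ancestors present in the IC table; the root is
    corpus-covered whenever the corpus is non-empty, so the maximisation has
    a floor of IC 0.
    """
    common = ontology.ancestors(t1) & ontology.ancestors(t2)
    covered = [ic.ic[t] for t in common if t in ic.ic]
    if not covered:
        raise OntologyError(
            f"no corpus-covered common ancestor of {t1!r} and {t2!r}: "
            "IC table does not match this ontology"
        )
    return math.sqrt(sim_jaccard(ontology, t1, t2) * max(covered))


# ---------------------------------------------------------------------------
# Cross-ontology bridging
# ---------------------------------------------------------------------------

class BridgeMap:
    """Exact cross-ontology term equivalences with ancestor fallback.

    Exact entries come from the input table; fallback images are derived on
    demand by walking up the source DAG breadth-first and taking the union
    of exact images at the nearest mapped depth.  The source root must be
    mapped, so every term has a non-empty image.
    """

    def __init__(
        self,
        source_species: str,
        target_species: str,
        entries: Mapping[str, Iterable[str]],
        source_ontology: Ontology,
        target_ontology: Ontology,
        strict: bool = False,
    ) -> None:
        self.source_species = source_species
        self.target_species = target_species
        self.exact: dict[str, frozenset[str]] = {}
        for src, targets in entries.items():
            if src not in source_ontology:
                if strict:
                    raise OntologyError(f"bridge source term {src!r} unknown")
                logger.warning("bridge: skipping unknown source term %s", src)
                continue
            kept = frozenset(t for t in targets if t in target_ontology)
            dropped = set(targets) - kept
            if dropped:
                if strict:
                    raise OntologyError(
                        f"bridge target term(s) {sorted(dropped)} unknown"
                    )
                logger.warning(
                    "bridge: %s: skipping unknown target term(s) %s",
                    src,
                    sorted(dropped),
                )
            if kept:
                self.exact[src] = kept
        if source_ontology.root not in self.exact:
            raise OntologyError(
                f"bridge does not map the source root "
                f"{source_ontology.root!r}; fallback cannot terminate"
            )
        self._source = source_ontology
        self._cache: dict[str, tuple[tuple[str, str], ...]] = {}

    def image(self, term_id: str) -> tuple[tuple[str, str], ...]:
        """Bridged image of ``term_id`` as ``((target_id, kind), ...)``,
        sorted by target id; ``kind`` is ``exact`` or ``ancestor-fallback``.
        """
        cached = self._cache.get(term_id)
        if cached is not None:
            return cached
        if term_id not in self._source:
            raise OntologyError(f"unknown source term {term_id!r}")
        if term_id in self.exact:
            result = tuple((t, EXACT) for t in sorted(self.exact[term_id]))
        else:
            frontier = set(self._source.parents(term_id))
            seen: set[str] = set(frontier)
            images: set[str] = set()
            while frontier and not images:
                for anc in frontier:
                    images |= self.exact.get(anc, frozenset())
                nxt: set[str] = set()
                for anc in frontier:
                    nxt |= self._source.parents(anc) - seen
                seen |= nxt
                frontier = nxt
            result = tuple((t, ANCESTOR_FALLBACK) for t in sorted(images))
        self._cache[term_id] = result
        return result


def bridge_term(
    bridge: BridgeMap, source_ontology: Ontology, term_id: str
) -> set[tuple[str, str]]:
    """Functional wrapper over :meth:`BridgeMap.image`."""
    del source_ontology  # the bridge already carries its source ontology
    return set(bridge.image(term_id))


def load_bridge(
    path: str,
    source_ontology: Ontology,
    target_ontology: Ontology,
) -> BridgeMap:
    """Read a bridge TSV (columns ``source_term_id``, ``target_term_id``,
    ``#`` comments, header required) into a :class:`BridgeMap`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"source_term_id", "target_term_id"}
    if not required.issubset(df.columns):
        raise OntologyError(
            f"{path}: bridge file must have columns {sorted(required)}"
        )
    entries: dict[str, set[str]] = {}
    for src, tgt in zip(df["source_term_id"], df["target_term_id"]):
        entries.setdefault(src, set()).add(tgt)
    return BridgeMap(
        source_ontology.species,
        target_ontology.species,
        entries,
        source_ontology,
        target_ontology,
    )


def write_bridge(bridge: BridgeMap, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source_term_id\ttarget_term_id\n")
        for src in sorted(bridge.exact):
            for tgt in sorted(bridge.exact[src]):
                fh.write(f"{src}\t{tgt}\n")
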