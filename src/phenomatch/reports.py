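"""Per-category phenotype frequency tables and best-match diagnostics.

These reproduce the manual-assessment view of the evaluation: the top-k
most frequently annotated clinical phenotypes across a category's
diseases, and for each clinical term the best-scoring model-organism
terms with their bridge provenance.  A match reached through an
ancestor-fallback bridge entry is flagged, making visible the cases where
a missing exact equivalence collapses a specific phenotype onto a generic
high-level match and its many in-use descendants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .benchmark import EvaluationSet
from .matching import MatchContext, PhenotypeProfile
from .ontology import ANCESTOR_FALLBACK, Ontology


@dataclass(frozen=True)
class PhenotypeFrequencyRow:
    term_id: str
    label: str
    count: int
    rank: int


@dataclass(frozen=True)
class BestMatchRow:
    """Best-scoring model-side matches of one human term: ``(model term,
    score, bridge kind)`` sorted by score descending then term id."""

    human_term: str
    matches: tuple[tuple[str, float, str], ...]


def top_phenotypes(
    category: EvaluationSet,
    disease_profiles: Mapping[str, PhenotypeProfile],
    k: int,
    ontology: Ontology | None = None,
) -> list[PhenotypeFrequencyRow]:
    """Top-k most frequent directly-annotated phenotype terms over a
    category's diseases (no ancestor propagation), ties broken by term id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not category.disease_ids:
        raise ValueError(f"category {category.category!r} has no diseases")
    counts: Counter[str] = Counter()
    for d in category.disease_ids:
        profile = disease_profiles[d]
        for t in profile.terms:
            counts[t] += 1
    labels = (
        {t: ontology.label(t) for t in counts if t in ontology}
        if ontology is not None
        else {}
    )
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    rows = []
    rank = 0
    prev: int | None = None
    for i, (term, count) in enumerate(ordered, start=1):
        if prev is None or count < prev:
            rank, prev = i, count
        rows.append(PhenotypeFrequencyRow(term, labels.get(term, ""), count, rank))
    return rows


def best_match_report(
    term: str,
    model_catalog_terms: Iterable[str],
    ctx: MatchContext,
    epsilon: float = 0.0,
) -> BestMatchRow:
    """Score one human term's bridged images against every model-side term
    in use and return all terms within ``epsilon`` of the top score.

    Each match carries the bridge kind of the image it was reached through
    (``exact`` or ``ancestor-fallback``); a tie between an unmapped term's
    ancestor image and that image's in-use descendants is the signature of
    a missing bridge entry.
    """
    catalog = sorted(set(model_catalog_terms))
    if not catalog:
        raise ValueError("empty model term catalog")
    image = ctx.bridge.image(term)
    scored: dict[str, tuple[float, str]] = {}
    for m in catalog:
        best = -1.0
        kind_best = ANCESTOR_FALLBACK
        for h, kind in image:
            s = ctx.pair_score(h, m)
            if s > best or (s == best and kind == "exact"):
                best, kind_best = s, kind
        scored[m] = (best, kind_best)
    top = max(s for s, _ in scored.values())
    matches = tuple(
        (m, s, kind)
        for m, (s, kind) in sorted(
            scored.items(), key=lambda kv: (-kv[1][0], kv[0])
        )
        if s >= top - epsilon
    )
    return BestMatchRow(human_term=term, matches=matches)
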