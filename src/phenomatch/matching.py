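"""Disease-vs-model phenotype profile scoring and gene ranking.

A disease's clinical phenotype profile (human-side terms) is bridged into
the model species' ontology and compared against each animal model's
profile.  For every term on either side the best pairwise match (simJ ×
MICA-IC geometric mean) is found; the maximum and the symmetric mean of
those best matches are normalised against the disease's self-match to give
a percentage score, 100 meaning a perfect phenocopy.  Genes inherit the
best percentage over their models and are ranked per disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .ontology import BridgeMap, ICTable, Ontology, term_pair_score

logger = logging.getLogger(__name__)

DISEASE = "disease"
MODEL = "model"


@dataclass(frozen=True)
class PhenotypeProfile:
    """A disease's or model's set of phenotype term identifiers."""

    entity_id: str
    kind: str  # disease | model
    species: str
    terms: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"profile {self.entity_id!r} has no terms")


@dataclass(frozen=True)
class ModelEntity:
    """One animal model (a single-gene mutant line) and its phenotypes."""

    model_id: str
    gene_id: str
    species: str
    profile: PhenotypeProfile

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError(f"model {self.model_id!r} has empty gene id")


@dataclass(frozen=True)
class ProfileSimilarity:
    disease_id: str
    model_id: str
    raw_max: float
    raw_mean: float
    self_max: float
    self_mean: float
    percentage: float


@dataclass(frozen=True)
class RankedCandidates:
    """Per-disease gene ranking: ``(gene_id, best percentage, best model)``
    sorted by percentage descending then gene id; ties share the minimum
    1-based rank."""

    disease_id: str
    entries: tuple[tuple[str, float, str], ...]

    def ranks(self) -> dict[str, int]:
        out: dict[str, int] = {}
        rank = 0
        prev: float | None = None
        for i, (gene, pct, _model) in enumerate(self.entries, start=1):
            if prev is None or pct < prev:
                rank = i
                prev = pct
            out[gene] = rank
        return out

    def scores(self) -> dict[str, float]:
        return {gene: pct for gene, pct, _ in self.entries}


class MatchContext:
    """Scoring context for one model species: its ontology, the human→model
    bridge, and the IC table over the combined model+disease corpus.

    Caches bridged images and term-pair scores, which dominate the cost of
    ranking a large catalog.
    """

    def __init__(self, ontology: Ontology, bridge: BridgeMap, ic: ICTable) -> None:
        self.ontology = ontology
        self.bridge = bridge
        self.ic = ic
        self._pair_cache: dict[tuple[str, str], float] = {}
        self._image_cache: dict[frozenset[str], tuple] = {}
        self._warned_zero_self: set[str] = set()

    def pair_score(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        s = self._pair_cache.get(key)
        if s is None:
            s = term_pair_score(self.ontology, self.ic, t1, t2)
            self._pair_cache[key] = s
        return s

    def image_terms(self, term: str) -> tuple[str, ...]:
        """Model-side image of one human term (exact or ancestor fallback)."""
        return tuple(t for t, _kind in self.bridge.image(term))

    def profile_image(
        self, terms: frozenset[str]
    ) -> tuple[tuple[tuple[str, ...], ...], tuple[str, ...]]:
        """Per-term images and their sorted union for a human profile."""
        cached = self._image_cache.get(terms)
        if cached is None:
            per_term = tuple(self.image_terms(t) for t in sorted(terms))
            union = tuple(sorted({t for img in per_term for t in img}))
            cached = (per_term, union)
            self._image_cache[terms] = cached
        return cached


def build_context(
    model_ontology: Ontology,
    bridge: BridgeMap,
    diseases: Iterable[PhenotypeProfile],
    models: Iterable[ModelEntity],
) -> MatchContext:
    """Assemble a :class:`MatchContext` whose IC corpus is all model
    entities of the species plus all diseases via their bridged images —
    the corpus over which disease–model scores are comparable."""
    from .ontology import information_content

    ctx = MatchContext(model_ontology, bridge, ICTable(1, {}, {}))
    annotations: list[tuple[str, Iterable[str]]] = []
    for m in models:
        annotations.append((m.model_id, m.profile.terms))
    for d in diseases:
        _per_term, union = ctx.profile_image(d.terms)
        annotations.append((d.entity_id, union))
    ctx.ic = information_content(model_ontology, annotations)
    ctx._pair_cache.clear()
    return ctx


def profile_similarity(
    disease: PhenotypeProfile, model: PhenotypeProfile, ctx: MatchContext
) -> ProfileSimilarity:
    """Score one disease profile against one model profile.

    For each disease term the best match over its bridged images and all
    model terms is taken, and symmetrically for each model term over all
    bridged disease images.  ``raw_max`` is the best of these; ``raw_mean``
    averages them over both directions, penalising models with many
    extraneous phenotypes.  Both are normalised against the disease image's
    self-match and combined as ``min(100, 50*(max_ratio + mean_ratio))``.
    """
    per_term, union = ctx.profile_image(disease.terms)
    pair = ctx.pair_score
    best_values: list[float] = []
    for images in per_term:  # disease direction
        best = 0.0
        for h in images:
            for m in model.terms:
                s = pair(h, m)
                if s > best:
                    best = s
        best_values.append(best)
    for m in model.terms:  # model direction
        best = 0.0
        for h in union:
            s = pair(h, m)
            if s > best:
                best = s
        best_values.append(best)
    raw_max = max(best_values)
    raw_mean = sum(best_values) / len(best_values)

    self_values = [pair(t, t) for t in union]
    self_max = max(self_values) if self_values else 0.0
    self_mean = sum(self_values) / len(self_values) if self_values else 0.0
    if self_max <= 0.0 or self_mean <= 0.0:
        if disease.entity_id not in ctx._warned_zero_self:
            logger.warning(
                "disease %s: self-match is zero (profile bridges only to "
                "uninformative terms); percentage set to 0",
                disease.entity_id,
            )
            ctx._warned_zero_self.add(disease.entity_id)
        pct = 0.0
    else:
        pct = min(100.0, 50.0 * (raw_max / self_max + raw_mean / self_mean))
    return ProfileSimilarity(
        disease_id=disease.entity_id,
        model_id=model.entity_id,
        raw_max=raw_max,
        raw_mean=raw_mean,
        self_max=self_max,
        self_mean=self_mean,
        percentage=pct,
    )


def rank_genes(
    disease: PhenotypeProfile,
    catalog: Sequence[ModelEntity],
    ctx: MatchContext,
) -> RankedCandidates:
    """Rank every gene in the catalog against one disease.

    A gene's score is the maximum percentage over its models (one faithful
    mutant suffices to implicate a gene); its best model breaks ties by
    smaller model id.  Genes are ordered by percentage descending, then
    gene id.
    """
    if not catalog:
        raise ValueError("empty model catalog")
    best: dict[str, tuple[float, str]] = {}
    for entity in catalog:
        sim = profile_similarity(disease, entity.profile, ctx)
        cur = best.get(entity.gene_id)
        cand = (sim.percentage, entity.model_id)
        if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
            best[entity.gene_id] = cand
    entries = tuple(
        (gene, pct, model_id)
        for gene, (pct, model_id) in sorted(
            best.items(), key=lambda kv: (-kv[1][0], kv[0])
        )
    )
    return RankedCandidates(disease_id=disease.entity_id, entries=entries)


def rank_all(
    diseases: Iterable[PhenotypeProfile],
    catalog: Sequence[ModelEntity],
    ctx: MatchContext,
) -> dict[str, RankedCandidates]:
    """Rank the catalog against every disease; keyed by disease id."""
    return {d.entity_id: rank_genes(d, catalog, ctx) for d in diseases}
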