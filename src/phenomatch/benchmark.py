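"""Benchmark inputs: gene–disease associations, orthology, disease categories.

Known human gene–disease associations (MorbidMap/Orphanet style) define the
true positives; an orthology table converts human genes into model-species
gene identifiers; per-category disease lists (one file per category, a
disease may belong to several) stratify the evaluation.  An evaluation set
is the subset of a category's diseases that have at least one association
whose human gene maps to at least one model gene of the species.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneDiseaseAssociation:
    disease_id: str
    gene_id: str
    source: str  # omim | orphanet | ...


@dataclass
class OrthologyMap:
    """human gene id -> set of model gene ids, for one model species."""

    species: str
    mapping: dict[str, frozenset[str]]

    def __getitem__(self, human_gene: str) -> frozenset[str]:
        return self.mapping.get(human_gene, frozenset())


@dataclass(frozen=True)
class DiseaseCategoryAssignment:
    category: str
    disease_ids: frozenset[str]


@dataclass
class EvaluationSet:
    """One category's evaluable diseases for one species, with their
    positive (truly associated, ortholog-mapped) model genes."""

    category: str
    species: str
    disease_ids: tuple[str, ...]
    positives: dict[str, frozenset[str]]
    evaluable: bool

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)


def _read_rows(path: str) -> list[tuple[int, list[str]]]:
    rows: list[tuple[int, list[str]]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            rows.append((lineno, line.split("\t")))
    return rows


def load_associations(paths: list[str]) -> list[GeneDiseaseAssociation]:
    """Read association TSVs (``disease_id``, ``gene_id``, ``source``) and
    merge them, deduplicating on (disease, gene).

    Malformed rows are skipped with a warning naming the line; the first
    source seen for a pair is kept.
    """
    seen: dict[tuple[str, str], GeneDiseaseAssociation] = {}
    per_source: dict[str, int] = {}
    for path in paths:
        rows = _read_rows(path)
        if not rows:
            continue
        header = rows[0][1]
        try:
            idx = [header.index(c) for c in ("disease_id", "gene_id", "source")]
        except ValueError:
            raise ValueError(
                f"{path}: header must contain disease_id, gene_id, source"
            ) from None
        for lineno, fields in rows[1:]:
            if len(fields) <= max(idx) or not all(fields[i].strip() for i in idx):
                logger.warning("%s:%d: malformed association row skipped", path, lineno)
                continue
            disease, gene, source = (fields[i].strip() for i in idx)
            per_source[source] = per_source.get(source, 0) + 1
            key = (disease, gene)
            if key not in seen:
                seen[key] = GeneDiseaseAssociation(disease, gene, source)
    if not seen:
        raise ValueError(f"no associations loaded from {paths}")
    for source, n in sorted(per_source.items()):
        logger.info("associations: %d rows from source %s", n, source)
    return sorted(seen.values(), key=lambda a: (a.disease_id, a.gene_id))


def load_orthology(path: str, species: str) -> OrthologyMap:
    """Read an orthology TSV (``human_gene_id``, ``model_gene_id``) into a
    many-to-many map; human genes without a row are simply absent."""
    rows = _read_rows(path)
    if not rows:
        raise ValueError(f"{path}: empty orthology file")
    header = rows[0][1]
    try:
        hi, mi = header.index("human_gene_id"), header.index("model_gene_id")
    except ValueError:
        raise ValueError(
            f"{path}: header must contain human_gene_id, model_gene_id"
        ) from None
    mapping: dict[str, set[str]] = {}
    for lineno, fields in rows[1:]:
        if len(fields) <= max(hi, mi) or not fields[hi].strip() or not fields[mi].strip():
            logger.warning("%s:%d: malformed orthology row skipped", path, lineno)
            continue
        mapping.setdefault(fields[hi].strip(), set()).add(fields[mi].strip())
    if not mapping:
        raise ValueError(f"{path}: no orthology rows")
    return OrthologyMap(species, {h: frozenset(m) for h, m in mapping.items()})


def load_categories(directory: str) -> list[DiseaseCategoryAssignment]:
    """Read per-category disease lists: one file per category (name taken
    from the file name without extension), one disease id per line.

    Multi-membership is preserved: a disease listed in several files
    appears in several assignments.
    """
    files = sorted(
        f for f in os.listdir(directory)
        if os.path.isfile(os.path.join(directory, f)) and not f.startswith(".")
    )
    if not files:
        raise ValueError(f"{directory}: no category files")
    out: list[DiseaseCategoryAssignment] = []
    for fname in files:
        category = os.path.splitext(fname)[0]
        ids = {
            fields[0].strip()
            for _lineno, fields in _read_rows(os.path.join(directory, fname))
            if fields[0].strip()
        }
        if not ids:
            logger.warning("category %s: empty file", category)
        out.append(DiseaseCategoryAssignment(category, frozenset(ids)))
    return out


def build_evaluation_sets(
    associations: list[GeneDiseaseAssociation],
    orthology: OrthologyMap,
    categories: list[DiseaseCategoryAssignment],
    species: str,
    min_size: int = 10,
) -> list[EvaluationSet]:
    """Construct per-category evaluation sets for one species.

    A disease is retained if at least one of its associated human genes has
    an ortholog in the species; its positives are the union of those model
    genes.  Sets smaller than ``min_size`` are kept but flagged
    non-evaluable (the analogue of a '-' row in a results table).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    assoc_by_disease: dict[str, set[str]] = {}
    for a in associations:
        assoc_by_disease.setdefault(a.disease_id, set()).add(a.gene_id)

    positives_all: dict[str, frozenset[str]] = {}
    for disease, genes in assoc_by_disease.items():
        model_genes: set[str] = set()
        for g in genes:
            model_genes |= orthology[g]
        if model_genes:
            positives_all[disease] = frozenset(model_genes)

    sets: list[EvaluationSet] = []
    for cat in sorted(categories, key=lambda c: c.category):
        retained: list[str] = []
        for d in sorted(cat.disease_ids):
            if d not in assoc_by_disease:
                logger.info("category %s: %s excluded (no association)", cat.category, d)
            elif d not in positives_all:
                logger.info("category %s: %s excluded (no ortholog)", cat.category, d)
            else:
                retained.append(d)
        sets.append(
            EvaluationSet(
                category=cat.category,
                species=species,
                disease_ids=tuple(retained),
                positives={d: positives_all[d] for d in retained},
                evaluable=len(retained) >= min_size,
            )
        )
    return sets
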