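"""Synthetic two-species ontology worlds with planted cross-species signal.

The generator emulates the data regime of a phenotype-based disease gene
benchmark: a human-side and a model-side phenotype DAG cloned from one
template (so exact term equivalences exist), a bridge table covering a
configurable fraction of human terms (missing entries emulate absent
logical definitions), diseases annotated with human terms, true disease
genes whose animal-model profiles are noisy phenocopies of the disease
profile at a per-category fidelity, and decoy genes with unrelated
profiles.  Every draw is taken from one seeded generator, so a world is a
pure function of its configuration.

Model profiles of true genes are derived from the *template* counterpart
of the disease profile, not from the bridge: the biological correspondence
between species exists regardless of how complete the curated bridge is,
which is what lets an incomplete bridge degrade scoring without touching
the underlying signal.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .benchmark import (
    DiseaseCategoryAssignment,
    GeneDiseaseAssociation,
    OrthologyMap,
    load_associations,
    load_categories,
    load_orthology,
)
from .matching import ModelEntity, PhenotypeProfile
from .ontology import (
    BridgeMap,
    Ontology,
    Term,
    load_bridge,
    load_obo,
    write_bridge,
    write_obo,
)

_PREFIX = {"human": "HP", "mouse": "MP", "fish": "ZP"}

#: per-category phenotype fidelity of the default world: categories span the
#: well-modelled to poorly-modelled range seen in real cross-species use
DEFAULT_FIDELITY = {
    "urogenital": 0.9,
    "bone": 0.8,
    "cardiac": 0.65,
    "neurological": 0.5,
    "hepatic": 0.35,
}


def _prefix(species: str) -> str:
    return _PREFIX.get(species, species[:1].upper() + "P")


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Everything the generator needs; a world is a pure function of this."""

    master_seed: int = 0
    species: str = "mouse"  # mouse-like 1:1 orthology; "fish" adds duplicates
    n_terms: int = 150
    max_parents: int = 2
    edge_perturbation: float = 0.05
    bridge_coverage: float = 1.0
    n_diseases: int = 100
    n_true_genes: int | None = None  # default: one per disease
    n_decoy_genes: int = 100
    models_per_gene: int = 1
    profile_size: tuple[int, int] = (4, 8)
    per_category_fidelity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIDELITY)
    )
    co_assignment_prob: float = 0.1
    dropout: float = 1.0
    generalization: float = 0.1
    swap: float = 0.1
    fish_duplication_prob: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "edge_perturbation", "bridge_coverage", "co_assignment_prob",
            "dropout", "generalization", "swap", "fish_duplication_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for v in self.per_category_fidelity.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("fidelities must be in [0, 1]")
        lo, hi = self.profile_size
        if not (1 <= lo <= hi):
            raise ValueError("profile_size must satisfy 1 <= min <= max")
        if hi > self.n_terms - 1:
            raise ValueError("profile size exceeds number of non-root terms")
        if min(self.n_terms, self.n_diseases, self.models_per_gene) < 1:
            raise ValueError("counts must be positive")
        if not self.per_category_fidelity:
            raise ValueError("need at least one category")


@dataclass
class SyntheticWorld:
    """A complete generated (or loaded) two-species world."""

    config: SyntheticWorldConfig | None
    human_ontology: Ontology
    model_ontology: Ontology
    bridge: BridgeMap
    disease_profiles: dict[str, PhenotypeProfile]
    models: list[ModelEntity]
    associations: list[GeneDiseaseAssociation]
    orthology: OrthologyMap
    categories: list[DiseaseCategoryAssignment]
    disease_fidelity: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _template_parents(rng: np.random.Generator, n_terms: int, max_parents: int):
    """Random rooted DAG: term i>0 picks parents among earlier terms."""
    parents: list[tuple[int, ...]] = [()]
    for i in range(1, n_terms):
        k = min(i, int(rng.integers(1, max_parents + 1)))
        parents.append(tuple(sorted(rng.choice(i, size=k, replace=False).tolist())))
    return parents


def _build_ontology(
    parents: Sequence[tuple[int, ...]], species: str
) -> Ontology:
    pre = _prefix(species)
    ids = [f"{pre}:{i:07d}" for i in range(len(parents))]
    terms = [
        Term(ids[i], f"{species} phenotype {i}", frozenset(ids[p] for p in ps))
        for i, ps in enumerate(parents)
    ]
    return Ontology(terms, species=species)


def corrupt_profile(
    profile: frozenset[str] | set[str],
    fidelity: float,
    rates: tuple[float, float, float],
    rng: np.random.Generator,
    ontology: Ontology,
) -> frozenset[str]:
    """Noise model for an animal-model profile relative to its disease.

    Each term is kept with probability ``fidelity``; kept terms are
    generalised to a random parent with probability ``generalization`` or
    exchanged for a random sibling with probability ``swap`` (a phenotype
    observed imprecisely or at the wrong granularity).  A dropped term is
    replaced by a uniformly random ontology term with probability
    ``dropout`` (an unrelated phenotype recorded instead — models are
    phenotyped broadly) and removed otherwise.  An emptied profile is
    padded with the root.
    """
    dropout, generalization, swap = rates
    if not profile:
        raise ValueError("profile must be non-empty")
    non_root = ontology.non_root_terms()
    out: set[str] = set()
    for t in sorted(profile):
        if rng.random() < fidelity:
            u = rng.random()
            parents = sorted(ontology.parents(t))
            if u < generalization and parents:
                t = parents[int(rng.integers(len(parents)))]
            elif u < generalization + swap and parents:
                p = parents[int(rng.integers(len(parents)))]
                siblings = sorted(
                    c for c in ontology.terms
                    if p in ontology.parents(c) and c != t
                )
                if siblings:
                    t = siblings[int(rng.integers(len(siblings)))]
            out.add(t)
        elif rng.random() < dropout:
            out.add(non_root[int(rng.integers(len(non_root)))])
    if not out:
        out = {ontology.root}
    return frozenset(out)


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Build a full world deterministically from ``config.master_seed``."""
    rng = np.random.default_rng(config.master_seed)
    cfg = config

    # -- shared template, two species-specific clones ------------------------
    template = _template_parents(rng, cfg.n_terms, cfg.max_parents)
    human = _build_ontology(template, "human")
    model_parents = list(template)
    for i in range(2, cfg.n_terms):  # term 1 keeps the root parent
        if rng.random() < cfg.edge_perturbation:
            k = min(i, int(rng.integers(1, cfg.max_parents + 1)))
            model_parents[i] = tuple(
                sorted(rng.choice(i, size=k, replace=False).tolist())
            )
    model = _build_ontology(model_parents, cfg.species)
    hp, mp = _prefix("human"), _prefix(cfg.species)
    counterpart = {
        f"{hp}:{i:07d}": f"{mp}:{i:07d}" for i in range(cfg.n_terms)
    }

    # -- bridge: exact entries for a coverage fraction, root always ----------
    n_non_root = cfg.n_terms - 1
    n_mapped = int(round(cfg.bridge_coverage * n_non_root))
    mapped_idx = rng.choice(n_non_root, size=n_mapped, replace=False) + 1
    entries = {f"{hp}:0000000": {f"{mp}:0000000"}}
    for i in sorted(mapped_idx.tolist()):
        entries[f"{hp}:{i:07d}"] = {f"{mp}:{i:07d}"}
    bridge = BridgeMap("human", cfg.species, entries, human, model, strict=True)

    # -- categories and per-disease fidelity ---------------------------------
    cat_names = sorted(cfg.per_category_fidelity)
    disease_ids = [f"DISEASE:{i:05d}" for i in range(cfg.n_diseases)]
    cat_members: dict[str, set[str]] = {c: set() for c in cat_names}
    disease_fidelity: dict[str, float] = {}
    for d in disease_ids:
        assigned = [cat_names[int(rng.integers(len(cat_names)))]]
        if len(cat_names) > 1 and rng.random() < cfg.co_assignment_prob:
            extra = cat_names[int(rng.integers(len(cat_names)))]
            if extra not in assigned:
                assigned.append(extra)
        for c in assigned:
            cat_members[c].add(d)
        # a disease spanning categories inherits its best-modelled one
        disease_fidelity[d] = max(cfg.per_category_fidelity[c] for c in assigned)
    categories = [
        DiseaseCategoryAssignment(c, frozenset(cat_members[c])) for c in cat_names
    ]

    # -- disease profiles -----------------------------------------------------
    human_terms = human.non_root_terms()
    lo, hi = cfg.profile_size
    disease_profiles: dict[str, PhenotypeProfile] = {}
    for d in disease_ids:
        size = int(rng.integers(lo, hi + 1))
        terms = rng.choice(len(human_terms), size=size, replace=False)
        disease_profiles[d] = PhenotypeProfile(
            d, "disease", "human",
            frozenset(human_terms[i] for i in terms.tolist()),
            source="synthetic",
        )

    # -- true genes, orthology, associations, phenocopying models ------------
    n_true = cfg.n_true_genes if cfg.n_true_genes is not None else cfg.n_diseases
    models: list[ModelEntity] = []
    associations: list[GeneDiseaseAssociation] = []
    orthology: dict[str, frozenset[str]] = {}
    rates = (cfg.dropout, cfg.generalization, cfg.swap)
    for g in range(n_true):
        d = disease_ids[g % cfg.n_diseases]
        human_gene = f"GENE:H{g:05d}"
        model_genes = [f"GENE:{mp}{g:05d}"]
        if cfg.species == "fish" and rng.random() < cfg.fish_duplication_prob:
            model_genes.append(f"GENE:{mp}{g:05d}b")
        orthology[human_gene] = frozenset(model_genes)
        associations.append(GeneDiseaseAssociation(d, human_gene, "omim"))
        fidelity = disease_fidelity[d]
        image = frozenset(counterpart[t] for t in disease_profiles[d].terms)
        for j, mg in enumerate(model_genes):
            for m in range(cfg.models_per_gene):
                mid = f"MODEL:{mg.split(':', 1)[1]}-{m}"
                if j == 0:
                    terms = corrupt_profile(image, fidelity, rates, rng, model)
                else:
                    # the second duplicate does not phenocopy the disease
                    size = int(rng.integers(lo, hi + 1))
                    picks = rng.choice(len(model.non_root_terms()), size=size,
                                       replace=False)
                    mt = model.non_root_terms()
                    terms = frozenset(mt[i] for i in picks.tolist())
                models.append(
                    ModelEntity(
                        mid, mg, cfg.species,
                        PhenotypeProfile(mid, "model", cfg.species, terms,
                                         source="synthetic"),
                    )
                )

    # -- decoy genes with unrelated profiles ---------------------------------
    model_terms = model.non_root_terms()
    for g in range(cfg.n_decoy_genes):
        mg = f"GENE:{mp}D{g:05d}"
        for m in range(cfg.models_per_gene):
            mid = f"MODEL:{mp}D{g:05d}-{m}"
            size = int(rng.integers(lo, hi + 1))
            picks = rng.choice(len(model_terms), size=size, replace=False)
            terms = frozenset(model_terms[i] for i in picks.tolist())
            models.append(
                ModelEntity(
                    mid, mg, cfg.species,
                    PhenotypeProfile(mid, "model", cfg.species, terms,
                                     source="synthetic"),
                )
            )

    return SyntheticWorld(
        config=cfg,
        human_ontology=human,
        model_ontology=model,
        bridge=bridge,
        disease_profiles=disease_profiles,
        models=models,
        associations=associations,
        orthology=OrthologyMap(cfg.species, orthology),
        categories=categories,
        disease_fidelity=disease_fidelity,
    )


# ---------------------------------------------------------------------------
# Serialization (plain-text formats, reloadable by the benchmark loaders)
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, directory: str) -> None:
    """Write a world as OBO + TSV files plus a JSON provenance record."""
    os.makedirs(directory, exist_ok=True)
    os.makedirs(os.path.join(directory, "categories"), exist_ok=True)
    write_obo(world.human_ontology, os.path.join(directory, "human.obo"))
    write_obo(world.model_ontology, os.path.join(directory, "model.obo"))
    write_bridge(world.bridge, os.path.join(directory, "bridge.tsv"))

    def _write_annotations(path: str, profiles: Sequence[PhenotypeProfile]):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("entity_id\tterm_id\n")
            for p in sorted(profiles, key=lambda p: p.entity_id):
                for t in sorted(p.terms):
                    fh.write(f"{p.entity_id}\t{t}\n")

    _write_annotations(
        os.path.join(directory, "disease_phenotypes.tsv"),
        list(world.disease_profiles.values()),
    )
    _write_annotations(
        os.path.join(directory, "model_phenotypes.tsv"),
        [m.profile for m in world.models],
    )
    with open(os.path.join(directory, "models.tsv"), "w", encoding="utf-8") as fh:
        fh.write("model_id\tgene_id\n")
        for m in sorted(world.models, key=lambda m: m.model_id):
            fh.write(f"{m.model_id}\t{m.gene_id}\n")
    with open(os.path.join(directory, "associations.tsv"), "w", encoding="utf-8") as fh:
        fh.write("disease_id\tgene_id\tsource\n")
        for a in sorted(world.associations, key=lambda a: (a.disease_id, a.gene_id)):
            fh.write(f"{a.disease_id}\t{a.gene_id}\t{a.source}\n")
    with open(os.path.join(directory, "orthology.tsv"), "w", encoding="utf-8") as fh:
        fh.write("human_gene_id\tmodel_gene_id\n")
        for h in sorted(world.orthology.mapping):
            for m in sorted(world.orthology.mapping[h]):
                fh.write(f"{h}\t{m}\n")
    for cat in world.categories:
        with open(
            os.path.join(directory, "categories", f"{cat.category}.txt"),
            "w", encoding="utf-8",
        ) as fh:
            for d in sorted(cat.disease_ids):
                fh.write(d + "\n")
    meta = {
        "species": world.orthology.species,
        "config": _config_to_dict(world.config) if world.config else None,
        "disease_fidelity": dict(sorted(world.disease_fidelity.items())),
    }
    with open(os.path.join(directory, "world.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _config_to_dict(cfg: SyntheticWorldConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["profile_size"] = list(d["profile_size"])
    d["per_category_fidelity"] = dict(d["per_category_fidelity"])
    return d


def config_from_dict(d: Mapping) -> SyntheticWorldConfig:
    d = dict(d)
    if "profile_size" in d:
        d["profile_size"] = tuple(d["profile_size"])
    return SyntheticWorldConfig(**d)


def load_world(directory: str) -> SyntheticWorld:
    """Reload a serialized world; inverse of :func:`write_world`."""
    with open(os.path.join(directory, "world.json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    species = meta["species"]
    human = load_obo(os.path.join(directory, "human.obo"), species="human")
    model = load_obo(os.path.join(directory, "model.obo"), species=species)
    bridge = load_bridge(os.path.join(directory, "bridge.tsv"), human, model)

    def _read_annotations(path: str) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        with open(path, "r", encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                entity, term = line.rstrip("\n").split("\t")
                out.setdefault(entity, set()).add(term)
        return {k: frozenset(v) for k, v in out.items()}

    disease_terms = _read_annotations(
        os.path.join(directory, "disease_phenotypes.tsv")
    )
    model_terms = _read_annotations(
        os.path.join(directory, "model_phenotypes.tsv")
    )
    disease_profiles = {
        d: PhenotypeProfile(d, "disease", "human", terms, source="file")
        for d, terms in sorted(disease_terms.items())
    }
    models: list[ModelEntity] = []
    with open(os.path.join(directory, "models.tsv"), "r", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            mid, gene = line.rstrip("\n").split("\t")
            models.append(
                ModelEntity(
                    mid, gene, species,
                    PhenotypeProfile(mid, "model", species, model_terms[mid],
                                     source="file"),
                )
            )
    associations = load_associations([os.path.join(directory, "associations.tsv")])
    orthology = load_orthology(os.path.join(directory, "orthology.tsv"), species)
    categories = load_categories(os.path.join(directory, "categories"))
    cfg = config_from_dict(meta["config"]) if meta.get("config") else None
    return SyntheticWorld(
        config=cfg,
        human_ontology=human,
        model_ontology=model,
        bridge=bridge,
        disease_profiles=disease_profiles,
        models=models,
        associations=associations,
        orthology=orthology,
        categories=categories,
        disease_fidelity={
            k: float(v) for k, v in meta.get("disease_fidelity", {}).items()
        },
    )
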