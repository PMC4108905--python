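"""Category-stratified ROC/AUC evaluation with a random-set simulation null.

For one evaluation set, every (disease, gene, score) record across all its
diseases is pooled and a single ROC curve is swept over distinct score
thresholds: a gene truly associated to its disease counts as a positive at
ranks above the threshold, any other gene as a negative.  Significance of
the pooled AUC is assessed against a null distribution obtained by drawing
random disease sets of the same size from the full evaluable pool,
recomputing the pooled AUC per draw, and summarising the draws by mean and
standard deviation; the p-value is two-sided Gaussian, so categories
scoring far *below* the null mean are flagged as readily as those above.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .benchmark import EvaluationSet
from .matching import RankedCandidates

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class RocCurve:
    """Pooled ROC curve: (fpr, tpr) points from (0,0) to (1,1) plus the
    trapezoid AUC."""

    points: tuple[tuple[float, float], ...]
    auc: float


@dataclass(frozen=True)
class NullDistribution:
    category: str
    n_sim: int
    aucs: tuple[float, ...]
    mean: float
    sd: float
    seed: int
    degenerate: bool


@dataclass(frozen=True)
class CategoryEvaluation:
    """One result-table row: category AUC against its simulation null."""

    category: str
    species: str
    n_diseases: int
    auc: float | None
    null_mean: float | None
    null_sd: float | None
    z: float | None
    p: float | None
    significant: bool | None


# ---------------------------------------------------------------------------
# Pooled ROC
# ---------------------------------------------------------------------------

def _pool_records(
    rankings: Mapping[str, RankedCandidates],
    positives: Mapping[str, frozenset[str] | set[str]],
    diseases: Iterable[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    ids = list(diseases) if diseases is not None else list(rankings)
    scores: list[float] = []
    labels: list[bool] = []
    for d in ids:
        ranking = rankings[d]
        pos = positives.get(d, frozenset())
        for gene, pct, _model in ranking.entries:
            scores.append(pct)
            labels.append(gene in pos)
    return np.asarray(scores, dtype=float), np.asarray(labels, dtype=bool)


def pooled_roc(
    rankings: Mapping[str, RankedCandidates],
    positives: Mapping[str, frozenset[str] | set[str]],
    diseases: Iterable[str] | None = None,
) -> RocCurve:
    """Pool (gene, score, label) records over diseases and sweep distinct
    score thresholds descending.  Tied scores fall at the same threshold,
    so the curve (and its AUC, which matches the Mann–Whitney statistic
    with ties counted 1/2) is independent of record order."""
    scores, labels = _pool_records(rankings, positives, diseases)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError(
            f"pooled ROC needs >=1 positive and >=1 negative "
            f"(got {n_pos} positives, {n_neg} negatives)"
        )
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # last index of each distinct-score run
    distinct = np.r_[np.nonzero(np.diff(scores))[0], scores.size - 1]
    tps = np.cumsum(labels)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    points = tuple(zip(fpr.tolist(), tpr.tolist()))
    return RocCurve(points=points, auc=auc)


def auc_trapezoid(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoid-rule area under an ROC point sequence from (0,0) to (1,1)."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise EvaluationError("need >=2 (fpr, tpr) points")
    if tuple(arr[0]) != (0.0, 0.0) or tuple(arr[-1]) != (1.0, 1.0):
        raise EvaluationError("curve must start at (0,0) and end at (1,1)")
    if np.any(np.diff(arr[:, 0]) < 0) or np.any(np.diff(arr[:, 1]) < 0):
        raise EvaluationError("fpr and tpr must be non-decreasing")
    return float(np.trapezoid(arr[:, 1], arr[:, 0]))


def macro_average_auc(
    rankings: Mapping[str, RankedCandidates],
    positives: Mapping[str, frozenset[str] | set[str]],
    diseases: Iterable[str] | None = None,
) -> float:
    """Mean of per-disease AUCs (diseases lacking both classes are skipped);
    the alternative to pooled (micro-averaged) counting."""
    ids = list(diseases) if diseases is not None else list(rankings)
    per_disease: list[float] = []
    for d in ids:
        try:
            per_disease.append(pooled_roc(rankings, positives, [d]).auc)
        except EvaluationError:
            continue
    if not per_disease:
        raise EvaluationError("no disease with both positives and negatives")
    return float(np.mean(per_disease))


# ---------------------------------------------------------------------------
# Null simulation and p-values
# ---------------------------------------------------------------------------

def simulate_null(
    all_diseases: Sequence[str],
    set_size: int,
    n_sim: int,
    seed: int,
    rankings: Mapping[str, RankedCandidates],
    positives: Mapping[str, frozenset[str] | set[str]],
    category: str = "",
) -> NullDistribution:
    """AUC null distribution from ``n_sim`` random disease sets of size
    ``set_size`` drawn uniformly without replacement from the full pool
    (the evaluated category's own diseases are not excluded)."""
    if set_size > len(all_diseases):
        raise EvaluationError(
            f"set_size {set_size} exceeds pool of {len(all_diseases)} diseases"
        )
    if n_sim < 2:
        raise EvaluationError("n_sim must be >= 2")
    rng = np.random.default_rng(seed)
    pool = np.asarray(sorted(all_diseases))
    aucs = []
    for _ in range(n_sim):
        chosen = rng.choice(pool, size=set_size, replace=False)
        aucs.append(pooled_roc(rankings, positives, chosen.tolist()).auc)
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1))
    degenerate = sd <= 1e-12
    if degenerate:
        logger.warning("null for %r is degenerate (sd = 0)", category)
    return NullDistribution(
        category=category,
        n_sim=n_sim,
        aucs=tuple(aucs),
        mean=mean,
        sd=sd,
        seed=seed,
        degenerate=degenerate,
    )


def p_value(auc_obs: float, null: NullDistribution, method: str = "gaussian") -> float:
    """Two-sided p-value of an observed AUC against a simulation null.

    ``gaussian`` (default): ``2 * (1 - Phi(|auc - mean| / sd))``, clamped to
    (0, 1].  ``empirical``: add-one tail fraction of simulated AUCs at
    least as far from the null mean as the observation.
    """
    if method == "empirical":
        dev = abs(auc_obs - null.mean)
        exceed = sum(1 for a in null.aucs if abs(a - null.mean) >= dev - 1e-15)
        return (1 + exceed) / (1 + null.n_sim)
    if null.degenerate:
        raise EvaluationError(
            "degenerate null (sd = 0): increase n_sim or the disease pool"
        )
    z = abs(auc_obs - null.mean) / null.sd
    p = 2.0 * float(norm.sf(z))
    return min(1.0, max(p, math.ulp(0.0)))


def _category_seed(master_seed: int, species: str, category: str) -> int:
    digest = hashlib.sha256(
        f"{master_seed}:{species}:{category}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


ALL_DISEASES = "all diseases"


def evaluate_all(
    sets: Sequence[EvaluationSet],
    rankings: Mapping[str, RankedCandidates],
    n_sim: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[CategoryEvaluation]:
    """Produce one result row per (category, species) plus an
    'all diseases' row per species.

    Rows are sorted by category name; non-evaluable sets keep their place
    with absent AUC and p.  Per-category null seeds are derived
    deterministically from the master seed, species and category name.
    The pooled 'all diseases' row has no matched-size null (a random set of
    the whole pool is the pool itself), hence no p-value.
    """
    rows: list[CategoryEvaluation] = []
    for species in sorted({s.species for s in sets}):
        species_sets = sorted(
            (s for s in sets if s.species == species), key=lambda s: s.category
        )
        pool = sorted({d for s in species_sets for d in s.disease_ids})
        positives: dict[str, frozenset[str]] = {}
        for s in species_sets:
            for d, genes in s.positives.items():
                positives[d] = positives.get(d, frozenset()) | genes
        for s in species_sets:
            if not s.evaluable:
                rows.append(
                    CategoryEvaluation(
                        s.category, species, s.n_diseases,
                        None, None, None, None, None, None,
                    )
                )
                continue
            auc = pooled_roc(rankings, positives, s.disease_ids).auc
            null = simulate_null(
                pool,
                s.n_diseases,
                n_sim,
                _category_seed(seed, species, s.category),
                rankings,
                positives,
                category=s.category,
            )
            if null.degenerate:
                z = p = None
                significant = None
            else:
                z = (auc - null.mean) / null.sd
                p = p_value(auc, null)
                significant = p < alpha
            rows.append(
                CategoryEvaluation(
                    s.category, species, s.n_diseases,
                    auc, null.mean, null.sd, z, p, significant,
                )
            )
        if pool:
            overall = pooled_roc(rankings, positives, pool).auc
            rows.append(
                CategoryEvaluation(
                    ALL_DISEASES, species, len(pool),
                    overall, None, None, None, None, None,
                )
            )
    return rows
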