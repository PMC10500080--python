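"""Species-centric benchmark metrics: Fmax, weighted Fmax, Smin.

All scored predictions for one species are pooled into a single
non-redundant GO set: each term's score is the maximum score any protein
of the species achieved for it, and scores are propagated to ancestors
(a parent is at least as confident as its best descendant).  Ground truth
is ancestor-closed the same way.  Metrics then sweep a score threshold
tau; with P(tau) the predicted set and T the truth:

* precision = |P n T| / |P|,  recall = |P n T| / |T|
* Fmax   = max_tau harmonic mean of precision and recall
* wFmax  = same with set sizes replaced by sums of per-term information
  content (ic), so specific terms weigh more than generic ones
* ru(tau) = sum of ic over missed truth (T \\ P)   — remaining uncertainty
* mi(tau) = sum of ic over false predictions (P \\ T) — misinformation
* Smin   = min_tau sqrt(ru^2 + mi^2)

ic(term) = -log2((N_term + 1) / (N_root + 1)) with cumulative annotation
counts N from a reference corpus and +1 smoothing; namespace roots have
ic = 0 and are excluded from both prediction and truth sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constraints import ConstraintSet, FrequencyTable, expand_constraints
from .errors import DataError
from .ontology import OntologyGraph
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

MAX_THRESHOLDS = 101


@dataclass
class SpeciesPrediction:
    """One species' pooled, scored, non-redundant GO set."""

    taxon_id: int
    scores: dict[str, float] = field(default_factory=dict)

    def in_namespace(self, g: OntologyGraph, namespace: str) -> "SpeciesPrediction":
        return SpeciesPrediction(
            self.taxon_id,
            {
                go: s
                for go, s in self.scores.items()
                if go in g and g.get(go).namespace == namespace
            },
        )


@dataclass
class GroundTruth:
    """Ancestor-closed true GO sets for one species, keyed by namespace."""

    taxon_id: int
    terms: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class ICTable:
    """Per-term information content in bits."""

    ic: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, go_id: str) -> float:
        return self.ic[go_id]

    def get(self, go_id: str, default: float = 0.0) -> float:
        return self.ic.get(go_id, default)


@dataclass
class MetricCurve:
    """Threshold sweep of precision/recall and their ic-weighted variants."""

    thresholds: np.ndarray
    precision: np.ndarray  # NaN where nothing is predicted (skipped)
    recall: np.ndarray
    w_precision: np.ndarray
    w_recall: np.ndarray
    ru: np.ndarray
    mi: np.ndarray

    @staticmethod
    def _fmax(pr: np.ndarray, rc: np.ndarray) -> float:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = 2 * pr * rc / (pr + rc)
        f = f[np.isfinite(f)]
        return float(f.max()) if f.size else 0.0

    @property
    def fmax(self) -> float:
        return self._fmax(self.precision, self.recall)

    @property
    def wfmax(self) -> float:
        return self._fmax(self.w_precision, self.w_recall)

    @property
    def smin(self) -> float:
        return float(np.sqrt(self.ru**2 + self.mi**2).min())


# ---------------------------------------------------------------------------
# building blocks


def aggregate_species(
    protein_predictions, taxon_id: int, g: OntologyGraph, propagate: bool = True
) -> SpeciesPrediction:
    """Pool per-protein ``(protein, go_id, score)`` triples for one species.

    Each GO term keeps the highest score any protein achieved for it.
    With ``propagate`` (default), scores are then propagated to ancestors
    as the max over descendants.  Namespace roots and unknown terms are
    dropped.
    """
    best: dict[str, float] = {}
    for _protein, go_id, score in protein_predictions:
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise DataError(f"prediction score {score} outside [0, 1] for {go_id}")
        if go_id not in g:
            continue
        go_id = g.resolve(go_id)
        if g.get(go_id).obsolete or g.is_root(go_id):
            continue
        if score > best.get(go_id, -1.0):
            best[go_id] = score
    if propagate:
        closed: dict[str, float] = {}
        for go_id, score in best.items():
            for anc in g.ancestors_or_self(go_id):
                if not g.is_root(anc) and score > closed.get(anc, -1.0):
                    closed[anc] = score
        best = closed
    return SpeciesPrediction(taxon_id, best)


def close_truth(terms, g: OntologyGraph) -> dict[str, set[str]]:
    """Ancestor-close a raw truth term set and split it by namespace."""
    out: dict[str, set[str]] = {}
    for go_id in terms:
        if go_id not in g:
            continue
        for term in g.ancestors_or_self(g.resolve(go_id)):
            if g.is_root(term) or g.get(term).obsolete:
                continue
            out.setdefault(g.get(term).namespace, set()).add(term)
    return out


def apply_constraint_filter(
    sp: SpeciesPrediction, cs: ConstraintSet, g: OntologyGraph, t: TaxonomyTree
) -> SpeciesPrediction:
    """Drop every predicted term prohibited for the species; idempotent."""
    prohibited = expand_constraints(cs, g, t, sp.taxon_id)
    return SpeciesPrediction(
        sp.taxon_id, {go: s for go, s in sp.scores.items() if go not in prohibited}
    )


def information_content(global_ft: FrequencyTable, g: OntologyGraph) -> ICTable:
    """ic(term) = -log2((cum[term]+1) / (cum[namespace root]+1)), in bits."""
    if not global_ft.cumulative:
        raise DataError("cannot compute information content from an empty table")
    table = ICTable()
    for go_id, info in g.terms.items():
        if info.obsolete:
            continue
        root = g.roots.get(info.namespace)
        if root is None:
            continue
        n_root = global_ft.cumulative.get(root, 0)
        n_term = global_ft.cumulative.get(go_id, 0)
        table.ic[go_id] = -math.log2((n_term + 1) / (n_root + 1))
    return table


# ---------------------------------------------------------------------------
# the threshold sweep


def _threshold_grid(scores) -> np.ndarray:
    """Evaluation thresholds, descending.

    The distinct predicted scores (so ties are evaluated exactly at the
    score value) plus the standard 0.01-step sweep; when the distinct
    scores alone exceed ``MAX_THRESHOLDS`` the fixed 0.01 grid is used.
    """
    distinct = set(float(s) for s in scores)
    steps = set(np.round(np.arange(0.01, 1.01, 0.01), 2))
    grid = steps if len(distinct) > MAX_THRESHOLDS else distinct | steps
    return np.array(sorted(grid, reverse=True), dtype=float)


def metric_curve(sp: SpeciesPrediction, gt_terms: set, ic: ICTable) -> MetricCurve:
    """Sweep thresholds over one namespace's prediction against its truth.

    ``gt_terms`` is the ancestor-closed truth set for the same namespace.
    Thresholds where nothing is predicted contribute no precision point
    (coverage handling) but still define ru/mi.
    """
    if not gt_terms:
        raise DataError("ground truth is empty: metrics undefined")
    T = set(gt_terms)
    ic_T = sum(ic.get(t) for t in T)
    n_thr_src = sp.scores.values() if sp.scores else [1.0]
    taus = _threshold_grid(n_thr_src)

    pr = np.full(taus.shape, np.nan)
    rc = np.zeros(taus.shape)
    wpr = np.full(taus.shape, np.nan)
    wrc = np.zeros(taus.shape)
    ru = np.zeros(taus.shape)
    mi = np.zeros(taus.shape)

    items = sorted(sp.scores.items(), key=lambda kv: -kv[1])
    idx = 0
    P: set[str] = set()
    for i, tau in enumerate(taus):
        while idx < len(items) and items[idx][1] >= tau:
            P.add(items[idx][0])
            idx += 1
        inter = P & T
        ic_P = sum(ic.get(p) for p in P)
        ic_inter = sum(ic.get(x) for x in inter)
        if P:
            pr[i] = len(inter) / len(P)
            wpr[i] = ic_inter / ic_P if ic_P > 0 else (1.0 if not P - T else 0.0)
        rc[i] = len(inter) / len(T)
        wrc[i] = ic_inter / ic_T if ic_T > 0 else 0.0
        ru[i] = sum(ic.get(x) for x in T - P)
        mi[i] = sum(ic.get(x) for x in P - T)
    return MetricCurve(taus, pr, rc, wpr, wrc, ru, mi)


# ---------------------------------------------------------------------------
# file IO and the benchmark driver


def read_predictions(path):
    """Yield ``(protein, go_id, score)`` from a TSV prediction file."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith(("#", "!")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                fields = line.split()
            yield fields[0], fields[1], float(fields[2])


def load_ground_truth_gaf(path, g: OntologyGraph) -> dict[int, GroundTruth]:
    """Build per-species ancestor-closed truth sets from a GAF file."""
    from .goa import read_gaf

    raw: dict[int, set[str]] = {}
    for rec in read_gaf(path):
        if "NOT" in rec.qualifiers:
            continue
        raw.setdefault(rec.taxon_id, set()).add(rec.go_id)
    return {
        taxid: GroundTruth(taxid, close_truth(terms, g))
        for taxid, terms in raw.items()
    }


def evaluate_species(
    sp: SpeciesPrediction, gt: GroundTruth, ic: ICTable, g: OntologyGraph
) -> dict[str, MetricCurve]:
    """Metric curves per namespace for one species."""
    out: dict[str, MetricCurve] = {}
    for namespace, truth in gt.terms.items():
        if not truth:
            continue
        out[namespace] = metric_curve(sp.in_namespace(g, namespace), truth, ic)
    return out


def evaluate_benchmark(
    predictions: dict[int, object],
    truth: dict[int, GroundTruth],
    constraint_sets: dict[str, ConstraintSet],
    g: OntologyGraph,
    t: TaxonomyTree,
    ic: ICTable,
    propagate: bool = True,
) -> pd.DataFrame:
    """Fmax/wFmax/Smin per (species, namespace, filter).

    ``predictions`` maps taxid to a prediction file path or an iterable of
    ``(protein, go_id, score)``; ``constraint_sets`` maps a filter name to
    the constraint set applied under that name — the unfiltered run is
    always included as filter ``"unfilt"``.  Species missing from the
    truth are skipped with a warning.
    """
    rows = []
    for taxid, source in predictions.items():
        if taxid not in truth:
            logger.warning("species %s absent from ground truth: skipped", taxid)
            continue
        triples = (
            read_predictions(source)
            if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__")
            else source
        )
        sp = aggregate_species(triples, taxid, g, propagate=propagate)
        variants: dict[str, SpeciesPrediction] = {"unfilt": sp}
        for name, cs in constraint_sets.items():
            variants[name] = apply_constraint_filter(sp, cs, g, t)
        for filt, variant in variants.items():
            for namespace, curve in evaluate_species(variant, truth[taxid], ic, g).items():
                rows.append(
                    {
                        "species": taxid,
                        "namespace": namespace,
                        "filter": filt,
                        "fmax": curve.fmax,
                        "wfmax": curve.wfmax,
                        "smin": curve.smin,
                    }
                )
    return pd.DataFrame(rows, columns=["species", "namespace", "filter", "fmax", "wfmax", "smin"])
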