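"""Coverage+GC feature space, PCA projection, DBSCAN seeding and SVM label
propagation — the scaffold binning core.

The feature vector of a scaffold is ``log10(coverage_s + pseudocount)`` for
each sample ``s`` plus the G+C fraction. Columns are standardised to zero
mean and unit spread over the included scaffolds; the GC column may be
re-weighted to tune its influence relative to the coverage columns. The top
three principal components of this space form the "galaxy" in which long
scaffolds (> 5 kbp by default) are clustered with DBSCAN; cluster labels are
then propagated to the remaining scaffolds (> 1.5 kbp) with an RBF-kernel
support vector classifier gated on calibrated confidence. Long scaffolds
DBSCAN marks as noise go to a ``background`` recruitment bin; low-confidence
propagations stay ``unbinned``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .io import ScaffoldRecord

logger = logging.getLogger(__name__)

NOISE = -1  # DBSCAN noise sentinel

__all__ = [
    "NOISE",
    "FeatureMatrix",
    "Projection",
    "ClusterLabels",
    "BinAssignment",
    "GridPoint",
    "TuningResult",
    "compute_gc",
    "build_feature_matrix",
    "project_top_components",
    "cluster_training_scaffolds",
    "propagate_bin_labels",
    "tune_clustering",
]


def compute_gc(sequence: str) -> float:
    """G+C fraction over unambiguous bases; N and IUPAC codes are excluded
    from the denominator. All-ambiguous or empty sequences are an error."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return gc / (gc + at)


@dataclass
class FeatureMatrix:
    """Scaled per-scaffold feature matrix (log-coverage columns + GC)."""

    scaffold_ids: list[str]
    lengths: np.ndarray
    features: np.ndarray  # rows = scaffolds, scaled
    column_names: list[str]
    center: np.ndarray
    spread: np.ndarray
    gc_weight: float = 1.0
    pseudocount: float = 1.0


def build_feature_matrix(
    scaffolds: list[ScaffoldRecord],
    min_len: int = 1500,
    pseudocount: float = 1.0,
    gc_weight: float = 1.0,
) -> FeatureMatrix:
    """Build the standardized log10-coverage + GC feature matrix for all
    scaffolds longer than ``min_len``.

    Each column is centred and scaled to unit spread over the included
    scaffolds; the GC column is then multiplied by ``gc_weight``. A
    zero-variance column keeps spread 1 (with a warning) rather than
    dividing by zero.
    """
    kept = [s for s in scaffolds if s.length_bp > min_len]
    if not kept:
        raise ValueError(f"no scaffolds longer than {min_len} bp")
    for s in kept:
        if s.coverage is None:
            raise ValueError(f"scaffold {s.scaffold_id!r} has no coverage vector")
        if s.gc is None:
            s.gc = compute_gc(s.sequence)
    n_samples = len(kept[0].coverage)
    cov = np.vstack([s.coverage for s in kept])
    raw = np.column_stack([np.log10(cov + pseudocount), [s.gc for s in kept]])
    center = raw.mean(axis=0)
    spread = raw.std(axis=0)
    zero = spread < 1e-12
    if zero.any():
        logger.warning("%d zero-variance feature column(s); spread set to 1", zero.sum())
        spread = np.where(zero, 1.0, spread)
    scaled = (raw - center) / spread
    scaled[:, -1] *= gc_weight
    names = [f"log_cov_{i}" for i in range(n_samples)] + ["gc"]
    return FeatureMatrix(
        scaffold_ids=[s.scaffold_id for s in kept],
        lengths=np.array([s.length_bp for s in kept]),
        features=scaled,
        column_names=names,
        center=center,
        spread=spread,
        gc_weight=gc_weight,
        pseudocount=pseudocount,
    )


@dataclass
class Projection:
    """Principal-component projection of a feature matrix.

    The component basis is fitted on scaffolds longer than ``fit_min_len``
    (the DBSCAN training set) so that both training and to-be-propagated
    scaffolds live in the same galaxy coordinates. Component signs are fixed
    so each component's largest-magnitude loading is positive.
    """

    scaffold_ids: list[str]
    lengths: np.ndarray
    components: np.ndarray  # (k, n_features)
    explained_variance: np.ndarray
    projected: np.ndarray  # (n_scaffolds, k)
    fit_min_len: int | None = None

    @property
    def train_mask(self) -> np.ndarray:
        if self.fit_min_len is None:
            return np.ones(len(self.scaffold_ids), dtype=bool)
        return self.lengths > self.fit_min_len


def project_top_components(
    fm: FeatureMatrix, k: int = 3, fit_min_len: int | None = None
) -> Projection:
    """Project onto the top-k principal components (k=3 by default)."""
    n_feat = fm.features.shape[1]
    if k > n_feat:
        raise ValueError(f"k={k} exceeds feature count {n_feat}")
    if fit_min_len is not None:
        fit_rows = fm.features[fm.lengths > fit_min_len]
        if fit_rows.shape[0] < k:
            raise ValueError("too few scaffolds above fit_min_len to fit PCA")
    else:
        fit_rows = fm.features
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(fit_rows)
    comps = pca.components_.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    projected = (fm.features - pca.mean_) @ comps.T
    return Projection(
        scaffold_ids=list(fm.scaffold_ids),
        lengths=fm.lengths.copy(),
        components=comps,
        explained_variance=pca.explained_variance_.copy(),
        projected=projected,
        fit_min_len=fit_min_len,
    )


@dataclass
class ClusterLabels:
    """DBSCAN labels over training scaffolds: 1..K by descending size, NOISE=-1."""

    labels: dict[str, int]
    eps: float
    min_samples: int
    min_train_len: int = 5000

    @property
    def n_clusters(self) -> int:
        return len({v for v in self.labels.values() if v != NOISE})

    @property
    def n_noise(self) -> int:
        return sum(1 for v in self.labels.values() if v == NOISE)


def cluster_training_scaffolds(
    proj: Projection, eps: float, min_samples: int, min_train_len: int = 5000
) -> ClusterLabels:
    """DBSCAN the projected training scaffolds (> min_train_len bp).

    Cluster labels are renumbered 1..K by descending member count for stable
    reporting; noise keeps the sentinel ``NOISE`` (-1).
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    mask = proj.lengths > min_train_len
    ids = [sid for sid, m in zip(proj.scaffold_ids, mask) if m]
    if not ids:
        raise ValueError(f"no scaffolds above min_train_len={min_train_len}")
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(proj.projected[mask])
    sizes = pd.Series(raw[raw >= 0]).value_counts()
    # descending size, ties by original label for determinism
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = {
        sid: (NOISE if lab < 0 else remap[lab]) for sid, lab in zip(ids, raw)
    }
    return ClusterLabels(labels, eps=eps, min_samples=min_samples, min_train_len=min_train_len)


@dataclass
class BinAssignment:
    """Final scaffold -> bin mapping with provenance and confidence."""

    table: pd.DataFrame  # scaffold_id, bin_label, provenance, confidence

    def labels_for(self, scaffold_ids: list[str]) -> pd.Series:
        return self.table.set_index("scaffold_id")["bin_label"].reindex(scaffold_ids)

    @property
    def bin_labels(self) -> list[str]:
        return sorted(
            {b for b in self.table["bin_label"] if b.startswith("bin:")},
            key=lambda b: int(b.split(":")[1]),
        )

    def members(self, bin_label: str) -> list[str]:
        return self.table.loc[self.table["bin_label"] == bin_label, "scaffold_id"].tolist()


def _class_confidences(clf, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted label and confidence per row.

    Uses Platt-calibrated probabilities when the classifier provides them;
    otherwise a softmax over the decision margins.
    """
    classes = clf.classes_
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(X)
    else:
        dec = clf.decision_function(X)
        if dec.ndim == 1:  # binary
            dec = np.column_stack([-dec, dec])
        proba = softmax(dec, axis=1)
    best = np.argmax(proba, axis=1)
    return classes[best], proba[np.arange(len(best)), best]


def propagate_bin_labels(
    labels: ClusterLabels,
    proj: Projection,
    min_class_len: int = 1500,
    conf_threshold: float = 0.5,
    svm_c: float = 1.0,
    svm_gamma: str | float = "scale",
    seed: int = 0,
) -> BinAssignment:
    """Propagate DBSCAN cluster labels to non-training scaffolds with an SVM.

    Training scaffolds keep their cluster label (``provenance=trained``);
    noise training scaffolds become ``background``. Other scaffolds longer
    than ``min_class_len`` get the classifier's label when its confidence
    reaches ``conf_threshold``, else ``unbinned``.
    """
    lab_map = labels.labels
    train_ids = [sid for sid, lab in lab_map.items() if lab != NOISE]
    if not train_ids:
        raise ValueError("no non-noise training scaffolds to propagate from")
    idx = {sid: i for i, sid in enumerate(proj.scaffold_ids)}
    X_train = proj.projected[[idx[sid] for sid in train_ids]]
    y_train = np.array([lab_map[sid] for sid in train_ids])
    n_classes = len(set(y_train))
    single_cluster = n_classes < 2

    min_class_size = int(pd.Series(y_train).value_counts().min())
    use_proba = min_class_size >= 5 and not single_cluster
    clf = None
    if not single_cluster:
        base = SVC(kernel="rbf", C=svm_c, gamma=svm_gamma, random_state=seed)
        if use_proba:
            # Platt-calibrated confidences; needs >= cv members per class
            clf = CalibratedClassifierCV(base, ensemble=False, cv=5)
        else:
            clf = base
            logger.info(
                "smallest cluster has %d member(s); using margin softmax "
                "instead of Platt calibration", min_class_size,
            )
        clf.fit(X_train, y_train)
    else:
        logger.warning("single-cluster training set; propagation gated on distance")

    rows = []
    to_predict: list[int] = []
    for i, sid in enumerate(proj.scaffold_ids):
        if sid in lab_map:
            lab = lab_map[sid]
            if lab == NOISE:
                rows.append((sid, "background", "trained", 1.0))
            else:
                rows.append((sid, f"bin:{lab}", "trained", 1.0))
        elif proj.lengths[i] > min_class_len:
            to_predict.append(i)
        else:
            rows.append((sid, "unbinned", "propagated", 0.0))

    if to_predict:
        X = proj.projected[to_predict]
        if single_cluster:
            only = int(y_train[0])
            # confidence via an RBF similarity to the lone cluster centre
            centre = X_train.mean(axis=0)
            d2 = ((X - centre) ** 2).sum(axis=1)
            scale = max(np.median(((X_train - centre) ** 2).sum(axis=1)), 1e-12)
            conf = np.exp(-d2 / (2 * scale))
            pred = np.full(len(to_predict), only)
        else:
            pred, conf = _class_confidences(clf, X)
        for i, p, c in zip(to_predict, pred, conf):
            sid = proj.scaffold_ids[i]
            if c >= conf_threshold:
                rows.append((sid, f"bin:{int(p)}", "propagated", float(c)))
            else:
                rows.append((sid, "unbinned", "propagated", float(c)))

    table = pd.DataFrame(rows, columns=["scaffold_id", "bin_label", "provenance", "confidence"])
    # preserve projection order
    order = {sid: i for i, sid in enumerate(proj.scaffold_ids)}
    table = table.sort_values("scaffold_id", key=lambda s: s.map(order)).reset_index(drop=True)
    return BinAssignment(table)


@dataclass(frozen=True)
class GridPoint:
    eps: float
    min_samples: int = 5
    gc_weight: float = 1.0


@dataclass
class TuningResult:
    """Grid search over (eps, min_samples, gc_weight) maximising
    mean bin completeness − lambda * mean bin duplication."""

    table: pd.DataFrame  # eps, min_samples, gc_weight, objective, n_clusters, n_noise
    best: GridPoint
    best_objective: float
    best_assignment: BinAssignment


def tune_clustering(
    grid: list[GridPoint],
    scaffolds: list[ScaffoldRecord],
    marker_hits: pd.DataFrame,
    universe,
    lambda_: float = 1.0,
    min_train_len: int = 5000,
    min_class_len: int = 1500,
    conf_threshold: float = 0.5,
    pseudocount: float = 1.0,
    n_components: int = 3,
    seed: int = 0,
) -> TuningResult:
    """Run cluster -> propagate -> marker QC for each grid point and return
    the argmax of mean completeness − lambda·mean duplication (over bins
    holding at least one marker). Ties break toward fewer noise scaffolds,
    then smaller eps.
    """
    from .quality import MarkerUniverse, assess_bin_quality

    if not grid:
        raise ValueError("empty tuning grid")
    if universe is None:
        universe = MarkerUniverse(frozenset(marker_hits["marker_gene_id"]))
    by_id = {s.scaffold_id: s for s in scaffolds}
    records = []
    results: dict[GridPoint, BinAssignment] = {}
    for pt in grid:
        fm = build_feature_matrix(
            scaffolds, min_len=min_class_len,
            pseudocount=pseudocount, gc_weight=pt.gc_weight,
        )
        proj = project_top_components(fm, k=n_components, fit_min_len=min_train_len)
        try:
            cl = cluster_training_scaffolds(
                proj, eps=pt.eps, min_samples=pt.min_samples, min_train_len=min_train_len
            )
            if cl.n_clusters < 2:
                raise ValueError("fewer than 2 clusters")
            assignment = propagate_bin_labels(
                cl, proj, min_class_len=min_class_len,
                conf_threshold=conf_threshold, seed=seed,
            )
        except ValueError as exc:
            logger.info("grid point %s failed: %s", pt, exc)
            records.append((pt.eps, pt.min_samples, pt.gc_weight, -np.inf, 0, 0))
            continue
        comp, dup = [], []
        for label in assignment.bin_labels:
            members = [by_id[sid] for sid in assignment.members(label) if sid in by_id]
            q = assess_bin_quality(members, marker_hits, universe, bin_label=label)
            if q.ess_found > 0:
                comp.append(q.completeness)
                dup.append(q.duplication)
        objective = (np.mean(comp) - lambda_ * np.mean(dup)) if comp else -np.inf
        records.append(
            (pt.eps, pt.min_samples, pt.gc_weight, objective, cl.n_clusters, cl.n_noise)
        )
        results[pt] = assignment

    table = pd.DataFrame(
        records,
        columns=["eps", "min_samples", "gc_weight", "objective", "n_clusters", "n_noise"],
    )
    if not results:
        raise ValueError("all grid points yielded fewer than 2 clusters")
    # argmax objective; ties -> fewer noise scaffolds -> smaller eps
    valid = table[np.isfinite(table["objective"])]
    ranked = valid.sort_values(
        ["objective", "n_noise", "eps"], ascending=[False, True, True]
    )
    top = ranked.iloc[0]
    best = next(
        pt for pt in grid
        if pt.eps == top["eps"] and pt.min_samples == top["min_samples"]
        and pt.gc_weight == top["gc_weight"]
    )
    return TuningResult(
        table=table, best=best, best_objective=float(top["objective"]),
        best_assignment=results[best],
    )
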