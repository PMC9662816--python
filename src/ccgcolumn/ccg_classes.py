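"""Shape-based classification of significant correlograms.

Significant corrected CCGs are restricted to lags −10…+10 ms (21 features),
z-scored per curve, embedded to 3 dimensions with t-SNE, and clustered with
k-means.  Cluster count is selected from the explained-variance (elbow) and
silhouette curves; clusters receive semantic labels from their mean-curve
templates:

- ``S_sync``  — narrow peak at lag 0
- ``B_sync``  — wide peak at lag 0
- ``F_async`` — probability mass shifted to positive lags (reference leads)
- ``R_async`` — mirror image (reference lags)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score as _sk_silhouette

from .correlogram import CcgSet

logger = logging.getLogger(__name__)

CLASS_LABELS = ("S_sync", "B_sync", "F_async", "R_async")
FEATURE_LAG_MS = 10
SHARP_WIDTH_MS = 4.0


@dataclass
class CcgFeatureMatrix:
    """Z-scored 21-lag feature rows, both orderings of every significant pair."""

    features: np.ndarray  # (n_rows, 21)
    pair_index: pd.DataFrame  # ref_unit, target_unit per row
    lags_ms: np.ndarray


@dataclass
class ClusterEvaluation:
    k: int
    labels: np.ndarray
    tss: float
    wcss: float
    eta: float
    silhouette: float = np.nan


def normalize_ccgs(ccg_set: CcgSet, feature_lag_ms: int = FEATURE_LAG_MS) -> CcgFeatureMatrix:
    """Build the feature matrix from the significant subset of a CcgSet.

    Both orderings of each significant pair are included (the mirrored
    ordering is the lag-reversed curve), then each row is z-scored so
    clustering sees shape rather than magnitude.  Zero-variance rows are
    dropped with a warning.
    """
    sig = ccg_set.significant
    if len(sig) < 2:
        raise ValueError("need at least 2 significant CCGs to build features")
    central = np.abs(ccg_set.lags_ms) <= feature_lag_ms + 1e-9
    lags = ccg_set.lags_ms[central]
    rows, index = [], []
    for _, rec in sig.iterrows():
        ref, tgt = int(rec["ref_unit"]), int(rec["target_unit"])
        curve = ccg_set.curve(ref, tgt)[central]
        for r, t, c in ((ref, tgt, curve), (tgt, ref, curve[::-1])):
            sd = c.std(ddof=0)
            if sd == 0:
                logger.warning("dropping zero-variance CCG row %d-%d", r, t)
                continue
            rows.append((c - c.mean()) / sd)
            index.append((r, t))
    return CcgFeatureMatrix(
        features=np.asarray(rows),
        pair_index=pd.DataFrame(index, columns=["ref_unit", "target_unit"]),
        lags_ms=lags,
    )


def embed(
    features: np.ndarray,
    out_dims: int = 3,
    seed: int = 0,
    perplexity: float = 30.0,
    max_iter: int = 1000,
) -> np.ndarray:
    """t-SNE embedding of the feature rows; deterministic for a fixed seed."""
    n = len(features)
    if n < out_dims + 1:
        raise ValueError(f"need at least {out_dims + 1} rows, got {n}")
    perplexity = min(perplexity, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=out_dims,
        perplexity=perplexity,
        max_iter=max_iter,
        init="pca",
        random_state=seed,
        method="barnes_hut" if out_dims <= 3 else "exact",
    )
    return tsne.fit_transform(np.asarray(features, dtype=np.float64))


def cluster_kmeans(
    embedding: np.ndarray,
    k_range=range(1, 11),
    replicates: int = 50,
    max_iter: int = 100,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Best-of-replicates k-means labels per k (lowest within-cluster SS)."""
    labels = {}
    n = len(embedding)
    for k in k_range:
        if k > n:
            logger.warning("skipping k=%d > %d points", k, n)
            continue
        km = KMeans(
            n_clusters=k, n_init=replicates, max_iter=max_iter, random_state=seed
        ).fit(embedding)
        labels[k] = km.labels_.copy()
    return labels


def explained_variance(points: np.ndarray, labels: np.ndarray) -> ClusterEvaluation:
    """η = (TSS − WCSS)/TSS with squared Euclidean norms.

    Every cluster id present in ``labels`` must be nonempty by construction;
    an explicit check guards against label relabelling bugs upstream.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    centroid = points.mean(axis=0)
    tss = float(((points - centroid) ** 2).sum())
    wcss = 0.0
    for c in ks:
        members = points[labels == c]
        if len(members) == 0:
            raise ValueError(f"empty cluster {c}")
        wcss += float(((members - members.mean(axis=0)) ** 2).sum())
    eta = 0.0 if tss == 0 else (tss - wcss) / tss
    return ClusterEvaluation(k=len(ks), labels=labels, tss=tss, wcss=wcss, eta=eta)


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient (Euclidean); NaN for degenerate inputs."""
    k = len(np.unique(labels))
    n = len(points)
    if k < 2 or k >= n:
        return np.nan
    try:
        return float(_sk_silhouette(points, labels, metric="euclidean"))
    except ValueError:
        return np.nan


def evaluate_clusterings(points: np.ndarray, labels_per_k: dict) -> pd.DataFrame:
    rows = []
    for k, lab in sorted(labels_per_k.items()):
        ev = explained_variance(points, lab)
        rows.append(dict(k=k, eta=ev.eta, silhouette=silhouette(points, lab)))
    return pd.DataFrame(rows)


def select_k(evaluation: pd.DataFrame, tol: float = 0.02) -> int:
    """Among k whose silhouette is within ``tol`` of the maximum, pick the one
    with the largest explained variance (tie-break toward more structure)."""
    ev = evaluation.dropna(subset=["silhouette"])
    if not len(ev):
        raise ValueError("no clustering with a defined silhouette")
    best = ev["silhouette"].max()
    near = ev[ev["silhouette"] >= best - tol]
    return int(near.loc[near["eta"].idxmax(), "k"])


def half_width_ms(curve: np.ndarray, lags_ms: np.ndarray) -> float:
    """Full width at half height of the dominant peak, by linear interpolation.

    Height is measured from the curve minimum (robust for z-scored templates
    whose baseline is negative).
    """
    i_peak = int(np.argmax(curve))
    base = float(curve.min())
    half = base + 0.5 * (curve[i_peak] - base)
    # walk left
    left = lags_ms[0]
    for i in range(i_peak, 0, -1):
        if curve[i - 1] < half:
            frac = (curve[i] - half) / (curve[i] - curve[i - 1])
            left = lags_ms[i] - frac * (lags_ms[i] - lags_ms[i - 1])
            break
    right = lags_ms[-1]
    for i in range(i_peak, len(curve) - 1):
        if curve[i + 1] < half:
            frac = (curve[i] - half) / (curve[i] - curve[i + 1])
            right = lags_ms[i] + frac * (lags_ms[i + 1] - lags_ms[i])
            break
    return float(right - left)


def classify_template(
    template: np.ndarray,
    lags_ms: np.ndarray,
    sharp_width_ms: float = SHARP_WIDTH_MS,
    sync_lag_ms: float = 1.0,
) -> str:
    """Semantic label of a template curve.

    Peak within ±``sync_lag_ms`` of zero → synchronous, split sharp/broad by
    full width at half maximum; otherwise forward/reverse by the side of the
    peak (falling back to the sign of the mass asymmetry).
    """
    if np.allclose(template, template[0]):
        return "unclassified"
    peak_lag = float(lags_ms[np.argmax(template)])
    if abs(peak_lag) <= sync_lag_ms:
        width = half_width_ms(template, lags_ms)
        return "S_sync" if width < sharp_width_ms else "B_sync"
    if peak_lag > sync_lag_ms:
        return "F_async"
    return "R_async"


@dataclass
class ClassAssignment:
    """Clustered, semantically labelled CCG classes."""

    evaluation: pd.DataFrame
    k: int
    templates: pd.DataFrame  # cluster_id, class_label + template curves
    template_curves: dict = field(default_factory=dict)
    per_row: pd.DataFrame | None = None  # ref/target/cluster/class per feature row
    per_pair: pd.DataFrame | None = None  # one random reference ordering per pair


def class_templates(
    features: CcgFeatureMatrix,
    labels: np.ndarray,
    sharp_width_ms: float = SHARP_WIDTH_MS,
) -> tuple[pd.DataFrame, dict]:
    """Mean z-scored curve per cluster and its semantic label."""
    rows, curves = [], {}
    for c in np.unique(labels):
        template = features.features[labels == c].mean(axis=0)
        label = classify_template(template, features.lags_ms, sharp_width_ms)
        if label == "unclassified":
            logger.warning("cluster %d template is flat; labelled unclassified", c)
        rows.append(dict(cluster_id=int(c), class_label=label, n=int((labels == c).sum())))
        curves[int(c)] = template
    return pd.DataFrame(rows), curves


def assign_classes(
    ccg_set: CcgSet,
    seed: int = 0,
    k_range=range(1, 11),
    tol: float = 0.02,
    perplexity: float = 30.0,
    force_k: int | None = None,
    sharp_width_ms: float = SHARP_WIDTH_MS,
) -> ClassAssignment:
    """Full classification stage: features → t-SNE → k-means → labels.

    The per-pair class uses one seeded random choice of reference ordering,
    so each significant pair gets exactly one label.
    """
    features = normalize_ccgs(ccg_set)
    emb = embed(features.features, seed=seed, perplexity=perplexity)
    labels_per_k = cluster_kmeans(emb, k_range=k_range, seed=seed)
    evaluation = evaluate_clusterings(emb, labels_per_k)
    k = force_k if force_k is not None else select_k(evaluation, tol=tol)
    labels = labels_per_k[k]
    templates, curves = class_templates(features, labels, sharp_width_ms=sharp_width_ms)
    class_of_cluster = templates.set_index("cluster_id")["class_label"]

    per_row = features.pair_index.copy()
    per_row["cluster_id"] = labels
    per_row["class_label"] = per_row["cluster_id"].map(class_of_cluster)

    rng = np.random.default_rng(seed)
    rows = []
    seen = set()
    for i in range(len(per_row)):
        ref, tgt = int(per_row["ref_unit"].iat[i]), int(per_row["target_unit"].iat[i])
        key = frozenset((ref, tgt))
        if key in seen:
            continue
        seen.add(key)
        # candidate rows: the two orderings of this pair
        cand = per_row[
            ((per_row["ref_unit"] == ref) & (per_row["target_unit"] == tgt))
            | ((per_row["ref_unit"] == tgt) & (per_row["target_unit"] == ref))
        ]
        pick = cand.iloc[int(rng.integers(len(cand)))]
        rows.append(
            dict(
                ref_unit=int(pick["ref_unit"]),
                target_unit=int(pick["target_unit"]),
                cluster_id=int(pick["cluster_id"]),
                class_label=pick["class_label"],
            )
        )
    per_pair = pd.DataFrame(rows)
    return ClassAssignment(
        evaluation=evaluation,
        k=k,
        templates=templates,
        template_curves=curves,
        per_row=per_row,
        per_pair=per_pair,
    )


def monosynaptic_candidate(
    corrected_curve: np.ndarray,
    lags_ms: np.ndarray,
    peak_lag_ms: float,
    max_width_ms: float = 5.0,
    feature_lag_ms: int = FEATURE_LAG_MS,
) -> bool:
    """Sharp, narrow, non-zero-lag criterion for putative monosynapses.

    True iff the corrected-CCG peak width at half height is below
    ``max_width_ms`` and the peak lag is nonzero.
    """
    if peak_lag_ms == 0:
        return False
    central = np.abs(lags_ms) <= feature_lag_ms + 1e-9
    width = half_width_ms(corrected_curve[central], lags_ms[central])
    return width < max_width_ms
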