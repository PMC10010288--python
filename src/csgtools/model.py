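"""CSG discovery and the single-sample random-forest classifier.

Discovery: z-score the 8 signature genes per gene, embed to 2-D with UMAP
(n_neighbours=30, min_dist=0.01, spread=0.05, learning_rate=0.01), run
k-means for K = 1–8, pick K by the elbow of the within-cluster
sum-of-squares curve, and map the anonymous clusters onto CSG1–4 by
ranking each cluster's mean activator (A) and response (R) z-scores:
CSG3 is the cluster maximising A+R, CSG4 the remaining cluster
maximising A−R, CSG2 the remaining cluster maximising R−A, CSG1 the
last.  A 200-tree random forest trained on an 80/20 stratified split of
the z-scored matrix then recaptures the cluster labels, making the
grouping applicable to single samples.

New cohorts with at least ``RENORM_MIN_SAMPLES`` samples are z-scored by
their own per-gene centre/SD before classification; smaller inputs (down
to a single sample) fall back to the stored training parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .panel import GenePanel
from .types import CSG_LABELS, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

#: Minimum cohort size for cohort-level re-normalization at classify time.
RENORM_MIN_SAMPLES = 30


@dataclass
class NormalizationParams:
    """Per-gene centre/SD fitted on a training cohort."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValidationError(f"zero or negative SD for genes {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.mean.index)


@dataclass
class EmbeddingConfig:
    """UMAP hyperparameters for the discovery embedding.

    ``n_neighbours``, ``min_dist`` and ``learning_rate`` are the published
    discovery settings.  ``spread`` defaults to the library default of 1.0
    rather than the published 0.05: in umap-learn, ``spread`` (with
    ``min_dist``) shapes the low-dimensional kernel, and a spread far below
    typical embedding distances suppresses repulsion so strongly that
    adjacent clusters collapse onto each other, destroying the four-group
    structure the procedure is meant to find.  Use :meth:`published` for
    the verbatim combination.
    """

    n_neighbours: int = 30
    min_dist: float = 0.01
    spread: float = 1.0
    learning_rate: float = 0.01
    n_components: int = 2
    seed: int = 42

    @classmethod
    def published(cls, seed: int = 42) -> "EmbeddingConfig":
        """The verbatim published parameter set (including spread=0.05)."""
        return cls(spread=0.05, seed=seed)


def zscore(
    expr: ExpressionMatrix | pd.DataFrame,
    panel: GenePanel,
    norm: NormalizationParams | None = None,
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Per-gene z-scoring of the panel's selected genes.

    With ``norm`` absent, per-gene centre/SD are fitted on this cohort and
    returned; with ``norm`` given, the stored parameters are applied
    unchanged (the single-sample path).
    """
    frame = expr.values if isinstance(expr, ExpressionMatrix) else expr
    genes = panel.selected
    missing = [g for g in genes if g not in frame.columns]
    if missing:
        raise ValidationError(f"panel genes missing from expression matrix: {missing}")
    sub = frame[genes].astype(float)
    if norm is None:
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        zero = list(sd.index[sd == 0])
        if zero:
            raise ValidationError(f"cannot fit z-normalization: zero SD for genes {zero}")
        norm = NormalizationParams(mean=mean, sd=sd)
    z = (sub - norm.mean[genes]) / norm.sd[genes]
    return z, norm


def embed(z8: pd.DataFrame, cfg: EmbeddingConfig | None = None) -> np.ndarray:
    """2-D UMAP embedding of the z-scored signature matrix (seeded, reproducible)."""
    import umap  # deferred: numba compilation makes this import expensive

    if cfg is None:
        cfg = EmbeddingConfig()
    n = len(z8)
    if n < cfg.n_neighbours + 1:
        raise ValidationError(
            f"need at least n_neighbours+1={cfg.n_neighbours + 1} samples for the embedding "
            f"(got {n}); reduce n_neighbours"
        )
    reducer = umap.UMAP(
        n_neighbors=cfg.n_neighbours,
        min_dist=cfg.min_dist,
        spread=cfg.spread,
        learning_rate=cfg.learning_rate,
        n_components=cfg.n_components,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        # disconnected neighbour graphs are expected for well-separated groups
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(z8.to_numpy())
    return np.asarray(coords, dtype=float)


def _wss_curve(coords: np.ndarray, k_range: range, seed: int, n_init: int) -> tuple[dict[int, float], dict[int, np.ndarray]]:
    wss, labels = {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(coords)
        wss[k] = float(km.inertia_)
        labels[k] = lab
    return wss, labels


def _kneedle(ks: list[int], values: np.ndarray) -> int:
    """Knee of a decreasing curve: max distance below the endpoint chord."""
    span = values[0] - values[-1]
    norm = (values - values[-1]) / span if span > 0 else np.zeros_like(values)
    x = (np.array(ks, dtype=float) - ks[0]) / (ks[-1] - ks[0])
    return ks[int(np.argmax((1 - x) - norm))]


def select_k(
    coords: np.ndarray,
    k_range: range = range(1, 9),
    seed: int = 0,
    n_init: int = 10,
    method: str = "log_kneedle",
) -> tuple[int, np.ndarray, dict[int, float]]:
    """k-means over ``k_range`` with elbow-based selection of K.

    Elbow rules (all operate on the within-cluster sum-of-squares curve):

    * ``"log_kneedle"`` (default) — Kneedle knee of log(WSS): the K of
      maximum distance below the chord joining the log-curve's endpoints.
      Working on the log scale makes the rule scale-invariant and
      sensitive to *relative* WSS drops, which locates the visually
      identified elbow even when some cluster pairs lie much closer
      together than others (where raw-scale rules saturate early).
    * ``"kneedle"`` — the same knee on the raw WSS curve.
    * ``"second_difference"`` — interior K maximising
      WSS(k−1) − 2·WSS(k) + WSS(k+1).
    """
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValidationError("non-finite coordinates passed to select_k")
    if len(coords) < max(k_range):
        raise ValidationError(f"need at least {max(k_range)} samples for k up to {max(k_range)}")
    wss, labels = _wss_curve(coords, k_range, seed, n_init)
    ks = sorted(wss)
    w = np.array([wss[k] for k in ks])
    if method == "second_difference":
        interior = ks[1:-1]
        curvature = {k: wss[k - 1] - 2 * wss[k] + wss[k + 1] for k in interior}
        best = max(interior, key=lambda k: (curvature[k], -k))
    elif method == "kneedle":
        best = _kneedle(ks, w)
    elif method == "log_kneedle":
        # floor protects the degenerate perfect-clustering case WSS = 0
        floor = max(w.max() * 1e-12, 1e-300)
        best = _kneedle(ks, np.log(np.maximum(w, floor)))
    else:
        raise ValueError(f"unknown elbow method {method!r}")
    return best, labels[best], wss


def assign_csg_labels(
    labels: np.ndarray, z8: pd.DataFrame, panel: GenePanel
) -> dict[int, str]:
    """Map anonymous cluster ids to CSG1–4 by activator/response z-means.

    Per cluster, A = mean activator-set z and R = mean response-set z;
    CSG3 := argmax(A+R); among the rest CSG4 := argmax(A−R); among the
    remaining two CSG2 := argmax(R−A); the last cluster is CSG1.  Ties
    break toward the lower cluster id (logged).
    """
    ids = sorted(set(int(l) for l in labels))
    if len(ids) != 4:
        raise ValidationError(f"CSG mapping requires exactly 4 clusters, got {len(ids)}")
    act = [g for g in panel.activator_set if g in z8.columns]
    resp = [g for g in panel.response_set if g in z8.columns]
    stats = {}
    for cid in ids:
        mask = labels == cid
        stats[cid] = (
            float(z8.loc[mask, act].to_numpy().mean()),
            float(z8.loc[mask, resp].to_numpy().mean()),
        )

    def pick(pool: list[int], key) -> int:
        scores = [key(stats[c]) for c in pool]
        best = max(scores)
        winners = [c for c, s in zip(pool, scores) if s == best]
        if len(winners) > 1:
            logger.warning("CSG mapping tie among clusters %s; taking lowest id", winners)
        return min(winners)

    remaining = list(ids)
    mapping: dict[int, str] = {}
    csg3 = pick(remaining, lambda ar: ar[0] + ar[1])
    mapping[csg3] = "CSG3"
    remaining.remove(csg3)
    csg4 = pick(remaining, lambda ar: ar[0] - ar[1])
    mapping[csg4] = "CSG4"
    remaining.remove(csg4)
    csg2 = pick(remaining, lambda ar: ar[1] - ar[0])
    mapping[csg2] = "CSG2"
    remaining.remove(csg2)
    mapping[remaining[0]] = "CSG1"
    return mapping


@dataclass
class CSGModel:
    """Everything needed to classify new samples, plus discovery provenance."""

    panel: GenePanel
    norm: NormalizationParams
    forest: RandomForestClassifier
    oob_error: float
    test_accuracy: float
    k: int = 4
    cluster_to_csg: dict[int, str] = field(default_factory=dict)
    train_fraction: float = 0.8
    wss_curve: dict[int, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "CSGModel":
        model = joblib.load(path)
        if not isinstance(model, CSGModel):
            raise ValidationError(f"{path} does not contain a CSGModel")
        return model


def train_classifier(
    z8: pd.DataFrame,
    csg_labels: pd.Series | np.ndarray,
    panel: GenePanel,
    norm: NormalizationParams,
    n_trees: int = 200,
    train_fraction: float = 0.8,
    seed: int = 0,
    **model_extra,
) -> CSGModel:
    """Train the 200-tree recapture forest on a stratified 80/20 split.

    OOB error is estimated on the training split's bootstrap structure;
    held-out test accuracy is recorded alongside.  Forest hyperparameters
    beyond tree count are scikit-learn defaults (√p features per split,
    unlimited depth) and travel with the serialized model.
    """
    y = pd.Series(np.asarray(csg_labels), index=z8.index)
    counts = y.value_counts()
    if (counts * train_fraction < 4).any():
        small = list(counts.index[counts * train_fraction < 4])
        raise ValidationError(f"need >=4 training samples per class; too few in {small}")
    x_train, x_test, y_train, y_test = train_test_split(
        z8, y, train_size=train_fraction, stratify=y, random_state=seed
    )
    forest = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed
    )
    forest.fit(x_train.to_numpy(), y_train.to_numpy())
    oob_error = 1.0 - float(forest.oob_score_)
    test_accuracy = float(forest.score(x_test.to_numpy(), y_test.to_numpy()))
    logger.info(
        "forest trained: OOB error %.3f%%, test accuracy %.3f%%",
        100 * oob_error, 100 * test_accuracy,
    )
    return CSGModel(
        panel=panel,
        norm=norm,
        forest=forest,
        oob_error=oob_error,
        test_accuracy=test_accuracy,
        train_fraction=train_fraction,
        **model_extra,
    )


def discover(
    expr: ExpressionMatrix,
    panel: GenePanel | None = None,
    embedding: EmbeddingConfig | None = None,
    k_range: range = range(1, 9),
    n_trees: int = 200,
    train_fraction: float = 0.8,
    seed: int = 0,
    elbow_method: str = "log_kneedle",
) -> tuple[CSGModel, pd.Series]:
    """Full discovery pipeline: z-score → embed → select K → map → train forest.

    Returns the fitted model and the per-sample discovery labels.
    """
    if panel is None:
        panel = GenePanel.default()
    if embedding is None:
        embedding = EmbeddingConfig(seed=seed)
    z8, norm = zscore(expr, panel)
    coords = embed(z8, embedding)
    k, raw_labels, wss = select_k(coords, k_range=k_range, seed=seed, method=elbow_method)
    if k != 4:
        raise ValidationError(
            f"elbow selected K={k}, but CSG semantics require 4 clusters; "
            "inspect the WSS curve or pass explicit labels"
        )
    mapping = assign_csg_labels(raw_labels, z8, panel)
    csg = pd.Series([mapping[int(l)] for l in raw_labels], index=z8.index, name="csg")
    model = train_classifier(
        z8, csg, panel, norm,
        n_trees=n_trees, train_fraction=train_fraction, seed=seed,
        k=k, cluster_to_csg=mapping, wss_curve=wss,
        provenance={"seed": seed, "embedding": vars(embedding), "elbow": elbow_method},
    )
    return model, csg


def classify(
    model: CSGModel, expr: ExpressionMatrix, renormalize: bool | None = None
) -> pd.DataFrame:
    """Assign CSG labels (plus per-class vote fractions) to new samples.

    ``renormalize=None`` (default) re-fits per-gene centre/SD on the input
    cohort when it has at least ``RENORM_MIN_SAMPLES`` samples and falls
    back to the stored training parameters otherwise; pass True/False to
    force either path.
    """
    frame = expr.values if isinstance(expr, ExpressionMatrix) else expr
    missing = [g for g in model.panel.selected if g not in frame.columns]
    if missing:
        raise ValidationError(f"cannot classify: missing panel genes {missing}")
    if renormalize is None:
        renormalize = len(frame) >= RENORM_MIN_SAMPLES
    if renormalize:
        z8, _ = zscore(frame, model.panel)
    else:
        z8, _ = zscore(frame, model.panel, norm=model.norm)
    votes = model.forest.predict_proba(z8.to_numpy())
    classes = list(model.forest.classes_)
    out = pd.DataFrame(votes, index=z8.index, columns=classes)
    out.insert(0, "csg", model.forest.predict(z8.to_numpy()))
    out.index.name = "sample_id"
    return out
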