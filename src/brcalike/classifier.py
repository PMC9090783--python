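"""Nearest shrunken centroid classification of copy-number profiles.

The BRCA1-like call is made by a two-class shrunken-centroid (PAM-family)
classifier on features that are genomic intervals: each feature value is the
mean log2 ratio of the profile bins it covers.  Per feature k and class j the
standardized centroid difference

    d_jk = (xbar_jk - xbar_k) / (m_j * (s_k + s0)),   m_j = sqrt(1/n_j - 1/n)

is soft-thresholded by delta, d'_jk = sign(d_jk) * max(|d_jk| - delta, 0),
and the shrunken class centroid is xbar'_jk = xbar_k + m_j*(s_k+s0)*d'_jk.
Classification uses the diagonal discriminant

    delta_j(x) = sum_k (x_k - xbar'_jk)^2 / (s_k + s0)^2 - 2*log(prior_j)

and the posterior probability of the BRCA1-like class is reported as a score
in [0, 1]; a profile is called BRCA1-like when the score reaches the fixed
threshold (>= 0.63 by default, ties resolving to BRCA1-like).

The published model's centroids are not public, so this module ships the
trainer plus a JSON model format; all tests and examples run on
synthetically trained models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import BRCA1_LIKE, NON_BRCA1_LIKE

DEFAULT_THRESHOLD = 0.63


@dataclass
class CentroidModel:
    feature_grid: pd.DataFrame          # chrom, start, end per feature
    overall_centroid: np.ndarray
    class_centroids: dict               # label -> per-feature shrunken centroid
    pooled_sd: np.ndarray
    s0: float
    delta: float
    priors: dict                        # label -> prior probability
    threshold: float = DEFAULT_THRESHOLD
    positive_label: str = BRCA1_LIKE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        p = len(self.overall_centroid)
        if len(self.feature_grid) != p or len(self.pooled_sd) != p:
            raise ValueError("centroids and sds must be index-aligned to the feature grid")
        for label, c in self.class_centroids.items():
            if len(c) != p:
                raise ValueError(f"class centroid {label!r} misaligned to feature grid")
        if abs(sum(self.priors.values()) - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.positive_label not in self.class_centroids:
            raise ValueError(f"positive label {self.positive_label!r} not among classes")

    @property
    def labels(self):
        return list(self.class_centroids)

    @property
    def n_active_features(self) -> int:
        diff = np.stack([c - self.overall_centroid for c in self.class_centroids.values()])
        return int(np.any(diff != 0.0, axis=0).sum())

    def to_json(self, path: str | Path) -> None:
        obj = {
            "feature_grid": self.feature_grid[["chrom", "start", "end"]].to_dict("list"),
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": {k: v.tolist() for k, v in self.class_centroids.items()},
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "delta": self.delta,
            "priors": self.priors,
            "threshold": self.threshold,
            "positive_label": self.positive_label,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(obj, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CentroidModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            feature_grid=pd.DataFrame(obj["feature_grid"]),
            overall_centroid=np.asarray(obj["overall_centroid"], dtype=float),
            class_centroids={k: np.asarray(v, dtype=float)
                             for k, v in obj["class_centroids"].items()},
            pooled_sd=np.asarray(obj["pooled_sd"], dtype=float),
            s0=float(obj["s0"]),
            delta=float(obj["delta"]),
            priors={k: float(v) for k, v in obj["priors"].items()},
            threshold=float(obj["threshold"]),
            positive_label=obj.get("positive_label", BRCA1_LIKE),
            metadata=obj.get("metadata", {}),
        )


@dataclass
class ClassifierResult:
    sample_id: str
    score: float
    label: str
    n_features_used: int
    n_missing: int = 0


def label_for_score(score: float, threshold: float = DEFAULT_THRESHOLD,
                    positive_label: str = BRCA1_LIKE,
                    negative_label: str = NON_BRCA1_LIKE) -> str:
    """Dichotomize a probability score; a score exactly at the threshold is
    called positive (the cutoff is 'greater than or equal')."""
    return positive_label if score >= threshold else negative_label


# ---------------------------------------------------------------------------
# feature mapping
# ---------------------------------------------------------------------------

def map_to_feature_grid(profile, feature_grid: pd.DataFrame,
                        overall_centroid: np.ndarray | None = None,
                        max_missing_fraction: float = 0.5) -> np.ndarray:
    """Aggregate a profile onto classifier features.

    Each feature value is the mean log2 ratio of the included profile bins
    overlapping the feature interval.  Features with no included bins are
    imputed with the overall centroid value when one is given (NaN
    otherwise).  A profile leaving more than `max_missing_fraction` of the
    features empty is rejected as quality-insufficient.
    """
    bins = profile.bins
    chrom = bins["chrom"].to_numpy()
    start = bins["start"].to_numpy()
    end = bins["end"].to_numpy()
    ratio = np.asarray(profile.log2_ratio, dtype=float)
    ok = np.asarray(profile.included, dtype=bool)

    values = np.full(len(feature_grid), np.nan)
    for i, (fc, fs, fe) in enumerate(
        zip(feature_grid["chrom"], feature_grid["start"], feature_grid["end"])
    ):
        hit = ok & (chrom == str(fc)) & (start < fe) & (end > fs)
        if hit.any():
            values[i] = float(ratio[hit].mean())
    missing = np.isnan(values)
    if missing.mean() > max_missing_fraction:
        raise ValueError(
            f"{int(missing.sum())}/{len(values)} features have no included bins; "
            "profile quality insufficient"
        )
    if overall_centroid is not None:
        values[missing] = np.asarray(overall_centroid, dtype=float)[missing]
    return values


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _centroid_stats(X: np.ndarray, y: np.ndarray, labels):
    n, p = X.shape
    overall = X.mean(axis=0)
    class_means, mj, njs = {}, {}, {}
    within_ss = np.zeros(p)
    for lab in labels:
        sel = y == lab
        nj = int(sel.sum())
        njs[lab] = nj
        class_means[lab] = X[sel].mean(axis=0)
        within_ss += ((X[sel] - class_means[lab]) ** 2).sum(axis=0)
        mj[lab] = np.sqrt(1.0 / nj - 1.0 / n)
    pooled_sd = np.sqrt(within_ss / (n - len(labels)))
    s0 = float(np.median(pooled_sd))
    return overall, class_means, pooled_sd, s0, mj, njs


def _shrink(overall, class_means, pooled_sd, s0, mj, delta):
    centroids = {}
    denom = pooled_sd + s0
    for lab, mean in class_means.items():
        d = (mean - overall) / (mj[lab] * denom)
        d_shr = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
        centroids[lab] = overall + mj[lab] * denom * d_shr
    return centroids


def train(
    X: np.ndarray,
    y,
    feature_grid: pd.DataFrame | None = None,
    delta_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    priors: dict | str = "equal",
    threshold: float = DEFAULT_THRESHOLD,
    positive_label: str | None = None,
) -> CentroidModel:
    """Train a shrunken-centroid model; delta chosen by stratified CV accuracy.

    X is samples x features; y holds the two class labels, each represented
    by at least 5 samples.  Ties in cross-validated accuracy resolve to the
    larger (more parsimonious) delta.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = sorted(pd.unique(y).tolist())
    if len(labels) < 2:
        raise ValueError("training data contains a single class; two are required")
    if len(labels) > 2:
        raise ValueError(f"expected two classes, got {labels}")
    for lab in labels:
        if (y == lab).sum() < 5:
            raise ValueError(f"class {lab!r} has fewer than 5 samples")
    if positive_label is None:
        positive_label = BRCA1_LIKE if BRCA1_LIKE in labels else labels[0]

    overall, class_means, pooled_sd, s0, mj, njs = _centroid_stats(X, y, labels)
    if delta_grid is None:
        denom = pooled_sd + s0
        dmax = max(
            float(np.max(np.abs((class_means[lab] - overall) / (mj[lab] * denom))))
            for lab in labels
        )
        delta_grid = np.linspace(0.0, dmax, 30)
    delta_grid = np.asarray(delta_grid, dtype=float)

    if isinstance(priors, str) and priors == "equal":
        prior_map = {lab: 1.0 / len(labels) for lab in labels}
    elif isinstance(priors, str) and priors == "empirical":
        prior_map = {lab: njs[lab] / len(y) for lab in labels}
    else:
        prior_map = {lab: float(priors[lab]) for lab in labels}

    best_delta = _choose_delta_cv(X, y, labels, delta_grid, cv_folds, seed, prior_map)
    centroids = _shrink(overall, class_means, pooled_sd, s0, mj, best_delta)
    return CentroidModel(
        feature_grid=(feature_grid if feature_grid is not None
                      else _dummy_grid(X.shape[1])),
        overall_centroid=overall,
        class_centroids=centroids,
        pooled_sd=pooled_sd,
        s0=s0,
        delta=float(best_delta),
        priors=prior_map,
        threshold=threshold,
        positive_label=positive_label,
        metadata={"n_samples": int(len(y)),
                  "class_sizes": {lab: int(njs[lab]) for lab in labels},
                  "cv_folds": int(cv_folds), "seed": int(seed)},
    )


def _dummy_grid(p: int) -> pd.DataFrame:
    # placeholder grid for models trained on bare feature matrices
    return pd.DataFrame({"chrom": ["1"] * p,
                         "start": np.arange(p, dtype=np.int64) * 20_000,
                         "end": (np.arange(p, dtype=np.int64) + 1) * 20_000})


def _stratified_folds(y, labels, n_folds, rng):
    folds = [[] for _ in range(n_folds)]
    for lab in labels:
        idx = np.flatnonzero(y == lab)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    return [np.asarray(sorted(f)) for f in folds]


def _choose_delta_cv(X, y, labels, delta_grid, cv_folds, seed, priors) -> float:
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, labels, cv_folds, rng)
    n_correct = np.zeros(len(delta_grid))
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = X[train_mask], y[train_mask]
        overall, class_means, pooled_sd, s0, mj, _ = _centroid_stats(Xtr, ytr, labels)
        for di, delta in enumerate(delta_grid):
            centroids = _shrink(overall, class_means, pooled_sd, s0, mj, delta)
            disc = _discriminants(X[test_idx], centroids, pooled_sd, s0, priors)
            pred = np.asarray(list(centroids))[np.argmin(
                np.column_stack([disc[lab] for lab in centroids]), axis=1)]
            n_correct[di] += (pred == y[test_idx]).sum()
    best = np.flatnonzero(n_correct == n_correct.max())[-1]  # ties -> larger delta
    return float(delta_grid[best])


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _discriminants(X: np.ndarray, centroids: dict, pooled_sd, s0, priors) -> dict:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    denom2 = (pooled_sd + s0) ** 2
    return {
        lab: ((X - c) ** 2 / denom2).sum(axis=1) - 2.0 * np.log(priors[lab])
        for lab, c in centroids.items()
    }


def posteriors(model: CentroidModel, x: np.ndarray) -> dict:
    """Class posterior probabilities exp(-delta_j/2) / sum_j exp(-delta_j/2),
    computed stably; NaN features are imputed with the overall centroid."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != len(model.overall_centroid):
        raise ValueError(
            f"feature vector of length {x.size} does not align with the "
            f"{len(model.overall_centroid)}-feature model grid"
        )
    x = np.where(np.isnan(x), model.overall_centroid, x)
    disc = _discriminants(x, model.class_centroids, model.pooled_sd, model.s0, model.priors)
    labs = list(disc)
    d = np.array([disc[lab][0] for lab in labs])
    w = np.exp(-(d - d.min()) / 2.0)
    w /= w.sum()
    return dict(zip(labs, w))


def score(model: CentroidModel, x: np.ndarray, sample_id: str = "") -> ClassifierResult:
    """Score one feature vector; the score is the posterior probability of
    the positive (BRCA1-like) class and the label follows the >= threshold."""
    x = np.asarray(x, dtype=float)
    n_missing = int(np.isnan(x).sum()) if x.ndim == 1 else 0
    post = posteriors(model, x)
    s = float(post[model.positive_label])
    negative = next(lab for lab in model.labels if lab != model.positive_label)
    return ClassifierResult(
        sample_id=sample_id,
        score=s,
        label=label_for_score(s, model.threshold, model.positive_label, negative),
        n_features_used=model.n_active_features,
        n_missing=n_missing,
    )


def classify_cohort(model: CentroidModel, profiles: dict):
    """Classify a cohort of GenomicProfiles; failures are recorded, not raised.

    Returns (results, failures, summary): per-sample ClassifierResults, a
    dict of sample id -> failure reason for profiles that could not be
    mapped, and a summary frame of class counts and percentages among the
    evaluable samples.
    """
    results, failures = [], {}
    for sid, profile in profiles.items():
        try:
            x = map_to_feature_grid(profile, model.feature_grid, model.overall_centroid)
            results.append(score(model, x, sample_id=sid))
        except ValueError as exc:
            failures[sid] = str(exc)
    n_eval = len(results)
    counts = {}
    for r in results:
        counts[r.label] = counts.get(r.label, 0) + 1
    rows = [
        {"label": lab, "n": n, "pct": 100.0 * n / n_eval if n_eval else np.nan}
        for lab, n in sorted(counts.items())
    ]
    summary = pd.DataFrame(rows, columns=["label", "n", "pct"])
    return results, failures, summary
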