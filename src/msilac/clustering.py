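"""Temporal expression-shape analysis.

Profiles are ratio triplets (baseline fixed at 1, two later time points).
Two complementary views are provided:

* a deterministic three-class shape rule — monotone down-regulation,
  dip-then-recover ("upright V"), rise-then-fall ("downright V") — which is
  the canonical classifier here because it reproduces every printed cluster
  label of the source tables; and
* repeated K-means on log2 profiles with 1 - Pearson correlation distance,
  the exploratory route the original analysis took (Cluster 3.0 style),
  whose centroids can be collapsed back onto the three shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

#: The three shape classes, in reporting order.
CLUSTER_DOWN = "cluster1_down"
CLUSTER_V_UP = "cluster2_V_up"
CLUSTER_V_DOWN = "cluster3_V_down"
SHAPE_CLASSES = (CLUSTER_DOWN, CLUSTER_V_UP, CLUSTER_V_DOWN)


@dataclass(frozen=True)
class TemporalProfile:
    """Expression ratios at baseline and two later times.

    ``times`` are caller-supplied labels (hours); nothing downstream assumes
    particular values, since published headers disagree on the middle point.
    """

    ratios: tuple[float, float, float]
    times: tuple[float, float, float] = (0.0, 24.0, 48.0)

    def __post_init__(self) -> None:
        r = tuple(float(x) for x in self.ratios)
        if len(r) != 3:
            raise InvalidInputError("a temporal profile has exactly 3 ratios")
        if any(x <= 0 for x in r):
            raise InvalidInputError("ratios must be positive for the log2 view")
        if abs(r[0] - 1.0) > 1e-9:
            raise InvalidInputError("baseline ratio must be 1 by construction")
        object.__setattr__(self, "ratios", r)

    def log2(self) -> np.ndarray:
        return np.log2(np.asarray(self.ratios))


def shape_classify(profile: TemporalProfile | Sequence[float]) -> str:
    """Assign a profile to one of the three temporal shape classes.

    Rule: rise-then-fall (downright V) if the middle ratio exceeds baseline;
    otherwise monotone down if the late ratio does not exceed the middle one;
    otherwise dip-then-recover (upright V).  Ties resolve toward monotone
    down / upright V, as written.
    """
    if not isinstance(profile, TemporalProfile):
        profile = TemporalProfile(tuple(profile))
    _, r1, r2 = profile.ratios
    if r1 > 1.0:
        return CLUSTER_V_DOWN
    if r2 <= r1:
        return CLUSTER_DOWN
    return CLUSTER_V_UP


def cluster_percentages(assignments: Iterable[str]) -> dict[str, float]:
    """Percentage of profiles per shape class, to one decimal."""
    labels = list(assignments)
    if not labels:
        raise InvalidInputError("no assignments given")
    n = len(labels)
    out = {}
    for cls in SHAPE_CLASSES:
        out[cls] = round(100.0 * labels.count(cls) / n, 1)
    extra = set(labels) - set(SHAPE_CLASSES)
    for cls in sorted(extra):
        out[cls] = round(100.0 * labels.count(cls) / n, 1)
    return out


def concordance(
    total: TemporalProfile,
    phospho: TemporalProfile | None,
) -> str:
    """Compare the temporal shape of a protein's total and phospho signals.

    ``concordant`` when the shape rule agrees on both, ``discordant``
    otherwise; a missing phospho profile reports ``phospho-absent`` (some
    proteins are only ever seen in the phospho stain, and vice versa)."""
    if phospho is None:
        return "phospho-absent"
    return (
        "concordant"
        if shape_classify(total) == shape_classify(phospho)
        else "discordant"
    )


# --- K-means with correlation distance -------------------------------------


def _pearson_rows(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r between rows of X and rows of C.

    Rows with zero variance (flat profiles) are treated as uncorrelated with
    everything (r = 0), which puts them at the maximal regular distance 1.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1, keepdims=True)
    cn = np.linalg.norm(Cc, axis=1, keepdims=True)
    xn[xn == 0] = np.inf
    cn[cn == 0] = np.inf
    return (Xc / xn) @ (Cc / cn).T


@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray  # in log2 space
    inertia: float
    k: int
    restarts: int
    seed: int


def kmeans_profiles(
    profiles: Sequence[TemporalProfile] | np.ndarray,
    k: int = 9,
    restarts: int = 100,
    seed: int = 0,
) -> KMeansResult:
    """Repeated K-means of log2 profiles under 1 - Pearson distance.

    Lloyd iterations with mean-centroid updates, best of ``restarts`` random
    initializations by total within-cluster distance.  Deterministic given
    ``seed``, and invariant to the input ordering: profiles are canonically
    sorted internally before initialization, so permuting the input permutes
    the labels but never changes the partition.
    """
    if isinstance(profiles, np.ndarray):
        X = np.asarray(profiles, dtype=float)
    else:
        X = np.vstack([p.log2() for p in profiles])
    n = X.shape[0]
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if restarts < 1:
        raise InvalidInputError("restarts must be >= 1")
    if k > n:
        raise InvalidInputError(f"k={k} exceeds the number of profiles ({n})")

    order = np.lexsort(X.T[::-1])  # canonical row order: sort by columns L->R
    Xs = X[order]

    rng = np.random.default_rng(seed)
    best_labels: np.ndarray | None = None
    best_cent: np.ndarray | None = None
    best_inertia = np.inf
    for _ in range(restarts):
        cent = Xs[rng.choice(n, size=k, replace=False)].copy()
        labels = np.zeros(n, dtype=int)
        for it in range(300):
            d = 1.0 - _pearson_rows(Xs, cent)
            new_labels = d.argmin(axis=1)
            # refill empty clusters with the worst-fit profile
            for j in range(k):
                if not (new_labels == j).any():
                    new_labels[d[np.arange(n), new_labels].argmax()] = j
            if it > 0 and (new_labels == labels).all():
                break
            labels = new_labels
            for j in range(k):
                members = Xs[labels == j]
                if len(members):  # degenerate restarts can still empty a cluster
                    cent[j] = members.mean(axis=0)
        inertia = float((1.0 - _pearson_rows(Xs, cent))[np.arange(n), labels].sum())
        if inertia < best_inertia - 1e-12:
            best_inertia, best_labels, best_cent = inertia, labels, cent

    assert best_labels is not None and best_cent is not None
    labels_out = np.empty(n, dtype=int)
    labels_out[order] = best_labels
    return KMeansResult(
        labels=labels_out,
        centroids=best_cent,
        inertia=best_inertia,
        k=k,
        restarts=restarts,
        seed=seed,
    )


def collapse_centroids(result: KMeansResult) -> dict[int, str]:
    """Map each K-means centroid to a shape class via the deterministic rule
    applied to the centroid's ratio-space profile (anchored at baseline 1)."""
    mapping = {}
    for j, c in enumerate(result.centroids):
        ratios = 2.0 ** (c - c[0])  # re-anchor: baseline back to ratio 1
        mapping[j] = shape_classify(TemporalProfile(tuple(ratios)))
    return mapping
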