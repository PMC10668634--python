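"""Onco-GPS-style 2D state maps.

A reference expression panel restricted to an oncogene-responsive gene
module is decomposed by NMF; each of the k factors becomes a *node* placed
deterministically on the unit circle (ordered by factor index), and
reference samples are grouped into *states* by k-means on their
L1-normalized factor-weight columns.  New samples are projected by
nonnegative regression onto the frozen factor matrix and placed in the
plane by a normalized weighted pull toward the nodes,

    xy = sum_j coords_j * w_j^p / sum_j w_j^p,

with p the pull exponent (default 2; larger p sharpens placement toward
the dominant node).  Because the pulled position is a convex combination
of node coordinates, every projection lies inside the nodes' convex hull.
A projected sample inherits the state of its nearest reference sample in
factor-weight space.

The k-means used for state definition is a seeded Lloyd's algorithm with
k-means++ style initialization implemented here, restarted 50 times.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, ValidationError
from .nmf import NMFModel, fit_nmf, project_onto_W

logger = logging.getLogger(__name__)

DEFAULT_PULL_EXPONENT = 2.0
KMEANS_RESTARTS = 50
KMEANS_MAX_ITER = 300


# ---------------------------------------------------------------------------
# in-repo k-means (Lloyd, k-means++ style init)
# ---------------------------------------------------------------------------


def kmeans(
    points: np.ndarray,
    n_clusters: int,
    n_restarts: int = KMEANS_RESTARTS,
    max_iter: int = KMEANS_MAX_ITER,
    seed: int = 7,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Seeded Lloyd k-means; returns (labels, centroids, inertia).

    Initialization samples centers with probability proportional to the
    squared distance from the nearest already-chosen center (k-means++).
    Empty clusters are reseeded at the point farthest from its centroid.
    """
    points = np.asarray(points, dtype=float)
    n, _ = points.shape
    if not 1 <= n_clusters <= n:
        raise ValidationError(f"n_clusters must lie in [1, {n}]")

    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng((seed + 7919 * r) % 2**31)
        centers = _kmeanspp_init(points, n_clusters, rng)
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = d2.argmin(axis=1)
            for c in range(n_clusters):
                mask = new_labels == c
                if mask.any():
                    centers[c] = points[mask].mean(axis=0)
                else:
                    centers[c] = points[d2.min(axis=1).argmax()]
            if (new_labels == labels).all():
                labels = new_labels
                break
            labels = new_labels
        inertia = float(((points - centers[labels]) ** 2).sum())
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    return best


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centers = [points[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            ((points[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(axis=2),
            axis=1,
        )
        total = d2.sum()
        if total == 0:
            centers.append(points[rng.integers(n)])
        else:
            centers.append(points[rng.choice(n, p=d2 / total)])
    return np.asarray(centers, dtype=float)


# ---------------------------------------------------------------------------
# map construction and projection
# ---------------------------------------------------------------------------


@dataclass
class OncoGPSMap:
    """Fitted reference decomposition plus planar node/state geometry."""

    module: GeneSet
    W_ref: pd.DataFrame  # module genes x k
    node_coords: pd.DataFrame  # k x (x, y), indexed by factor name
    states: dict[str, str]  # reference sample -> state label
    reference_weights: pd.DataFrame  # k x reference samples, column-L1-normalized
    n_states: int
    pull_exponent: float = DEFAULT_PULL_EXPONENT
    seed: int = 7

    def __post_init__(self) -> None:
        coords = self.node_coords.to_numpy()
        if len(np.unique(coords.round(12), axis=0)) != coords.shape[0]:
            raise ValidationError("node coordinates must be distinct")
        if self.pull_exponent <= 0:
            raise ValidationError("pull_exponent must be positive")
        missing = set(self.reference_weights.columns) - set(self.states)
        if missing:
            raise ValidationError(f"reference samples without a state: {sorted(missing)}")

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]


@dataclass(frozen=True)
class Projection:
    sample_id: str
    xy: tuple[float, float]
    factor_weights: tuple[float, ...]
    nearest_state: str
    degenerate: bool = False


def circular_node_coords(factor_names: list[str]) -> pd.DataFrame:
    """k nodes equally spaced on the unit circle, ordered by factor index."""
    k = len(factor_names)
    angles = 2.0 * np.pi * np.arange(k) / k
    return pd.DataFrame(
        {"x": np.cos(angles), "y": np.sin(angles)}, index=factor_names
    )


def build_map(
    reference: ExpressionMatrix,
    module: GeneSet,
    k_nodes: int = 9,
    n_states: int = 4,
    nmf_restarts: int = 5,
    seed: int = 7,
    pull_exponent: float = DEFAULT_PULL_EXPONENT,
) -> OncoGPSMap:
    """Build a state map from a reference panel and an oncogene module."""
    if k_nodes < 2:
        raise ValidationError("need at least 2 nodes")
    if n_states < 1:
        raise ValidationError("need at least 1 state")
    present = [g for g in module.genes if g in set(reference.gene_ids)]
    if len(present) < 0.8 * len(module):
        raise ValidationError(
            f"module overlap {len(present)}/{len(module)} below the 80% floor"
        )

    restricted = reference.subset_genes(present)
    model: NMFModel = fit_nmf(
        restricted, rank=k_nodes, n_restarts=nmf_restarts, seed=seed
    )
    weights = model.sample_weights

    labels, _, _ = kmeans(
        weights.to_numpy().T, n_clusters=n_states, seed=seed
    )
    states = {
        sample: f"state{label}" for sample, label in zip(weights.columns, labels)
    }
    return OncoGPSMap(
        module=module,
        W_ref=model.W,
        node_coords=circular_node_coords(model.factor_names),
        states=states,
        reference_weights=weights,
        n_states=n_states,
        pull_exponent=pull_exponent,
        seed=seed,
    )


def pull_coordinates(
    weights: np.ndarray, node_coords: np.ndarray, pull_exponent: float
) -> np.ndarray:
    """Planar position of one weight vector: power-normalized pull to nodes."""
    powered = np.asarray(weights, dtype=float) ** pull_exponent
    total = powered.sum()
    if total == 0:
        return node_coords.mean(axis=0)
    return (powered[:, None] * node_coords).sum(axis=0) / total


def project_samples(
    gps_map: OncoGPSMap, samples: ExpressionMatrix, seed: int = 7
) -> list[Projection]:
    """Project study samples onto a fitted map."""
    h_new = project_onto_W(gps_map.W_ref, samples, seed=seed)
    node_xy = gps_map.node_coords.to_numpy()
    ref = gps_map.reference_weights.to_numpy().T  # samples x k
    ref_samples = list(gps_map.reference_weights.columns)

    projections = []
    for sample in h_new.columns:
        w = h_new[sample].to_numpy()
        degenerate = w.sum() == 0
        if degenerate:
            logger.warning("sample %r projected with all-zero weights", sample)
        xy = pull_coordinates(w, node_xy, gps_map.pull_exponent)
        nearest = int(((ref - w[None, :]) ** 2).sum(axis=1).argmin())
        projections.append(
            Projection(
                sample_id=sample,
                xy=(float(xy[0]), float(xy[1])),
                factor_weights=tuple(float(v) for v in w),
                nearest_state=gps_map.states[ref_samples[nearest]],
                degenerate=degenerate,
            )
        )
    return projections


def projections_table(projections: list[Projection]) -> pd.DataFrame:
    k = len(projections[0].factor_weights) if projections else 0
    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in projections],
            "x": [p.xy[0] for p in projections],
            "y": [p.xy[1] for p in projections],
            "nearest_state": [p.nearest_state for p in projections],
            **{
                f"F{i}": [p.factor_weights[i] for p in projections]
                for i in range(k)
            },
        }
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_map(gps_map: OncoGPSMap, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "module": {
            "name": gps_map.module.name,
            "description": gps_map.module.description,
            "genes": list(gps_map.module.genes),
        },
        "W_ref": {
            "index": list(gps_map.W_ref.index),
            "columns": list(gps_map.W_ref.columns),
            "values": gps_map.W_ref.to_numpy().tolist(),
        },
        "node_coords": {
            "index": list(gps_map.node_coords.index),
            "values": gps_map.node_coords.to_numpy().tolist(),
        },
        "states": gps_map.states,
        "reference_weights": {
            "index": list(gps_map.reference_weights.index),
            "columns": list(gps_map.reference_weights.columns),
            "values": gps_map.reference_weights.to_numpy().tolist(),
        },
        "n_states": gps_map.n_states,
        "pull_exponent": gps_map.pull_exponent,
        "seed": gps_map.seed,
    }
    path.write_text(json.dumps(payload))
    return path


def load_map(path: str | Path) -> OncoGPSMap:
    payload = json.loads(Path(path).read_text())
    return OncoGPSMap(
        module=GeneSet(
            payload["module"]["name"],
            payload["module"]["description"],
            tuple(payload["module"]["genes"]),
        ),
        W_ref=pd.DataFrame(
            payload["W_ref"]["values"],
            index=payload["W_ref"]["index"],
            columns=payload["W_ref"]["columns"],
        ),
        node_coords=pd.DataFrame(
            payload["node_coords"]["values"],
            index=payload["node_coords"]["index"],
            columns=["x", "y"],
        ),
        states=dict(payload["states"]),
        reference_weights=pd.DataFrame(
            payload["reference_weights"]["values"],
            index=payload["reference_weights"]["index"],
            columns=payload["reference_weights"]["columns"],
        ),
        n_states=int(payload["n_states"]),
        pull_exponent=float(payload["pull_exponent"]),
        seed=int(payload["seed"]),
    )
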