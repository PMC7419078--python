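"""Latent-space profiling: 2D t-SNE maps, cluster separability, representatives.

Cluster separation is always *scored* on the latent codes themselves via
silhouette, with t-SNE reserved for visualization: t-SNE distances are not
metrically meaningful, so the quantitative separated/overlapping verdicts
must not depend on them. Groups come from the frame labels (substrate or
variant); there is no density-based cluster discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .cvae import LatentEmbedding

GroupKey = str  # "variant" | "substrate" | "condition"


def _group_values(embedding: LatentEmbedding, group_by: GroupKey) -> np.ndarray:
    if group_by == "variant":
        return np.array([l[0] for l in embedding.labels])
    if group_by == "substrate":
        return np.array([l[1] for l in embedding.labels])
    if group_by == "condition":
        return np.array([f"{l[0]}/{l[1]}" for l in embedding.labels])
    raise ValueError(f"unknown group key '{group_by}'")


@dataclass
class Embedding2D:
    points: np.ndarray
    labels: list[tuple[str, str, int]]
    tsne_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if len(self.labels) != self.points.shape[0]:
            raise ValueError("one label per point required")


def project_2d(embedding: LatentEmbedding, perplexity: float = 30.0,
               seed: int = 0, n_iter: int = 1000) -> Embedding2D:
    """Seeded t-SNE of the latent codes (PCA initialisation)."""
    n = embedding.codes.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"t-SNE needs n > 3·perplexity points (n={n}, perplexity={perplexity} "
            f"requires n > {3 * perplexity:g})"
        )
    from sklearn.manifold import TSNE

    points = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        max_iter=n_iter,
        init="pca",
    ).fit_transform(embedding.codes)
    return Embedding2D(
        points=points,
        labels=list(embedding.labels),
        tsne_params={"perplexity": perplexity, "seed": seed, "n_iter": n_iter},
    )


@dataclass
class SeparabilityReport:
    grouping: GroupKey
    threshold: float
    silhouette: float
    per_group: dict[str, float]
    pair_silhouette: dict[tuple[str, str], float]
    centroid_distances: dict[tuple[str, str], float]
    verdicts: dict[tuple[str, str], str]  # "separated" | "overlapping"

    @property
    def all_separated(self) -> bool:
        return all(v == "separated" for v in self.verdicts.values())

    @property
    def all_overlapping(self) -> bool:
        return all(v == "overlapping" for v in self.verdicts.values())


def separability(embedding: LatentEmbedding, group_by: GroupKey = "substrate",
                 threshold: float = 0.25) -> SeparabilityReport:
    """Silhouette-based cluster separation of labelled latent codes.

    A label pair is judged "separated" when the silhouette computed on just
    those two groups is ≥ threshold, "overlapping" otherwise. The default
    threshold of 0.25 sits midway between typical overlapping (≈0) and
    well-separated (≳0.5) regimes.
    """
    from sklearn.metrics import silhouette_samples, silhouette_score

    groups = _group_values(embedding, group_by)
    names, counts = np.unique(groups, return_counts=True)
    if names.size < 2:
        raise ValueError(f"need >= 2 groups to score separability, found {names.size}")
    small = names[counts < 2]
    if small.size:
        raise ValueError(f"group(s) with fewer than 2 points: {small.tolist()}")

    codes = embedding.codes
    overall = float(silhouette_score(codes, groups))
    samples = silhouette_samples(codes, groups)
    per_group = {str(g): float(samples[groups == g].mean()) for g in names}

    centroids = {str(g): codes[groups == g].mean(axis=0) for g in names}
    pair_sil: dict[tuple[str, str], float] = {}
    centroid_d: dict[tuple[str, str], float] = {}
    verdicts: dict[tuple[str, str], str] = {}
    for a, b in combinations(names, 2):
        mask = (groups == a) | (groups == b)
        s = float(silhouette_score(codes[mask], groups[mask]))
        key = (str(a), str(b))
        pair_sil[key] = s
        centroid_d[key] = float(np.linalg.norm(centroids[str(a)] - centroids[str(b)]))
        verdicts[key] = "separated" if s >= threshold else "overlapping"

    return SeparabilityReport(
        grouping=group_by,
        threshold=threshold,
        silhouette=overall,
        per_group=per_group,
        pair_silhouette=pair_sil,
        centroid_distances=centroid_d,
        verdicts=verdicts,
    )


def representative_frames(embedding: LatentEmbedding,
                          group_by: GroupKey = "substrate") -> dict[str, int]:
    """Centroid-nearest frame per group; ties break to the lowest frame index."""
    groups = _group_values(embedding, group_by)
    frame_idx = np.array([l[2] for l in embedding.labels])
    out: dict[str, int] = {}
    for g in np.unique(groups):
        mask = groups == g
        codes = embedding.codes[mask]
        frames = frame_idx[mask]
        dists = np.linalg.norm(codes - codes.mean(axis=0), axis=1)
        # lexicographic: distance first (rounded to kill float jitter at exact
        # ties), then frame index
        order = np.lexsort((frames, np.round(dists, 12)))
        out[str(g)] = int(frames[order[0]])
    return out


def export_report_tsv(report: SeparabilityReport, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "group_a": a,
            "group_b": b,
            "pair_silhouette": report.pair_silhouette[(a, b)],
            "centroid_distance": report.centroid_distances[(a, b)],
            "verdict": report.verdicts[(a, b)],
        }
        for (a, b) in report.pair_silhouette
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plot_embedding(emb2d: Embedding2D, path: str | Path,
                   color_by: GroupKey = "substrate") -> None:
    """Scatter plot of the 2D map coloured by label group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = _group_values(
        LatentEmbedding(codes=np.zeros((len(emb2d.labels), 2)), labels=emb2d.labels),
        color_by,
    )
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in np.unique(labels):
        mask = labels == g
        ax.scatter(emb2d.points[mask, 0], emb2d.points[mask, 1], s=4, label=str(g))
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(markerscale=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
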