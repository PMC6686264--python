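"""Latent-space diagnostics: where does platform variance live?

Both platforms' latent (or raw) features are stacked and decomposed with a
single PCA. In this combined basis the dominant component typically captures
the platform offset — quantified here as the AUC of the PC1 score against
the platform label — while the second component carries per-sample,
platform-independent structure, quantified as the squared Pearson
correlation of each sample's PC2 score across the two platforms. Encoders
that learn platform-independent representations push that r-squared up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .encoders import LatentFeatures
from .evaluation import auc


@dataclass
class PCAResult:
    """Combined-platform component scores with per-row platform tags."""

    sample_ids: list[str]
    platforms: list[str]
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray

    def __post_init__(self):
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions must be nonincreasing, sum <= 1")


def pca_combined(latent_a: LatentFeatures, latent_b: LatentFeatures,
                 platform_a: str, platform_b: str, k: int = 2) -> PCAResult:
    """Fit one PCA on the stacked rows of both platforms' features.

    Features are mean-centered but not variance-scaled (latent features share
    a common scale). The sign of each component is fixed by forcing its
    largest-magnitude loading positive, so scores are reproducible.
    """
    mat_a, mat_b = latent_a.matrix, latent_b.matrix
    if mat_a.shape[1] != mat_b.shape[1]:
        raise ValueError(f"feature widths differ: {mat_a.shape[1]} vs {mat_b.shape[1]}")
    stacked = np.vstack([mat_a, mat_b])
    pca = PCA(n_components=min(k, *stacked.shape), svd_solver="full")
    scores = pca.fit_transform(stacked)
    loadings = pca.components_
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    return PCAResult(
        sample_ids=list(latent_a.sample_ids) + list(latent_b.sample_ids),
        platforms=[platform_a] * mat_a.shape[0] + [platform_b] * mat_b.shape[0],
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings,
    )


def pc1_platform_separation(r: PCAResult) -> float:
    """How well PC1 alone separates the platforms, as a symmetrized AUC.

    1.0 means perfect separation (all of one platform's scores beyond the
    other's); 0.5 means PC1 carries no platform information. Degenerate
    all-tied scores return 0.5.
    """
    uniq = sorted(set(r.platforms))
    if len(uniq) < 2:
        raise ValueError("need both platforms present to measure separation")
    is_b = np.array([p == uniq[1] for p in r.platforms], dtype=int)
    pc1 = r.scores[:, 0]
    if np.allclose(pc1, pc1[0]):
        return 0.5
    a = auc(pc1, is_b)
    return max(a, 1.0 - a)


def pc2_cross_platform_r2(r: PCAResult) -> float:
    """Squared Pearson correlation of paired per-sample PC2 scores.

    Every sample must appear exactly once per platform; pairing is by sample
    id. Sign conventions cancel in the square.
    """
    uniq = sorted(set(r.platforms))
    if len(uniq) != 2:
        raise ValueError("need exactly two platforms")
    by_platform: dict[str, dict[str, float]] = {u: {} for u in uniq}
    for sid, plat, row in zip(r.sample_ids, r.platforms, r.scores):
        if sid in by_platform[plat]:
            raise ValueError(f"sample {sid!r} appears twice on platform {plat!r}")
        by_platform[plat][sid] = row[1]
    ids_a, ids_b = (set(by_platform[u]) for u in uniq)
    if ids_a != ids_b:
        raise ValueError(f"unpaired samples: {sorted(ids_a ^ ids_b)[:5]} ...")
    ordered = sorted(ids_a)
    xa = np.array([by_platform[uniq[0]][s] for s in ordered])
    xb = np.array([by_platform[uniq[1]][s] for s in ordered])
    rho = stats.pearsonr(xa, xb).statistic
    return float(rho ** 2)


def write_scores(r: PCAResult, path) -> None:
    cols = {f"PC{i + 1}": r.scores[:, i] for i in range(r.scores.shape[1])}
    pd.DataFrame({"sample_id": r.sample_ids, "platform": r.platforms, **cols}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
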