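"""Synthetic paired two-platform expression cohorts with known truth.

The generator encodes the premise that an expression value is the sum of a
platform-independent component (per-sample shared latent factors) and a
platform-related component (per-platform latent factors plus a global
per-platform offset):

    x_ip = W z_i + V_p u_ip + c_p + baseline + eps,

with z_i ~ N(0, I_k_shared) shared across platforms and u_ip ~ N(0,
I_k_platform) specific to platform p. Loadings are drawn once per cohort
with N(0, 1/k) entries, the shared loading additionally scaled by
``shared_strength`` so platform-independent biological variance dominates
the platform-specific factors; the shared-factor loading W is common to both
platforms because the mapped gene columns measure the same transcripts, so
with no offset, no platform factors and no noise the two matrices coincide.
Platform-related variance enters through V_p, a random offset c_p of norm
``platform_offset_scale``, and i.i.d. Gaussian noise. The default offset is
large enough that platform identity dominates the combined covariance, as
it does in real paired microarray/RNA-seq data.

Three binary endpoints of decreasing predictability are drawn from the
shared factors alone, y_i ~ Bernoulli(sigmoid(beta * w.z_i)) with beta
easy > medium > hard = 0 — the hard endpoint is pure noise, emulating
clinically unpredictable outcomes. Every draw flows from one seed, so a
cohort is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .io_data import EndpointLabels, ExpressionMatrix, GeneMap

#: endpoint effect sizes on the logit scale, strongest first
DEFAULT_BETAS = {"easy": 3.0, "medium": 1.2, "hard": 0.0}


@dataclass
class SyntheticConfig:
    n_samples: int = 200
    n_genes: int = 300
    k_shared: int = 5
    k_platform: int = 3
    shared_strength: float = 1.8
    platform_offset_scale: float = 30.0
    noise_sd: float = 0.5
    betas: dict = field(default_factory=lambda: dict(DEFAULT_BETAS))
    baseline: float = 8.0
    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_samples, self.n_genes, self.k_shared) <= 0:
            raise ValueError("n_samples, n_genes and k_shared must be positive")
        if self.k_platform < 0 or self.noise_sd < 0 or self.platform_offset_scale < 0:
            raise ValueError("k_platform, noise_sd, platform_offset_scale must be >= 0")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class CohortTruth:
    """Ground-truth latent state, for recovery tests."""

    z: np.ndarray
    u: dict[str, np.ndarray]
    W: np.ndarray
    V: dict[str, np.ndarray]
    c: dict[str, np.ndarray]
    w_endpoint: np.ndarray
    endpoint_logit_scores: np.ndarray


def _platform_block(rng, cfg, z, W):
    k_p, g = cfg.k_platform, cfg.n_genes
    if k_p > 0:
        V = rng.standard_normal((k_p, g)) / np.sqrt(k_p)
        u = rng.standard_normal((cfg.n_samples, k_p))
    else:
        V = np.zeros((0, g))
        u = np.zeros((cfg.n_samples, 0))
    direction = rng.standard_normal(g)
    c = direction / np.linalg.norm(direction) * cfg.platform_offset_scale
    eps = rng.standard_normal((cfg.n_samples, g)) * cfg.noise_sd
    x = z @ W + u @ V + c + cfg.baseline + eps
    return x, V, u, c


def simulate_cohort(cfg: SyntheticConfig) -> tuple[
        ExpressionMatrix, ExpressionMatrix, GeneMap,
        dict[str, EndpointLabels], CohortTruth]:
    """Draw one paired cohort: two matrices, a gene map, three endpoints, truth."""
    rng = np.random.default_rng(cfg.seed)
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    z = rng.standard_normal((cfg.n_samples, cfg.k_shared))
    W = rng.standard_normal((cfg.k_shared, cfg.n_genes)) * (
        cfg.shared_strength / np.sqrt(cfg.k_shared))

    xa, Va, ua, ca = _platform_block(rng, cfg, z, W)
    xb, Vb, ub, cb = _platform_block(rng, cfg, z, W)

    genes_a = [f"G{j:04d}_A" for j in range(cfg.n_genes)]
    genes_b = [f"G{j:04d}_B" for j in range(cfg.n_genes)]
    a = ExpressionMatrix(sample_ids, genes_a, xa, platform="microarray")
    b = ExpressionMatrix(sample_ids, genes_b, xb, platform="rnaseq")
    gene_map = GeneMap(list(zip(genes_a, genes_b)))

    w = rng.standard_normal(cfg.k_shared)
    w /= np.linalg.norm(w)
    score = z @ w  # ~ N(0,1) per sample
    endpoints = {}
    for name, beta in cfg.betas.items():
        p = 1.0 / (1.0 + np.exp(-beta * score))
        y = (rng.random(cfg.n_samples) < p).astype(int)
        if y.min() == y.max():  # pathological draw at extreme beta/tiny n
            y[np.argmax(score if y[0] == 0 else -score)] = 1 - y[0]
        endpoints[name] = EndpointLabels(name, list(sample_ids), y)

    truth = CohortTruth(
        z=z, u={"microarray": ua, "rnaseq": ub},
        W=W, V={"microarray": Va, "rnaseq": Vb},
        c={"microarray": ca, "rnaseq": cb},
        w_endpoint=w, endpoint_logit_scores=score,
    )
    return a, b, gene_map, endpoints, truth


def train_test_split_cohort(labels: EndpointLabels, train_fraction: float,
                            seed: int) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive, label-stratified sample-id split."""
    counts = np.bincount(labels.labels, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples to stratify the split")
    train_ids, test_ids = train_test_split(
        labels.sample_ids, train_size=train_fraction,
        stratify=labels.labels, random_state=seed % (2 ** 31 - 1),
    )
    return list(train_ids), list(test_ids)
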