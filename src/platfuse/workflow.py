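"""Composition helpers tying alignment, normalization, the three encoding
networks and feature extraction into one pipeline, shared by the CLI and the
test/benchmark scripts."""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .encoders import (EncoderSpec, EncodingNetwork, LatentFeatures, TrainLog,
                       concat_features, encode, train_ae, train_cross, train_pooled)
from .io_data import (ExpressionMatrix, GeneMap, NormalizationParams,
                      align_platforms, apply_minmax, fit_minmax)

# seed offsets so the four networks never share an init by accident
_SEED_OFFSETS = {"ae_a": 0, "ae_b": 101, "pooled": 202, "cross": 303}


def prepare_normalized(a: ExpressionMatrix, b: ExpressionMatrix, gene_map: GeneMap,
                       fit_sample_ids: list[str] | None = None
                       ) -> tuple[ExpressionMatrix, ExpressionMatrix, NormalizationParams]:
    """Align both platforms to the gene map and min-max normalize jointly.

    One normalization is fitted on the pooled rows of both platforms
    (optionally restricted to ``fit_sample_ids``, e.g. the training split)
    and applied to both, so both platforms live in a single [0, 1] feature
    space and genuine between-platform shifts survive normalization.
    Platform-B columns are relabeled to platform-A gene ids, the shared
    mapped feature space.
    """
    a_al, b_al = align_platforms(a, b, gene_map)
    b_al = dc_replace(b_al, gene_ids=list(a_al.gene_ids))
    fit_a = a_al.subset_samples(fit_sample_ids) if fit_sample_ids else a_al
    fit_b = b_al.subset_samples(fit_sample_ids) if fit_sample_ids else b_al
    pooled = ExpressionMatrix(
        [f"{s}@A" for s in fit_a.sample_ids] + [f"{s}@B" for s in fit_b.sample_ids],
        list(a_al.gene_ids),
        np.vstack([fit_a.values, fit_b.values]),
        platform="other",
    )
    params = fit_minmax(pooled)
    return apply_minmax(a_al, params), apply_minmax(b_al, params), params


@dataclass
class EncoderBundle:
    """The four trained networks: one AE per platform, pooled, and cross."""

    ae: dict[str, EncodingNetwork]  # keyed by platform
    pooled: EncodingNetwork
    cross: EncodingNetwork
    logs: dict[str, TrainLog]


def train_encoder_bundle(a: ExpressionMatrix, b: ExpressionMatrix,
                         spec: EncoderSpec) -> EncoderBundle:
    """Train all encoding networks on normalized, aligned matrices."""
    def with_seed(offset):
        return dc_replace(spec, seed=spec.seed + offset)

    ae_a, log_a = train_ae(a, with_seed(_SEED_OFFSETS["ae_a"]))
    ae_b, log_b = train_ae(b, with_seed(_SEED_OFFSETS["ae_b"]))
    pooled, log_p = train_pooled(a, b, with_seed(_SEED_OFFSETS["pooled"]))
    cross, log_c = train_cross(a, b, with_seed(_SEED_OFFSETS["cross"]))
    return EncoderBundle(
        ae={a.platform: ae_a, b.platform: ae_b},
        pooled=pooled,
        cross=cross,
        logs={f"ae_{a.platform}": log_a, f"ae_{b.platform}": log_b,
              "pooled": log_p, "cross": log_c},
    )


def fused_features(bundle: EncoderBundle, x: ExpressionMatrix) -> LatentFeatures:
    """ae + pooled + cross bottleneck blocks for one platform's samples."""
    return concat_features(
        encode(bundle.ae[x.platform], x),
        encode(bundle.pooled, x),
        encode(bundle.cross, x),
    )


def latent_pair(bundle: EncoderBundle, a: ExpressionMatrix, b: ExpressionMatrix,
                source: str) -> tuple[LatentFeatures, LatentFeatures]:
    """Per-platform latent blocks for one feature source, for diagnostics.

    ``source``: "ae" uses each platform's own autoencoder (two distinct
    models); "pooled"/"cross" use the single shared network; "fused"
    concatenates all three blocks per platform.
    """
    if source == "ae":
        return encode(bundle.ae[a.platform], a), encode(bundle.ae[b.platform], b)
    if source == "pooled":
        return encode(bundle.pooled, a), encode(bundle.pooled, b)
    if source == "cross":
        return encode(bundle.cross, a), encode(bundle.cross, b)
    if source == "fused":
        return fused_features(bundle, a), fused_features(bundle, b)
    raise ValueError(f"unknown feature source {source!r}")
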