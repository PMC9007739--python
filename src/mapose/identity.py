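"""Consumers of externally supplied identity scores and embeddings.

Identity information enters the pipeline from outside (e.g. a network
trained to recognize individuals): per-detection probability vectors over
named individuals, or fixed-length appearance embedding vectors per
tracklet. Three uses are exposed: grouping keypoints by identity during
assembly, soft voting during frame-by-frame tracking, and down-weighting
stitch edges between tracklets of similar appearance.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np


def soft_vote(
    member_probs: Sequence[np.ndarray],
) -> tuple[int | None, float]:
    """Soft-voting over an assembly's bodyparts.

    Each bodypart acts as an individual classifier supplying an identity
    probability vector; the assembly's label is the argmax of the mean
    vector and the confidence is that mean probability. Ties break toward
    the lower individual index; no scores yield (None, 0.0).
    """
    probs = [np.asarray(p, dtype=float) for p in member_probs if p is not None]
    if not probs:
        return None, 0.0
    mean = np.mean(probs, axis=0)
    label = int(np.argmax(mean))  # argmax takes the first maximum: tie rule
    return label, float(mean[label])


def tracklet_cosine(e1: np.ndarray, e2: np.ndarray) -> float:
    """Cosine similarity of two embedding vectors, in [-1, 1]."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape:
        raise ValueError("embedding dimensions differ")
    n1, n2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-norm embedding")
    return float(np.clip(e1 @ e2 / (n1 * n2), -1.0, 1.0))


def triplet_accuracy(
    embeddings: Mapping[int, np.ndarray] | Sequence[np.ndarray],
    triplets: Sequence[tuple[int, int, int]],
) -> float:
    """Fraction of (anchor, positive, negative) triplets ranked correctly.

    A triplet counts as correct when cos(anchor, positive) strictly
    exceeds cos(anchor, negative); ties count as failures.
    """
    if not triplets:
        return 0.0
    correct = 0
    for a, p, n in triplets:
        cp = tracklet_cosine(embeddings[a], embeddings[p])
        cn = tracklet_cosine(embeddings[a], embeddings[n])
        if cp > cn:
            correct += 1
    return correct / len(triplets)


def synthetic_embeddings(
    tracklet_ids: Sequence[int],
    true_identity: Mapping[int, int],
    n_identities: int,
    dim: int = 128,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Informative synthetic appearance embeddings (a stand-in for a trained
    re-identification model, labelled synthetic).

    Each identity gets a fixed random unit prototype; a tracklet's
    embedding is its identity prototype plus isotropic Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    protos = rng.normal(size=(n_identities, dim))
    protos /= np.linalg.norm(protos, axis=1, keepdims=True)
    out = {}
    for tid in tracklet_ids:
        ident = true_identity[tid]
        vec = protos[ident] + rng.normal(0.0, noise_sd, size=dim)
        out[tid] = vec
    return out
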