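"""Nearest shrunken centroid (NSC) molecular subtyping.

Implements the PAM-style classifier over a 50-gene intrinsic-subtype panel,
restricted to the four clinically emphasized classes (Basal-like, Luminal
A, Luminal B, HER2-enriched); the Normal-like class is deliberately
excluded.

Training soft-thresholds the standardized class-vs-overall centroid
differences

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),
    d'_ik = sign(d_ik) * max(|d_ik| - delta, 0),

with s_i the pooled within-class standard deviation of gene i, s0 the
median of the s_i (a fudge factor guarding against near-zero dispersions)
and m_k = sqrt(1/n_k + 1/n) by default (sqrt(1/n_k - 1/n) is available
behind a switch, as some implementations use it).  Shrunken centroids are
reconstructed as xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik.  Classification
minimizes the discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k,

with ties broken by the fixed class order above.

Published PAM50 centroid values are not redistributed; only the gene list
ships with the package, and centroids are always estimated from training
data supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import DataFormatError, DegenerateDataError

SUBTYPE_CLASSES = ("Basal", "LumA", "LumB", "Her2")


def pam50_genes() -> list[str]:
    """The packaged 50-gene intrinsic-subtype panel."""
    text = resources.files("seqdx.data").joinpath("pam50_genes.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass
class ShrunkenCentroidModel:
    genes: list[str]
    classes: list[str]
    overall_centroid: np.ndarray  # (g,)
    shrunken_centroids: np.ndarray  # (g, k)
    s: np.ndarray  # pooled within-class sd per gene, (g,)
    s0: float  # median of s
    priors: np.ndarray  # (k,)
    delta: float
    d_shrunk: np.ndarray  # (g, k) soft-thresholded standardized differences

    @property
    def active_genes(self) -> list[str]:
        """Genes with a non-zero shrunken difference for at least one class."""
        mask = np.any(self.d_shrunk != 0.0, axis=1)
        return [g for g, m in zip(self.genes, mask) if m]


def train_nsc(m, labels, delta: float = 0.0, priors=None,
              minus_variant: bool = False) -> ShrunkenCentroidModel:
    """Train a nearest shrunken centroid model.

    Parameters
    ----------
    m
        ExpressionMatrix (scale log2), genes x samples.
    labels
        Per-sample class labels (aligned with ``m.sample_ids`` or a mapping
        / Series indexed by sample id).
    delta
        Shrinkage threshold (>= 0).  delta=0 reproduces plain standardized
        centroids.
    priors
        Class priors; defaults to empirical class frequencies.
    minus_variant
        Use m_k = sqrt(1/n_k - 1/n) instead of sqrt(1/n_k + 1/n).
    """
    if m.scale != "log2":
        raise DataFormatError("train_nsc expects a log2-scale matrix")
    if delta < 0:
        raise DataFormatError(f"delta must be >= 0, got {delta}")
    y = _align_labels(labels, m.sample_ids)
    classes = sorted(set(y), key=lambda c: (SUBTYPE_CLASSES.index(c)
                                            if c in SUBTYPE_CLASSES else len(SUBTYPE_CLASSES),
                                            c))
    if len(classes) < 2:
        raise DegenerateDataError("at least 2 classes are required")
    X = m.values.to_numpy(dtype=float)  # (g, n)
    n = X.shape[1]
    nk = np.array([(y == c).sum() for c in classes])
    if (nk < 2).any():
        bad = [c for c, k in zip(classes, nk) if k < 2]
        raise DegenerateDataError(f"classes with fewer than 2 samples: {', '.join(bad)}")

    overall = X.mean(axis=1)
    centroids = np.column_stack([X[:, y == c].mean(axis=1) for c in classes])
    within_ss = np.zeros(X.shape[0])
    for j, c in enumerate(classes):
        dev = X[:, y == c] - centroids[:, [j]]
        within_ss += (dev ** 2).sum(axis=1)
    s = np.sqrt(within_ss / (n - len(classes)))
    s0 = float(np.median(s))
    if minus_variant:
        mk = np.sqrt(np.maximum(1.0 / nk - 1.0 / n, 0.0))
    else:
        mk = np.sqrt(1.0 / nk + 1.0 / n)
    denom = mk[None, :] * (s + s0)[:, None]
    d = (centroids - overall[:, None]) / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall[:, None] + denom * d_shrunk

    if priors is None:
        pri = nk / n
    else:
        if isinstance(priors, dict):
            pri = np.array([priors[c] for c in classes], dtype=float)
        else:
            pri = np.asarray(priors, dtype=float)
        if len(pri) != len(classes) or (pri < 0).any() or abs(pri.sum() - 1.0) > 1e-9:
            raise DataFormatError("priors must be non-negative and sum to 1 over the classes")

    return ShrunkenCentroidModel(
        genes=list(m.gene_ids), classes=list(classes), overall_centroid=overall,
        shrunken_centroids=shrunken, s=s, s0=s0, priors=pri, delta=float(delta),
        d_shrunk=d_shrunk,
    )


def classify_nsc(model: ShrunkenCentroidModel, sample_expression):
    """Classify one sample or a whole matrix.

    ``sample_expression`` may be a Series / dict of gene -> log2 value, or
    an ExpressionMatrix; returns ``(subtype, scores)`` for a single sample
    or ``(Series of subtypes, DataFrame of scores)`` for a matrix.  The
    discriminant scores are lower-is-better.
    """
    from .expression import ExpressionMatrix  # local import to avoid cycle

    if isinstance(sample_expression, ExpressionMatrix):
        sub = sample_expression.subset_genes(model.genes)
        X = sub.values.to_numpy(dtype=float)
        calls, scores = _discriminant(model, X)
        return (
            pd.Series(calls, index=sub.sample_ids, name="subtype"),
            pd.DataFrame(scores.T, index=sub.sample_ids, columns=model.classes),
        )
    vec = pd.Series(sample_expression)
    missing = [g for g in model.genes if g not in vec.index]
    if missing:
        raise DataFormatError(f"missing model genes: {', '.join(missing)}")
    X = vec.loc[model.genes].to_numpy(dtype=float)[:, None]
    calls, scores = _discriminant(model, X)
    return calls[0], dict(zip(model.classes, scores[:, 0]))


def _discriminant(model: ShrunkenCentroidModel, X: np.ndarray):
    """delta_k per class for columns of X; argmin with fixed-order ties."""
    w = (model.s + model.s0) ** 2  # (g,)
    scores = np.empty((len(model.classes), X.shape[1]))
    for j in range(len(model.classes)):
        dev = X - model.shrunken_centroids[:, [j]]
        scores[j] = (dev ** 2 / w[:, None]).sum(axis=0) - 2.0 * np.log(model.priors[j])
    best = np.argmin(scores, axis=0)  # argmin takes the first minimum: fixed class order
    calls = np.array(model.classes, dtype=object)[best]
    return calls, scores


def write_nsc_model(model: ShrunkenCentroidModel, path) -> None:
    """Serialize as TSV: gene, overall centroid, per-class shrunken
    centroids, s_i; metadata (s0, delta, priors) in header comments."""
    with open(path, "w") as fh:
        fh.write(f"# s0={model.s0!r}\tdelta={model.delta!r}\n")
        fh.write("# priors=" + ",".join(f"{c}:{p!r}" for c, p in zip(model.classes, model.priors)) + "\n")
        cols = ["gene", "overall"] + [f"centroid_{c}" for c in model.classes] + ["s"]
        fh.write("\t".join(cols) + "\n")
        for i, g in enumerate(model.genes):
            row = [g, repr(model.overall_centroid[i])]
            row += [repr(v) for v in model.shrunken_centroids[i]]
            row.append(repr(model.s[i]))
            fh.write("\t".join(row) + "\n")


def _align_labels(labels, sample_ids) -> np.ndarray:
    if isinstance(labels, pd.Series):
        return labels.loc[list(sample_ids)].to_numpy()
    if isinstance(labels, dict):
        return np.array([labels[s] for s in sample_ids])
    arr = np.asarray(labels)
    if len(arr) != len(sample_ids):
        raise DataFormatError("labels length does not match number of samples")
    return arr
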