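"""Gene-expression signature scoring: coherence filtering and activity.

A signature is a gene set expected to move together transcriptionally.  Two
quantities are computed from the expression matrix:

* the **coherence score** ``CS`` of a signature -- the mean pairwise Pearson
  correlation between its genes across samples, in [-1, 1].  Signatures with
  ``CS`` below a threshold (default 0.1) are considered incoherently
  expressed and dropped from the feature space.
* the per-sample **activity score** -- each gene is z-scored across samples,
  then the z-scores are averaged over the signature's genes, giving one
  continuous feature per retained signature.

By default z-scoring statistics come from the full sample set ("global"
scope), matching how such scores are usually computed on a complete screen
before any train/test splitting; a "train_only" scope is available to keep
the transform free of test-set information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["SignatureScores", "coherence_score", "signature_activity", "filter_signatures", "score_signatures"]

DEFAULT_CS_THRESHOLD = 0.1


class UndefinedScoreError(ValueError):
    """Raised when a score has no valid value (e.g. no correlatable gene pair)."""


@dataclass
class SignatureScores:
    """Coherence scores plus activity matrix for the retained signatures."""

    cs: dict[str, float]
    activity: pd.DataFrame  # samples x retained signatures
    retained: list[str]
    threshold: float | None = None

    def __post_init__(self) -> None:
        if list(self.activity.columns) != list(self.retained):
            raise ValueError("activity columns must be exactly the retained signatures")


def coherence_score(X: np.ndarray | pd.DataFrame, axis: str = "genes") -> float:
    """Mean pairwise Pearson correlation of a signature's expression block.

    Parameters
    ----------
    X : array of shape (genes, samples) for one signature.
    axis : which vectors to correlate. The default ``"genes"`` correlates the
        gene rows across samples, so the score reads as the average
        co-expression of the signature's genes.  ``"samples"`` correlates the
        sample columns instead and is provided for comparison only.

    Zero-variance genes cannot enter a Pearson correlation; their pairs are
    excluded with a warning.  If fewer than two usable genes remain the score
    is undefined and :class:`UndefinedScoreError` is raised.
    """
    M = np.asarray(X, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-D genes x samples matrix")
    if axis == "samples":
        M = M.T
    elif axis != "genes":
        raise ValueError("axis must be 'genes' or 'samples'")
    if M.shape[0] < 2:
        raise UndefinedScoreError("coherence requires at least two genes")
    sds = M.std(axis=1)
    keep = sds > 0
    if keep.sum() < M.shape[0]:
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance gene(s) from coherence",
            stacklevel=2,
        )
    M = M[keep]
    if M.shape[0] < 2:
        raise UndefinedScoreError("no valid gene pair remains after dropping zero-variance genes")
    C = np.corrcoef(M)
    iu = np.triu_indices_from(C, k=1)
    return float(np.clip(C[iu].mean(), -1.0, 1.0))


def signature_activity(
    expression: pd.DataFrame,
    sets: GeneSetCollection,
    scope: str = "global",
    train_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample activity of each signature (mean of per-gene z-scores).

    ``expression`` is samples x genes.  With ``scope="train_only"`` the
    z-scoring mean/sd come from ``train_samples`` only but scores are emitted
    for all samples.  Genes absent from the matrix are dropped (count logged);
    a signature with no present gene, or only zero-variance genes, is excluded
    with a warning.
    """
    if scope not in ("global", "train_only"):
        raise ValueError("scope must be 'global' or 'train_only'")
    if scope == "train_only":
        if train_samples is None:
            raise ValueError("train_only scope requires train_samples")
        ref = expression.loc[train_samples]
    else:
        ref = expression

    columns: dict[str, np.ndarray] = {}
    for name, genes in sets:
        present = [g for g in genes if g in expression.columns]
        dropped = len(genes) - len(present)
        if dropped:
            logger.info("signature %s: %d gene(s) absent from expression matrix", name, dropped)
        if not present:
            warnings.warn(f"signature {name!r} has no gene in the expression matrix; excluded", stacklevel=2)
            continue
        block = expression[present].to_numpy(dtype=float)
        mu = ref[present].to_numpy(dtype=float).mean(axis=0)
        sd = ref[present].to_numpy(dtype=float).std(axis=0)
        usable = sd > 0
        if not usable.any():
            warnings.warn(f"signature {name!r} has only zero-variance genes; excluded", stacklevel=2)
            continue
        z = (block[:, usable] - mu[usable]) / sd[usable]
        columns[name] = z.mean(axis=1)
    return pd.DataFrame(columns, index=expression.index)


def filter_signatures(scores: SignatureScores, threshold: float = DEFAULT_CS_THRESHOLD) -> SignatureScores:
    """Retain signatures with ``CS >= threshold``; restrict activity accordingly."""
    retained = [s for s in scores.cs if s in scores.activity.columns and scores.cs[s] >= threshold]
    return SignatureScores(
        cs=dict(scores.cs),
        activity=scores.activity[retained],
        retained=retained,
        threshold=threshold,
    )


def score_signatures(
    expression: pd.DataFrame,
    sets: GeneSetCollection,
    threshold: float = DEFAULT_CS_THRESHOLD,
    scope: str = "global",
    train_samples: list[str] | None = None,
) -> SignatureScores:
    """Compute CS for every signature, then activity for those passing the filter."""
    cs: dict[str, float] = {}
    for name, genes in sets:
        present = [g for g in genes if g in expression.columns]
        if len(present) < 2:
            logger.info("signature %s: <2 genes present, no coherence score", name)
            continue
        block = expression[present].to_numpy(dtype=float).T  # genes x samples
        try:
            cs[name] = coherence_score(block)
        except UndefinedScoreError:
            logger.info("signature %s: coherence undefined", name)
    activity = signature_activity(expression, sets, scope=scope, train_samples=train_samples)
    scored = SignatureScores(
        cs=cs,
        activity=activity[[s for s in activity.columns if s in cs]],
        retained=[s for s in activity.columns if s in cs],
    )
    return filter_signatures(scored, threshold)
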