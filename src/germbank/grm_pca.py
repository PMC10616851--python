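"""Additive genomic relationship matrix (VanRaden) and its PCA.

Missing calls are imputed to the locus mean, markers are centered at twice
the alt-allele frequency, and ``A = W W' / (2 * sum_l p_l (1 - p_l))``. The
principal components are the eigenvectors of ``A`` scaled by the square root
of their (non-negative) eigenvalues; variance explained is relative to the
sum of all eigenvalues after clipping negatives to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, ValidationError


@dataclass
class RelationshipMatrix:
    labels: list[str]
    values: np.ndarray
    locus_means: np.ndarray  # per-locus mean call used to impute missing data

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class PcaResult:
    labels: list[str]
    coordinates: np.ndarray  # accessions x components
    eigenvalues: np.ndarray  # descending, full spectrum of A
    variance_explained: np.ndarray  # per retained component, over all eigenvalues
    degenerate: bool = False  # tied or ~zero eigenvalues among retained components

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.coordinates[:, i] for i in range(self.coordinates.shape[1])}
        return pd.DataFrame(cols, index=pd.Index(self.labels, name="accession_id"))


def relationship_matrix(G: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden additive relationship matrix from 0/1/2 calls."""
    if G.n_accessions < 2:
        raise ValidationError("need at least two accessions")
    calls = G.calls.astype(float)
    present = G.calls != MISSING
    n_called = present.sum(axis=0)
    if np.any(n_called == 0):
        bad = int(np.argmin(n_called))
        raise ValidationError(f"locus {G.locus_ids[bad]!r} has no calls")
    mean_call = np.where(present, calls, 0.0).sum(axis=0) / n_called
    p = mean_call / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValidationError("no segregating loci; relationship matrix undefined")
    X = np.where(present, calls, mean_call)
    W = X - mean_call
    A = (W @ W.T) / denom
    A = 0.5 * (A + A.T)
    return RelationshipMatrix(list(G.accession_ids), A, mean_call)


def pca(A: RelationshipMatrix, n_components: int = 10) -> PcaResult:
    """Eigendecomposition of the relationship matrix.

    Components are ordered by descending eigenvalue; each eigenvector's sign
    is fixed so its largest-magnitude loading is positive, and coordinates
    are eigenvectors scaled by sqrt(max(eigenvalue, 0)). Requesting more
    components than available pads with ~zero eigenvalues and sets the
    ``degenerate`` flag.
    """
    vals, vecs = np.linalg.eigh(A.values)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    clipped = np.clip(vals, 0.0, None)
    total = clipped.sum()
    k = min(n_components, len(vals))
    degenerate = n_components > len(vals)
    coords = np.empty((len(A.labels), k))
    var_exp = np.empty(k)
    for i in range(k):
        v = vecs[:, i]
        pivot = int(np.argmax(np.abs(v)))
        if v[pivot] < 0:
            v = -v
        coords[:, i] = v * np.sqrt(clipped[i])
        var_exp[i] = clipped[i] / total if total > 0 else 0.0
        if clipped[i] <= 1e-10 * max(total, 1.0):
            degenerate = True
    # detect (near-)tied retained eigenvalues: coordinates only defined up to rotation
    if k > 1 and np.any(np.abs(np.diff(vals[:k])) <= 1e-10 * max(abs(vals[0]), 1.0)):
        degenerate = True
    return PcaResult(
        labels=list(A.labels),
        coordinates=coords,
        eigenvalues=vals,
        variance_explained=var_exp,
        degenerate=degenerate,
    )
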