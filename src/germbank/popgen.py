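"""Per-group diversity statistics and Nei's G_ST differentiation.

Gene diversity at a biallelic locus is ``h = 2p(1-p)`` with ``p`` the
alt-allele frequency in the group; the group's Nei index is the mean of
``h`` over all loci with a defined frequency (monomorphic loci contribute 0).
Differentiation between groups is Nei's G_ST = (H_T - H_S)/H_T computed as a
multi-locus ratio of sums, with H_S the unweighted mean of the within-group
diversities and H_T the diversity at the unweighted mean allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, ValidationError


@dataclass
class DiversityReport:
    group: str
    n_accessions: int
    n_loci: int
    n_segregating: int
    nei_index: float


@dataclass
class FstMatrix:
    """Pairwise Nei G_ST between groups (symmetric, zero diagonal)."""

    labels: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def group_allele_freqs(G: GenotypeMatrix, member_ids: Sequence[str]) -> np.ndarray:
    """Per-locus alt-allele frequency within the group (NaN where no calls).

    Frequencies are allele-count based over non-missing calls: a het
    contributes one alt allele, a hom-alt two.
    """
    if len(member_ids) == 0:
        raise ValidationError("empty member set")
    calls = G.calls[G.row_indices(member_ids)]
    called = calls != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)


def nei_diversity(
    G: GenotypeMatrix,
    member_ids: Sequence[str],
    group: str = "group",
    unbiased: bool = False,
) -> DiversityReport:
    """Nei's gene diversity and segregating-locus count for one group.

    ``unbiased=True`` applies the small-sample correction ``2n/(2n-1)`` to
    each locus diversity (off by default; reported indices are plug-in).
    """
    p = group_allele_freqs(G, member_ids)
    defined = ~np.isnan(p)
    h = 2.0 * p[defined] * (1.0 - p[defined])
    if unbiased:
        calls = G.calls[G.row_indices(member_ids)][:, defined]
        n_called = (calls != MISSING).sum(axis=0)
        h = h * (2.0 * n_called) / np.maximum(2.0 * n_called - 1.0, 1.0)
    nei = float(h.mean()) if h.size else float("nan")
    seg = int(((p > 0.0) & (p < 1.0)).sum())
    return DiversityReport(
        group=group,
        n_accessions=len(member_ids),
        n_loci=int(defined.sum()),
        n_segregating=seg,
        nei_index=nei,
    )


def gst(G: GenotypeMatrix, groups: Mapping[str, Sequence[str]]) -> float:
    """Multi-locus Nei G_ST across two or more groups.

    Only loci with a defined frequency in every group are used. Per locus,
    ``H_S = mean_g 2 p_g (1 - p_g)`` and ``H_T = 2 pbar (1 - pbar)`` with
    ``pbar`` the unweighted mean of the group frequencies; the multi-locus
    value is ``sum(H_T - H_S) / sum(H_T)`` (0 when every locus has H_T = 0).
    """
    if len(groups) < 2:
        raise ValidationError("G_ST requires at least two groups")
    freqs = np.vstack([group_allele_freqs(G, ids) for ids in groups.values()])
    defined = ~np.isnan(freqs).any(axis=0)
    if not defined.any():
        raise ValidationError("no locus has defined frequencies in every group")
    p = freqs[:, defined]
    h_s = (2.0 * p * (1.0 - p)).mean(axis=0)
    pbar = p.mean(axis=0)
    h_t = 2.0 * pbar * (1.0 - pbar)
    denom = h_t.sum()
    if denom == 0.0:
        return 0.0
    return float((h_t - h_s).sum() / denom)


def pairwise_gst(
    G: GenotypeMatrix, group_a_ids: Sequence[str], group_b_ids: Sequence[str]
) -> float:
    """Nei G_ST between two groups (symmetric in the arguments)."""
    return gst(G, {"a": group_a_ids, "b": group_b_ids})


def fst_matrix(G: GenotypeMatrix, groups: Mapping[str, Sequence[str]]) -> FstMatrix:
    """All pairwise G_ST values between the given groups."""
    labels = list(groups)
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pairwise_gst(G, groups[labels[i]], groups[labels[j]])
    return FstMatrix(labels=labels, values=out)


def maf_spectrum(
    G: GenotypeMatrix, bins: int | Sequence[float] = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-locus minor-allele frequencies over [0, 0.5].

    Returns ``(counts, bin_edges)``; counts sum to the number of loci with a
    defined MAF. An empty matrix yields all-zero counts.
    """
    from .genotype_io import site_stats

    if G.n_loci == 0:
        edges = np.histogram_bin_edges([], bins=bins, range=(0.0, 0.5))
        return np.zeros(len(edges) - 1, dtype=int), edges
    maf = site_stats(G)["maf"].to_numpy()
    maf = maf[~np.isnan(maf)]
    return np.histogram(maf, bins=bins, range=(0.0, 0.5))


def diversity_table(
    G: GenotypeMatrix, groups: Mapping[str, Sequence[str]], unbiased: bool = False
) -> pd.DataFrame:
    """Per-group diversity summary (group, n_accessions, segregating, Nei index)."""
    reports = [nei_diversity(G, ids, group=g, unbiased=unbiased) for g, ids in groups.items()]
    return pd.DataFrame(
        {
            "group": [r.group for r in reports],
            "n_accessions": [r.n_accessions for r in reports],
            "segregating_loci": [r.n_segregating for r in reports],
            "nei_index": [r.nei_index for r in reports],
        }
    )
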