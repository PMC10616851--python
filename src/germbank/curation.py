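"""Two-step gene-bank curation: misclassification flags and duplicate sets.

Step 1 flags accessions whose recorded species disagrees with their genetic
neighborhood (k-nearest-neighbor majority vote on a genetic distance matrix,
an algorithmic stand-in for visual inspection of a colored phylogeny).

Step 2 finds genetically identical accessions by identity-by-state (IBS)
allele matching over sites that are homozygous and non-missing in both
members of a pair; pairs above the IBS threshold (default 99%) are linked and
duplicate sets are the connected components of that graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .genotype_io import (
    DUPLICATE_PREFILTER,
    MISSING,
    AccessionRecord,
    FilterParams,
    GenotypeMatrix,
    ValidationError,
    filter_sites,
)

logger = logging.getLogger("germbank")


@dataclass
class PairwiseMatch:
    """IBS comparison between two accessions over mutually homozygous sites."""

    accession_a: str
    accession_b: str
    n_compared: int
    n_matching: int
    self_comparison: bool = False

    @property
    def ibs(self) -> float | None:
        """Fraction of compared sites with identical calls; None if no overlap."""
        if self.n_compared == 0:
            return None
        return self.n_matching / self.n_compared


@dataclass
class DuplicateGroups:
    """Connected components of the above-threshold IBS graph (size >= 2)."""

    groups: list[list[str]]
    threshold: float
    pairs: list[PairwiseMatch] = field(default_factory=list)
    low_overlap_pairs: list[PairwiseMatch] = field(default_factory=list)
    sub_threshold_within_groups: list[PairwiseMatch] = field(default_factory=list)

    @property
    def n_sets(self) -> int:
        return len(self.groups)

    @property
    def n_members(self) -> int:
        return sum(len(g) for g in self.groups)


@dataclass
class MisclassificationFlag:
    """An accession whose genetic neighbors vote for a different species."""

    accession_id: str
    recorded_species: str
    suggested_species: str
    support: float  # fraction of the k neighbors carrying suggested_species


# ---------------------------------------------------------------------------
# Identity by state
# ---------------------------------------------------------------------------

def pairwise_ibs(G: GenotypeMatrix, a: str, b: str) -> PairwiseMatch:
    """IBS between accessions ``a`` and ``b``.

    Sites where either call is heterozygous or missing are excluded; the IBS
    is the exact rational n_matching / n_compared.
    """
    ca, cb = G.row(a), G.row(b)
    hom = ((ca == 0) | (ca == 2)) & ((cb == 0) | (cb == 2))
    n_compared = int(hom.sum())
    n_matching = int((ca[hom] == cb[hom]).sum())
    return PairwiseMatch(a, b, n_compared, n_matching, self_comparison=(a == b))


def ibs_matrix(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs IBS via matrix products.

    Returns ``(ibs, n_compared)`` arrays of shape (n, n); ``ibs`` is NaN where
    no site is mutually homozygous. Matches :func:`pairwise_ibs` exactly.
    """
    hom0 = (G.calls == 0).astype(np.float64)
    hom2 = (G.calls == 2).astype(np.float64)
    hom = hom0 + hom2
    n_compared = hom @ hom.T
    n_matching = hom0 @ hom0.T + hom2 @ hom2.T
    with np.errstate(divide="ignore", invalid="ignore"):
        ibs = np.where(n_compared > 0, n_matching / n_compared, np.nan)
    return ibs, n_compared.astype(np.int64)


def find_duplicates(
    G: GenotypeMatrix,
    metadata: list[AccessionRecord] | None = None,
    ibs_threshold: float = 0.99,
    prefilter: FilterParams | None = DUPLICATE_PREFILTER,
    min_overlap: int = 100,
    group_by_species: bool = True,
) -> DuplicateGroups:
    """Detect genetically identical accessions by IBS allele matching.

    Markers are prefiltered (default MAF > 0.01, missing < 50%, het < 20%)
    per analysis group before matching; ``prefilter=None`` disables this. When ``metadata`` is given and
    ``group_by_species`` is True, matching runs within each recorded species
    (duplicates across species labels are a misclassification problem, not a
    redundancy one). Pairs with IBS > ``ibs_threshold`` and at least
    ``min_overlap`` mutually homozygous sites become graph edges; duplicate
    sets are connected components of size >= 2. Within-component pairs that
    fall below the threshold are annotated, not split.
    """
    if G.n_accessions < 2:
        raise ValidationError("need at least two accessions")
    if metadata is not None and group_by_species:
        by_species: dict[str, list[str]] = {}
        for r in metadata:
            by_species.setdefault(r.recorded_species, []).append(r.accession_id)
        partitions = [ids for ids in by_species.values() if len(ids) >= 2]
    else:
        partitions = [G.accession_ids]

    graph = nx.Graph()
    pairs: list[PairwiseMatch] = []
    low_overlap: list[PairwiseMatch] = []
    for ids in partitions:
        sub = G.subset(accession_ids=ids)
        if prefilter is not None:
            sub = filter_sites(sub, prefilter)
        if sub.n_loci == 0:
            logger.warning("duplicate prefilter removed all loci for group %r", ids[:3])
            continue
        ibs, n_cmp = ibs_matrix(sub)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if n_cmp[i, j] < min_overlap:
                    if not np.isnan(ibs[i, j]) and ibs[i, j] > ibs_threshold:
                        low_overlap.append(
                            PairwiseMatch(ids[i], ids[j], int(n_cmp[i, j]),
                                          int(round(ibs[i, j] * n_cmp[i, j])))
                        )
                    continue
                if ibs[i, j] > ibs_threshold:
                    m = PairwiseMatch(ids[i], ids[j], int(n_cmp[i, j]),
                                      int(round(ibs[i, j] * n_cmp[i, j])))
                    pairs.append(m)
                    graph.add_edge(ids[i], ids[j], ibs=float(ibs[i, j]))

    groups = [sorted(c) for c in nx.connected_components(graph) if len(c) >= 2]
    groups.sort()
    # annotate within-component pairs that did not themselves pass the threshold
    sub_thr: list[PairwiseMatch] = []
    for comp in groups:
        for i in range(len(comp)):
            for j in range(i + 1, len(comp)):
                if not graph.has_edge(comp[i], comp[j]):
                    sub_thr.append(pairwise_ibs(G, comp[i], comp[j]))
    return DuplicateGroups(
        groups=groups,
        threshold=ibs_threshold,
        pairs=pairs,
        low_overlap_pairs=low_overlap,
        sub_threshold_within_groups=sub_thr,
    )


# ---------------------------------------------------------------------------
# Misclassification flagging
# ---------------------------------------------------------------------------

def flag_misclassified(
    D: "DistanceMatrix",
    records: list[AccessionRecord],
    k: int = 5,
) -> list[MisclassificationFlag]:
    """Flag accessions whose k nearest neighbors vote for another species.

    For each accession the ``k`` nearest non-self neighbors (by genetic
    distance) are collected; if a single species other than the recorded one
    holds a strict majority (> 0.5) among them, a flag is emitted. With fewer
    than ``k`` other accessions available, all of them are used. Majority
    ties produce no flag and are logged as ambiguous.
    """
    labels = {r.accession_id: r.recorded_species for r in records}
    ids = D.labels
    missing = [a for a in ids if a not in labels]
    if missing:
        raise ValidationError(f"no metadata for accessions {missing[:3]!r}")
    n = len(ids)
    flags: list[MisclassificationFlag] = []
    dm = D.values
    for i, acc in enumerate(ids):
        order = np.argsort(dm[i], kind="stable")
        neighbors = [j for j in order if j != i][: min(k, n - 1)]
        if not neighbors:
            continue
        votes: dict[str, int] = {}
        for j in neighbors:
            sp = labels[ids[j]]
            votes[sp] = votes.get(sp, 0) + 1
        top = max(votes.values())
        winners = [sp for sp, v in votes.items() if v == top]
        if len(winners) > 1:
            if labels[acc] not in winners:
                logger.info("ambiguous neighborhood for %s: tie among %s", acc, winners)
            continue
        winner = winners[0]
        support = top / len(neighbors)
        if winner != labels[acc] and support > 0.5:
            flags.append(
                MisclassificationFlag(
                    accession_id=acc,
                    recorded_species=labels[acc],
                    suggested_species=winner,
                    support=support,
                )
            )
    return flags
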