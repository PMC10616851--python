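"""Synthetic multi-species genotype panels with known ground truth.

The generator emulates the structure of a gene-bank GBS panel over a
multi-ploidy wild-wheat-like genus: highly inbred diploid species diverged
under the Balding-Nichols model, allopolyploids carrying the union of calls
over their component subgenomes' locus blocks, planted genetic duplicates,
planted species-label errors, and per-(accession, candidate genome) mapping
evidence with separated present/absent regimes.

Model
-----
Loci are partitioned into disjoint blocks, one per genome symbol. Per block,
ancestral alt-allele frequencies are drawn ``p0 ~ Beta(a, b)``; each species
carrying that genome draws its own frequencies
``p_s ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F)`` where ``F`` is the species'
divergence (the Balding-Nichols F_ST against the ancestral pool). Accessions
are inbred: a call is hom-alt with probability ``p_s``, hom-ref otherwise,
flipped to het with probability ``residual_het``. Diploids are called at
their own block at rate ``1 - missing_rate`` and cross-called at foreign
blocks at ``cross_call_rate`` (emulating conserved restriction sites);
polyploids are called at carried blocks at the evidence "present" loci rate
and at foreign blocks at the "absent" loci rate, mirroring observed
segregating-locus recovery in tetraploids. Everything is reproducible from
the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    AccessionRecord,
    GenotypeMatrix,
    ValidationError,
    write_genotype_tsv,
    write_metadata,
)
from .subgenome import MappingEvidence, canonical_formula, diploid_panel_loci, write_evidence_tsv


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    """One species: its subgenome composition, panel size and divergence."""

    name: str
    genomes: tuple[str, ...]
    n_accessions: int
    fst: float = 0.3  # Balding-Nichols divergence from the ancestral pool

    def __post_init__(self) -> None:
        self.genomes = tuple(self.genomes)
        if not self.genomes:
            raise ValidationError(f"{self.name}: species needs at least one genome")
        from .genotype_io import GENOME_SYMBOLS

        bad = set(self.genomes) - GENOME_SYMBOLS
        if bad:
            raise ValidationError(f"{self.name}: unknown genome symbols {sorted(bad)!r}")
        if not (0.0 < self.fst < 1.0):
            raise ValidationError(f"{self.name}: fst={self.fst} outside (0, 1)")
        if self.n_accessions < 1:
            raise ValidationError(f"{self.name}: n_accessions must be >= 1")

    @property
    def ploidy(self) -> int:
        return 2 * len(self.genomes)

    @property
    def formula(self) -> str:
        return canonical_formula(self.genomes)


@dataclass
class DuplicateSpec:
    """Plant ``n_copies`` near-identical copies of a source accession."""

    source_accession: str
    n_copies: int = 1
    error_rate: float = 0.001   # per-call probability of a random different call
    extra_missing: float = 0.30  # additional missingness on top of the copy


@dataclass
class EvidenceParams:
    """Read- and locus-rate regimes for present vs absent subgenomes."""

    read_present_mean: float = 0.38
    read_present_sd: float = 0.03
    read_absent_mean: float = 0.21
    read_absent_sd: float = 0.03
    loci_present_rate: float = 0.48  # call rate at a carried genome's panel loci
    loci_absent_rate: float = 0.17   # cross-mapped call rate at a foreign genome


@dataclass
class SimulationConfig:
    seed: int
    species: list[SpeciesSpec]
    loci_per_genome: int = 2000
    shared_loci: int = 2000  # genus-wide conserved loci, callable in every species
    ancestral_beta: tuple[float, float] = (0.5, 0.5)
    residual_het: float = 0.02
    missing_rate: float = 0.10
    cross_call_rate: float = 0.15
    duplicate_specs: list[DuplicateSpec] = field(default_factory=list)
    misclassification_rate: float = 0.0
    evidence: EvidenceParams = field(default_factory=EvidenceParams)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("residual_het", "missing_rate", "cross_call_rate", "misclassification_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate species names")


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic panel."""

    true_species: dict[str, str]           # accession -> true species name
    true_formula: dict[str, str]           # species -> canonical genome formula
    true_ploidy: dict[str, int]            # species -> ploidy
    duplicate_sets: list[list[str]]        # each sorted, size >= 2
    mislabeled: dict[str, str]             # accession -> true species (record holds the wrong one)
    panel_loci: dict[str, list[str]]       # genome -> segregating loci of its diploid panel

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------

def _inbred_block(
    rng: np.random.Generator,
    freqs: np.ndarray,
    n: int,
    call_rate: float,
    het_rate: float,
) -> np.ndarray:
    """Calls for ``n`` inbred accessions at one genome block."""
    L = freqs.shape[0]
    calls = (2 * (rng.random((n, L)) < freqs[None, :])).astype(np.int8)
    calls[rng.random((n, L)) < het_rate] = 1
    calls[rng.random((n, L)) >= call_rate] = MISSING
    return calls


def simulate_panel(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, list[AccessionRecord], TruthSet]:
    """Generate the genotype matrix, metadata records and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    genomes: list[str] = []
    for sp in cfg.species:
        for g in sp.genomes:
            if g not in genomes:
                genomes.append(g)
    L = cfg.loci_per_genome
    S = cfg.shared_loci
    locus_ids = [f"core{i:05d}" for i in range(S)]
    locus_ids += [f"{g}{i:05d}" for g in genomes for i in range(L)]
    shared_block = slice(0, S)
    block = {g: slice(S + k * L, S + (k + 1) * L) for k, g in enumerate(genomes)}
    a, b = cfg.ancestral_beta
    p0_shared = np.clip(rng.beta(a, b, size=S), 1e-6, 1.0 - 1e-6)
    p0 = {g: np.clip(rng.beta(a, b, size=L), 1e-6, 1.0 - 1e-6) for g in genomes}

    accession_ids: list[str] = []
    true_species: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for sp in cfg.species:
        carried = set(sp.genomes)
        # species allele frequencies per carried genome (Balding-Nichols)
        ps = {
            g: rng.beta(p0[g] * (1 - sp.fst) / sp.fst, (1 - p0[g]) * (1 - sp.fst) / sp.fst)
            for g in sp.genomes
        }
        calls = np.full((sp.n_accessions, len(locus_ids)), MISSING, dtype=np.int8)
        diploid = sp.ploidy == 2
        if S > 0:
            # conserved genus-wide loci: every species is a Balding-Nichols
            # population at these sites and they are well-called at any ploidy
            ps_shared = rng.beta(
                p0_shared * (1 - sp.fst) / sp.fst, (1 - p0_shared) * (1 - sp.fst) / sp.fst
            )
            calls[:, shared_block] = _inbred_block(
                rng, ps_shared, sp.n_accessions, 1.0 - cfg.missing_rate, cfg.residual_het
            )
        for g in genomes:
            if g in carried:
                rate = (1.0 - cfg.missing_rate) if diploid else cfg.evidence.loci_present_rate
                calls[:, block[g]] = _inbred_block(rng, ps[g], sp.n_accessions, rate, cfg.residual_het)
            else:
                rate = cfg.cross_call_rate if diploid else cfg.evidence.loci_absent_rate
                calls[:, block[g]] = _inbred_block(rng, p0[g], sp.n_accessions, rate, cfg.residual_het)
        for i in range(sp.n_accessions):
            acc = f"{sp.name}_{i:03d}"
            accession_ids.append(acc)
            true_species[acc] = sp.name
        rows.append(calls)
    calls = np.vstack(rows)

    # planted duplicates (appended after the base panel)
    dup_sets: dict[str, list[str]] = {}
    dup_rows: list[np.ndarray] = []
    index_of = {acc: i for i, acc in enumerate(accession_ids)}
    protected = {d.source_accession for d in cfg.duplicate_specs}
    for d in cfg.duplicate_specs:
        if d.source_accession not in index_of:
            raise ValidationError(f"duplicate source {d.source_accession!r} not in panel")
        src = calls[index_of[d.source_accession]]
        for c in range(d.n_copies):
            copy = src.copy()
            called = copy != MISSING
            err = (rng.random(copy.shape) < d.error_rate) & called
            # replace erroneous calls with a uniformly chosen different code
            shift = 1 + (rng.random(copy.shape) < 0.5).astype(np.int8)
            copy[err] = (copy[err] + shift[err]) % 3
            copy[(rng.random(copy.shape) < d.extra_missing) & called] = MISSING
            acc = f"{d.source_accession}_dup{c + 1}"
            dup_sets.setdefault(d.source_accession, [d.source_accession]).append(acc)
            true_species[acc] = true_species[d.source_accession]
            dup_rows.append(copy)
            accession_ids.append(acc)
    if dup_rows:
        calls = np.vstack([calls, np.stack(dup_rows)])
    duplicate_sets = sorted(sorted(v) for v in dup_sets.values())
    dup_members = {a for s in duplicate_sets for a in s}

    # planted species-label errors (never on duplicates or their sources,
    # so the two kinds of injected structure stay orthogonal)
    species_names = [sp.name for sp in cfg.species]
    eligible = [a for a in accession_ids if a not in dup_members and a not in protected]
    n_mis = int(round(cfg.misclassification_rate * len(eligible)))
    mislabeled: dict[str, str] = {}
    recorded = dict(true_species)
    if n_mis > 0 and len(species_names) > 1:
        chosen = rng.choice(len(eligible), size=n_mis, replace=False)
        for idx in sorted(chosen):
            acc = eligible[idx]
            others = [s for s in species_names if s != true_species[acc]]
            recorded[acc] = others[int(rng.integers(len(others)))]
            mislabeled[acc] = true_species[acc]

    spec_by_name = {sp.name: sp for sp in cfg.species}
    records = [
        AccessionRecord(
            accession_id=acc,
            recorded_species=recorded[acc],
            genome_formula=spec_by_name[recorded[acc]].formula,
            ploidy=spec_by_name[recorded[acc]].ploidy,
            origin="synthetic",
        )
        for acc in accession_ids
    ]
    tags = [""] * S + [g for g in genomes for _ in range(L)]
    meta = pd.DataFrame(
        {"ref": "A", "alt": "T", "subgenome": tags},
        index=pd.Index(locus_ids, name="locus_id"),
    )
    G = GenotypeMatrix(accession_ids, locus_ids, calls, meta)

    # realized per-genome diploid panel loci (true labels, diploids only)
    panel_loci: dict[str, list[str]] = {}
    for g in genomes:
        members = [
            acc
            for acc, sp_name in true_species.items()
            if spec_by_name[sp_name].genomes == (g,)
        ]
        if members:
            panel_loci[g] = diploid_panel_loci(G, members, g)

    truth = TruthSet(
        true_species=true_species,
        true_formula={sp.name: sp.formula for sp in cfg.species},
        true_ploidy={sp.name: sp.ploidy for sp in cfg.species},
        duplicate_sets=[list(s) for s in duplicate_sets],
        mislabeled=mislabeled,
        panel_loci=panel_loci,
    )
    return G, records, truth


# ---------------------------------------------------------------------------
# Mapping evidence
# ---------------------------------------------------------------------------

def simulate_evidence(
    cfg: SimulationConfig,
    truth: TruthSet,
    G: GenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> list[MappingEvidence]:
    """Mapping evidence for every polyploid accession x candidate genome.

    Read rates are drawn from the present/absent normal regimes (truncated to
    [0, 1]) according to the true genome formula; locus-recovery rates are
    computed from the actual genotype calls against the per-genome diploid
    panel loci. Candidates are the genomes with a diploid panel.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    ep = cfg.evidence
    candidates = sorted(truth.panel_loci)
    panel_idx = {
        g: np.array([G._col_index[l] for l in loci], dtype=int)
        for g, loci in truth.panel_loci.items()
        if loci
    }
    out: list[MappingEvidence] = []
    for acc in G.accession_ids:
        sp = truth.true_species[acc]
        if truth.true_ploidy[sp] <= 2:
            continue
        formula = truth.true_formula[sp]
        row = G.row(acc)
        for g in candidates:
            if g not in panel_idx:
                continue
            present = g in formula
            mean = ep.read_present_mean if present else ep.read_absent_mean
            sd = ep.read_present_sd if present else ep.read_absent_sd
            read_rate = float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
            loci_rate = float((row[panel_idx[g]] != MISSING).mean())
            out.append(MappingEvidence(acc, g, read_rate, loci_rate))
    return out


# ---------------------------------------------------------------------------
# Canonical study-like configuration
# ---------------------------------------------------------------------------

def default_config(seed: int) -> SimulationConfig:
    """The standard synthetic panel used throughout the test-bench.

    Five inbred diploid species over four genomes (two sharing the S genome,
    as in a *Sitopsis*-like section), one UM allotetraploid and one UX
    allotetraploid whose second subgenome has no diploid representative,
    three planted duplicate sets (sizes 3, 2, 2) and 5% planted species-label
    errors.
    """
    return SimulationConfig(
        seed=seed,
        species=[
            SpeciesSpec("sp_U", ("U",), 20, 0.3),
            SpeciesSpec("sp_M", ("M",), 20, 0.3),
            SpeciesSpec("sp_S1", ("S",), 20, 0.3),
            SpeciesSpec("sp_S2", ("S",), 20, 0.3),
            SpeciesSpec("sp_D", ("D",), 20, 0.3),
            SpeciesSpec("tet_UM", ("U", "M"), 15, 0.3),
            SpeciesSpec("tet_UX", ("U", "X"), 15, 0.3),
        ],
        duplicate_specs=[
            DuplicateSpec("sp_D_000", n_copies=2),
            DuplicateSpec("sp_S1_000"),
            DuplicateSpec("sp_U_000"),
        ],
        misclassification_rate=0.05,
    )


def write_simulation(
    outdir: str | Path,
    G: GenotypeMatrix,
    records: Sequence[AccessionRecord],
    truth: TruthSet,
    evidence: Sequence[MappingEvidence] | None = None,
) -> dict[str, str]:
    """Write genotypes.tsv, metadata.tsv, truth.json (and evidence.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": str(outdir / "genotypes.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_genotype_tsv(G, paths["genotypes"])
    write_metadata(list(records), paths["metadata"])
    truth.to_json(paths["truth"])
    if evidence is not None:
        paths["evidence"] = str(outdir / "evidence.tsv")
        write_evidence_tsv(list(evidence), paths["evidence"])
    return paths
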