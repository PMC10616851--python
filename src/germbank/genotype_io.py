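"""Genotype-matrix I/O, per-site statistics, and marker/accession filtering.

Genotype calls are unphased biallelic dosages coded ``0`` (hom-ref), ``1``
(het), ``2`` (hom-alt) and ``MISSING`` (``-1``). Filtering follows the usual
GBS curation rules: a site is kept when its minor-allele frequency, missing
rate and heterozygosity rate all pass strict-inequality thresholds, and
accessions with an excessive fraction of missing calls are dropped before any
site-level filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("germbank")

#: Sentinel for a missing genotype call (stored in int8 matrices).
MISSING: int = -1

GENOME_SYMBOLS = frozenset("ABCDMNSTUX")


class GermbankError(Exception):
    """Base class for all package errors."""


class ValidationError(GermbankError):
    """Invalid inputs or parameters."""


class ParseError(GermbankError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AccessionRecord:
    """Identity and recorded taxonomy of a gene-bank accession.

    ``genome_formula`` is the symbolic subgenome composition (e.g. ``"MU"``
    for an allotetraploid with M and U subgenomes, ``"X"`` marking an unknown
    subgenome); ``ploidy`` is the somatic chromosome-set count (2, 4 or 6).
    When both are present, ploidy must equal twice the number of genome
    symbols.
    """

    accession_id: str
    recorded_species: str = "unknown"
    genome_formula: str = ""
    ploidy: int | None = None
    origin: str | None = None

    def __post_init__(self) -> None:
        if not self.accession_id:
            raise ValidationError("accession_id must be non-empty")
        if self.genome_formula:
            bad = set(self.genome_formula) - GENOME_SYMBOLS
            if bad:
                raise ValidationError(
                    f"{self.accession_id}: unknown genome symbols {sorted(bad)!r}"
                )
        if self.ploidy is not None and self.genome_formula:
            if self.ploidy != 2 * len(self.genome_formula):
                raise ValidationError(
                    f"{self.accession_id}: ploidy {self.ploidy} inconsistent with "
                    f"genome formula {self.genome_formula!r}"
                )


class GenotypeMatrix:
    """Accessions x loci matrix of biallelic genotype calls.

    Parameters
    ----------
    accession_ids
        Ordered, unique accession keys (rows).
    locus_ids
        Ordered, unique locus keys (columns).
    calls
        int8 array of shape ``(n_accessions, n_loci)`` with entries in
        ``{0, 1, 2, MISSING}``.
    locus_meta
        Optional per-locus table indexed by locus id; recognised columns are
        ``ref``, ``alt``, ``subgenome``, ``chrom``, ``pos``.
    """

    def __init__(
        self,
        accession_ids: Sequence[str],
        locus_ids: Sequence[str],
        calls: np.ndarray,
        locus_meta: pd.DataFrame | None = None,
    ) -> None:
        self.accession_ids = list(accession_ids)
        self.locus_ids = list(locus_ids)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.accession_ids), len(self.locus_ids)):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.locus_ids)} loci"
            )
        valid = np.isin(calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(calls[~valid])
            raise ValidationError(f"invalid genotype codes {bad.tolist()}")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValidationError("duplicate accession ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValidationError("duplicate locus ids")
        self.calls = calls
        if locus_meta is None:
            locus_meta = pd.DataFrame(
                {"ref": "A", "alt": "T"}, index=pd.Index(self.locus_ids, name="locus_id")
            )
        else:
            locus_meta = locus_meta.copy()
            if list(locus_meta.index) != self.locus_ids:
                locus_meta = locus_meta.reindex(self.locus_ids)
            locus_meta.index.name = "locus_id"
        self.locus_meta = locus_meta
        self._row_index = {a: i for i, a in enumerate(self.accession_ids)}
        self._col_index = {l: j for j, l in enumerate(self.locus_ids)}

    # -- basic introspection ------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def row(self, accession_id: str) -> np.ndarray:
        try:
            return self.calls[self._row_index[accession_id]]
        except KeyError:
            raise KeyError(f"unknown accession {accession_id!r}") from None

    def row_indices(self, accession_ids: Iterable[str]) -> np.ndarray:
        return np.array([self._row_index[a] for a in accession_ids], dtype=int)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset(
        self,
        accession_ids: Sequence[str] | None = None,
        locus_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a sub-matrix restricted to the given accessions/loci (order kept)."""
        rows = (
            slice(None)
            if accession_ids is None
            else self.row_indices(accession_ids)
        )
        if locus_ids is None:
            cols = slice(None)
            loci = self.locus_ids
        else:
            cols = np.array([self._col_index[l] for l in locus_ids], dtype=int)
            loci = list(locus_ids)
        accs = self.accession_ids if accession_ids is None else list(accession_ids)
        return GenotypeMatrix(
            accs, loci, self.calls[rows][:, cols], self.locus_meta.loc[loci]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_accessions} accessions x {self.n_loci} loci)"


@dataclass
class FilterParams:
    """Thresholds for site- and accession-level filtering.

    All comparisons are strict: a site is kept iff ``maf > maf_min`` and
    ``missing_rate < site_missing_max`` and ``het_rate < site_het_max``; an
    accession is dropped iff its missing fraction ``> accession_missing_max``.
    """

    maf_min: float = 0.01
    site_missing_max: float = 0.30
    site_het_max: float = 0.10
    accession_missing_max: float = 0.80

    def __post_init__(self) -> None:
        for name in ("maf_min", "site_missing_max", "site_het_max", "accession_missing_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")


#: Relaxed prefilter used before identity-by-state duplicate matching.
DUPLICATE_PREFILTER = FilterParams(
    maf_min=0.01, site_missing_max=0.50, site_het_max=0.20, accession_missing_max=1.0
)


# ---------------------------------------------------------------------------
# Per-site statistics
# ---------------------------------------------------------------------------

def site_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus call statistics.

    Returns a DataFrame indexed like ``G.locus_ids`` with columns
    ``n_called``, ``alt_freq``, ``maf``, ``missing_rate``, ``het_rate`` and
    ``segregating``. Allele frequencies are computed on allele counts over
    non-missing calls (a het contributes one alt allele); loci with zero
    non-missing calls get ``maf``/``alt_freq``/``het_rate`` NaN,
    ``missing_rate`` 1.0 and ``segregating`` False.
    """
    if G.n_loci == 0 or G.n_accessions == 0:
        raise ValidationError("empty genotype matrix")
    calls = G.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_het = (calls == 1).sum(axis=0)
    n_homalt = (calls == 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = np.where(n_called > 0, (2.0 * n_homalt + n_het) / (2.0 * n_called), np.nan)
        het_rate = np.where(n_called > 0, n_het / n_called, np.nan)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    missing_rate = 1.0 - n_called / G.n_accessions
    segregating = np.nan_to_num(maf, nan=0.0) > 0.0
    return pd.DataFrame(
        {
            "n_called": n_called,
            "alt_freq": alt_freq,
            "maf": maf,
            "missing_rate": missing_rate,
            "het_rate": het_rate,
            "segregating": segregating,
        },
        index=pd.Index(G.locus_ids, name="locus_id"),
    )


def filter_sites(G: GenotypeMatrix, params: FilterParams | None = None) -> GenotypeMatrix:
    """Keep sites with ``maf > maf_min``, ``missing < site_missing_max`` and
    ``het < site_het_max`` (strict inequalities).

    Loci with no non-missing calls are always removed (their MAF is
    undefined). The accession set is unchanged; the operation is idempotent.
    """
    params = params or FilterParams()
    stats = site_stats(G)
    keep = (
        (stats["maf"].to_numpy() > params.maf_min)
        & (stats["missing_rate"].to_numpy() < params.site_missing_max)
        & (stats["het_rate"].to_numpy() < params.site_het_max)
    )
    keep &= stats["n_called"].to_numpy() > 0  # NaN stats compare False already
    kept = [l for l, k in zip(G.locus_ids, keep) if k]
    if not kept:
        logger.warning("filter_sites removed every locus")
    return G.subset(locus_ids=kept)


def filter_accessions(
    G: GenotypeMatrix, max_missing: float = 0.80
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop accessions whose missing-call fraction exceeds ``max_missing``."""
    if not (0.0 <= max_missing <= 1.0):
        raise ValidationError(f"max_missing={max_missing} outside [0, 1]")
    miss = G.missing_mask().mean(axis=1)
    removed = [a for a, m in zip(G.accession_ids, miss) if m > max_missing]
    if removed:
        logger.info("removed %d accessions with missing > %.0f%%", len(removed), 100 * max_missing)
    kept = [a for a in G.accession_ids if a not in set(removed)]
    return G.subset(accession_ids=kept), removed


# ---------------------------------------------------------------------------
# Metadata I/O (tab-separated, header required)
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[AccessionRecord]:
    """Read an accession metadata TSV with columns
    ``accession_id, species, genome_formula, ploidy, origin``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "accession_id" not in df.columns:
        raise ParseError(f"{path}: metadata requires an 'accession_id' column")
    if df["accession_id"].duplicated().any():
        dup = df.loc[df["accession_id"].duplicated(), "accession_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate accession_id {dup!r} in metadata")
    records = []
    for row in df.itertuples(index=False):
        ploidy = getattr(row, "ploidy", "")
        records.append(
            AccessionRecord(
                accession_id=row.accession_id,
                recorded_species=getattr(row, "species", "") or "unknown",
                genome_formula=getattr(row, "genome_formula", ""),
                ploidy=int(ploidy) if ploidy not in ("", "NA") else None,
                origin=getattr(row, "origin", "") or None,
            )
        )
    return records


def write_metadata(records: Sequence[AccessionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "accession_id": [r.accession_id for r in records],
            "species": [r.recorded_species for r in records],
            "genome_formula": [r.genome_formula for r in records],
            "ploidy": ["" if r.ploidy is None else r.ploidy for r in records],
            "origin": [r.origin or "" for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype TSV dialect
# ---------------------------------------------------------------------------
# header: locus_id  ref  alt  [subgenome]  <accession ...>
# one row per locus, calls in {0,1,2,NA}

_META_COLS = ("locus_id", "ref", "alt", "subgenome", "chrom", "pos")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "locus_id" not in df.columns:
        raise ParseError(f"{path}: genotype TSV requires a 'locus_id' column")
    meta_cols = [c for c in _META_COLS if c in df.columns]
    acc_cols = [c for c in df.columns if c not in meta_cols]
    if not acc_cols:
        raise ParseError(f"{path}: no accession columns found")
    calls = np.empty((len(acc_cols), len(df)), dtype=np.int8)
    mapping = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "": MISSING}
    for j, col in enumerate(acc_cols):
        try:
            calls[j] = [mapping[v] for v in df[col]]
        except KeyError as exc:
            bad = exc.args[0]
            line = 2 + list(df[col]).index(bad)
            raise ParseError(f"{path}:{line}: invalid call {bad!r} for {col}") from None
    meta = df[meta_cols].set_index("locus_id")
    if "pos" in meta.columns:
        meta["pos"] = pd.to_numeric(meta["pos"])
    return GenotypeMatrix(acc_cols, list(df["locus_id"]), calls, meta)


def write_genotype_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    meta = G.locus_meta.reset_index()
    cols = {c: meta[c] for c in _META_COLS if c in meta.columns}
    rev = {0: "0", 1: "1", 2: "2", MISSING: "NA"}
    for i, acc in enumerate(G.accession_ids):
        cols[acc] = [rev[int(v)] for v in G.calls[i]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF subset (biallelic SNPs, GT subfield only)
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF (GT subfield only).

    Multiallelic records are skipped with a logged warning. ``0/0`` maps to 0,
    ``0/1``/``1/0`` (phased or not) to 1, ``1/1`` to 2 and ``./.`` to MISSING.
    """
    from cyvcf2 import VCF

    try:
        reader = VCF(str(path))
    except Exception as exc:  # htslib reports its own diagnostics
        raise ParseError(f"{path}: cannot parse VCF ({exc})") from exc
    samples = list(reader.samples)
    locus_ids: list[str] = []
    meta_rows: list[tuple[str, str, str, int]] = []
    rows: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for k, var in enumerate(reader):
        if len(var.ALT) != 1:
            logger.warning("%s: skipping multiallelic record %s", path, var.ID or f"#{k + 1}")
            continue
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        locus_ids.append(lid)
        meta_rows.append((var.REF, var.ALT[0], var.CHROM, var.POS))
        rows.append(remap[np.clip(var.gt_types, 0, 3)])
    reader.close()
    if not locus_ids:
        raise ParseError(f"{path}: no biallelic SNP records")
    calls = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    meta = pd.DataFrame(
        meta_rows, columns=["ref", "alt", "chrom", "pos"], index=pd.Index(locus_ids, name="locus_id")
    )
    return GenotypeMatrix(samples, locus_ids, calls.astype(np.int8), meta)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal VCF 4.2 with GT-only sample fields."""
    rev = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    meta = G.locus_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.accession_ids)
            + "\n"
        )
        for j, lid in enumerate(G.locus_ids):
            chrom = str(meta["chrom"].iloc[j]) if "chrom" in meta.columns else "1"
            pos = int(meta["pos"].iloc[j]) if "pos" in meta.columns else j + 1
            ref = str(meta["ref"].iloc[j]) if "ref" in meta.columns else "A"
            alt = str(meta["alt"].iloc[j]) if "alt" in meta.columns else "T"
            gts = "\t".join(rev[int(v)] for v in G.calls[:, j])
            fh.write(f"{chrom}\t{pos}\t{lid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotypes(
    genotype_path: str | Path, metadata_path: str | Path | None = None
) -> tuple[GenotypeMatrix, list[AccessionRecord]]:
    """Read a genotype matrix (VCF or TSV, chosen by extension) plus metadata.

    Accessions present in the genotypes but absent from the metadata receive a
    record with unknown species. Input accession order is preserved.
    """
    genotype_path = Path(genotype_path)
    if genotype_path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        G = read_vcf(genotype_path)
    else:
        G = read_genotype_tsv(genotype_path)
    by_id: dict[str, AccessionRecord] = {}
    if metadata_path is not None:
        by_id = {r.accession_id: r for r in read_metadata(metadata_path)}
    records = [
        by_id.get(a, AccessionRecord(accession_id=a, recorded_species="unknown"))
        for a in G.accession_ids
    ]
    return G, records
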