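"""Readers, writers and validators for the five input table kinds.

All tables are tab-separated UTF-8 with ``#``-prefixed comment lines ignored.
Species-stratified gene-family tables follow the HUMAnN2 dialect
(``GeneFamilyID|Species`` in the first column, one column per sample, values
in copies-per-million); taxonomic profiles follow the MetaPhlAn convention
(species rows, sample columns, relative abundances); haplotype alignments are
per-species FASTA multiple alignments whose record ids are sample ids.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

ROLES = ("mother", "infant")
BREASTFEEDING = ("exclusive", "partial", "none", "unknown")
ALIGNMENT_ALPHABET = frozenset("ACGTN-")

#: per-sample CPM total may not exceed one million (unclassified remainder allowed)
CPM_TOTAL = 1_000_000.0
_CPM_TOL = 1e-3


class TableFormatError(ValueError):
    """Raised when an on-disk table violates its format contract."""


@dataclass(frozen=True)
class SampleMetadata:
    """One sample: who it came from and its feeding context."""

    sample_id: str
    family_id: str
    role: str
    breastfeeding: str = "unknown"
    site: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TableFormatError(
                f"unknown role {self.role!r} for sample {self.sample_id!r}; "
                f"expected one of {ROLES}"
            )
        if self.breastfeeding not in BREASTFEEDING:
            raise TableFormatError(
                f"unknown breastfeeding status {self.breastfeeding!r} for "
                f"sample {self.sample_id!r}; expected one of {BREASTFEEDING}"
            )


class MetadataTable:
    """Collection of :class:`SampleMetadata` with family/role lookups."""

    def __init__(self, records: Iterable[SampleMetadata]):
        self.records = list(records)
        seen: dict[str, SampleMetadata] = {}
        for rec in self.records:
            if rec.sample_id in seen:
                raise TableFormatError(f"duplicate sample_id {rec.sample_id!r}")
            seen[rec.sample_id] = rec
        self._by_id = seen

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> SampleMetadata:
        return self._by_id[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def families(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.family_id not in out:
                out.append(r.family_id)
        return out

    def role_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].role

    def family_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].family_id

    def dyads(self) -> list[tuple[str, str, str]]:
        """(family_id, mother_sample, infant_sample) triples.

        Families with multiple samples per role yield one triple per
        mother x infant combination.
        """
        out = []
        for fam in self.families:
            mothers = [r.sample_id for r in self.records
                       if r.family_id == fam and r.role == "mother"]
            infants = [r.sample_id for r in self.records
                       if r.family_id == fam and r.role == "infant"]
            for m in mothers:
                for i in infants:
                    out.append((fam, m, i))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "family_id": r.family_id,
                    "role": r.role,
                    "breastfeeding": r.breastfeeding,
                    "site": r.site,
                }
                for r in self.records
            ]
        )


def read_metadata(path: str | Path) -> MetadataTable:
    """Read a sample metadata TSV.

    Required columns: ``sample_id``, ``family_id``, ``role``. Optional:
    ``breastfeeding`` (defaults to ``unknown``), ``site``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample_id", "family_id", "role"):
        if col not in df.columns:
            raise TableFormatError(f"metadata is missing required column {col!r}")
    if "breastfeeding" not in df.columns:
        df["breastfeeding"] = "unknown"
    if "site" not in df.columns:
        df["site"] = ""
    df = df.fillna({"breastfeeding": "unknown", "site": ""})
    records = [
        SampleMetadata(
            sample_id=row.sample_id,
            family_id=row.family_id,
            role=row.role,
            breastfeeding=row.breastfeeding,
            site=row.site,
        )
        for row in df.itertuples()
    ]
    return MetadataTable(records)


def write_metadata(meta: MetadataTable, path: str | Path) -> None:
    meta.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# taxonomic profiles


def read_taxonomic_profile(path: str | Path) -> pd.DataFrame:
    """Read a taxonomic profile TSV into a samples x species DataFrame.

    On disk the table is species rows by sample columns (the MetaPhlAn
    orientation). Rows summing to ~100 per sample are rescaled to fractions.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    profile = df.T.astype(float)
    profile.index.name = "sample_id"
    profile.columns.name = "species"
    return validate_taxonomic_profile(profile)


def validate_taxonomic_profile(profile: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    """Check nonnegativity and row sums; rescale percentage-convention rows."""
    if (profile.values < 0).any():
        raise TableFormatError("taxonomic profile contains negative abundances")
    sums = profile.sum(axis=1)
    pct = (sums - 100.0).abs() <= 100.0 * tol
    if pct.any():
        profile = profile.copy()
        profile.loc[pct] = profile.loc[pct].div(sums[pct], axis=0)
        sums = profile.sum(axis=1)
    bad = (sums - 1.0).abs() > tol
    if bad.any():
        raise TableFormatError(
            f"taxonomic profile rows do not sum to 1 (or 100): "
            f"{list(profile.index[bad])[:5]}"
        )
    return profile


def write_taxonomic_profile(profile: pd.DataFrame, path: str | Path) -> None:
    out = profile.T
    out.index.name = "species"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene-family annotation


@dataclass
class AnnotationConfig:
    """How to decide whether a gene family has a functional annotation.

    A gene family is *unannotated* when its id is in ``unannotated_ids`` or
    matches ``unannotated_pattern``. An explicit two-column TSV
    (gene_family_id, annotated/unannotated) overrides both.
    """

    unannotated_ids: frozenset[str] = frozenset()
    unannotated_pattern: str = r"_unknown$"
    overrides: Mapping[str, bool] = field(default_factory=dict)  # id -> annotated?

    def is_annotated(self, gene_family_id: str) -> bool:
        if gene_family_id in self.overrides:
            return self.overrides[gene_family_id]
        if gene_family_id in self.unannotated_ids:
            return False
        return re.search(self.unannotated_pattern, gene_family_id) is None

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "AnnotationConfig":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["gene_family_id", "status"], dtype=str)
        bad = ~df["status"].isin(["annotated", "unannotated"])
        if bad.any():
            raise TableFormatError(
                f"annotation TSV has invalid status values: "
                f"{df.loc[bad, 'status'].unique().tolist()}"
            )
        overrides = {
            r.gene_family_id: r.status == "annotated" for r in df.itertuples()
        }
        return cls(overrides=overrides, **kwargs)


# ---------------------------------------------------------------------------
# species-stratified gene-family tables


class GeneFamilyTable:
    """Species-stratified gene-family abundances for one molecule type.

    ``data`` is a wide DataFrame indexed by (species, gene_family) with one
    float column per sample, values in copies-per-million.
    """

    def __init__(self, data: pd.DataFrame, molecule: str,
                 annotation: AnnotationConfig | None = None):
        if molecule not in ("DNA", "RNA"):
            raise ValueError(f"molecule must be 'DNA' or 'RNA', got {molecule!r}")
        if (data.values < 0).any():
            raise TableFormatError(f"{molecule} gene-family table has negative values")
        totals = data.sum(axis=0)
        over = totals > CPM_TOTAL * (1 + _CPM_TOL)
        if over.any():
            raise TableFormatError(
                f"{molecule} per-sample CPM totals exceed 1e6 for samples "
                f"{list(totals.index[over])[:5]}"
            )
        self.data = data
        self.molecule = molecule
        self.annotation = annotation or AnnotationConfig()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def species(self) -> list[str]:
        return sorted(self.data.index.get_level_values("species").unique())

    def stratum(self, species: str, sample_id: str) -> pd.Series:
        """Gene-family CPM vector of one species in one sample."""
        sub = self.data.xs(species, level="species")
        return sub[sample_id]


_STRAT_SEP = "|"


def read_stratified_table(
    path: str | Path,
    molecule: str,
    annotation: AnnotationConfig | None = None,
    sep: str = _STRAT_SEP,
) -> GeneFamilyTable:
    """Read a HUMAnN2-style stratified gene-family TSV.

    The first column holds ``GeneFamilyID|Species`` rows; unstratified rows
    (no separator) are dropped with a logged count; rows with a malformed
    stratification (empty id or species) are rejected with a warning.
    """
    # the header line itself starts with '#' in this dialect, so comment
    # filtering must spare the first row
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df[~df.index.astype(str).str.startswith("#")]
    genes: list[str] = []
    species: list[str] = []
    keep: list[int] = []
    n_unstratified = 0
    for i, key in enumerate(df.index.astype(str)):
        if sep not in key:
            n_unstratified += 1
            continue
        gene, _, sp = key.partition(sep)
        if not gene or not sp:
            logger.warning("rejecting malformed stratified row %r", key)
            continue
        genes.append(gene)
        species.append(sp)
        keep.append(i)
    if n_unstratified:
        logger.info(
            "dropped %d unstratified rows from %s", n_unstratified, path
        )
    data = df.iloc[keep].astype(float)
    neg = np.argwhere(data.values < 0)
    if neg.size:
        r, c = neg[0]
        raise TableFormatError(
            f"negative value at row {data.index[r]!r}, column {data.columns[c]!r}"
        )
    data.index = pd.MultiIndex.from_arrays([species, genes],
                                           names=["species", "gene_family"])
    return GeneFamilyTable(data, molecule=molecule, annotation=annotation)


def write_stratified_table(table: GeneFamilyTable, path: str | Path,
                           sep: str = _STRAT_SEP) -> None:
    out = table.data.copy()
    keys = [
        f"{g}{sep}{s}"
        for s, g in zip(out.index.get_level_values("species"),
                        out.index.get_level_values("gene_family"))
    ]
    out.index = pd.Index(keys, name="# Gene Family")
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# pathway tables


def read_pathway_table(path: str | Path, molecule: str) -> pd.DataFrame:
    """Read a pathway abundance TSV into a samples x pathways DataFrame.

    On disk: pathway rows, sample columns. The ``molecule`` tag is recorded in
    ``df.attrs['molecule']``.
    """
    if molecule not in ("DNA", "RNA"):
        raise ValueError(f"molecule must be 'DNA' or 'RNA', got {molecule!r}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    table = df.T.astype(float)
    if (table.values < 0).any():
        raise TableFormatError("pathway table contains negative values")
    if any(not str(p) for p in table.columns):
        raise TableFormatError("pathway table contains an empty pathway_id")
    table.index.name = "sample_id"
    table.columns.name = "pathway_id"
    table.attrs["molecule"] = molecule
    return table


def write_pathway_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.T
    out.index.name = "pathway_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# haplotype alignments


@dataclass
class HaplotypeAlignment:
    """Aligned dominant-strain SNP haplotypes of one species, one per sample."""

    species: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise TableFormatError(
                f"ragged alignment for {self.species}: lengths {sorted(lengths)}"
            )
        for sid, seq in self.sequences.items():
            extra = set(seq) - ALIGNMENT_ALPHABET
            if extra:
                raise TableFormatError(
                    f"sequence {sid!r} contains invalid characters {sorted(extra)}"
                )

    @property
    def alignment_length(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def read_alignment(path: str | Path, species: str) -> HaplotypeAlignment:
    """Read a per-species FASTA alignment; record ids are sample ids."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise TableFormatError(f"empty alignment file {path}")
    return HaplotypeAlignment(species=species, sequences=sequences)


def write_alignment(aln: HaplotypeAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.sequences.items():
            fh.write(f">{sid}\n{seq}\n")


def genus_of(species: str) -> str:
    """First ``_``- or whitespace-delimited token of a species name."""
    return re.split(r"[_\s]", species, maxsplit=1)[0]
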