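"""Synthetic mother-infant cohort generator with planted ground truth.

Every downstream stage of the pipeline is testable against this generator:
it emits the five input kinds (metadata, taxonomic profiles, per-species
haplotype alignments, DNA/RNA gene-family tables, DNA/RNA pathway tables)
together with the planted truth — which (family, species) strains were
transmitted from mother to infant, which gene families on those strains were
activated or deactivated in the infant, and which pathways differ between
roles.

The emulated structure mirrors the analyzed cohort: one stool sample per
subject, transmitted strains are near-identical haplotype pairs against a
background of much more divergent strains, RNA abundance equals DNA
abundance times multiplicative lognormal noise on the RNA/DNA ratio (the
analyzed statistic), and infants draw lower-diversity taxonomic profiles
than mothers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from dyadshift.io_tables import (
    GeneFamilyTable,
    HaplotypeAlignment,
    MetadataTable,
    SampleMetadata,
    write_alignment,
    write_metadata,
    write_pathway_table,
    write_stratified_table,
    write_taxonomic_profile,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_GENERA = (
    "Bacteroides", "Bifidobacterium", "Parabacteroides", "Escherichia",
    "Faecalibacterium", "Prevotella", "Roseburia", "Clostridium",
    "Collinsella", "Blautia",
)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Divergences are substitutions/site; fractions are in [0, 1];
    ``activation_fold`` is the multiplicative RNA shift planted on activated
    genes (deactivated genes are divided by it) and must exceed 2 for the
    calling thresholds to be able to recover the truth.
    """

    n_families: int = 10
    n_species: int = 20
    n_genes_per_species: int = 500
    transmission_probability: float = 0.3
    transmitted_strain_divergence: float = 1e-4
    background_strain_divergence: float = 1e-2
    activated_fraction: float = 0.05
    deactivated_fraction: float = 0.05
    activation_fold: float = 8.0
    ratio_noise_sd: float = 0.1
    unannotated_fraction: float = 0.5
    pathway_effect_size: float = 4.0
    n_pathways: int = 60
    differential_pathway_fraction: float = 0.1
    pathway_noise_sd: float = 0.2
    pathway_sparsity: float = 0.05
    alignment_length: int = 1000
    gap_rate: float = 0.0
    mother_dirichlet_alpha: float = 1.0
    infant_dirichlet_alpha: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("transmission_probability", "activated_fraction",
                     "deactivated_fraction", "unannotated_fraction",
                     "differential_pathway_fraction", "pathway_sparsity",
                     "gap_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.activated_fraction + self.deactivated_fraction > 1:
            raise ValueError("activated + deactivated fractions exceed 1")
        for name in ("transmitted_strain_divergence",
                     "background_strain_divergence"):
            v = getattr(self, name)
            if not 0 <= v < 0.75:
                raise ValueError(f"{name} must be in [0, 0.75), got {v}")
        if self.activation_fold <= 2:
            raise ValueError(
                "activation_fold must exceed 2 (the calling threshold) for "
                "the planted truth to be recoverable"
            )
        if self.ratio_noise_sd < 0 or self.pathway_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        for name in ("n_families", "n_species", "n_genes_per_species",
                     "n_pathways", "alignment_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (self.mother_dirichlet_alpha > 0 and self.infant_dirichlet_alpha > 0):
            raise ValueError("Dirichlet concentrations must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown cohort config keys: {sorted(extra)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted events the pipeline should recover."""

    transmissions: set = field(default_factory=set)  # (family, species)
    shifts: set = field(default_factory=set)  # (family, species, gene, direction)
    differential_pathways: set = field(default_factory=set)  # (pathway, direction)

    def __post_init__(self) -> None:
        trans = self.transmissions
        for fam, sp, _gene, _direction in self.shifts:
            if (fam, sp) not in trans:
                raise ValueError(
                    f"planted shift on ({fam}, {sp}) without a planted transmission"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "transmission", "family_id": f, "species": s,
             "gene_family": "", "direction": ""}
            for f, s in sorted(self.transmissions)
        ]
        rows += [
            {"kind": "shift", "family_id": f, "species": s,
             "gene_family": g, "direction": d}
            for f, s, g, d in sorted(self.shifts)
        ]
        rows += [
            {"kind": "pathway", "family_id": "", "species": "",
             "gene_family": p, "direction": d}
            for p, d in sorted(self.differential_pathways)
        ]
        return pd.DataFrame(
            rows, columns=["kind", "family_id", "species", "gene_family",
                           "direction"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        t = cls()
        for r in df.itertuples():
            if r.kind == "transmission":
                t.transmissions.add((r.family_id, r.species))
            elif r.kind == "shift":
                t.shifts.add((r.family_id, r.species, r.gene_family, r.direction))
            elif r.kind == "pathway":
                t.differential_pathways.add((r.gene_family, r.direction))
        return t


@dataclass
class Cohort:
    """A generated cohort: all pipeline inputs plus the planted truth."""

    config: CohortConfig
    metadata: MetadataTable
    taxonomic_profile: pd.DataFrame
    alignments: dict
    dna: GeneFamilyTable
    rna: GeneFamilyTable
    pathways_dna: pd.DataFrame
    pathways_rna: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_metadata(self.metadata, outdir / "metadata.tsv")
        write_taxonomic_profile(self.taxonomic_profile,
                                outdir / "taxonomic_profile.tsv")
        aln_dir = outdir / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for species, aln in self.alignments.items():
            write_alignment(aln, aln_dir / f"{species}.fasta")
        write_stratified_table(self.dna, outdir / "genefamilies_dna.tsv")
        write_stratified_table(self.rna, outdir / "genefamilies_rna.tsv")
        write_pathway_table(self.pathways_dna, outdir / "pathways_dna.tsv")
        write_pathway_table(self.pathways_rna, outdir / "pathways_rna.tsv")
        self.truth.write_tsv(outdir / "truth.tsv")


def mutate_haplotype(ancestor: str, divergence: float,
                     rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``divergence``.

    A substituted site gets one of the three other bases, uniformly.
    Divergence must lie in [0, 0.75) — the domain on which the Jukes-Cantor
    correction of the resulting p-distance is defined.
    """
    if not 0 <= divergence < 0.75:
        raise ValueError(f"divergence must be in [0, 0.75), got {divergence}")
    seq = np.frombuffer(ancestor.encode("ascii"), dtype=np.uint8).copy()
    if not np.isin(seq, _BASES).all():
        raise ValueError("ancestor must be over the alphabet {A, C, G, T}")
    hit = rng.random(seq.size) < divergence
    n = int(hit.sum())
    if n:
        # index of current base in ACGT, shifted by 1..3 mod 4: always different
        idx = np.searchsorted(_BASES, seq[hit])
        seq[hit] = _BASES[(idx + rng.integers(1, 4, size=n)) % 4]
    return seq.tobytes().decode("ascii")


def _species_names(n: int) -> list[str]:
    return [f"{_GENERA[i % len(_GENERA)]}_sp_{i:02d}" for i in range(n)]


def _make_metadata(cfg: CohortConfig, rng: np.random.Generator) -> MetadataTable:
    records = []
    statuses = np.array(["exclusive", "partial", "none"])
    for i in range(cfg.n_families):
        fam = f"F{i + 1:02d}"
        bf = str(rng.choice(statuses, p=[0.5, 0.4, 0.1]))
        site = "SiteA" if i % 2 == 0 else "SiteB"
        records.append(SampleMetadata(f"{fam}M", fam, "mother", bf, site))
        records.append(SampleMetadata(f"{fam}I", fam, "infant", bf, site))
    return MetadataTable(records)


def _make_profiles(cfg: CohortConfig, meta: MetadataTable, species: list[str],
                   rng: np.random.Generator) -> pd.DataFrame:
    rows = {}
    for rec in meta:
        alpha = (cfg.mother_dirichlet_alpha if rec.role == "mother"
                 else cfg.infant_dirichlet_alpha)
        rows[rec.sample_id] = rng.dirichlet(np.full(cfg.n_species, alpha))
    profile = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    profile.index.name = "sample_id"
    profile.columns.name = "species"
    return profile


def _make_alignments(cfg: CohortConfig, meta: MetadataTable, species: list[str],
                     transmissions: set, rng: np.random.Generator) -> dict:
    alignments = {}
    for sp in species:
        ancestor = rng.choice(_BASES, cfg.alignment_length).tobytes().decode("ascii")
        seqs = {}
        for fam, mother, infant in meta.dyads():
            if (fam, sp) in transmissions:
                strain = mutate_haplotype(ancestor,
                                          cfg.background_strain_divergence, rng)
                half = cfg.transmitted_strain_divergence / 2
                seqs[mother] = mutate_haplotype(strain, half, rng)
                seqs[infant] = mutate_haplotype(strain, half, rng)
            else:
                seqs[mother] = mutate_haplotype(
                    ancestor, cfg.background_strain_divergence, rng)
                seqs[infant] = mutate_haplotype(
                    ancestor, cfg.background_strain_divergence, rng)
        if cfg.gap_rate > 0:
            for sid, s in seqs.items():
                arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
                arr[rng.random(arr.size) < cfg.gap_rate] = ord("-")
                seqs[sid] = arr.tobytes().decode("ascii")
        alignments[sp] = HaplotypeAlignment(species=sp, sequences=seqs)
    return alignments


def _gene_ids(cfg: CohortConfig, species: str,
              rng: np.random.Generator) -> list[str]:
    n_unannot = int(round(cfg.unannotated_fraction * cfg.n_genes_per_species))
    unannot = set(rng.choice(cfg.n_genes_per_species, n_unannot, replace=False))
    return [
        f"UniRef90_{species}_{j:04d}" + ("_unknown" if j in unannot else "")
        for j in range(cfg.n_genes_per_species)
    ]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort; all randomness flows from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = _species_names(config.n_species)
    meta = _make_metadata(config, rng)
    profile = _make_profiles(config, meta, species, rng)

    truth = GroundTruth()
    for fam, _m, _i in meta.dyads():
        for sp in species:
            if rng.random() < config.transmission_probability:
                truth.transmissions.add((fam, sp))

    alignments = _make_alignments(config, meta, species, truth.transmissions, rng)

    # gene-family tables: DNA mass per stratum follows the taxonomic profile
    gene_ids = {sp: _gene_ids(config, sp, rng) for sp in species}
    index = pd.MultiIndex.from_tuples(
        [(sp, g) for sp in species for g in gene_ids[sp]],
        names=["species", "gene_family"],
    )
    sample_ids = meta.sample_ids
    n_genes = config.n_genes_per_species
    dna = np.empty((len(index), len(sample_ids)))
    rna = np.empty_like(dna)

    planted: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    n_act = int(round(config.activated_fraction * n_genes))
    n_deact = int(round(config.deactivated_fraction * n_genes))
    for fam, sp in sorted(truth.transmissions):
        chosen = rng.choice(n_genes, n_act + n_deact, replace=False)
        act, deact = chosen[:n_act], chosen[n_act:]
        planted[(fam, sp)] = (act, deact)
        for j in act:
            truth.shifts.add((fam, sp, gene_ids[sp][j], "activated"))
        for j in deact:
            truth.shifts.add((fam, sp, gene_ids[sp][j], "deactivated"))

    for c, sid in enumerate(sample_ids):
        fam = meta.family_of(sid)
        role = meta.role_of(sid)
        col_dna = np.empty(len(index))
        col_rna = np.empty(len(index))
        for k, sp in enumerate(species):
            lo, hi = k * n_genes, (k + 1) * n_genes
            w = rng.lognormal(0.0, 1.0, n_genes)
            col_dna[lo:hi] = 1e6 * profile.loc[sid, sp] * w / w.sum()
            noise = rng.lognormal(0.0, config.ratio_noise_sd, n_genes) \
                if config.ratio_noise_sd > 0 else np.ones(n_genes)
            shift = np.ones(n_genes)
            if role == "infant" and (fam, sp) in planted:
                act, deact = planted[(fam, sp)]
                shift[act] = config.activation_fold
                shift[deact] = 1.0 / config.activation_fold
            col_rna[lo:hi] = col_dna[lo:hi] * noise * shift
        col_rna *= 1e6 / col_rna.sum()  # renormalize RNA to CPM
        dna[:, c] = col_dna
        rna[:, c] = col_rna

    dna_table = GeneFamilyTable(
        pd.DataFrame(dna, index=index, columns=sample_ids), molecule="DNA")
    rna_table = GeneFamilyTable(
        pd.DataFrame(rna, index=index, columns=sample_ids), molecule="RNA")

    pathways_dna, pathways_rna = _make_pathways(config, meta, truth, rng)

    return Cohort(
        config=config, metadata=meta, taxonomic_profile=profile,
        alignments=alignments, dna=dna_table, rna=rna_table,
        pathways_dna=pathways_dna, pathways_rna=pathways_rna, truth=truth,
    )


def _make_pathways(cfg: CohortConfig, meta: MetadataTable, truth: GroundTruth,
                   rng: np.random.Generator):
    pathway_ids = [f"PWY-{1000 + k}" for k in range(cfg.n_pathways)]
    n_diff = int(round(cfg.differential_pathway_fraction * cfg.n_pathways))
    diff_idx = rng.choice(cfg.n_pathways, n_diff, replace=False)
    directions = {}
    for rank, k in enumerate(sorted(diff_idx)):
        directions[k] = "infant" if rank % 2 == 0 else "mother"
        truth.differential_pathways.add((pathway_ids[k], directions[k]))

    base_mu = rng.normal(0.0, 1.0, cfg.n_pathways)
    tables = []
    for _molecule in ("DNA", "RNA"):
        mat = np.empty((len(meta), cfg.n_pathways))
        for r, rec in enumerate(meta):
            vals = rng.lognormal(base_mu, cfg.pathway_noise_sd)
            for k, direction in directions.items():
                if rec.role == direction:
                    vals[k] *= cfg.pathway_effect_size
            if cfg.pathway_sparsity > 0:
                vals[rng.random(cfg.n_pathways) < cfg.pathway_sparsity] = 0.0
            mat[r] = vals
        table = pd.DataFrame(mat, index=meta.sample_ids, columns=pathway_ids)
        table.index.name = "sample_id"
        table.columns.name = "pathway_id"
        tables.append(table)
    tables[0].attrs["molecule"] = "DNA"
    tables[1].attrs["molecule"] = "RNA"
    return tables[0], tables[1]
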