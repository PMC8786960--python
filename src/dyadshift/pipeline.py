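"""Pipeline orchestration: simulate -> community -> share -> shift -> pathways.

Each stage writes its tables under the output directory and contributes to a
machine-readable ``summary.json``. A single global seed is fanned out to
per-stage child seeds by a fixed derivation so stages can be rerun in
isolation reproducibly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dyadshift import community_profile, expression_shifts, pathway_da, strain_sharing
from dyadshift.io_tables import (
    AnnotationConfig,
    GeneFamilyTable,
    MetadataTable,
    read_alignment,
    read_metadata,
    read_pathway_table,
    read_stratified_table,
    read_taxonomic_profile,
)
from dyadshift.synthetic_cohort import Cohort, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

_STAGE_OFFSETS = {"simulate": 1, "community": 2, "share": 3, "shift": 4,
                  "pathways": 5}


def stage_seed(seed: int, stage: str) -> int:
    """Fixed, collision-free child seed for one stage (kept below 2^31)."""
    return (seed * 10007 + _STAGE_OFFSETS[stage]) % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_dir: str | None = None
    simulate: CohortConfig | None = None
    sharing_threshold: float = strain_sharing.SHARING_THRESHOLD
    activation_threshold: float = expression_shifts.ACTIVATION_THRESHOLD
    deactivation_threshold: float = expression_shifts.DEACTIVATION_THRESHOLD
    min_overlap: int = strain_sharing.MIN_OVERLAP
    min_genes: int = expression_shifts.MIN_GENES
    min_samples: int = pathway_da.MIN_SAMPLES
    n_permutations: int = 999
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir / simulate must be set")
        for name in ("sharing_threshold", "activation_threshold",
                     "deactivation_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.activation_threshold > 1 > self.deactivation_threshold:
            raise ValueError(
                "activation threshold must exceed 1 and deactivation "
                "threshold must be below 1"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        cfg = cls(**d)
        if sim is not None:
            cfg.simulate = CohortConfig.from_dict(sim)
        return cfg


@dataclass
class InputBundle:
    """All loaded pipeline inputs."""

    metadata: MetadataTable
    taxonomic_profile: pd.DataFrame
    alignments: dict
    dna: GeneFamilyTable
    rna: GeneFamilyTable
    pathways_dna: pd.DataFrame
    pathways_rna: pd.DataFrame


def load_inputs(input_dir: str | Path,
                annotation: AnnotationConfig | None = None) -> InputBundle:
    """Load a directory tree laid out as the simulator writes it."""
    input_dir = Path(input_dir)
    metadata = read_metadata(input_dir / "metadata.tsv")
    profile = read_taxonomic_profile(input_dir / "taxonomic_profile.tsv")
    alignments = {}
    for fasta in sorted((input_dir / "alignments").glob("*.fasta")):
        species = fasta.stem
        alignments[species] = read_alignment(fasta, species)
    dna = read_stratified_table(input_dir / "genefamilies_dna.tsv", "DNA",
                                annotation=annotation)
    rna = read_stratified_table(input_dir / "genefamilies_rna.tsv", "RNA",
                                annotation=annotation)
    pdna = read_pathway_table(input_dir / "pathways_dna.tsv", "DNA")
    prna = read_pathway_table(input_dir / "pathways_rna.tsv", "RNA")
    return InputBundle(metadata, profile, alignments, dna, rna, pdna, prna)


def bundle_from_cohort(cohort: Cohort) -> InputBundle:
    return InputBundle(
        cohort.metadata, cohort.taxonomic_profile, cohort.alignments,
        cohort.dna, cohort.rna, cohort.pathways_dna, cohort.pathways_rna,
    )


def stage_community(bundle: InputBundle, outdir: Path, n_permutations: int,
                    seed: int) -> dict:
    diversity = community_profile.diversity_table(bundle.taxonomic_profile)
    div_df = diversity.rename_axis("sample_id").reset_index()
    div_df["role"] = [bundle.metadata.role_of(s) for s in div_df["sample_id"]]
    div_df.to_csv(outdir / "diversity.tsv", sep="\t", index=False)

    bc = community_profile.bray_curtis(bundle.taxonomic_profile)
    bc.to_csv(outdir / "bray_curtis.tsv", sep="\t")

    roles = {s: bundle.metadata.role_of(s) for s in bc.index}
    perma = community_profile.permanova(bc, roles,
                                        n_permutations=n_permutations, seed=seed)
    mothers = div_df.loc[div_df["role"] == "mother", "shannon"]
    infants = div_df.loc[div_df["role"] == "infant", "shannon"]
    ttest = community_profile.compare_diversity(mothers, infants)
    result = {"permanova": perma, "diversity_ttest": ttest}
    with open(outdir / "permanova.json", "w") as fh:
        json.dump(result, fh, indent=2)
    return result


def stage_share(bundle: InputBundle, outdir: Path, threshold: float,
                min_overlap: int) -> dict:
    per_species = [
        strain_sharing.compute_pair_distances(aln, bundle.metadata,
                                              min_overlap=min_overlap)
        for aln in bundle.alignments.values()
    ]
    distances = pd.concat([d for d in per_species if not d.empty],
                          ignore_index=True) if per_species else pd.DataFrame()
    normalized = strain_sharing.normalize_distances(distances)
    events = strain_sharing.call_shared_strains(normalized, bundle.metadata,
                                                threshold=threshold)
    summary, totals = strain_sharing.summarize_sharing(events, bundle.metadata)

    normalized.to_csv(outdir / "pair_distances.tsv", sep="\t", index=False)
    events.to_csv(outdir / "sharing_events.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "sharing_summary.tsv", sep="\t", index=False)

    tree_dir = outdir / "trees"
    tree_dir.mkdir(exist_ok=True)
    for species in sorted(set(normalized["species"])) if len(normalized) else []:
        dm = strain_sharing.jc_distance_matrix(normalized, species)
        if dm.shape[0] >= 3:
            (tree_dir / f"{species}.nwk").write_text(
                strain_sharing.build_nj_tree(dm))
    return {"events": events, "totals": totals}


def stage_shift(bundle: InputBundle, events: pd.DataFrame, outdir: Path,
                act_threshold: float, deact_threshold: float,
                min_genes: int) -> dict:
    res = expression_shifts.analyze_shifts(
        events, bundle.dna, bundle.rna, min_genes=min_genes,
        act_threshold=act_threshold, deact_threshold=deact_threshold)
    calls = res["calls"]
    res["records"].to_csv(outdir / "relative_expression.tsv", sep="\t",
                          index=False)
    calls.to_csv(outdir / "shift_calls.tsv", sep="\t", index=False)
    if len(calls):
        table, totals = expression_shifts.count_events(calls)
        repl = expression_shifts.replication_table(calls)
        ann = expression_shifts.annotation_rate_test(calls)
    else:
        table = pd.DataFrame()
        totals = {"universe": 0, "activation_events": 0,
                  "deactivation_events": 0, "activation_pct": float("nan"),
                  "deactivation_pct": float("nan")}
        repl = pd.DataFrame(columns=["species", "replication_rate"])
        ann = {"per_strain": pd.DataFrame(), "p_activated": float("nan"),
               "p_deactivated": float("nan")}
    table.to_csv(outdir / "shift_summary.tsv", sep="\t", index=False)
    repl.to_csv(outdir / "replication_rates.tsv", sep="\t", index=False)
    with open(outdir / "annotation_test.json", "w") as fh:
        json.dump(
            {
                "p_activated": ann["p_activated"],
                "p_deactivated": ann["p_deactivated"],
                "per_strain": ann["per_strain"].to_dict(orient="records"),
            },
            fh, indent=2,
        )
    return {"eligible": res["eligible"], "calls": calls, "totals": totals,
            "replication": repl, "annotation": ann}


def stage_pathways(bundle: InputBundle, outdir: Path, min_samples: int) -> dict:
    out = {}
    for molecule, table in (("dna", bundle.pathways_dna),
                            ("rna", bundle.pathways_rna)):
        results = pathway_da.test_pathways(table, bundle.metadata,
                                           min_samples=min_samples)
        results.to_csv(outdir / f"pathway_tests_{molecule}.tsv", sep="\t",
                       index=False)
        out[molecule] = results
    return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage in order and write ``summary.json``.

    Returns the summary dict. Any stage failure is logged with the stage
    name and re-raised; outputs of completed stages are retained.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_run_log(outdir)

    stage = "simulate"
    try:
        if config.simulate is not None:
            sim_cfg = config.simulate
            sim_cfg.seed = stage_seed(config.seed, "simulate")
            cohort = generate_cohort(sim_cfg)
            cohort.write(outdir / "inputs")
            bundle = bundle_from_cohort(cohort)
        else:
            bundle = load_inputs(config.input_dir)

        stage = "community"
        community = stage_community(bundle, outdir, config.n_permutations,
                                    stage_seed(config.seed, "community"))
        stage = "share"
        share = stage_share(bundle, outdir, config.sharing_threshold,
                            config.min_overlap)
        stage = "shift"
        shift = stage_shift(bundle, share["events"], outdir,
                            config.activation_threshold,
                            config.deactivation_threshold, config.min_genes)
        stage = "pathways"
        pathways = stage_pathways(bundle, outdir, config.min_samples)
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        raise

    summary = {
        "seed": config.seed,
        "n_samples": len(bundle.metadata),
        "community": {
            "permanova_R2": community["permanova"]["R2"],
            "permanova_p": community["permanova"]["p"],
            "diversity_t": community["diversity_ttest"]["t"],
            "diversity_p": community["diversity_ttest"]["p"],
        },
        "sharing": share["totals"],
        "shifts": {
            "n_eligible_transcribed_strains": int(len(shift["eligible"])),
            **{k: (v if isinstance(v, int) else _nan_to_none(v))
               for k, v in shift["totals"].items()},
            "replication_rates": {
                r.species: _nan_to_none(r.replication_rate)
                for r in shift["replication"].itertuples()
            },
            "annotation_p_activated": _nan_to_none(
                shift["annotation"]["p_activated"]),
            "annotation_p_deactivated": _nan_to_none(
                shift["annotation"]["p_deactivated"]),
        },
        "pathways": {
            "significant_dna": int(pathways["dna"]["significant"].sum()),
            "tested_dna": int(len(pathways["dna"])),
            "significant_rna": int(pathways["rna"]["significant"].sum()),
            "tested_rna": int(len(pathways["rna"])),
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _nan_to_none(x):
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return float(x) if isinstance(x, (np.floating, float)) else x


def _setup_run_log(outdir: Path) -> None:
    root = logging.getLogger("dyadshift")
    if not any(isinstance(h, logging.FileHandler)
               and getattr(h, "_dyadshift_run", False) for h in root.handlers):
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler._dyadshift_run = True
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(handler)
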