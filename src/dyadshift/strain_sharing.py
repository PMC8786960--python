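"""Detection of strains shared within mother-infant pairs.

For every species, the dominant-strain SNP haplotypes of all samples are
compared pairwise: gap/N columns are excluded, the observed p-distance is
corrected for multiple hits with the Jukes-Cantor model, and each pair's
distance is divided by the per-species median of all pairwise distances.
This median normalization puts species with very different within-species
diversity on a common scale (0 = identical haplotypes, 1 = median
dissimilarity). A within-family mother-infant pair whose normalized distance
falls at or below a conservative threshold (default 0.2) is called a shared
strain. Direction of transfer is not inferred.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from dyadshift.io_tables import HaplotypeAlignment, MetadataTable, genus_of

logger = logging.getLogger(__name__)

SHARING_THRESHOLD = 0.2
MIN_OVERLAP = 100

PAIR_WITHIN_FAMILY = "within_family_mother_infant"
PAIR_OTHER = "other"


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Observed proportion of differing sites between two aligned haplotypes.

    Columns where either sequence has a gap (``-``) or an ambiguous base
    (``N``) are excluded from the comparison.

    Returns
    -------
    (p, n_sites) : observed mismatch fraction and the number of compared sites.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    a = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    bad = np.frombuffer(b"-N", dtype=np.uint8)
    valid = ~(np.isin(a, bad) | np.isin(b, bad))
    n_sites = int(valid.sum())
    if n_sites == 0:
        return float("nan"), 0
    mismatches = int((a[valid] != b[valid]).sum())
    return mismatches / n_sites, n_sites


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p), substitutions/site.

    Defined for observed p-distance in [0, 0.75).
    """
    if not 0 <= p < 0.75:
        raise ValueError(f"Jukes-Cantor distance undefined for p = {p}")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def compute_pair_distances(
    alignment: HaplotypeAlignment,
    metadata: MetadataTable,
    min_overlap: int = MIN_OVERLAP,
) -> pd.DataFrame:
    """All pairwise haplotype distances within one species.

    Pairs with fewer than ``min_overlap`` comparable sites are skipped with a
    warning. Each pair is classed as ``within_family_mother_infant`` when the
    two samples come from the same family with one mother and one infant,
    otherwise ``other``.

    Returns a DataFrame with columns species, sample_a, sample_b, p_distance,
    n_sites, jc_distance, pair_class.
    """
    sids = alignment.sample_ids
    rows = []
    for i in range(len(sids)):
        for j in range(i + 1, len(sids)):
            sa, sb = sids[i], sids[j]
            p, n_sites = p_distance(alignment.sequences[sa], alignment.sequences[sb])
            if n_sites < min_overlap:
                logger.warning(
                    "skipping pair (%s, %s) of %s: only %d comparable sites",
                    sa, sb, alignment.species, n_sites,
                )
                continue
            if p >= 0.75:
                logger.warning(
                    "skipping pair (%s, %s) of %s: p-distance %.3f saturates "
                    "the Jukes-Cantor model", sa, sb, alignment.species, p,
                )
                continue
            rows.append(
                {
                    "species": alignment.species,
                    "sample_a": sa,
                    "sample_b": sb,
                    "p_distance": p,
                    "n_sites": n_sites,
                    "jc_distance": jukes_cantor(p),
                    "pair_class": _classify_pair(sa, sb, metadata),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "sample_a", "sample_b", "p_distance", "n_sites",
            "jc_distance", "pair_class",
        ],
    )


def _classify_pair(sa: str, sb: str, metadata: MetadataTable) -> str:
    try:
        ma, mb = metadata[sa], metadata[sb]
    except KeyError:
        return PAIR_OTHER
    if ma.family_id == mb.family_id and {ma.role, mb.role} == {"mother", "infant"}:
        return PAIR_WITHIN_FAMILY
    return PAIR_OTHER


def normalize_distances(distances: pd.DataFrame) -> pd.DataFrame:
    """Divide each pair's Jukes-Cantor distance by its species' median.

    The normalizing median pools all pairwise comparisons of the species
    (within-family and other pairs alike). Species whose median distance is 0
    (all strains identical) are excluded with a warning.
    """
    out = []
    for species, sub in distances.groupby("species", sort=True):
        if len(sub) < 2:
            logger.warning(
                "species %s has %d pair(s); need >= 2 for normalization, skipping",
                species, len(sub),
            )
            continue
        med = float(sub["jc_distance"].median())
        if med == 0:
            logger.warning(
                "species %s: median pairwise distance is 0, excluded", species
            )
            continue
        sub = sub.copy()
        sub["normalized_distance"] = sub["jc_distance"] / med
        out.append(sub)
    if not out:
        cols = list(distances.columns) + ["normalized_distance"]
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


def call_shared_strains(
    distances: pd.DataFrame,
    metadata: MetadataTable,
    threshold: float = SHARING_THRESHOLD,
) -> pd.DataFrame:
    """Call shared strains from normalized within-family distances.

    A sharing event is a within-family mother-infant pair whose
    median-normalized distance is <= ``threshold`` (inclusive); at most one
    event per (species, family) — the smallest-distance pair wins.

    Returns a DataFrame with columns species, family_id, mother_sample,
    infant_sample, normalized_distance, breastfeeding.
    """
    cols = ["species", "family_id", "mother_sample", "infant_sample",
            "normalized_distance", "breastfeeding"]
    if distances.empty:
        return pd.DataFrame(columns=cols)
    if "normalized_distance" not in distances.columns:
        raise ValueError("distances must be normalized first (normalize_distances)")
    fam = distances[distances["pair_class"] == PAIR_WITHIN_FAMILY]
    fam = fam[fam["normalized_distance"] <= threshold]
    rows = []
    for r in fam.itertuples():
        a, b = metadata[r.sample_a], metadata[r.sample_b]
        mother, infant = (a, b) if a.role == "mother" else (b, a)
        rows.append(
            {
                "species": r.species,
                "family_id": mother.family_id,
                "mother_sample": mother.sample_id,
                "infant_sample": infant.sample_id,
                "normalized_distance": r.normalized_distance,
                "breastfeeding": infant.breastfeeding,
            }
        )
    events = pd.DataFrame(rows, columns=cols)
    if events.empty:
        return events
    events = (
        events.sort_values(["species", "family_id", "normalized_distance"])
        .drop_duplicates(["species", "family_id"], keep="first")
        .sort_values(["species", "family_id"])
        .reset_index(drop=True)
    )
    return events


def summarize_sharing(events: pd.DataFrame, metadata: MetadataTable | None = None):
    """Per-species sharing counts and cohort totals.

    Returns
    -------
    table : DataFrame
        One row per species with >= 1 event: total events and counts by
        breastfeeding status.
    totals : dict
        ``n_strains`` (events), ``n_species``, ``n_genera`` (first name token).
    """
    statuses = ["exclusive", "partial", "none", "unknown"]
    if events.empty:
        table = pd.DataFrame(columns=["species", "events"] + statuses)
        return table, {"n_strains": 0, "n_species": 0, "n_genera": 0}
    rows = []
    for species, sub in events.groupby("species", sort=True):
        row = {"species": species, "events": len(sub)}
        counts = sub["breastfeeding"].value_counts()
        for st in statuses:
            row[st] = int(counts.get(st, 0))
        rows.append(row)
    table = (
        pd.DataFrame(rows)
        .sort_values(["events", "species"], ascending=[False, True])
        .reset_index(drop=True)
    )
    totals = {
        "n_strains": int(table["events"].sum()),
        "n_species": int(len(table)),
        "n_genera": int(table["species"].map(genus_of).nunique()),
    }
    return table, totals


def jc_distance_matrix(distances: pd.DataFrame, species: str) -> DistanceMatrix:
    """Assemble the per-species Jukes-Cantor distance matrix from pair rows."""
    sub = distances[distances["species"] == species]
    ids = sorted(set(sub["sample_a"]) | set(sub["sample_b"]))
    idx = {s: i for i, s in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)))
    for r in sub.itertuples():
        i, j = idx[r.sample_a], idx[r.sample_b]
        mat[i, j] = mat[j, i] = r.jc_distance
    return DistanceMatrix(mat, ids)


def build_nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree of one species' strains, as a newick string.

    Negative branch lengths are clamped to zero.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    tree = nj(dm, neg_as_zero=True)
    return str(tree)
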