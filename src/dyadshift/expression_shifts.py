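"""Relative expression and activation/deactivation of shared strains.

RNA and DNA gene-family abundances are both relative quantifications
(copies-per-million), so a transcriptionally hyperactive species depletes the
apparent RNA of every other species in the sample. The analysis therefore
divides each gene family's RNA/DNA ratio by the median RNA/DNA ratio of its
species-and-sample stratum; this median-normalized ratio is the *relative
expression*. A gene family on a shared strain is called *activated* when its
infant relative expression exceeds 2 and is more than twofold its relative
expression in the mother, and *deactivated* when both quantities fall below
one half (strict inequalities on all four thresholds).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from dyadshift.io_tables import AnnotationConfig, GeneFamilyTable

logger = logging.getLogger(__name__)

ACTIVATION_THRESHOLD = 2.0
DEACTIVATION_THRESHOLD = 0.5
MIN_GENES = 10

#: n at or below which the Wilcoxon signed-rank test is computed exactly
_WILCOXON_EXACT_N = 25


class StratumError(ValueError):
    """A (species, sample) stratum cannot support relative expression."""


def to_cpm(raw_counts, assume_cpm: bool = False) -> np.ndarray:
    """Scale raw per-sample counts to copies-per-million (sums to 1e6)."""
    counts = np.asarray(raw_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if assume_cpm:
        return counts
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot scale a sample with zero total counts")
    return counts * 1e6 / total


def relative_expression(
    dna: GeneFamilyTable,
    rna: GeneFamilyTable,
    species: str,
    sample_id: str,
    min_genes: int = MIN_GENES,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Relative expression of one species' gene families in one sample.

    Only gene families with ``dna_cpm > 0`` enter the stratum (the RNA/DNA
    ratio is undefined otherwise); a gene with no RNA gets ratio 0 and still
    participates in the median — it is a real "not transcribed" observation.
    A pseudocount, added to both CPM values, is available for sensitivity
    analysis and is off by default.

    Returns a DataFrame with columns gene_family, dna_cpm, rna_cpm, ratio,
    relative_expression (ratio over the stratum median ratio).

    Raises
    ------
    StratumError
        If the stratum has fewer than ``min_genes`` gene families with
        positive DNA, or its median RNA/DNA ratio is 0.
    """
    try:
        dna_stratum = dna.stratum(species, sample_id)
    except KeyError as exc:
        raise StratumError(f"no DNA stratum for ({species}, {sample_id})") from exc
    try:
        rna_stratum = rna.stratum(species, sample_id)
    except KeyError:
        rna_stratum = pd.Series(0.0, index=dna_stratum.index)

    d = dna_stratum + pseudocount
    genes = d.index[d > 0]
    if len(genes) < min_genes:
        raise StratumError(
            f"stratum ({species}, {sample_id}) has {len(genes)} gene families "
            f"with positive DNA; need >= {min_genes}"
        )
    r = rna_stratum.reindex(genes).fillna(0.0) + pseudocount
    ratio = r / d.loc[genes]
    median_ratio = float(ratio.median())
    if median_ratio <= 0:
        raise StratumError(
            f"stratum ({species}, {sample_id}) has median RNA/DNA ratio 0; "
            f"no usable transcriptome signal"
        )
    return pd.DataFrame(
        {
            "gene_family": genes,
            "dna_cpm": dna_stratum.loc[genes].values,
            "rna_cpm": rna_stratum.reindex(genes).fillna(0.0).values,
            "ratio": ratio.values,
            "relative_expression": (ratio / median_ratio).values,
        }
    ).reset_index(drop=True)


def detect_shared_transcribed_strains(
    events: pd.DataFrame,
    dna: GeneFamilyTable,
    rna: GeneFamilyTable,
    min_genes: int = MIN_GENES,
) -> pd.DataFrame:
    """Shared strains with a usable transcriptome signal in mother and infant.

    Keeps sharing events whose mother and infant (species, sample) strata both
    support relative expression (enough genes with DNA, nonzero median ratio).
    """
    keep = []
    for idx, ev in events.iterrows():
        ok = True
        for sample in (ev["mother_sample"], ev["infant_sample"]):
            try:
                relative_expression(dna, rna, ev["species"], sample,
                                    min_genes=min_genes)
            except StratumError as exc:
                logger.info("excluding shared strain: %s", exc)
                ok = False
                break
        if ok:
            keep.append(idx)
    return events.loc[keep].reset_index(drop=True)


def call_shifts(
    infant_records: pd.DataFrame,
    mother_records: pd.DataFrame,
    species: str,
    family_id: str,
    act_threshold: float = ACTIVATION_THRESHOLD,
    deact_threshold: float = DEACTIVATION_THRESHOLD,
    annotation: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Activation/deactivation calls for one shared strain (species, family).

    Gene families present (positive DNA) in both the mother and the infant
    stratum are compared; fold = infant / mother relative expression, with
    fold = +inf when the mother's relative expression is 0. Direction is
    ``activated`` (infant > act_threshold and fold > act_threshold),
    ``deactivated`` (infant < deact_threshold and fold < deact_threshold) or
    ``neutral``; all inequalities strict.
    """
    annotation = annotation or AnnotationConfig()
    inf = infant_records.set_index("gene_family")["relative_expression"]
    mot = mother_records.set_index("gene_family")["relative_expression"]
    shared_genes = inf.index.intersection(mot.index)
    i = inf.loc[shared_genes].to_numpy(dtype=float)
    m = mot.loc[shared_genes].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(m > 0, i / m, np.where(i > 0, np.inf, np.nan))
    activated = (i > act_threshold) & (fold > act_threshold)
    deactivated = (i < deact_threshold) & (fold < deact_threshold)
    direction = np.where(activated, "activated",
                         np.where(deactivated, "deactivated", "neutral"))
    return pd.DataFrame(
        {
            "species": species,
            "family_id": family_id,
            "gene_family": shared_genes,
            "infant_rel_expr": i,
            "mother_rel_expr": m,
            "fold": fold,
            "direction": direction,
            "annotated": [annotation.is_annotated(g) for g in shared_genes],
        }
    )


def analyze_shifts(
    events: pd.DataFrame,
    dna: GeneFamilyTable,
    rna: GeneFamilyTable,
    min_genes: int = MIN_GENES,
    act_threshold: float = ACTIVATION_THRESHOLD,
    deact_threshold: float = DEACTIVATION_THRESHOLD,
    pseudocount: float = 0.0,
) -> dict:
    """Run the full shift analysis over all shared strains.

    Returns a dict with ``eligible`` (events with transcriptome signal),
    ``calls`` (concatenated per-strain shift calls; the comparable gene
    families of each strain are its rows) and ``records`` (per-stratum
    relative expression, long form).
    """
    _check_single_infant(events)
    eligible = detect_shared_transcribed_strains(events, dna, rna,
                                                min_genes=min_genes)
    all_calls, all_records = [], []
    for ev in eligible.itertuples():
        recs = {}
        for role, sample in (("mother", ev.mother_sample),
                             ("infant", ev.infant_sample)):
            rec = relative_expression(dna, rna, ev.species, sample,
                                      min_genes=min_genes,
                                      pseudocount=pseudocount)
            rec.insert(0, "species", ev.species)
            rec.insert(1, "family_id", ev.family_id)
            rec.insert(2, "sample_id", sample)
            rec.insert(3, "role", role)
            recs[role] = rec
            all_records.append(rec)
        calls = call_shifts(
            recs["infant"], recs["mother"], ev.species, ev.family_id,
            act_threshold=act_threshold, deact_threshold=deact_threshold,
            annotation=dna.annotation,
        )
        all_calls.append(calls)
    empty_calls = pd.DataFrame(
        columns=["species", "family_id", "gene_family", "infant_rel_expr",
                 "mother_rel_expr", "fold", "direction", "annotated"])
    return {
        "eligible": eligible,
        "calls": pd.concat(all_calls, ignore_index=True) if all_calls else empty_calls,
        "records": pd.concat(all_records, ignore_index=True) if all_records
        else pd.DataFrame(),
    }


def _check_single_infant(events: pd.DataFrame) -> None:
    if events.empty:
        return
    multi = events.groupby(["species", "family_id"]).size()
    if (multi > 1).any():
        raise ValueError(
            "multiple sharing events per (species, family); select one infant "
            "sample per family explicitly before the shift analysis"
        )


def count_events(calls: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Count (de)activation events per species and overall.

    The gene-family universe is the set of comparable gene families per
    strain, i.e. one unit per (species, family, gene_family) row of ``calls``
    — a gene carried by three shared strains counts three times, matching how
    the strain-by-strain totals add up. Unique counts deduplicate gene
    families within a species across families (a gene family activated in
    several infants counts once).

    Returns
    -------
    table : per-species DataFrame with event and unique-gene-family counts.
    totals : dict with overall event counts, the universe size, and event
        percentages of the universe.
    """
    if calls.empty or len(calls) == 0:
        raise ValueError("empty gene-family universe; no comparable strains")
    rows = []
    for species, sub in calls.groupby("species", sort=True):
        act = sub[sub["direction"] == "activated"]
        deact = sub[sub["direction"] == "deactivated"]
        rows.append(
            {
                "species": species,
                "n_families": sub["family_id"].nunique(),
                "universe": len(sub),
                "activation_events": len(act),
                "deactivation_events": len(deact),
                "unique_activated_families": act["gene_family"].nunique(),
                "unique_deactivated_families": deact["gene_family"].nunique(),
            }
        )
    table = pd.DataFrame(rows)
    universe = int(table["universe"].sum())
    n_act = int(table["activation_events"].sum())
    n_deact = int(table["deactivation_events"].sum())
    totals = {
        "universe": universe,
        "activation_events": n_act,
        "deactivation_events": n_deact,
        "activation_pct": 100.0 * n_act / universe,
        "deactivation_pct": 100.0 * n_deact / universe,
    }
    return table, totals


def replication_rate(calls: pd.DataFrame, species: str) -> float:
    """Consistency of infant activation across a species' family pairs.

    Of the unique gene families activated in at least one infant, the
    fraction activated in two or more infants. NaN when the species has
    fewer than two family pairs with calls.
    """
    sub = calls[calls["species"] == species]
    if sub["family_id"].nunique() < 2:
        return float("nan")
    act = sub[sub["direction"] == "activated"]
    per_gene = act.groupby("gene_family")["family_id"].nunique()
    if len(per_gene) == 0:
        return float("nan")
    return float((per_gene >= 2).sum() / len(per_gene))


def replication_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Replication rate per species (NaN where undefined)."""
    rows = [
        {"species": sp, "replication_rate": replication_rate(calls, sp)}
        for sp in sorted(calls["species"].unique())
    ]
    return pd.DataFrame(rows, columns=["species", "replication_rate"])


def _signed_rank_p(diff: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p; exact for small n without ties."""
    diff = diff[diff != 0]
    if len(diff) == 0:
        return 1.0
    has_ties = len(np.unique(np.abs(diff))) < len(diff)
    if len(diff) <= _WILCOXON_EXACT_N and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(diff, zero_method="wilcox", correction=(method == "approx"),
                         alternative="two-sided", method=method)
    return float(res.pvalue)


def annotation_rate_test(calls: pd.DataFrame) -> dict:
    """Compare annotation rates of (de)activated genes against all genes.

    For each shared strain, the percentage of annotated gene families among
    all comparable genes and among the (de)activated genes are computed; the
    paired percentages are compared across strains with a Wilcoxon
    signed-rank test (exact for n <= 25 without ties, normal approximation
    with continuity correction otherwise).

    Returns a dict with ``per_strain`` (DataFrame of paired percentages),
    ``p_activated`` and ``p_deactivated`` (NaN when fewer than two strains
    have the percentage defined).
    """
    rows = []
    for (species, family_id), sub in calls.groupby(["species", "family_id"]):
        act = sub[sub["direction"] == "activated"]
        deact = sub[sub["direction"] == "deactivated"]
        rows.append(
            {
                "species": species,
                "family_id": family_id,
                "pct_annotated_all": 100.0 * sub["annotated"].mean(),
                "pct_annotated_activated":
                    100.0 * act["annotated"].mean() if len(act) else float("nan"),
                "pct_annotated_deactivated":
                    100.0 * deact["annotated"].mean() if len(deact) else float("nan"),
            }
        )
    per_strain = pd.DataFrame(
        rows, columns=["species", "family_id", "pct_annotated_all",
                       "pct_annotated_activated", "pct_annotated_deactivated"])
    out = {"per_strain": per_strain}
    for key, col in (("p_activated", "pct_annotated_activated"),
                     ("p_deactivated", "pct_annotated_deactivated")):
        paired = per_strain.dropna(subset=[col, "pct_annotated_all"])
        if len(paired) < 2:
            out[key] = float("nan")
            continue
        diff = (paired[col] - paired["pct_annotated_all"]).to_numpy()
        out[key] = _signed_rank_p(diff)
    return out


def fraction_pct(numerator: float, denominator: float) -> float:
    """Percentage numerator/denominator * 100 (NaN-safe guard on zero)."""
    if denominator == 0:
        return math.nan
    return 100.0 * numerator / denominator
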