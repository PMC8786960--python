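"""Bundled example data: shared-strain counts from a ten-dyad pilot cohort.

A published pilot cohort of ten mother-infant dyads reported, per bacterial
species, how many mother-infant pairs shared a strain and how those events
split by the infant's breastfeeding status at six months. The table and the
cohort's aggregate gene-family counts are bundled so the package's summary
operations have a realistic worked example that needs no external data.
"""

from __future__ import annotations

import pandas as pd

# species, events, and events by breastfeeding status (exclusive, partial, none)
_SHARING_COUNTS = [
    ("Bacteroides ovatus", 4, 0, 4, 0),
    ("Bacteroides dorei", 3, 1, 2, 0),
    ("Bacteroides sp 3 1 33FAA", 3, 1, 1, 1),
    ("Bacteroides sp 3 1 40A", 3, 1, 1, 1),
    ("Bacteroides sp 4 3 47FAA", 3, 1, 1, 1),
    ("Bacteroides sp D1", 3, 0, 3, 0),
    ("Bacteroides caccae", 2, 0, 2, 0),
    ("Bacteroides sp 2 1 16", 2, 2, 0, 0),
    ("Bacteroides sp 2 1 7", 2, 1, 1, 0),
    ("Bacteroides sp 9 1 42FAA", 2, 1, 1, 0),
    ("Bifidobacterium adolescentis", 2, 0, 2, 0),
    ("Bifidobacterium longum", 2, 0, 2, 0),
    ("Parabacteroides distasonis", 2, 1, 1, 0),
    ("Parabacteroides sp 20 3", 2, 1, 1, 0),
    ("Bacteroides cellulosilyticus", 1, 1, 0, 0),
    ("Bacteroides fragilis", 1, 1, 0, 0),
    ("Bacteroides sp 1 1 30", 1, 0, 1, 0),
    ("Bacteroides sp 2 1 22", 1, 0, 1, 0),
    ("Bacteroides sp 2 2 4", 1, 0, 1, 0),
    ("Bacteroides sp 4 1 36", 1, 0, 1, 0),
    ("Bacteroides thetaiotaomicron", 1, 1, 0, 0),
    ("Bacteroides uniformis", 1, 0, 1, 0),
    ("Bacteroides vulgatus", 1, 0, 0, 1),
    ("Bifidobacterium bifidum", 1, 0, 1, 0),
    ("Bifidobacterium sp 12 1 47BFAA", 1, 0, 1, 0),
    ("Clostridium sp SS2 1", 1, 1, 0, 0),
    ("Collinsella aerofaciens", 1, 1, 0, 0),
    ("Lachnospiraceae bacterium 5 1 63FAA", 1, 1, 0, 0),
    ("Parabacteroides merdae", 1, 0, 1, 0),
    ("Roseburia inulinivorans", 1, 1, 0, 0),
]

#: aggregate counts reported for the same cohort's shift analysis: the
#: gene-family universe over shared strains with a transcriptome signal,
#: activation/deactivation event totals, and their annotation breakdown.
EXAMPLE_COHORT_COUNTS = {
    "gene_family_universe": 68_850,
    "activation_events": 12_574,
    "deactivation_events": 14_844,
    "unannotated_gene_families": 37_156,
    # the annotation comparison was reported against a slightly different
    # activated total than the event count above (an inconsistency in the
    # source report; both are kept verbatim)
    "activated_total_annotation": 12_564,
    "activated_unannotated": 5_764,
    "deactivated_total_annotation": 14_844,
    "deactivated_unannotated": 9_935,
}


def example_sharing_counts() -> pd.DataFrame:
    """Per-species shared-strain counts of the example cohort."""
    return pd.DataFrame(
        _SHARING_COUNTS,
        columns=["species", "events", "exclusive", "partial", "none"],
    )


def example_sharing_events() -> pd.DataFrame:
    """The example cohort's sharing counts expanded to one row per event.

    Family and sample identities were not published; placeholder ids are
    assigned so the events table satisfies the sharing-event schema.
    """
    rows = []
    k = 0
    for species, _total, n_ex, n_pa, n_no in _SHARING_COUNTS:
        for status, n in (("exclusive", n_ex), ("partial", n_pa), ("none", n_no)):
            for _ in range(n):
                k += 1
                rows.append(
                    {
                        "species": species,
                        "family_id": f"E{k:02d}",
                        "mother_sample": f"E{k:02d}M",
                        "infant_sample": f"E{k:02d}I",
                        "normalized_distance": float("nan"),
                        "breastfeeding": status,
                    }
                )
    return pd.DataFrame(rows)
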