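"""Mother-vs-infant differential abundance of metabolic pathway profiles.

Pathways observed in at least ``min_samples`` samples are tested one at a
time with a linear mixed-effects model on log10(abundance + pseudocount):
role (mother/infant) as the fixed effect and family as a random intercept,
the only plausible grouping with one sample per subject. p-values are
Benjamini-Hochberg adjusted within each molecule type over the filtered
pathway set. DNA and RNA tables are tested separately so genomic and
transcriptional differences can be contrasted pathway by pathway.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from dyadshift.io_tables import MetadataTable

logger = logging.getLogger(__name__)

MIN_SAMPLES = 2
Q_SIGNIFICANT = 0.05


def prevalence_filter(table: pd.DataFrame, min_samples: int = MIN_SAMPLES) -> pd.DataFrame:
    """Keep pathways with a positive value in at least ``min_samples`` samples."""
    observed = (table > 0).sum(axis=0)
    kept = table.loc[:, observed >= min_samples]
    kept.attrs = dict(table.attrs)
    return kept


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _pseudocount(table: pd.DataFrame) -> float:
    """Half the smallest nonzero value of the table (1.0 on all-zero input)."""
    vals = table.values
    nz = vals[vals > 0]
    return float(nz.min() / 2) if nz.size else 1.0


def test_pathways(
    table: pd.DataFrame,
    metadata: MetadataTable,
    min_samples: int = MIN_SAMPLES,
    q_threshold: float = Q_SIGNIFICANT,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Differential abundance of each pathway between mothers and infants.

    Fits log10(abundance + pseudocount) ~ role with a random intercept per
    family. A singular or failing mixed fit falls back to an ordinary linear
    model with a logged downgrade; pathways constant across samples are
    skipped with a warning.

    Returns a DataFrame with columns pathway_id, molecule,
    n_samples_observed, direction, coef, p, q, significant, model.
    """
    table = prevalence_filter(table, min_samples=min_samples)
    molecule = table.attrs.get("molecule", "NA")
    samples = [s for s in table.index if s in {r.sample_id for r in metadata}]
    if len(samples) < len(table.index):
        logger.warning("dropping %d samples absent from metadata",
                       len(table.index) - len(samples))
    table = table.loc[samples]
    roles = pd.Series({s: metadata.role_of(s) for s in samples})
    if roles.nunique() < 2:
        raise ValueError("both roles (mother, infant) must be present")
    families = pd.Series({s: metadata.family_of(s) for s in samples})
    pc = _pseudocount(table) if pseudocount is None else pseudocount

    rows = []
    for pathway in table.columns:
        y = np.log10(table[pathway].to_numpy(dtype=float) + pc)
        if np.ptp(y) == 0:
            logger.warning("pathway %s constant across samples; skipped", pathway)
            continue
        df = pd.DataFrame({
            "y": y,
            # infant effect relative to mothers: positive coef = higher in infants
            "is_infant": (roles.values == "infant").astype(float),
            "family": families.values,
        })
        coef, p, model_used = _fit_role_effect(df, pathway)
        rows.append(
            {
                "pathway_id": pathway,
                "molecule": molecule,
                "n_samples_observed": int((table[pathway] > 0).sum()),
                "direction": "infant" if coef > 0 else "mother",
                "coef": coef,
                "p": p,
                "model": model_used,
            }
        )
    results = pd.DataFrame(
        rows, columns=["pathway_id", "molecule", "n_samples_observed",
                       "direction", "coef", "p", "model"])
    if len(results):
        results["q"] = bh_fdr(results["p"].values)
        results["significant"] = results["q"] < q_threshold
    else:
        results["q"] = pd.Series(dtype=float)
        results["significant"] = pd.Series(dtype=bool)
    return results


def _fit_role_effect(df: pd.DataFrame, pathway: str) -> tuple[float, float, str]:
    """Role coefficient and two-sided p, mixed model with OLS fallback.

    The Wald statistic is referred to a t distribution with containment
    degrees of freedom (n_obs - n_families - 1 for a role effect varying
    within family) rather than the normal, which is anticonservative at
    cohort sizes of ~10 families.
    """
    from scipy import stats as sps

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = smf.mixedlm("y ~ is_infant", df, groups=df["family"]).fit(reml=True)
        coef = float(fit.params["is_infant"])
        se = float(fit.bse["is_infant"])
        ddf = len(df) - df["family"].nunique() - 1
        if se > 0 and np.isfinite(se) and ddf >= 1:
            tval = coef / se
            p = float(2 * sps.t.sf(abs(tval), ddf))
            return coef, p, "mixed"
        raise ValueError("degenerate mixed fit")
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("mixed model failed for %s (%s); falling back to OLS",
                       pathway, exc)
        X = sm.add_constant(df["is_infant"])
        fit = sm.OLS(df["y"], X).fit()
        return float(fit.params["is_infant"]), float(fit.pvalues["is_infant"]), "ols"
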