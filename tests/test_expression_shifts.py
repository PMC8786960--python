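import itertools

import numpy as np
import pandas as pd
import pytest

from dyadshift.expression_shifts import (
    StratumError,
    _signed_rank_p,
    analyze_shifts,
    annotation_rate_test,
    call_shifts,
    count_events,
    relative_expression,
    replication_rate,
    to_cpm,
)
from dyadshift.io_tables import AnnotationConfig, GeneFamilyTable


def make_table(strata, molecule):
    """strata: {(species, sample): {gene: cpm}} -> GeneFamilyTable."""
    index = set()
    for (sp, sid), genes in strata.items():
        for g, v in genes.items():
            index.add((sp, g))
    index = pd.MultiIndex.from_tuples(sorted(index),
                                      names=["species", "gene_family"])
    samples = sorted({sid for _, sid in strata})
    data = pd.DataFrame(0.0, index=index, columns=samples)
    for (sp, sid), genes in strata.items():
        for g, v in genes.items():
            data.loc[(sp, g), sid] = v
    return GeneFamilyTable(data, molecule=molecule)


class TestToCpm:
    def test_scales_to_one_million(self):
        assert list(to_cpm([1, 1, 2])) == [250_000, 250_000, 500_000]

    def test_single_gene(self):
        assert to_cpm([7])[0] == 1e6

    def test_assume_cpm_passthrough(self):
        vals = [5.0, 10.0]
        assert list(to_cpm(vals, assume_cpm=True)) == vals

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            to_cpm([0.0, 0.0])


class TestRelativeExpression:
    def _tables(self, dna_genes, rna_genes):
        dna = make_table({("sp", "S1"): dna_genes}, "DNA")
        rna = make_table({("sp", "S1"): rna_genes}, "RNA")
        return dna, rna

    def test_equal_rna_dna_gives_unit_relative_expression(self):
        genes = {f"g{i}": 10.0 for i in range(12)}
        dna, rna = self._tables(genes, genes)
        rec = relative_expression(dna, rna, "sp", "S1")
        assert np.allclose(rec.relative_expression, 1.0)

    def test_median_normalization(self):
        dna = {f"g{i}": 1.0 for i in range(11)}
        # ratios 1..11 with median 6 -> rel expr i/6
        rna = {f"g{i}": float(i + 1) for i in range(11)}
        d, r = self._tables(dna, rna)
        rec = relative_expression(d, r, "sp", "S1").set_index("gene_family")
        assert rec.loc["g5", "relative_expression"] == pytest.approx(1.0)
        assert rec.loc["g10", "relative_expression"] == pytest.approx(11 / 6)

    def test_stratum_median_is_one_for_odd_counts(self, small_cohort):
        meta = small_cohort.metadata
        sp = small_cohort.dna.species[0]
        rec = relative_expression(small_cohort.dna, small_cohort.rna, sp,
                                  meta.sample_ids[0])
        if len(rec) % 2 == 1:
            assert np.median(rec.relative_expression) == pytest.approx(
                1.0, abs=1e-12)

    def test_zero_dna_gene_excluded_from_stratum(self):
        dna = {f"g{i}": 1.0 for i in range(11)}
        dna["zero_dna"] = 0.0
        rna = {f"g{i}": 1.0 for i in range(11)}
        rna["zero_dna"] = 5.0
        d, r = self._tables(dna, rna)
        rec = relative_expression(d, r, "sp", "S1")
        assert "zero_dna" not in set(rec.gene_family)

    def test_zero_rna_gene_gets_ratio_zero(self):
        dna = {f"g{i}": 1.0 for i in range(11)}
        rna = {f"g{i}": 1.0 for i in range(10)}  # g10 untranscribed
        d, r = self._tables(dna, rna)
        rec = relative_expression(d, r, "sp", "S1").set_index("gene_family")
        assert rec.loc["g10", "ratio"] == 0.0

    def test_too_few_genes_excluded(self):
        d, r = self._tables({"g0": 1.0}, {"g0": 1.0})
        with pytest.raises(StratumError, match=">= 10"):
            relative_expression(d, r, "sp", "S1")

    def test_invariant_to_rna_stratum_rescaling(self):
        rng = np.random.default_rng(0)
        dna_genes = {f"g{i}": float(v) for i, v in
                     enumerate(rng.lognormal(1, 1, 15))}
        rna_genes = {g: v * rng.lognormal(0, 0.5) for g, v in dna_genes.items()}
        d, r = self._tables(dna_genes, rna_genes)
        rec = relative_expression(d, r, "sp", "S1")
        r_scaled = make_table(
            {("sp", "S1"): {g: 7.3 * v for g, v in rna_genes.items()}}, "RNA")
        rec2 = relative_expression(d, r_scaled, "sp", "S1")
        assert np.allclose(rec.relative_expression, rec2.relative_expression)


class TestCallShifts:
    def _records(self, rel_exprs):
        return pd.DataFrame({
            "gene_family": list(rel_exprs),
            "dna_cpm": 1.0,
            "rna_cpm": 1.0,
            "ratio": 1.0,
            "relative_expression": list(rel_exprs.values()),
        })

    @pytest.mark.parametrize(
        "infant, mother, direction",
        [
            (3.0, 1.0, "activated"),
            (0.4, 1.0, "deactivated"),
            (3.0, 2.0, "neutral"),      # fold 1.5 fails fold condition
            (2.0, 0.5, "neutral"),      # boundary: strict >
            (0.5, 1.01, "neutral"),     # boundary: strict <
            (3.0, 0.0, "activated"),    # fold = +inf
            (0.0, 1.0, "deactivated"),  # fold = 0
        ],
    )
    def test_threshold_rules(self, infant, mother, direction):
        calls = call_shifts(self._records({"g": infant}),
                            self._records({"g": mother}), "sp", "F01")
        assert calls.iloc[0].direction == direction

    def test_only_genes_in_both_strata_compared(self):
        calls = call_shifts(self._records({"a": 3.0, "b": 1.0}),
                            self._records({"b": 1.0, "c": 1.0}), "sp", "F01")
        assert set(calls.gene_family) == {"b"}

    def test_activated_and_deactivated_disjoint(self, small_cohort):
        rng = np.random.default_rng(1)
        rel = {f"g{i}": float(v) for i, v in
               enumerate(rng.lognormal(0, 1.5, 200))}
        rel_m = {g: float(v) for g, v in
                 zip(rel, rng.lognormal(0, 1.5, 200))}
        calls = call_shifts(self._records(rel), self._records(rel_m),
                            "sp", "F01")
        act = set(calls[calls.direction == "activated"].gene_family)
        deact = set(calls[calls.direction == "deactivated"].gene_family)
        assert not (act & deact)

    def test_annotation_flag_carried(self):
        ann = AnnotationConfig()
        calls = call_shifts(self._records({"g_unknown": 3.0, "g": 3.0}),
                            self._records({"g_unknown": 1.0, "g": 1.0}),
                            "sp", "F01", annotation=ann)
        flags = calls.set_index("gene_family").annotated
        assert bool(flags["g"]) and not bool(flags["g_unknown"])


class TestCountEvents:
    def _calls(self, rows):
        return pd.DataFrame(
            rows, columns=["species", "family_id", "gene_family",
                           "infant_rel_expr", "mother_rel_expr", "fold",
                           "direction", "annotated"])

    def test_unique_deduplication_across_families(self):
        rows = [
            ("sp", "FX", "G", 3, 1, 3, "activated", True),
            ("sp", "FY", "G", 4, 1, 4, "activated", True),
            ("sp", "FX", "H", 1, 1, 1, "neutral", True),
        ]
        table, totals = count_events(self._calls(rows))
        row = table.iloc[0]
        assert row.activation_events == 2
        assert row.unique_activated_families == 1
        assert totals["universe"] == 3
        assert totals["activation_pct"] == pytest.approx(100 * 2 / 3)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            count_events(self._calls([]))

    def test_counts_monotone_in_thresholds(self, small_cohort):
        """Looser thresholds can only add (de)activation events."""
        events = pd.DataFrame([
            {"species": sp, "family_id": fam, "mother_sample": f"{fam}M",
             "infant_sample": f"{fam}I"}
            for fam, sp in sorted(small_cohort.truth.transmissions)
        ])
        strict = analyze_shifts(events, small_cohort.dna, small_cohort.rna,
                                act_threshold=3.0, deact_threshold=0.25)
        loose = analyze_shifts(events, small_cohort.dna, small_cohort.rna,
                               act_threshold=2.0, deact_threshold=0.5)
        n_strict = (strict["calls"].direction == "activated").sum()
        n_loose = (loose["calls"].direction == "activated").sum()
        assert n_loose >= n_strict


class TestReplicationRate:
    def _calls(self, activations):
        rows = [("sp", fam, g, 3, 1, 3, "activated", True)
                for fam, genes in activations.items() for g in genes]
        rows.append(("sp", next(iter(activations)), "neutral_g",
                     1, 1, 1, "neutral", True))
        return pd.DataFrame(
            rows, columns=["species", "family_id", "gene_family",
                           "infant_rel_expr", "mother_rel_expr", "fold",
                           "direction", "annotated"])

    def test_hand_enumerated_rate(self):
        calls = self._calls({"F1": ["A", "B", "C"], "F2": ["A", "B"]})
        assert replication_rate(calls, "sp") == pytest.approx(2 / 3)

    def test_fully_consistent_activations(self):
        calls = self._calls({"F1": ["A", "B"], "F2": ["A", "B"]})
        assert replication_rate(calls, "sp") == 1.0

    def test_single_family_is_undefined(self):
        calls = self._calls({"F1": ["A", "B"]})
        assert np.isnan(replication_rate(calls, "sp"))


class TestAnnotationRateTest:
    def exhaustive_signed_rank_p(self, diffs):
        """Oracle: exact two-sided p by enumerating all sign assignments."""
        diffs = np.asarray(diffs, float)
        diffs = diffs[diffs != 0]
        n = len(diffs)
        ranks = pd.Series(np.abs(diffs)).rank().to_numpy()
        w_obs = ranks[diffs > 0].sum()
        w_all = []
        for signs in itertools.product([0, 1], repeat=n):
            w_all.append(sum(r for r, s in zip(ranks, signs) if s))
        w_all = np.asarray(w_all, float)
        mu = w_all.mean()
        more_extreme = np.abs(w_all - mu) >= abs(w_obs - mu) - 1e-12
        return more_extreme.mean()

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            diffs = rng.normal(size=8)
            assert _signed_rank_p(diffs) == pytest.approx(
                self.exhaustive_signed_rank_p(diffs), abs=1e-9)

    def test_consistent_onesided_shift_gives_two_over_sixtyfour(self):
        # 6 strains, activated% strictly below all-genes%: two-tailed p = 2/64
        diffs = np.array([-5.0, -3.0, -8.0, -1.0, -2.5, -4.0])
        assert _signed_rank_p(diffs) == pytest.approx(2 / 64)

    def test_identical_percentages_give_p_one(self):
        calls = pd.DataFrame({
            "species": ["sp"] * 4, "family_id": ["F1", "F1", "F2", "F2"],
            "gene_family": ["a", "b", "a", "b"],
            "infant_rel_expr": [3, 1, 3, 1], "mother_rel_expr": [1, 1, 1, 1],
            "fold": [3, 1, 3, 1],
            "direction": ["activated", "neutral"] * 2,
            "annotated": [True, True, True, True],
        })
        res = annotation_rate_test(calls)
        assert res["p_activated"] == 1.0
        assert len(res["per_strain"]) == 2

    def test_recovers_planted_annotation_depletion(self):
        # activated genes heavily depleted of annotation across 8 strains
        rng = np.random.default_rng(5)
        rows = []
        for k in range(8):
            for i in range(40):
                annotated = bool(rng.random() < 0.5)
                rows.append((f"sp{k}", "F1", f"g{i}", 1, 1, 1, "neutral",
                             annotated))
            for i in range(10):
                rows.append((f"sp{k}", "F1", f"act{i}", 3, 1, 3, "activated",
                             bool(rng.random() < 0.05)))
        calls = pd.DataFrame(
            rows, columns=["species", "family_id", "gene_family",
                           "infant_rel_expr", "mother_rel_expr", "fold",
                           "direction", "annotated"])
        res = annotation_rate_test(calls)
        assert res["p_activated"] < 0.05


class TestAnalyzeShifts:
    def test_multiple_infants_per_family_rejected(self, small_cohort):
        events = pd.DataFrame({
            "species": ["sp", "sp"], "family_id": ["F01", "F01"],
            "mother_sample": ["F01M", "F01M"],
            "infant_sample": ["F01Ia", "F01Ib"],
        })
        with pytest.raises(ValueError, match="explicit"):
            analyze_shifts(events, small_cohort.dna, small_cohort.rna)

    def test_no_events_yields_empty_results(self, small_cohort):
        events = pd.DataFrame(
            columns=["species", "family_id", "mother_sample", "infant_sample"])
        res = analyze_shifts(events, small_cohort.dna, small_cohort.rna)
        assert res["eligible"].empty and res["calls"].empty

    def test_planted_shifts_recovered(self, small_cohort):
        events = pd.DataFrame([
            {"species": sp, "family_id": fam, "mother_sample": f"{fam}M",
             "infant_sample": f"{fam}I"}
            for fam, sp in sorted(small_cohort.truth.transmissions)
        ])
        res = analyze_shifts(events, small_cohort.dna, small_cohort.rna)
        calls = res["calls"]
        called = {
            (r.family_id, r.species, r.gene_family, r.direction)
            for r in calls[calls.direction != "neutral"].itertuples()}
        planted = small_cohort.truth.shifts
        tp = len(called & planted)
        assert tp / len(called) > 0.95   # precision
        assert tp / len(planted) > 0.95  # recall
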