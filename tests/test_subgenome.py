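import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wheatdecay.io import SNVRecord
from wheatdecay.motifs import StructureMotifSeed, match_seed
from wheatdecay.subgenome import (asymmetry_correlation, classify_pairs,
                                  fst_hudson, fst_stratified_comparison,
                                  fst_weir_cockerham,
                                  motif_subgenome_enrichment, pairs_frame,
                                  snv_motif_perturbation)


def weir_cockerham_oracle(freqs, counts):
    """Independently coded textbook variance-components evaluation.

    Written directly from the a/b component definitions (haploid samples, no
    heterozygosity term) without reference to the library implementation.
    """
    freqs = list(map(float, freqs))
    counts = list(map(float, counts))
    r = len(freqs)
    nbar = sum(counts) / r
    sum_sq = sum(c * c for c in counts)
    nc = (r * nbar - sum_sq / (r * nbar)) / (r - 1)
    pbar = sum(c * p for c, p in zip(counts, freqs)) / (r * nbar)
    s2 = sum(c * (p - pbar) ** 2 for c, p in zip(counts, freqs)) / (
        (r - 1) * nbar
    )
    a = (nbar / nc) * (
        s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    )
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    return a / (a + b)


def replicate_rates(rates_a, rates_b):
    frame = pd.DataFrame(
        [rates_a, rates_b], index=["ga", "gb"],
        columns=[f"rep{i + 1}" for i in range(len(rates_a))],
    )
    return frame


class TestClassifyPairs:
    PAIRS = pd.DataFrame({"gene_a": ["ga"], "gene_b": ["gb"]})
    ABUNDANCE = pd.Series({"ga": 100.0, "gb": 50.0})

    def test_identical_rates_are_nsd(self):
        rr = replicate_rates([0.01, 0.011, 0.009], [0.01, 0.011, 0.009])
        out = classify_pairs(self.PAIRS, rr, self.ABUNDANCE)
        assert out[0].classification == "NSD"

    def test_separated_rates_a_gt_b(self):
        ra, rb = [0.02, 0.021, 0.019], [0.01, 0.0105, 0.0095]
        rr = replicate_rates(ra, rb)
        out = classify_pairs(self.PAIRS, rr, self.ABUNDANCE)
        assert out[0].classification == "A_gt_B"
        # p agrees with an independent one-sided t-test
        expected = stats.ttest_ind(ra, rb, alternative="greater").pvalue
        assert out[0].p_a_gt_b == pytest.approx(expected)
        assert out[0].fold_change == pytest.approx(np.mean(ra) / np.mean(rb))

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ra = list(rng.lognormal(-5, 0.2, 3))
            rb = list(rng.lognormal(-5.5, 0.2, 3))
            fwd = classify_pairs(self.PAIRS, replicate_rates(ra, rb),
                                 self.ABUNDANCE)[0].classification
            rev = classify_pairs(self.PAIRS, replicate_rates(rb, ra),
                                 self.ABUNDANCE)[0].classification
            swap = {"A_gt_B": "A_lt_B", "A_lt_B": "A_gt_B", "NSD": "NSD"}
            assert rev == swap[fwd]

    def test_single_replicate_rejected(self):
        rr = pd.DataFrame({"rep1": [0.01, 0.02]}, index=["ga", "gb"])
        with pytest.raises(ValueError, match="2 replicates"):
            classify_pairs(self.PAIRS, rr, self.ABUNDANCE)


class TestAsymmetryCorrelation:
    def test_exact_anticorrelation(self):
        rng = np.random.default_rng(1)
        n = 50
        rates_a = rng.lognormal(-6, 0.5, n)
        rates_b = rng.lognormal(-6, 0.5, n)
        frame = pd.DataFrame(
            {
                "gene_a": [f"a{i}" for i in range(n)],
                "gene_b": [f"b{i}" for i in range(n)],
                "classification": "A_gt_B",
                "delta_decay": np.log2(rates_a / rates_b),
                "delta_abundance": -np.log2(rates_a / rates_b),
            }
        )
        out = asymmetry_correlation(frame).set_index("stratum")
        assert out.loc["A_gt_B", "r"] == pytest.approx(-1.0)

    def test_empty_stratum_is_na(self):
        frame = pd.DataFrame(
            {
                "gene_a": ["a"], "gene_b": ["b"], "classification": ["NSD"],
                "delta_decay": [0.1], "delta_abundance": [0.2],
            }
        )
        out = asymmetry_correlation(frame).set_index("stratum")
        assert np.isnan(out.loc["A_lt_B", "r"])


class TestMotifSubgenomeEnrichment:
    def test_balanced_presence_odds_one(self):
        genes = [f"a{i}" for i in range(50)] + [f"b{i}" for i in range(50)]
        sub = pd.Series(["A"] * 50 + ["B"] * 50, index=genes)
        presence = pd.DataFrame(
            [[True] * 10 + [False] * 40 + [True] * 10 + [False] * 40],
            index=["m1"], columns=genes,
        )
        out = motif_subgenome_enrichment(presence, sub)
        assert out.loc[0, "odds_ratio"] == pytest.approx(1.0)

    def test_contingency_arithmetic(self):
        genes = [f"a{i}" for i in range(100)] + [f"b{i}" for i in range(100)]
        sub = pd.Series(["A"] * 100 + ["B"] * 100, index=genes)
        presence = pd.DataFrame(
            [[True] * 20 + [False] * 80 + [True] * 5 + [False] * 95],
            index=["m1"], columns=genes,
        )
        out = motif_subgenome_enrichment(presence, sub)
        assert out.loc[0, "odds_ratio"] == pytest.approx(
            (20 * 95) / (80 * 5)
        )

    def test_absent_motif_is_na(self):
        genes = ["a1", "a2", "b1", "b2"]
        sub = pd.Series(["A", "A", "B", "B"], index=genes)
        presence = pd.DataFrame([[False] * 4], index=["m1"], columns=genes)
        out = motif_subgenome_enrichment(presence, sub)
        assert np.isnan(out.loc[0, "odds_ratio"])

    def test_null_fdr_control(self):
        rng = np.random.default_rng(3)
        genes = [f"a{i}" for i in range(200)] + [f"b{i}" for i in range(200)]
        sub = pd.Series(["A"] * 200 + ["B"] * 200, index=genes)
        presence = pd.DataFrame(
            rng.random((50, 400)) < 0.2, index=[f"m{i}" for i in range(50)],
            columns=genes,
        )
        out = motif_subgenome_enrichment(presence, sub)
        assert (out["p_adj"] < 0.05).sum() <= 2


class TestFst:
    def test_fixation_gives_one(self):
        assert fst_weir_cockerham([0.0, 1.0], [1000, 1000]) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_identical_frequencies_near_zero(self):
        assert fst_weir_cockerham([0.5, 0.5], [100, 100]) == 0.0
        raw = fst_weir_cockerham([0.5, 0.5], [100, 100], clip=False)
        assert raw <= 0.0

    def test_matches_independent_textbook_evaluation(self):
        cases = [
            ([0.2, 0.8], [50, 50]),
            ([0.1, 0.5, 0.9], [60, 60, 60]),
            ([0.3, 0.35, 0.32], [40, 80, 120]),
        ]
        for freqs, sizes in cases:
            mine = fst_weir_cockerham(freqs, sizes, clip=False)
            oracle = weir_cockerham_oracle(freqs, sizes)
            assert mine == pytest.approx(oracle, abs=1e-3)

    def test_hudson_closed_form_on_large_samples(self):
        p1, p2, n = 0.2, 0.8, 100_000
        hudson = fst_hudson(p1, p2, n, n)
        closed = (p1 - p2) ** 2 / (p1 * (1 - p2) + p2 * (1 - p1))
        assert hudson == pytest.approx(closed, abs=1e-3)

    def test_monomorphic_is_na(self):
        assert np.isnan(fst_weir_cockerham([0.0, 0.0], [50, 50]))

    def test_too_few_populations(self):
        with pytest.raises(ValueError):
            fst_weir_cockerham([0.5], [50])


class TestSnvPerturbation:
    SEED = StructureMotifSeed("sRSM1", "GCAUC", "NNNN")
    SEQ = "GG" + "GCAUC" + "AAAA" + "GAUGC" + "CCC"

    def _snv(self, pos, ref, alt):
        return SNVRecord("s", "t", pos, ref, alt, {"WEW": (1, 10)})

    def matches(self, seed=None):
        return match_seed(seed or self.SEED, self.SEQ)

    def test_wobble_substitution_retains_match(self):
        # right-arm C paired with left-arm G; C->U leaves a GU pair
        snv = snv_motif_perturbation(self._snv(16, "C", "U"), self.SEED,
                                     self.matches(), self.SEQ)
        assert snv.motif_context == ("sRSM1", 3, "stem")
        assert not snv.perturbs_structure

    def test_strict_wc_flags_wobble(self):
        seed = StructureMotifSeed("s", "GCAUC", "NNNN", allow_gu=False)
        snv = snv_motif_perturbation(self._snv(16, "C", "U"), seed,
                                     match_seed(seed, self.SEQ), self.SEQ)
        assert snv.perturbs_structure

    def test_non_pairing_substitution_breaks_match(self):
        snv = snv_motif_perturbation(self._snv(16, "C", "A"), self.SEED,
                                     self.matches(), self.SEQ)
        assert snv.perturbs_structure

    def test_loop_n_position_is_unconstrained(self):
        snv = snv_motif_perturbation(self._snv(9, "A", "G"), self.SEED,
                                     self.matches(), self.SEQ)
        assert snv.motif_context == ("sRSM1", 3, "loop")
        assert not snv.perturbs_structure

    def test_reference_substitution_never_perturbs(self):
        for pos in range(3, 17):
            base = self.SEQ[pos - 1]
            snv = snv_motif_perturbation(self._snv(pos, base, base),
                                         self.SEED, self.matches(), self.SEQ)
            assert not snv.perturbs_structure

    def test_outside_three_utr_is_ignored(self):
        from wheatdecay.annotation import TranscriptAnnotation

        ann = TranscriptAnnotation(
            "g", "t", regions={"cds": [(1, 18)], "three_utr": [(19, 19)]}
        )
        snv = snv_motif_perturbation(self._snv(7, "C", "A"), self.SEED,
                                     self.matches(), self.SEQ, annotation=ann)
        assert snv.motif_context is None
        assert not snv.perturbs_structure


class TestFstStratified:
    def _records(self, fst_values):
        out = []
        for i, f in enumerate(fst_values):
            rec = SNVRecord(f"s{i}", "t", 1, "A", "G", {"WEW": (1, 10)})
            rec.fst = f
            out.append(rec)
        return out

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.beta(2, 5, 200)
        records = self._records(np.concatenate([vals, vals]))
        mask = np.array([True] * 200 + [False] * 200)
        _, p = fst_stratified_comparison(records, mask)
        assert p >= 0.4

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        low = rng.beta(2, 8, 200)
        high = rng.beta(4, 6, 200)
        records = self._records(np.concatenate([high, low]))
        mask = np.array([True] * 200 + [False] * 200)
        _, p = fst_stratified_comparison(records, mask)
        assert p < 0.05

    def test_small_stratum_is_na(self):
        records = self._records([0.1, 0.2, 0.3, 0.4])
        mask = np.array([True, False, False, False])
        with pytest.warns(UserWarning, match="fewer than 3"):
            _, p = fst_stratified_comparison(records, mask)
        assert np.isnan(p)

    def test_all_tied_is_na(self):
        records = self._records([0.2] * 10)
        mask = np.array([True] * 5 + [False] * 5)
        _, p = fst_stratified_comparison(records, mask)
        assert np.isnan(p)
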