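"""Homoeolog asymmetry, motif subgenome preference, F_ST and SNV
motif-perturbation calls.

Homoeolog pairs (A- vs B-subgenome gene copies) are classified by one-sided
two-sample t-tests on replicate-level decay rates; allele-frequency
differentiation across the wild emmer / domesticated emmer / durum (WEW /
DEW / DW) populations is measured with the Weir-Cockerham F_ST estimator
(Hudson's pairwise estimator is available as an alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motifs import MotifMatcher


@dataclass
class HomoeologPair:
    """A classified homoeologous gene pair."""

    gene_a: str
    gene_b: str
    rate_a: float
    rate_b: float
    abundance_a: float
    abundance_b: float
    classification: str  # 'A_gt_B', 'A_lt_B', 'NSD'
    p_a_gt_b: float
    p_a_lt_b: float

    @property
    def fold_change(self) -> float:
        return self.rate_a / self.rate_b

    @property
    def delta_decay(self) -> float:
        return float(np.log2(self.rate_a / self.rate_b))

    @property
    def delta_abundance(self) -> float:
        return float(np.log2(self.abundance_a / self.abundance_b))


def classify_pairs(pairs: pd.DataFrame, replicate_rates: pd.DataFrame,
                   abundance: pd.Series, alpha=0.05) -> list[HomoeologPair]:
    """Classify each homoeolog pair by one-sided t-tests on replicate rates.

    ``replicate_rates`` is a gene x replicate table of per-replicate decay
    rates.  A pair is ``A_gt_B`` when the one-sided test that the A copy
    decays faster rejects at ``alpha``, ``A_lt_B`` for the opposite test,
    otherwise NSD (no significant difference).
    """
    if replicate_rates.shape[1] < 2:
        raise ValueError("need >= 2 replicates for the pair t-test")
    out = []
    for row in pairs.itertuples(index=False):
        ra = replicate_rates.loc[row.gene_a].dropna().to_numpy()
        rb = replicate_rates.loc[row.gene_b].dropna().to_numpy()
        if len(ra) < 2 or len(rb) < 2:
            raise ValueError(f"pair {row.gene_a}/{row.gene_b}: missing replicates")
        with np.errstate(invalid="ignore", divide="ignore"):
            p_gt = stats.ttest_ind(ra, rb, alternative="greater").pvalue
            p_lt = stats.ttest_ind(ra, rb, alternative="less").pvalue
        # identical constant samples give an undefined t; that is no evidence
        p_gt = 1.0 if np.isnan(p_gt) else float(p_gt)
        p_lt = 1.0 if np.isnan(p_lt) else float(p_lt)
        if p_gt < alpha:
            cls = "A_gt_B"
        elif p_lt < alpha:
            cls = "A_lt_B"
        else:
            cls = "NSD"
        out.append(
            HomoeologPair(
                gene_a=row.gene_a, gene_b=row.gene_b,
                rate_a=float(np.mean(ra)), rate_b=float(np.mean(rb)),
                abundance_a=float(abundance.get(row.gene_a, np.nan)),
                abundance_b=float(abundance.get(row.gene_b, np.nan)),
                classification=cls, p_a_gt_b=p_gt, p_a_lt_b=p_lt,
            )
        )
    return out


def pairs_frame(classified: list[HomoeologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a, "gene_b": p.gene_b,
                "rate_a": p.rate_a, "rate_b": p.rate_b,
                "abundance_a": p.abundance_a, "abundance_b": p.abundance_b,
                "classification": p.classification,
                "fold_change": p.fold_change,
                "delta_decay": p.delta_decay,
                "delta_abundance": p.delta_abundance,
            }
            for p in classified
        ]
    )


def asymmetry_correlation(classified, strata=("A_lt_B", "A_gt_B"),
                          restrict_to=None) -> pd.DataFrame:
    """Pearson correlation of delta-decay vs delta-abundance per stratum.

    ``restrict_to`` optionally limits the computation to pairs whose genes
    appear in the given collection (e.g. motif-bearing pairs).
    """
    frame = pairs_frame(classified) if not isinstance(classified, pd.DataFrame) \
        else classified
    if restrict_to is not None:
        keep = set(restrict_to)
        frame = frame[
            frame["gene_a"].isin(keep) | frame["gene_b"].isin(keep)
        ]
    rows = []
    for stratum in strata:
        sub = frame if stratum == "all" else frame[
            frame["classification"] == stratum
        ]
        sub = sub.dropna(subset=["delta_decay", "delta_abundance"])
        if len(sub) < 3:
            rows.append({"stratum": stratum, "r": np.nan, "p": np.nan,
                         "n": len(sub)})
            continue
        r, p = stats.pearsonr(sub["delta_decay"], sub["delta_abundance"])
        rows.append({"stratum": stratum, "r": float(r), "p": float(p),
                     "n": len(sub)})
    return pd.DataFrame(rows)


def motif_subgenome_enrichment(presence: pd.DataFrame,
                               subgenome_of: pd.Series) -> pd.DataFrame:
    """Fisher's exact test of motif presence vs subgenome, BH-adjusted.

    ``presence`` is a motif x gene boolean matrix; ``subgenome_of`` maps
    gene -> 'A'/'B'.  The odds ratio is (A-present * B-absent) /
    (A-absent * B-present).
    """
    genes = [g for g in presence.columns if subgenome_of.get(g) in ("A", "B")]
    sub = subgenome_of[genes]
    if set(sub.unique()) != {"A", "B"}:
        raise ValueError("both subgenomes must be represented")
    a_genes = [g for g in genes if sub[g] == "A"]
    b_genes = [g for g in genes if sub[g] == "B"]
    rows = []
    for motif in presence.index:
        pa = int(presence.loc[motif, a_genes].sum())
        pb = int(presence.loc[motif, b_genes].sum())
        if pa + pb == 0:
            rows.append({"motif": motif, "odds_ratio": np.nan, "p": np.nan,
                         "n_a": 0, "n_b": 0})
            continue
        table = [[pa, len(a_genes) - pa], [pb, len(b_genes) - pb]]
        odds, p = stats.fisher_exact(table)
        rows.append({"motif": motif, "odds_ratio": float(odds), "p": float(p),
                     "n_a": pa, "n_b": pb})
    frame = pd.DataFrame(rows)
    mask = frame["p"].notna()
    frame["p_adj"] = np.nan
    if mask.any():
        frame.loc[mask, "p_adj"] = multipletests(frame.loc[mask, "p"],
                                                 method="fdr_bh")[1]
    return frame


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def fst_weir_cockerham(freqs, sizes, clip=True):
    """Weir-Cockerham theta over >= 2 populations of a biallelic locus.

    ``freqs`` are per-population alternate-allele frequencies and ``sizes``
    the allele sample sizes (haploid counts; the heterozygosity term of the
    diploid estimator is zero for allele-count data).  Returns the estimate
    clipped to [0, 1] unless ``clip=False`` (the raw value can be slightly
    negative for undifferentiated loci).
    """
    p = np.asarray(freqs, dtype=float)
    n = np.asarray(sizes, dtype=float)
    if len(p) < 2 or np.any(n <= 0):
        raise ValueError("need >= 2 populations with positive sample sizes")
    r = len(p)
    n_bar = n.mean()
    n_c = (r * n_bar - np.sum(n ** 2) / (r * n_bar)) / (r - 1)
    p_bar = np.sum(n * p) / (r * n_bar)
    s2 = np.sum(n * (p - p_bar) ** 2) / ((r - 1) * n_bar)
    if p_bar in (0.0, 1.0) and s2 == 0:
        return np.nan  # monomorphic across all populations
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2
    )
    denom = a + b
    if denom == 0:
        return np.nan
    theta = a / denom
    return float(np.clip(theta, 0.0, 1.0)) if clip else float(theta)


def fst_hudson(p1, p2, n1, n2):
    """Hudson's pairwise F_ST estimator for two populations."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0:
        return np.nan
    return num / den


def fst(snv, estimator="weir_cockerham", clip=True):
    """F_ST of one SNV record across its populations."""
    pops = sorted(snv.populations)
    freqs = [snv.allele_frequency(p) for p in pops]
    sizes = [snv.populations[p][1] for p in pops]
    if estimator == "weir_cockerham":
        return fst_weir_cockerham(freqs, sizes, clip=clip)
    if estimator == "hudson" and len(pops) == 2:
        return fst_hudson(freqs[0], freqs[1], sizes[0], sizes[1])
    raise ValueError(f"unknown estimator {estimator!r} for {len(pops)} populations")


def annotate_fst(snvs, estimator="weir_cockerham"):
    for snv in snvs:
        snv.fst = fst(snv, estimator=estimator)
    return snvs


# ---------------------------------------------------------------------------
# SNV motif perturbation
# ---------------------------------------------------------------------------

def snv_motif_perturbation(snv, seed, matches, sequence, annotation=None):
    """Decide whether an SNV's alternate allele disrupts a motif match.

    ``matches`` are 1-based offsets of ``seed`` in ``sequence`` (transcript
    coordinates).  The SNV perturbs the structure when substituting the
    alternate allele breaks a stem base pair (non-Watson-Crick, and non-GU
    when wobble is allowed) or violates the seed's IUPAC constraint so that
    the match is lost; the call is made by re-evaluating the match on the
    substituted sequence.  Updates and returns the record.
    """
    from .motifs import match_seed

    seq = sequence.upper().replace("T", "U")
    pos = snv.position
    snv.motif_context = None
    snv.perturbs_structure = False
    if annotation is not None and annotation.region_of(pos) != "three_utr":
        return snv
    if pos < 1 or pos > len(seq):
        return snv
    if seq[pos - 1] != snv.ref_allele:
        warnings.warn(
            f"{snv.locus_id}: reference allele {snv.ref_allele} does not match "
            f"sequence base {seq[pos - 1]} at position {pos}"
        )
    s, w = seed.stem_length, seed.width
    for offset in matches:
        rel = pos - offset  # 0-based position within the window
        if not 0 <= rel < w:
            continue
        if rel < s or rel >= w - s:
            role = "stem"
        else:
            role = "loop"
        snv.motif_context = (seed.seed_id, offset, role)
        mutated = seq[: pos - 1] + snv.alt_allele + seq[pos:]
        still = offset in match_seed(seed, mutated)
        if not still:
            snv.perturbs_structure = True
            return snv
    return snv


def fst_stratified_comparison(snvs, perturbing_mask=None):
    """One-sided rank-sum test: perturbing SNVs have higher F_ST.

    Returns ``(statistic, p)``; strata smaller than 3 give ``p = NaN`` with
    a warning, as do all-tied values.
    """
    fst_vals = np.array([s.fst for s in snvs], dtype=float)
    if perturbing_mask is None:
        perturbing_mask = np.array([s.perturbs_structure for s in snvs])
    perturbing_mask = np.asarray(perturbing_mask, dtype=bool)
    x = fst_vals[perturbing_mask]
    y = fst_vals[~perturbing_mask]
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        warnings.warn("a stratum has fewer than 3 SNVs; p undefined")
        return np.nan, np.nan
    if np.all(x == x[0]) and np.all(y == x[0]):
        return np.nan, np.nan  # all tied: no ordering information
    stat, p = stats.mannwhitneyu(x, y, alternative="greater")
    return float(stat), float(p)


def motif_presence_by_subgenome(sequences: dict, seeds, subgenome_of: pd.Series,
                                shapes=None) -> pd.DataFrame:
    """Convenience: motif x gene presence matrix for enrichment testing."""
    matcher = MotifMatcher(sequences, shapes)
    data = {s.seed_id: matcher.presence(s) for s in seeds}
    return pd.DataFrame(data, index=list(sequences)).T
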