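"""Sequence-level mRNA features correlated with stability.

Covers region lengths and GC/AU composition, per-gene codon frequencies,
the codon stabilization coefficient (CSC: per-codon Pearson correlation of
codon frequency against a per-gene stability measure), and the geometric-mean
codon indices cAI (codon adaptation) and tAI (tRNA adaptation).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import REGION_NAMES

STOP_CODONS = {"UAA", "UAG", "UGA"}
SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product("ACGU", repeat=3))
    if c not in STOP_CODONS
)  # 61 codons in lexicographic order


def region_composition(annotation, sequence: str) -> dict:
    """Per-region lengths and GC/AU fractions for one transcript.

    Ambiguous bases are excluded from composition denominators; an empty
    region yields missing metrics (NaN), never zero.
    """
    seq = sequence.upper().replace("T", "U")
    out = {"gene_id": annotation.gene_id, "transcript_length": len(seq)}
    for region in REGION_NAMES:
        sub = annotation.region_sequence(seq, region)
        out[f"{region}_length"] = len(sub) if sub else np.nan
        unambiguous = [c for c in sub if c in "ACGU"]
        if not unambiguous:
            out[f"{region}_gc"] = np.nan
            out[f"{region}_au"] = np.nan
            continue
        n = len(unambiguous)
        gc = sum(1 for c in unambiguous if c in "GC")
        out[f"{region}_gc"] = gc / n
        out[f"{region}_au"] = 1.0 - gc / n
    return out


def codon_frequencies(cds: str) -> pd.Series:
    """Fractions of the 61 sense codons in a frame-0 CDS.

    The terminal stop codon is excluded; an internal stop truncates the CDS
    at that point with a warning.  Codons containing ambiguous bases are
    skipped.  Fractions sum to 1 over the counted codons.
    """
    seq = cds.upper().replace("T", "U")
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    kept = []
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            warnings.warn(f"internal stop codon at codon {i + 1}; CDS truncated")
            break
        kept.append(c)
    counts = pd.Series(0.0, index=list(SENSE_CODONS))
    for c in kept:
        if c in counts.index:
            counts[c] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable sense codons")
    return counts / total


def csc(codon_freqs: pd.DataFrame, stability: pd.Series) -> pd.DataFrame:
    """Codon stabilization coefficients.

    Per codon: the Pearson correlation across genes between that codon's
    frequency and the per-gene stability measure.  With the default
    half-life measure a positive CSC marks a codon enriched in stable
    mRNAs; pass decay rates instead to flip the orientation (the choice is
    the caller's and should be reported alongside the table).

    ``codon_freqs`` is gene x 61-codon; ``stability`` gene -> measure.
    """
    common = codon_freqs.index.intersection(stability.dropna().index)
    if len(common) < 10:
        raise ValueError("need >= 10 genes with codon and stability data")
    x = stability[common].to_numpy(dtype=float)
    rows = []
    for codon in SENSE_CODONS:
        y = codon_freqs.loc[common, codon].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(x) == 0:
            rows.append({"codon": codon, "csc": np.nan, "p_value": np.nan,
                         "n_genes": len(common)})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            r, p = stats.pearsonr(y, x)
        rows.append({"codon": codon, "csc": r, "p_value": p, "n_genes": len(common)})
    return pd.DataFrame(rows).set_index("codon")


def _geometric_mean_index(cds: str, weights: pd.Series, name: str) -> float:
    freqs_seq = cds.upper().replace("T", "U")
    if len(freqs_seq) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [freqs_seq[i : i + 3] for i in range(0, len(freqs_seq), 3)]
    codons = [c for c in codons if c not in STOP_CODONS]
    if not codons:
        raise ValueError("CDS has no sense codons")
    logs = []
    for c in codons:
        if set(c) - set("ACGU"):
            continue  # ambiguous codons are skipped
        if c not in weights.index or not np.isfinite(weights[c]):
            raise ValueError(f"missing {name} weight for codon {c}")
        w = float(weights[c])
        if not (0 < w <= 1):
            raise ValueError(f"{name} weight for {c} must be in (0, 1]")
        logs.append(np.log(w))
    if not logs:
        raise ValueError("no unambiguous codons to score")
    return float(np.exp(np.mean(logs)))


def cai(cds: str, reference_weights: pd.Series) -> float:
    """Codon adaptation index: geometric mean of relative-adaptiveness
    weights over the CDS (stop codons excluded)."""
    return _geometric_mean_index(cds, reference_weights, "cAI")


def tai(cds: str, trna_weights: pd.Series) -> float:
    """tRNA adaptation index: geometric mean of tRNA-derived weights."""
    return _geometric_mean_index(cds, trna_weights, "tAI")


def relative_adaptiveness(reference_freqs: pd.DataFrame) -> pd.Series:
    """cAI weights from a highly expressed reference gene set.

    Within each synonymous-codon family the weight is the codon's total
    usage divided by the family maximum.
    """
    from Bio.Data.CodonTable import standard_rna_table

    usage = reference_freqs.sum(axis=0)
    families = {}
    for codon in SENSE_CODONS:
        aa = standard_rna_table.forward_table[codon]
        families.setdefault(aa, []).append(codon)
    weights = pd.Series(np.nan, index=list(SENSE_CODONS))
    for codons in families.values():
        peak = max(usage[c] for c in codons)
        for c in codons:
            weights[c] = usage[c] / peak if peak > 0 else 1.0
    return weights.clip(lower=1e-4)


def feature_decay_correlations(features: pd.DataFrame, fits: pd.DataFrame
                               ) -> pd.DataFrame:
    """Two-sided Pearson correlation of each numeric feature with decay rate."""
    rates = fits.set_index("gene")["alpha_per_min"]
    frame = features.set_index("gene_id") if "gene_id" in features else features
    rows = []
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            continue
        paired = pd.DataFrame({"x": frame[col], "rate": rates}).dropna()
        if len(paired) < 3:
            continue
        if paired["x"].std() == 0 or paired["rate"].std() == 0:
            warnings.warn(f"feature {col} has zero variance; skipped")
            rows.append({"feature": col, "r": np.nan, "p": np.nan,
                         "n": len(paired)})
            continue
        r, p = stats.pearsonr(paired["x"], paired["rate"])
        rows.append({"feature": col, "r": r, "p": p, "n": len(paired)})
    return pd.DataFrame(rows)


def within_pair_feature_relationships(pairs: pd.DataFrame, features: pd.Series,
                                      rates: pd.Series) -> dict:
    """Counts of homoeolog pairs whose within-pair feature and rate
    differences agree (positive) or oppose (negative) in sign."""
    pos = neg = 0
    for row in pairs.itertuples(index=False):
        if row.gene_a not in features.index or row.gene_b not in features.index:
            continue
        df_feat = features[row.gene_a] - features[row.gene_b]
        df_rate = rates.get(row.gene_a, np.nan) - rates.get(row.gene_b, np.nan)
        if not (np.isfinite(df_feat) and np.isfinite(df_rate)):
            continue
        if df_feat * df_rate > 0:
            pos += 1
        elif df_feat * df_rate < 0:
            neg += 1
    return {"positive": pos, "negative": neg}
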