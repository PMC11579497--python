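"""Region-level RNA structure summaries from SHAPE probing and base-pairing
probabilities, and their correlation with decay rates.

High SHAPE reactivity marks single-stranded nucleotides; the per-nucleotide
pairing probability q(i) = sum_j p(i, j) summarizes the thermodynamic
ensemble from an external partition-function folder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import REGION_NAMES

DEFAULT_COVERAGE_THRESHOLD = 0.3


@dataclass
class RegionStructureSummary:
    gene_id: str
    mean_shape: dict  # region -> mean reactivity or NaN
    mean_bpp: dict  # region -> mean pairing probability or NaN
    coverage: dict  # region -> fraction of positions with data


def region_average_shape(profile, annotation,
                         coverage_threshold=DEFAULT_COVERAGE_THRESHOLD
                         ) -> RegionStructureSummary:
    """Arithmetic mean of non-missing reactivities per region.

    Returns NaN for a region that is absent or whose covered fraction falls
    below ``coverage_threshold``.
    """
    react = np.asarray(profile.reactivity, dtype=float)
    if len(react) != annotation.transcript_length:
        raise ValueError(
            f"{annotation.transcript_id}: SHAPE profile length {len(react)} "
            f"!= transcript length {annotation.transcript_length}"
        )
    means, cover = {}, {}
    for region in REGION_NAMES:
        positions = annotation.region_positions(region)
        if not positions:
            means[region] = np.nan
            cover[region] = np.nan
            continue
        vals = react[np.asarray(positions) - 1]
        frac = float(np.mean(np.isfinite(vals)))
        cover[region] = frac
        means[region] = (
            float(np.nanmean(vals)) if frac >= coverage_threshold and frac > 0
            else np.nan
        )
    return RegionStructureSummary(annotation.gene_id, means, {}, cover)


def per_nucleotide_bpp(bpp) -> np.ndarray:
    """q(i) = sum_j p(i, j), clipped into [0, 1]; index 0 is position 1."""
    q = np.zeros(bpp.length)
    for i, j, p in bpp.pairs:
        if not (1 <= i <= bpp.length and 1 <= j <= bpp.length):
            raise ValueError(f"pair index out of range: ({i}, {j})")
        q[i - 1] += p
        q[j - 1] += p
    n_clipped = int(np.sum(q > 1))
    if n_clipped:
        import logging

        logging.getLogger(__name__).info(
            "%s: clipped %d positions with q > 1", bpp.transcript_id, n_clipped
        )
    return np.clip(q, 0.0, 1.0)


def region_average_bpp(bpp, annotation,
                       coverage_threshold=DEFAULT_COVERAGE_THRESHOLD
                       ) -> RegionStructureSummary:
    """Mean per-nucleotide pairing probability per region."""
    q = per_nucleotide_bpp(bpp)
    if len(q) != annotation.transcript_length:
        raise ValueError(
            f"{annotation.transcript_id}: BPP length {len(q)} != "
            f"transcript length {annotation.transcript_length}"
        )
    means, cover = {}, {}
    for region in REGION_NAMES:
        positions = annotation.region_positions(region)
        if not positions:
            means[region] = np.nan
            cover[region] = np.nan
            continue
        vals = q[np.asarray(positions) - 1]
        cover[region] = 1.0
        means[region] = float(np.mean(vals))
    return RegionStructureSummary(annotation.gene_id, {}, means, cover)


def structure_decay_correlation(summaries, fits: pd.DataFrame,
                                measure="shape", regions=None) -> pd.DataFrame:
    """Per-region Pearson correlation of mean structure signal vs decay rate.

    ``measure`` selects ``shape`` (mean reactivity) or ``bpp`` (mean pairing
    probability).  ``regions`` defaults to the regions that carry any data;
    a requested region with fewer than 3 paired values is an error.
    """
    rates = fits.set_index("gene")["alpha_per_min"]
    attr = "mean_shape" if measure == "shape" else "mean_bpp"
    if regions is None:
        regions = [
            r for r in REGION_NAMES
            if any(np.isfinite(getattr(s, attr).get(r, np.nan))
                   for s in summaries)
        ]
    rows = []
    for region in regions:
        pairs = []
        for summ in summaries:
            val = getattr(summ, attr).get(region, np.nan)
            rate = rates.get(summ.gene_id, np.nan)
            if np.isfinite(val) and np.isfinite(rate):
                pairs.append((val, rate))
        if len(pairs) < 3:
            raise ValueError(f"region {region}: fewer than 3 paired values")
        x, y = map(np.asarray, zip(*pairs))
        r, p = stats.pearsonr(x, y)
        rows.append({"region": region, "r": r, "p": p, "n": len(pairs)})
    return pd.DataFrame(rows)
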