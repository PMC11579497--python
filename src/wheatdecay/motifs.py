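"""Discovery of stability-associated stem-loop motifs in 3' UTRs.

A motif *seed* is a degenerate stem-loop: an IUPAC left arm of length s
(4-7 nt), an IUPAC loop of length l (4-9 nt), and an implicit right arm in
which position k of the left arm pairs with position s-k+1 of the right arm
(Watson-Crick, optionally G-U wobble).  Seeds are constrained to 14-20 bits
of information content and 4-6 degenerate positions.

Transcripts with decay estimates are split into 15 equal-frequency stability
bins (bin 1 = most stable).  Each seed's binary presence vector R over
transcripts is scored against the bin assignment A by the plug-in mutual
information MI(R;A) in bits, and calibrated with a permutation Z-score from
randomly shuffled bin labels.  Motifs with MI above threshold and Z above
threshold are classified as sRSM (enriched among stable transcripts) or uRSM
(enriched among unstable ones) from the trend of their per-bin frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}
_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_SENTINEL = 4  # separator value that matches nothing

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}

DEFAULT_MI_THRESHOLD = 0.001
DEFAULT_Z_THRESHOLD = 2.0
DEFAULT_N_BINS = 15


def encode(sequence: str) -> np.ndarray:
    """Sequence -> int8 codes (A=0 C=1 G=2 U=3, anything else 4)."""
    seq = sequence.upper().replace("T", "U")
    return np.array([_NUC_INDEX.get(c, _SENTINEL) for c in seq], dtype=np.int8)


def _char_mask(iupac_char: str) -> np.ndarray:
    mask = np.zeros(5, dtype=bool)
    for c in IUPAC[iupac_char]:
        mask[_NUC_INDEX[c]] = True
    return mask


def _pair_table(allow_gu: bool) -> np.ndarray:
    table = np.zeros((5, 5), dtype=bool)
    pairs = WC_PAIRS | (GU_PAIRS if allow_gu else set())
    for a, b in pairs:
        table[_NUC_INDEX[a], _NUC_INDEX[b]] = True
    return table


def information_content(left_arm: str, loop: str) -> float:
    """Bits of sequence information in one arm plus loop.

    Every fully specified position contributes 2 bits; a degenerate IUPAC
    code with d admissible nucleotides contributes 2 - log2(d).  The right
    arm is treated as determined by Watson-Crick complementarity and adds
    nothing.
    """
    bits = 0.0
    for c in left_arm + loop:
        if c not in IUPAC:
            raise ValueError(f"non-IUPAC character {c!r}")
        bits += 2.0 - np.log2(len(IUPAC[c]))
    return bits


def n_degenerate(left_arm: str, loop: str) -> int:
    return sum(1 for c in left_arm + loop if len(IUPAC[c]) > 1)


@dataclass
class SeedConstraints:
    stem: tuple = (4, 7)
    loop: tuple = (4, 9)
    information: tuple = (14.0, 20.0)
    degenerate: tuple = (4, 6)


@dataclass
class StructureMotifSeed:
    """A degenerate stem-loop seed pattern."""

    seed_id: str
    left_arm: str
    loop: str
    allow_gu: bool = True
    source: str = "grammar"  # or 'imported'
    flags: set = field(default_factory=set)

    def __post_init__(self):
        self.left_arm = self.left_arm.upper().replace("T", "U")
        self.loop = self.loop.upper().replace("T", "U")
        for c in self.left_arm + self.loop:
            if c not in IUPAC:
                raise ValueError(f"{self.seed_id}: non-IUPAC character {c!r}")

    @property
    def stem_length(self) -> int:
        return len(self.left_arm)

    @property
    def loop_length(self) -> int:
        return len(self.loop)

    @property
    def width(self) -> int:
        return 2 * self.stem_length + self.loop_length

    @property
    def information_content(self) -> float:
        return information_content(self.left_arm, self.loop)

    @property
    def n_degenerate(self) -> int:
        return n_degenerate(self.left_arm, self.loop)

    def satisfies(self, constraints: SeedConstraints = SeedConstraints()) -> bool:
        c = constraints
        return (
            c.stem[0] <= self.stem_length <= c.stem[1]
            and c.loop[0] <= self.loop_length <= c.loop[1]
            and c.information[0] <= self.information_content <= c.information[1]
            and c.degenerate[0] <= self.n_degenerate <= c.degenerate[1]
        )


_DEGENERATE_CODES = "RYSWKMBDHVN"
_SPECIFIED = "ACGU"


def enumerate_seeds(constraints: SeedConstraints = SeedConstraints(),
                    budget=10_000, seed=0, allow_gu=True,
                    max_attempts=None) -> list[StructureMotifSeed]:
    """Deterministic sample (without replacement) from the constrained seed
    grammar.

    The grammar space is far too large to enumerate exhaustively, so seeds
    are drawn by seeded rejection sampling up to ``budget`` accepted seeds.
    """
    rng = np.random.default_rng(seed)
    if max_attempts is None:
        max_attempts = budget * 500
    seen = set()
    out = []
    s_lo, s_hi = constraints.stem
    l_lo, l_hi = constraints.loop
    d_lo, d_hi = constraints.degenerate
    if s_lo > s_hi or l_lo > l_hi:
        raise ValueError("empty constraint space")
    attempts = 0
    while len(out) < budget and attempts < max_attempts:
        attempts += 1
        s = int(rng.integers(s_lo, s_hi + 1))
        l = int(rng.integers(l_lo, l_hi + 1))
        ndeg = int(rng.integers(d_lo, d_hi + 1))
        if ndeg > s + l:
            continue
        positions = rng.choice(s + l, size=ndeg, replace=False)
        chars = list(rng.choice(list(_SPECIFIED), size=s + l))
        for p in positions:
            chars[p] = rng.choice(list(_DEGENERATE_CODES))
        left = "".join(chars[:s])
        loop = "".join(chars[s:])
        cand = StructureMotifSeed(f"seed{len(out) + 1:05d}", left, loop,
                                  allow_gu=allow_gu)
        if not cand.satisfies(constraints):
            continue
        key = (left, loop)
        if key in seen:
            continue
        seen.add(key)
        out.append(cand)
    if not out:
        raise ValueError("no seeds satisfy the constraints")
    return out


def import_seeds(path, constraints: SeedConstraints = SeedConstraints()
                 ) -> list[StructureMotifSeed]:
    """Load an external seed library (e.g. thermodynamically folded aptamer
    libraries) from TSV with columns seed_id, left_arm, loop[, allow_gu].

    Imported seeds are validated for IUPAC content; seeds outside the
    grammar constraints are retained but flagged ``out_of_range``.
    """
    frame = pd.read_csv(path, sep="\t")
    if frame.empty:
        warnings.warn(f"{path}: empty seed library")
        return []
    seeds = []
    for row in frame.itertuples(index=False):
        gu = bool(getattr(row, "allow_gu", True))
        seed = StructureMotifSeed(str(row.seed_id), str(row.left_arm),
                                  str(row.loop), allow_gu=gu, source="imported")
        if not seed.satisfies(constraints):
            seed.flags.add("out_of_range")
            warnings.warn(f"imported seed {seed.seed_id} outside grammar constraints")
        seeds.append(seed)
    return seeds


def write_seeds(seeds, path):
    pd.DataFrame(
        [
            {
                "seed_id": s.seed_id,
                "left_arm": s.left_arm,
                "loop": s.loop,
                "allow_gu": s.allow_gu,
                "source": s.source,
            }
            for s in seeds
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

class MotifMatcher:
    """Vectorized stem-loop matching over a set of 3' UTR sequences.

    All sequences are concatenated with separator symbols; each seed is then
    scanned in a handful of numpy passes.  A window of width 2s+l matches
    when (a) left arm and loop satisfy their IUPAC constraints, (b) every
    stem position pairs Watson-Crick (or G-U if the seed allows wobble) with
    its opposite base, and (c), when SHAPE data are available, the mean stem
    reactivity is below both the mean loop reactivity and a per-transcript
    cutoff (default: the transcript's median reactivity), reflecting that a
    formed stem is protected from chemical probing in vivo.
    """

    def __init__(self, sequences: dict, shapes: dict | None = None,
                 stem_cutoff="median"):
        self.ids = list(sequences)
        codes, shape_vals, tidx, starts = [], [], [], []
        pos = 0
        cutoffs = np.full(len(self.ids), np.nan)
        for i, tid in enumerate(self.ids):
            seq = encode(sequences[tid])
            starts.append(pos)
            codes.append(seq)
            tidx.append(np.full(len(seq), i, dtype=np.int32))
            if shapes is not None and tid in shapes:
                react = np.asarray(shapes[tid].reactivity, dtype=float)
                if len(react) != len(seq):
                    raise ValueError(f"{tid}: SHAPE length mismatch")
                shape_vals.append(react)
                if np.isfinite(react).any():
                    cutoffs[i] = (
                        np.nanmedian(react) if stem_cutoff == "median"
                        else float(stem_cutoff)
                    )
            else:
                shape_vals.append(np.full(len(seq), np.nan))
            # separator
            codes.append(np.array([_SENTINEL], dtype=np.int8))
            shape_vals.append(np.array([np.nan]))
            tidx.append(np.array([-1], dtype=np.int32))
            pos += len(seq) + 1
        self.seq = np.concatenate(codes)
        self.shape = np.concatenate(shape_vals)
        self.tidx = np.concatenate(tidx)
        self.starts = np.asarray(starts)
        self._cutoffs = cutoffs
        self.has_shape = shapes is not None and np.isfinite(self.shape).any()
        self._shape_filled = np.nan_to_num(self.shape, nan=0.0)
        self._shape_known = np.isfinite(self.shape).astype(float)

    @property
    def n_transcripts(self):
        return len(self.ids)

    def _window_valid(self, seed: StructureMotifSeed):
        s, l, w = seed.stem_length, seed.loop_length, seed.width
        n_win = len(self.seq) - w + 1
        if n_win <= 0:
            return np.zeros(0, dtype=bool)
        valid = np.ones(n_win, dtype=bool)
        pair_ok = _pair_table(seed.allow_gu)
        for k in range(s):
            mask = _char_mask(seed.left_arm[k])
            valid &= mask[self.seq[k : k + n_win]]
            valid &= pair_ok[self.seq[k : k + n_win],
                             self.seq[w - 1 - k : w - 1 - k + n_win]]
        for i in range(l):
            mask = _char_mask(seed.loop[i])
            valid &= mask[self.seq[s + i : s + i + n_win]]

        if self.has_shape and valid.any():
            stem_idx = [k for k in range(s)] + [w - 1 - k for k in range(s)]
            loop_idx = list(range(s, s + l))
            stem_sum = sum(self._shape_filled[k : k + n_win] for k in stem_idx)
            stem_cnt = sum(self._shape_known[k : k + n_win] for k in stem_idx)
            loop_sum = sum(self._shape_filled[k : k + n_win] for k in loop_idx)
            loop_cnt = sum(self._shape_known[k : k + n_win] for k in loop_idx)
            with np.errstate(invalid="ignore", divide="ignore"):
                stem_mean = np.where(stem_cnt > 0, stem_sum / np.maximum(stem_cnt, 1),
                                     np.nan)
                loop_mean = np.where(loop_cnt > 0, loop_sum / np.maximum(loop_cnt, 1),
                                     np.nan)
            cut = np.full(n_win, np.nan)
            tw = self.tidx[:n_win]
            inside = tw >= 0
            cut[inside] = self._cutoffs[tw[inside]]
            # filter applies only where structure data exist for the window
            have = np.isfinite(stem_mean) & np.isfinite(loop_mean) & np.isfinite(cut)
            fail = have & ~((stem_mean < loop_mean) & (stem_mean < cut))
            valid &= ~fail
        return valid

    def presence(self, seed: StructureMotifSeed) -> np.ndarray:
        """Boolean per-transcript vector: >= 1 match anywhere in the UTR."""
        valid = self._window_valid(seed)
        out = np.zeros(self.n_transcripts, dtype=bool)
        if valid.any():
            hits = self.tidx[: len(valid)][valid]
            out[hits[hits >= 0]] = True
        return out

    def matches(self, seed: StructureMotifSeed):
        """All matches as (transcript_id, 1-based offset) tuples."""
        valid = self._window_valid(seed)
        out = []
        for p in np.where(valid)[0]:
            t = self.tidx[p]
            if t >= 0:
                out.append((self.ids[t], int(p - self.starts[t] + 1)))
        return out


def match_seed(seed: StructureMotifSeed, sequence: str, shape=None):
    """Match one seed against one sequence; returns 1-based offsets."""
    shapes = None if shape is None else {"__seq__": shape}
    matcher = MotifMatcher({"__seq__": sequence}, shapes)
    return [off for _, off in matcher.matches(seed)]


# ---------------------------------------------------------------------------
# binning, mutual information, permutation calibration
# ---------------------------------------------------------------------------

@dataclass
class BinAssignment:
    """Equal-frequency stability bins, 1 = most stable (lowest decay rate)."""

    transcripts: list
    bins: np.ndarray  # 1-based bin index per transcript
    n_bins: int

    @property
    def bin_sizes(self) -> np.ndarray:
        return np.bincount(self.bins, minlength=self.n_bins + 1)[1:]

    def as_series(self) -> pd.Series:
        return pd.Series(self.bins, index=self.transcripts, name="bin")


def bin_transcripts(rates: pd.Series, n_bins: int = DEFAULT_N_BINS) -> BinAssignment:
    """Split transcripts into equal-frequency bins by ascending decay rate.

    Bin sizes differ by at most one; ties in rate break by transcript id so
    the assignment is deterministic.
    """
    rates = rates.dropna()
    n = len(rates)
    if n < n_bins:
        raise ValueError(f"need >= {n_bins} transcripts, got {n}")
    order = rates.to_frame("rate").reset_index()
    order.columns = ["transcript", "rate"]
    order = order.sort_values(["rate", "transcript"], kind="mergesort")
    sizes = [n // n_bins + (1 if i < n % n_bins else 0) for i in range(n_bins)]
    labels = np.repeat(np.arange(1, n_bins + 1), sizes)
    return BinAssignment(order["transcript"].tolist(), labels, n_bins)


def _mi_from_counts(c1: np.ndarray, bin_totals: np.ndarray) -> np.ndarray:
    """MI in bits from per-bin presence counts.

    ``c1`` is (..., B) presence counts per bin; ``bin_totals`` the bin sizes.
    """
    c1 = np.asarray(c1, dtype=float)
    n = float(bin_totals.sum())
    c0 = bin_totals - c1
    counts = np.stack([c0, c1], axis=-2)  # (..., 2, B)
    p = counts / n
    pr = p.sum(axis=-1, keepdims=True)  # (..., 2, 1)
    pa = bin_totals / n  # (B,)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * (np.log2(p) - np.log2(pr) - np.log2(pa))
    return np.nansum(term, axis=(-2, -1))


def mutual_information(R, A) -> float:
    """Plug-in mutual information (bits) between binary presence and bins.

    MI(R;A) = sum_r sum_a p(r,a) log2[ p(r,a) / (p(r) p(a)) ], with
    0 log 0 := 0.
    """
    R = np.asarray(R).astype(int)
    A = np.asarray(A)
    if R.size == 0:
        raise ValueError("empty input")
    if R.shape != A.shape:
        raise ValueError("R and A lengths differ")
    _, inv = np.unique(A, return_inverse=True)
    bin_totals = np.bincount(inv).astype(float)
    c1 = np.bincount(inv, weights=R, minlength=len(bin_totals))
    return float(_mi_from_counts(c1, bin_totals))


def random_permutations(n, n_shuffle, seed=0, rng=None):
    """A (n_shuffle, n) matrix of independent uniform permutations."""
    rng = rng or np.random.default_rng(seed)
    return rng.permuted(
        np.tile(np.arange(n), (n_shuffle, 1)), axis=1
    )


@dataclass
class RandomizationResult:
    mi: float
    z: float
    p_emp: float
    shuffled_mean: float
    shuffled_sd: float
    reason: str = ""
    shuffled: np.ndarray | None = None


def randomization_z(R, A, n_shuffle=1000, seed=0, perms=None,
                    return_shuffled=False) -> RandomizationResult:
    """Permutation calibration of MI(R;A).

    The bin labels are permuted uniformly ``n_shuffle`` times (preserving
    both marginals);  Z = (MI_obs - mean(MI_shuffled)) / sd(MI_shuffled) and
    p_emp = (1 + #{MI_shuffled >= MI_obs}) / (n_shuffle + 1).  A constant R
    yields an undefined Z, reported as NaN with a reason.
    """
    R = np.asarray(R).astype(int)
    A = np.asarray(A)
    _, inv = np.unique(A, return_inverse=True)
    bin_totals = np.bincount(inv).astype(float)
    onehot = np.zeros((len(R), len(bin_totals)))
    onehot[np.arange(len(R)), inv] = 1.0
    mi_obs = float(_mi_from_counts(R @ onehot, bin_totals))
    if perms is None:
        perms = random_permutations(len(R), n_shuffle, seed=seed)
    shuffled = _mi_from_counts(R[perms] @ onehot, bin_totals)
    mean = float(shuffled.mean())
    sd = float(shuffled.std(ddof=0))
    p_emp = float((1 + np.sum(shuffled >= mi_obs)) / (len(shuffled) + 1))
    keep = shuffled if return_shuffled else None
    if sd == 0:
        return RandomizationResult(mi_obs, np.nan, p_emp, mean, sd,
                                   reason="zero-variance null (constant R)",
                                   shuffled=keep)
    return RandomizationResult(mi_obs, (mi_obs - mean) / sd, p_emp, mean, sd,
                               shuffled=keep)


def per_bin_enrichment(R, A):
    """Per-bin presence frequency and its ratio to the global frequency."""
    R = np.asarray(R).astype(float)
    A = np.asarray(A)
    labels, inv = np.unique(A, return_inverse=True)
    totals = np.bincount(inv).astype(float)
    c1 = np.bincount(inv, weights=R, minlength=len(totals))
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, c1 / totals, np.nan)
    global_freq = R.mean()
    ratio = freq / global_freq if global_freq > 0 else np.full_like(freq, np.nan)
    return pd.DataFrame({"bin": labels, "frequency": freq, "enrichment": ratio})


def classify_trend(per_bin_freq, stable_trend="decreasing"):
    """sRSM/uRSM call from the Spearman trend of frequency across bins.

    With bin 1 the most stable, a frequency that *decreases* toward unstable
    bins marks a stabilizing motif (sRSM) under the default convention; the
    ``stable_trend`` switch flips the orientation.
    """
    freq = np.asarray(per_bin_freq, dtype=float)
    ok = np.isfinite(freq)
    if ok.sum() < 3 or np.nanstd(freq[ok]) == 0:
        return "none", np.nan
    rho, _ = stats.spearmanr(np.arange(1, len(freq) + 1)[ok], freq[ok])
    if not np.isfinite(rho) or rho == 0:
        return "none", rho
    decreasing = rho < 0
    if stable_trend == "decreasing":
        return ("sRSM" if decreasing else "uRSM"), rho
    return ("uRSM" if decreasing else "sRSM"), rho


def select_and_classify(stats_frame: pd.DataFrame,
                        mi_threshold=DEFAULT_MI_THRESHOLD,
                        z_threshold=DEFAULT_Z_THRESHOLD,
                        stable_trend="decreasing") -> pd.DataFrame:
    """Apply the MI and Z gates, then classify passing motifs by trend.

    ``stats_frame`` needs columns ``mi_bits``, ``z`` and a
    ``per_bin_frequency`` column of sequences.
    """
    frame = stats_frame.copy()
    classes, rhos = [], []
    for row in frame.itertuples(index=False):
        passing = (
            np.isfinite(row.z)
            and row.mi_bits > mi_threshold
            and row.z > z_threshold
        )
        if not passing:
            classes.append("none")
            rhos.append(np.nan)
            continue
        cls, rho = classify_trend(row.per_bin_frequency, stable_trend)
        if cls == "none":
            warnings.warn(f"{row.seed_id}: passing motif with flat frequency")
        classes.append(cls)
        rhos.append(rho)
    frame["trend_rho"] = rhos
    frame["class"] = classes
    return frame


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class MotifDiscovery:
    """Stability-motif discovery model over 3' UTRs.

    Parameters
    ----------
    sequences : dict transcript_id -> 3' UTR sequence
    rates : Series transcript_id -> decay rate (per minute)
    shapes : dict transcript_id -> ShapeProfile, optional
        Enables the in-vivo structure filter during matching.
    seeds : list of StructureMotifSeed, or None to enumerate from the grammar
    """

    def __init__(self, sequences, rates, shapes=None, seeds=None,
                 n_bins=DEFAULT_N_BINS, n_seeds=200, seed_rng=0,
                 min_support=10, mi_threshold=DEFAULT_MI_THRESHOLD,
                 z_threshold=DEFAULT_Z_THRESHOLD, stable_trend="decreasing"):
        rates = rates.dropna()
        common = [t for t in rates.index if t in sequences]
        self.bins = bin_transcripts(rates[common], n_bins)
        self.sequences = {t: sequences[t] for t in self.bins.transcripts}
        self.shapes = shapes
        self.seeds = (
            seeds
            if seeds is not None
            else enumerate_seeds(budget=n_seeds, seed=seed_rng)
        )
        self.min_support = min_support
        self.mi_threshold = mi_threshold
        self.z_threshold = z_threshold
        self.stable_trend = stable_trend
        self.matcher = MotifMatcher(self.sequences, shapes)

    def fit(self, n_shuffle=1000, seed=0) -> "MotifDiscoveryResults":
        A = self.bins.bins
        n = len(A)
        perms = random_permutations(n, n_shuffle, seed=seed)
        rows = []
        for s in self.seeds:
            R = self.matcher.presence(s)
            support = int(R.sum())
            enrich = per_bin_enrichment(R, A)
            if support < self.min_support:
                rows.append(
                    {
                        "seed_id": s.seed_id, "left_arm": s.left_arm,
                        "loop": s.loop, "source": s.source,
                        "n_present": support, "mi_bits": np.nan, "z": np.nan,
                        "p_emp": np.nan, "shuffled_mean": np.nan,
                        "shuffled_sd": np.nan,
                        "per_bin_frequency": enrich["frequency"].tolist(),
                        "flag": "low_support",
                    }
                )
                continue
            rz = randomization_z(R, A, n_shuffle=n_shuffle, perms=perms)
            rows.append(
                {
                    "seed_id": s.seed_id, "left_arm": s.left_arm,
                    "loop": s.loop, "source": s.source,
                    "n_present": support, "mi_bits": rz.mi, "z": rz.z,
                    "p_emp": rz.p_emp, "shuffled_mean": rz.shuffled_mean,
                    "shuffled_sd": rz.shuffled_sd,
                    "per_bin_frequency": enrich["frequency"].tolist(),
                    "flag": rz.reason or "ok",
                }
            )
        stats_frame = select_and_classify(
            pd.DataFrame(rows), self.mi_threshold, self.z_threshold,
            self.stable_trend,
        )
        return MotifDiscoveryResults(self, stats_frame)


class MotifDiscoveryResults:
    """Per-seed MI/Z statistics with sRSM/uRSM classification."""

    def __init__(self, model: MotifDiscovery, stats_frame: pd.DataFrame):
        self.model = model
        self.stats = stats_frame

    @property
    def selected(self) -> pd.DataFrame:
        return self.stats[self.stats["class"] != "none"]

    def presence_matrix(self, seeds=None) -> pd.DataFrame:
        """Motif x transcript boolean matrix for downstream enrichment."""
        seeds = seeds or [
            s for s in self.model.seeds
            if s.seed_id in set(self.selected["seed_id"])
        ]
        data = {s.seed_id: self.model.matcher.presence(s) for s in seeds}
        return pd.DataFrame(data, index=self.model.bins.transcripts).T

    def summary(self) -> str:
        scored = self.stats[self.stats["flag"] != "low_support"]
        counts = self.stats["class"].value_counts().to_dict()
        lines = [
            "Motif discovery results",
            "=======================",
            f"transcripts binned:   {len(self.model.bins.transcripts)}"
            f" into {self.model.bins.n_bins} bins",
            f"seeds scored:         {len(scored)} / {len(self.stats)}",
            f"selection:            MI > {self.model.mi_threshold} bits"
            f" and Z > {self.model.z_threshold}",
            f"classes:              sRSM {counts.get('sRSM', 0)},"
            f" uRSM {counts.get('uRSM', 0)}",
        ]
        return "\n".join(lines)

    def write_tsv(self, path):
        frame = self.stats.copy()
        frame["per_bin_frequency"] = frame["per_bin_frequency"].map(
            lambda v: ",".join(f"{x:.6g}" for x in v)
        )
        frame.to_csv(path, sep="\t", index=False, na_rep="NA")

    def plot_enrichment_heatmap(self, ax=None, which="sRSM", top=10):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sel = self.stats[self.stats["class"] == which].nlargest(top, "z")
        mat = np.array([row for row in sel["per_bin_frequency"]])
        if mat.size:
            mat = mat / mat.mean(axis=1, keepdims=True)
            im = ax.imshow(mat, aspect="auto", cmap="RdBu_r")
            plt.colorbar(im, ax=ax, label="enrichment")
            ax.set_yticks(range(len(sel)), sel["seed_id"])
        ax.set_xlabel("stability bin (1 = most stable)")
        return ax
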