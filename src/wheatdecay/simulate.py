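"""Synthetic data with controlled ground truth for every pipeline input.

The generator emulates the statistical structure of a cordycepin
transcription-arrest experiment in an allotetraploid transcriptome:

* per-gene exponential decay with a wide log-normal half-life distribution
  (median 6 h, log-sd 1.0, clipped to [2 min, 48 h]);
* negative-binomial count noise (default dispersion 0.05) on top of
  per-time-point library-depth drift (a +/-20% log-scale random walk), which
  the decay-factor normalization must undo;
* a set of highly expressed, truly stable reference ("decay factor") genes;
* 3' UTRs with planted stem-loop occurrences whose frequency varies across
  stability bins, and SHAPE profiles low on paired / high on unpaired
  positions (Beta(1,9) vs Beta(3,2));
* CDS sets whose usage of a designated codon tracks half-life linearly;
* homoeolog pairs with controlled decay/abundance log-fold-change structure;
* tri-population allele counts with controlled differentiation.

Every generator is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ShapeProfile, SNVRecord
from .motifs import IUPAC, StructureMotifSeed
from .timecourse import DEFAULT_TIMES, TimeCourseTable

LN2 = float(np.log(2.0))

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the synthetic study.

    Defaults reproduce the study conditions the pipeline targets: the
    0/15/30/60/120/240/480-minute grid with three replicates, a log-normal
    half-life distribution with median 6 h and log-sd 1.0 clipped to
    [2 min, 48 h], negative-binomial dispersion 0.05 and a +/-20%
    library-depth random walk.
    """

    n_genes: int = 2000
    times: tuple = DEFAULT_TIMES
    replicates: int = 3
    seed: int = 0
    # half-life distribution (minutes)
    half_life_median_min: float = 360.0
    half_life_log_sd: float = 1.0
    half_life_clip_min: tuple = (2.0, 48.0 * 60.0)
    # abundance and noise
    t0_rpm_median: float = 50.0
    t0_rpm_log_sd: float = 1.0
    dispersion: float = 0.05  # negative-binomial; 0 = noiseless
    library_size: float = 5e6
    depth_drift_sd: float = 0.2  # log-scale random-walk step; 0 = no drift
    n_stable_reference: int = 30
    # 3' UTR / motif planting
    n_utrs: int = 1500
    utr_length: int = 120
    motif_seed: StructureMotifSeed | None = None
    motif_bin_frequencies: tuple | None = None  # one frequency per bin
    n_bins: int = 15
    shape_paired_beta: tuple = (1.0, 9.0)
    shape_unpaired_beta: tuple = (3.0, 2.0)
    # CDS codon bias
    n_cds: int = 500
    cds_codons: int = 200
    designated_codon: str = "GCU"
    codon_slope: float = 0.05
    codon_base_freq: float = 0.1
    # homoeolog pairs
    n_pairs: int = 1000
    pair_rate_fold_change: float | None = 2.0
    pair_delta_correlation: float = 0.33
    pair_delta_decay_sd: float = 0.5  # log2
    pair_delta_abundance_sd: float = 1.0  # log2
    # populations
    populations: dict = field(
        default_factory=lambda: {"WEW": 60, "DEW": 60, "DW": 60}
    )
    n_snvs: int = 200
    perturbing_fraction: float = 0.5
    differentiation_perturbing: float = 0.30
    differentiation_background: float = 0.05

    def __post_init__(self):
        if self.n_genes < 1 or self.replicates < 1:
            raise ValueError("counts must be positive")
        if self.times[0] != 0:
            raise ValueError("time grid must include 0")
        if self.motif_bin_frequencies is not None and not all(
            0 <= f <= 1 for f in self.motif_bin_frequencies
        ):
            raise ValueError("motif frequencies must be in [0, 1]")


def _draw_rates(rng, n, config):
    hl = np.exp(
        rng.normal(np.log(config.half_life_median_min), config.half_life_log_sd, n)
    )
    hl = np.clip(hl, *config.half_life_clip_min)
    return LN2 / hl  # per minute


def _nb_sample(rng, mean, dispersion):
    if dispersion == 0:
        return mean
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(float)


def generate_decay_counts(config: SimulationConfig):
    """Time-course abundances with known decay rates.

    Returns ``(table, truth)`` where ``truth`` has per-gene columns
    ``alpha_per_min``, ``half_life_min``, ``t0_rpm`` and
    ``is_stable_reference``.  Expected abundance is
    A_g exp(-alpha_g t) d_(t,r) with d the depth-drift multiplier; counts are
    negative-binomial unless ``dispersion == 0`` (then exact).
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times, dtype=float)
    n, n_ref = config.n_genes, config.n_stable_reference
    if n_ref >= n:
        raise ValueError("n_stable_reference must be < n_genes")

    alpha = _draw_rates(rng, n, config)
    a0 = np.exp(rng.normal(np.log(config.t0_rpm_median), config.t0_rpm_log_sd, n))
    is_ref = np.zeros(n, dtype=bool)
    is_ref[:n_ref] = True
    alpha[is_ref] = 0.0
    a0[is_ref] = np.exp(
        rng.normal(np.log(config.t0_rpm_median * 20), 0.3, n_ref)
    )  # decay factors: highly expressed and stable

    # depth drift: per-replicate log-scale random walk anchored at t0
    drift = np.ones((len(times), config.replicates))
    if config.depth_drift_sd > 0:
        steps = rng.normal(0.0, config.depth_drift_sd,
                           (len(times) - 1, config.replicates))
        drift[1:] = np.exp(np.cumsum(steps, axis=0))

    expected_rpm = (
        a0[:, None, None]
        * np.exp(-alpha[:, None] * times[None, :])[:, :, None]
        * drift[None, :, :]
    )
    if config.dispersion == 0:
        rpm = expected_rpm
        library_sizes = np.full(drift.shape, config.library_size)
    else:
        mean_counts = expected_rpm * (config.library_size / 1e6)
        counts = _nb_sample(rng, mean_counts, config.dispersion)
        rpm = counts / config.library_size * 1e6
        library_sizes = np.full(drift.shape, config.library_size)

    genes = [f"gene{i + 1:05d}" for i in range(n)]
    table = TimeCourseTable(genes, times, rpm, library_sizes)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "alpha_per_min": alpha,
            "half_life_min": np.where(alpha > 0, LN2 / np.where(alpha > 0, alpha, 1),
                                      np.inf),
            "t0_rpm": a0,
            "is_stable_reference": is_ref,
        }
    )
    return table, truth


def _realize_iupac(rng, pattern):
    return "".join(rng.choice(list(IUPAC[c])) for c in pattern)


def _reverse_complement(seq):
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def generate_utr_with_motifs(config: SimulationConfig):
    """3' UTRs with a stem-loop planted at bin-dependent frequency.

    Returns ``(sequences, shapes, rates, truth)``.  Background sequence is
    i.i.d. uniform ACGU; in stability bin b a fraction f_b of transcripts
    receives one embedded instance (concrete left arm + loop realization and
    the reverse-complement right arm).  SHAPE reactivities are drawn
    Beta(1,9) on embedded stem positions and Beta(3,2) elsewhere.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_utrs
    seed_motif = config.motif_seed
    freqs = config.motif_bin_frequencies
    if seed_motif is not None:
        if freqs is None:
            raise ValueError("motif_bin_frequencies required with motif_seed")
        if len(freqs) != config.n_bins:
            raise ValueError("need one plant frequency per bin")
        if seed_motif.width > config.utr_length:
            raise ValueError("embedded instance longer than UTR")

    rates = np.sort(_draw_rates(rng, n, config))
    ids = [f"utr{i + 1:05d}" for i in range(n)]
    # transcripts are rate-sorted, so equal splits give the stability bins
    sizes = [n // config.n_bins + (1 if i < n % config.n_bins else 0)
             for i in range(config.n_bins)]
    bins = np.repeat(np.arange(1, config.n_bins + 1), sizes)

    a_un, b_un = config.shape_unpaired_beta
    a_p, b_p = config.shape_paired_beta
    sequences, shapes, rows = {}, {}, []
    for i, tid in enumerate(ids):
        seq = list(rng.choice(list("ACGU"), size=config.utr_length))
        react = rng.beta(a_un, b_un, size=config.utr_length)
        planted = False
        offset = -1
        if seed_motif is not None and rng.random() < freqs[bins[i] - 1]:
            left = _realize_iupac(rng, seed_motif.left_arm)
            loop = _realize_iupac(rng, seed_motif.loop)
            instance = left + loop + _reverse_complement(left)
            offset = int(rng.integers(0, config.utr_length - len(instance) + 1))
            seq[offset : offset + len(instance)] = list(instance)
            s = seed_motif.stem_length
            stem_pos = list(range(offset, offset + s)) + list(
                range(offset + len(instance) - s, offset + len(instance))
            )
            react[stem_pos] = rng.beta(a_p, b_p, size=2 * s)
            planted = True
        sequences[tid] = "".join(seq)
        shapes[tid] = ShapeProfile(tid, react)
        rows.append({"transcript": tid, "bin": int(bins[i]),
                     "alpha_per_min": rates[i], "has_motif": planted,
                     "offset": offset + 1 if planted else 0})
    truth = pd.DataFrame(rows)
    return sequences, shapes, pd.Series(rates, index=ids), truth


def generate_cds_codon_bias(config: SimulationConfig):
    """CDS set whose designated-codon frequency is linear in half-life.

    Returns ``(cds_sequences, half_lives_h, truth)``.  The designated codon's
    target frequency is ``base + slope * z`` where z is the standardized log
    half-life; remaining positions are uniform over the other sense codons.
    """
    from .seqfeat import SENSE_CODONS

    rng = np.random.default_rng(config.seed)
    n = config.n_cds
    alpha = _draw_rates(rng, n, config)
    hl_h = LN2 / alpha / 60.0
    z = (np.log(hl_h) - np.mean(np.log(hl_h))) / np.std(np.log(hl_h))
    target = np.clip(config.codon_base_freq + config.codon_slope * z, 0.005, 0.6)

    others = [c for c in SENSE_CODONS if c != config.designated_codon]
    cds = {}
    ids = [f"cds{i + 1:05d}" for i in range(n)]
    for i, gid in enumerate(ids):
        use = rng.random(config.cds_codons) < target[i]
        codons = np.where(
            use,
            config.designated_codon,
            rng.choice(others, size=config.cds_codons),
        )
        cds[gid] = "".join(codons)
    truth = pd.DataFrame(
        {"gene": ids, "half_life_h": hl_h, "target_frequency": target}
    )
    return cds, pd.Series(hl_h, index=ids), truth


def generate_homoeolog_pairs(config: SimulationConfig):
    """Paired A/B time courses with controlled decay and abundance deltas.

    Returns ``(table, pairs, truth)``.  With ``pair_rate_fold_change`` set,
    each pair's B-copy rate is the A-copy rate times the fold change, the
    direction (which copy is faster) alternating deterministically;
    otherwise (``None``) the pair's log2 rate and abundance deltas are drawn
    from a bivariate normal with correlation ``pair_delta_correlation``.
    The emitted table includes the stable reference genes required by the
    decay-factor normalization.
    """
    fc = config.pair_rate_fold_change
    if fc is not None and fc <= 0:
        raise ValueError("fold change must be positive")
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    alpha_a = _draw_rates(rng, n, config)
    ab_a = np.exp(rng.normal(np.log(config.t0_rpm_median),
                             config.t0_rpm_log_sd, n))
    if fc is not None:
        direction = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        delta_decay = direction * np.log2(fc)
        delta_abundance = -delta_decay  # faster copy is less abundant
    else:
        rho = config.pair_delta_correlation
        cov = np.array(
            [
                [config.pair_delta_decay_sd ** 2,
                 rho * config.pair_delta_decay_sd * config.pair_delta_abundance_sd],
                [rho * config.pair_delta_decay_sd * config.pair_delta_abundance_sd,
                 config.pair_delta_abundance_sd ** 2],
            ]
        )
        deltas = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        delta_decay, delta_abundance = deltas[:, 0], deltas[:, 1]
    alpha_b = alpha_a / 2.0 ** delta_decay
    lo, hi = LN2 / config.half_life_clip_min[1], LN2 / config.half_life_clip_min[0]
    alpha_b = np.clip(alpha_b, lo, hi)
    ab_b = ab_a / 2.0 ** delta_abundance

    genes_a = [f"geneA{i + 1:05d}" for i in range(n)]
    genes_b = [f"geneB{i + 1:05d}" for i in range(n)]
    n_ref = config.n_stable_reference
    ref_genes = [f"ref{i + 1:03d}" for i in range(n_ref)]
    ref_a0 = np.exp(rng.normal(np.log(config.t0_rpm_median * 20), 0.3, n_ref))

    times = np.asarray(config.times, dtype=float)
    # the drift is shared by every gene so the factor normalization can undo it
    drift = np.ones((len(times), config.replicates))
    if config.depth_drift_sd > 0:
        steps = rng.normal(0.0, config.depth_drift_sd,
                           (len(times) - 1, config.replicates))
        drift[1:] = np.exp(np.cumsum(steps, axis=0))

    def make_rpm(a0, alpha):
        expected = (
            a0[:, None, None]
            * np.exp(-alpha[:, None] * times[None, :])[:, :, None]
            * drift[None, :, :]
        )
        if config.dispersion == 0:
            return expected
        counts = _nb_sample(rng, expected * (config.library_size / 1e6),
                            config.dispersion)
        return counts / config.library_size * 1e6

    rpm = np.concatenate(
        [
            make_rpm(ab_a, alpha_a),
            make_rpm(ab_b, alpha_b),
            make_rpm(ref_a0, np.zeros(n_ref)),
        ]
    )
    library_sizes = np.full(drift.shape, config.library_size)
    table = TimeCourseTable(
        genes_a + genes_b + ref_genes, times, rpm, library_sizes
    )
    pairs = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
    truth = pd.DataFrame(
        {
            "gene_a": genes_a, "gene_b": genes_b,
            "alpha_a": alpha_a, "alpha_b": alpha_b,
            "abundance_a": ab_a, "abundance_b": ab_b,
            "delta_decay_log2": np.log2(alpha_a / alpha_b),
            "delta_abundance_log2": np.log2(ab_a / ab_b),
        }
    )
    return table, pairs, truth


def generate_population_snvs(config: SimulationConfig):
    """SNV records with binomial allele counts in each population.

    Half of the loci (``perturbing_fraction``) get strongly differentiated
    per-population frequencies, the rest weakly differentiated; the truth
    column ``is_perturbing`` marks the planted stratum.
    """
    rng = np.random.default_rng(config.seed)
    pops = dict(config.populations)
    records, rows = [], []
    for i in range(config.n_snvs):
        perturbing = i < int(config.n_snvs * config.perturbing_fraction)
        spread = (config.differentiation_perturbing if perturbing
                  else config.differentiation_background)
        base = rng.uniform(0.2, 0.8)
        populations = {}
        for pop, n_alleles in pops.items():
            p = float(np.clip(base + rng.normal(0.0, spread), 0.0, 1.0))
            ac = int(rng.binomial(n_alleles, p))
            populations[pop] = (ac, n_alleles)
        ref, alt = rng.choice(list("ACGU"), size=2, replace=False)
        rec = SNVRecord(
            locus_id=f"snv{i + 1:04d}",
            transcript_id=f"utr{i + 1:05d}",
            position=int(rng.integers(1, config.utr_length + 1)),
            ref_allele=str(ref), alt_allele=str(alt),
            populations=populations,
        )
        records.append(rec)
        rows.append({"locus_id": rec.locus_id, "is_perturbing": perturbing})
    return records, pd.DataFrame(rows)


def write_dataset(config: SimulationConfig, outdir):
    """Emit a self-contained dataset directory with ground-truth tables.

    Writes counts.tsv, utrs.fasta, shape/<id>.tsv, pairs.tsv, snvs.tsv,
    transcripts.gff3 + transcripts.fasta (single-exon gene models carrying
    the generated UTRs), the truth tables, and a config echo.
    """
    import yaml

    from .io import write_pairs, write_shape, write_snv_table

    from pathlib import Path

    out = Path(outdir)
    (out / "shape").mkdir(parents=True, exist_ok=True)

    table, decay_truth = generate_decay_counts(config)
    table.write_tsv(out / "counts.tsv")
    decay_truth.to_csv(out / "truth_decay.tsv", sep="\t", index=False)

    sequences, shapes, rates, utr_truth = generate_utr_with_motifs(config)
    with open(out / "utrs.fasta", "w") as fh:
        for tid, seq in sequences.items():
            fh.write(f">{tid}\n{seq}\n")
    for tid, prof in shapes.items():
        write_shape(prof, out / "shape" / f"{tid}.tsv")
    utr_truth.to_csv(out / "truth_utrs.tsv", sep="\t", index=False)
    # fitted-rate-style table for the UTR set (feeds motif discovery)
    utr_truth.rename(
        columns={"transcript": "gene"}
    )[["gene", "alpha_per_min"]].to_csv(
        out / "utr_rates.tsv", sep="\t", index=False, float_format="%.17g"
    )

    cds, _, cds_truth = generate_cds_codon_bias(config)
    cds_truth.to_csv(out / "truth_cds.tsv", sep="\t", index=False)

    # single-exon gene models: 5' UTR + CDS + generated 3' UTR
    rng = np.random.default_rng(config.seed + 7)
    cds_list = list(cds.items())
    with open(out / "transcripts.gff3", "w") as gff, open(
        out / "transcripts.fasta", "w"
    ) as fa:
        gff.write("##gff-version 3\n")
        pos = 1
        for i, (tid, utr3) in enumerate(list(sequences.items())[: len(cds_list)]):
            utr5 = "".join(rng.choice(list("ACGU"), size=60))
            body = "AUG" + cds_list[i][1] + "UAA"
            full = utr5 + body + utr3
            chrom = "1A" if i % 2 == 0 else "1B"
            gid, mid = tid, f"{tid}.1"
            start, end = pos, pos + len(full) - 1
            cds_lo = start + len(utr5)
            cds_hi = cds_lo + len(body) - 1
            gff.write(f"{chrom}\t.\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n")
            gff.write(
                f"{chrom}\t.\tmRNA\t{start}\t{end}\t.\t+\t.\tID={mid};Parent={gid}\n"
            )
            gff.write(
                f"{chrom}\t.\texon\t{start}\t{end}\t.\t+\t.\t"
                f"ID=e_{tid};Parent={mid}\n"
            )
            gff.write(
                f"{chrom}\t.\tCDS\t{cds_lo}\t{cds_hi}\t.\t+\t0\t"
                f"ID=c_{tid};Parent={mid}\n"
            )
            fa.write(f">{mid}\n{full}\n")
            pos = end + 100

    pair_table, pairs, pair_truth = generate_homoeolog_pairs(config)
    pair_table.write_tsv(out / "pair_counts.tsv")
    write_pairs(pairs, out / "pairs.tsv")
    pair_truth.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)

    snvs, snv_truth = generate_population_snvs(config)
    write_snv_table(snvs, out / "snvs.tsv")
    snv_truth.to_csv(out / "truth_snvs.tsv", sep="\t", index=False)

    def plain(value):
        if isinstance(value, dict):
            return {k: plain(v) for k, v in value.items()}
        if isinstance(value, (list, tuple)):
            return [plain(v) for v in value]
        if isinstance(value, (np.floating, float)):
            return float(value)
        if isinstance(value, (np.integer, int, np.bool_, bool)):
            return int(value)
        return value

    echo = asdict(config)
    echo["motif_seed"] = (
        None if config.motif_seed is None
        else {"left_arm": config.motif_seed.left_arm,
              "loop": config.motif_seed.loop}
    )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(plain(echo), fh)
    return out
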