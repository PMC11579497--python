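"""Readers/writers for the pipeline's tabular formats.

Dialects (all tab-separated, with header):

* SHAPE:   ``position<TAB>reactivity`` — one file per transcript, 1-based
  positions; missing reactivities as ``NA`` or ``-999``.
* BPP:     ``i<TAB>j<TAB>p`` base-pairing probabilities with ``1 <= i < j``.
* pairs:   ``gene_a<TAB>gene_b`` homoeolog pairs (A- then B-subgenome copy).
* SNV:     ``locus_id  transcript_id  position  ref  alt  <POP>_ac  <POP>_an ...``
  with one allele-count (ac) / allele-number (an) column pair per population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NA_TOKENS = ("NA", "-999", "-999.0")


@dataclass
class ShapeProfile:
    """Per-nucleotide SHAPE reactivity; high values mean single-stranded."""

    transcript_id: str
    reactivity: np.ndarray  # float array, NaN for missing

    def __post_init__(self):
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        finite = self.reactivity[np.isfinite(self.reactivity)]
        if np.any(finite < 0):
            raise ValueError(f"{self.transcript_id}: negative SHAPE reactivity")

    def __len__(self):
        return len(self.reactivity)


@dataclass
class BppTable:
    """Base-pairing probabilities p(i, j) from a partition-function folder."""

    transcript_id: str
    length: int
    pairs: list = field(default_factory=list)  # (i, j, p) with 1 <= i < j <= length

    def __post_init__(self, tolerance=1e-3):
        per_nt = np.zeros(self.length + 1)
        for i, j, p in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"{self.transcript_id}: bad pair indices ({i}, {j})")
            if not (0 < p <= 1):
                raise ValueError(f"{self.transcript_id}: probability {p} out of (0, 1]")
            per_nt[i] += p
            per_nt[j] += p
        if np.any(per_nt > 1 + tolerance):
            bad = int(np.argmax(per_nt))
            raise ValueError(
                f"{self.transcript_id}: total pairing probability "
                f"{per_nt[bad]:.3f} > 1 at position {bad}"
            )


@dataclass
class SNVRecord:
    """A single-nucleotide variant with per-population allele counts."""

    locus_id: str
    transcript_id: str
    position: int  # 1-based transcript coordinate
    ref_allele: str
    alt_allele: str
    populations: dict = field(default_factory=dict)  # pop -> (alt count, total)
    fst: float = np.nan
    motif_context: tuple | None = None  # (seed_id, offset, role)
    perturbs_structure: bool = False

    def allele_frequency(self, pop):
        ac, an = self.populations[pop]
        return ac / an if an else np.nan


def _read_tsv(path, expected_cols):
    frame = pd.read_csv(path, sep="\t", na_values=list(NA_TOKENS),
                        keep_default_na=False, float_precision="round_trip")
    missing = [c for c in expected_cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return frame


def read_shape(path, transcript_id=None, length=None) -> ShapeProfile:
    path = Path(path)
    frame = _read_tsv(path, ["position", "reactivity"])
    positions = frame["position"].to_numpy(dtype=int)
    if len(positions) and positions.min() < 1:
        raise ValueError(f"{path}: positions must be 1-based")
    if len(np.unique(positions)) != len(positions):
        raise ValueError(f"{path}: duplicate positions")
    n = length or (positions.max() if len(positions) else 0)
    react = np.full(n, np.nan)
    react[positions - 1] = frame["reactivity"].to_numpy(dtype=float)
    return ShapeProfile(transcript_id or path.stem, react)


def write_shape(profile: ShapeProfile, path):
    frame = pd.DataFrame(
        {
            "position": np.arange(1, len(profile) + 1),
            "reactivity": profile.reactivity,
        }
    )
    frame.to_csv(path, sep="\t", index=False, na_rep="NA",
                 float_format="%.17g")


def read_bpp(path, transcript_id=None, length=None) -> BppTable:
    path = Path(path)
    frame = _read_tsv(path, ["i", "j", "p"])
    pairs = [
        (int(i), int(j), float(p))
        for i, j, p in zip(frame["i"], frame["j"], frame["p"])
    ]
    n = length or max((j for _, j, _ in pairs), default=0)
    return BppTable(transcript_id or path.stem, n, pairs)


def write_bpp(table: BppTable, path):
    pd.DataFrame(table.pairs, columns=["i", "j", "p"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_pairs(path) -> pd.DataFrame:
    frame = _read_tsv(path, ["gene_a", "gene_b"])
    if frame["gene_a"].duplicated().any() or frame["gene_b"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene in homoeolog pair table")
    return frame[["gene_a", "gene_b"]]


def write_pairs(frame: pd.DataFrame, path):
    frame[["gene_a", "gene_b"]].to_csv(path, sep="\t", index=False)


def read_snv_table(path) -> list[SNVRecord]:
    frame = _read_tsv(path, ["locus_id", "transcript_id", "position", "ref", "alt"])
    pops = sorted(
        {c[:-3] for c in frame.columns if c.endswith("_ac")}
        & {c[:-3] for c in frame.columns if c.endswith("_an")}
    )
    if frame["locus_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate locus_id")
    records = []
    for row in frame.itertuples(index=False):
        populations = {
            p: (int(getattr(row, f"{p}_ac")), int(getattr(row, f"{p}_an")))
            for p in pops
        }
        records.append(
            SNVRecord(
                locus_id=str(row.locus_id),
                transcript_id=str(row.transcript_id),
                position=int(row.position),
                ref_allele=str(row.ref).upper().replace("T", "U"),
                alt_allele=str(row.alt).upper().replace("T", "U"),
                populations=populations,
            )
        )
    return records


def write_snv_table(records, path):
    pops = sorted({p for r in records for p in r.populations})
    rows = []
    for r in records:
        row = {
            "locus_id": r.locus_id,
            "transcript_id": r.transcript_id,
            "position": r.position,
            "ref": r.ref_allele,
            "alt": r.alt_allele,
        }
        for p in pops:
            ac, an = r.populations.get(p, (np.nan, np.nan))
            row[f"{p}_ac"] = ac
            row[f"{p}_an"] = an
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_snv_vcf(path, populations=("WEW", "DEW", "DW")) -> list[SNVRecord]:
    """Read SNVs from a VCF 4.2 file with AC_<POP>/AN_<POP> INFO fields.

    CHROM is interpreted as the transcript id and POS as the 1-based
    transcript position.
    """
    from cyvcf2 import VCF

    records = []
    for i, variant in enumerate(VCF(str(path))):
        pops = {}
        for p in populations:
            ac = variant.INFO.get(f"AC_{p}")
            an = variant.INFO.get(f"AN_{p}")
            if ac is None or an is None:
                continue
            pops[p] = (int(ac), int(an))
        records.append(
            SNVRecord(
                locus_id=variant.ID or f"snv{i + 1}",
                transcript_id=variant.CHROM,
                position=variant.POS,
                ref_allele=variant.REF.upper().replace("T", "U"),
                alt_allele=variant.ALT[0].upper().replace("T", "U"),
                populations=pops,
            )
        )
    return records


def read_te_table(path) -> pd.Series:
    """Translation-efficiency values consumed as an external input table."""
    frame = _read_tsv(path, ["gene", "te"])
    return frame.set_index("gene")["te"].astype(float)
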