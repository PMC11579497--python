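"""Transcript annotation from GFF3 + FASTA.

Coordinates are 1-based inclusive throughout (GFF3 convention); transcript
coordinates run 5'->3' on the sense strand.  One representative transcript is
kept per gene (the longest annotated mRNA): the downstream analyses operate at
the gene level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

REGION_NAMES = ("five_utr", "cds", "three_utr")


@dataclass
class TranscriptAnnotation:
    """One gene's representative transcript with its region structure.

    ``regions`` maps region name (``five_utr``/``cds``/``three_utr``) to a
    list of ``(start, end)`` intervals in 1-based inclusive transcript
    coordinates, ordered 5'->3'.  ``intron_count`` equals the number of exons
    minus one.
    """

    gene_id: str
    transcript_id: str
    subgenome: str = "unknown"  # 'A', 'B' or 'unknown'
    regions: dict = field(default_factory=dict)
    intron_count: int = 0
    flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.intron_count < 0:
            raise ValueError("intron_count must be non-negative")
        if self.intron_count == 0:
            self.flags.add("intronless")
        for name, ivals in self.regions.items():
            last_end = 0
            for start, end in ivals:
                if start < 1 or end < start:
                    raise ValueError(f"bad interval ({start}, {end}) in {name}")
                if start <= last_end:
                    raise ValueError(f"overlapping/unordered intervals in {name}")
                last_end = end

    @property
    def intronless(self) -> bool:
        return self.intron_count == 0

    def region_length(self, name: str) -> int:
        return sum(end - start + 1 for start, end in self.regions.get(name, []))

    @property
    def transcript_length(self) -> int:
        return sum(self.region_length(n) for n in REGION_NAMES)

    def region_positions(self, name: str) -> list[int]:
        """All transcript positions (1-based) belonging to a region."""
        out = []
        for start, end in self.regions.get(name, []):
            out.extend(range(start, end + 1))
        return out

    def region_sequence(self, sequence: str, name: str) -> str:
        return "".join(
            sequence[start - 1 : end] for start, end in self.regions.get(name, [])
        )

    def region_of(self, position: int) -> str | None:
        """Region name containing a 1-based transcript position, or None."""
        for name in REGION_NAMES:
            for start, end in self.regions.get(name, []):
                if start <= position <= end:
                    return name
        return None


def infer_subgenome(seqid: str) -> str:
    """Infer the subgenome from a chromosome name such as ``1A`` or ``chr3B``."""
    tag = seqid.rstrip("0123456789")  # tolerate e.g. '4A1' style suffixes
    for cand in (seqid, tag):
        if cand and cand[-1] in "AB":
            return cand[-1]
    return "unknown"


def _genomic_to_transcript(exons, strand):
    """Return a function mapping genomic position -> 1-based transcript position."""
    ordered = sorted(exons, key=lambda e: e[0], reverse=(strand == "-"))
    offsets = []
    acc = 0
    for start, end in ordered:
        offsets.append((start, end, acc))
        acc += end - start + 1

    def convert(pos):
        for start, end, off in offsets:
            if start <= pos <= end:
                if strand == "-":
                    return off + (end - pos) + 1
                return off + (pos - start) + 1
        raise ValueError(f"genomic position {pos} not exonic")

    return convert, acc


def read_annotation(gff3_path, fasta_path, keep_all_transcripts=False):
    """Read a GFF3 + transcript FASTA into :class:`TranscriptAnnotation` records.

    Returns ``(annotations, sequences)`` where ``sequences`` maps
    transcript_id -> RNA sequence (T converted to U).  The longest mRNA is
    selected per gene unless ``keep_all_transcripts``.  Transcripts whose
    FASTA sequence length disagrees with the summed exon length are rejected
    with a warning; CDS features without a parent mRNA raise a record-level
    error.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    sequences = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sequences[rec.id] = str(rec.seq).upper().replace("T", "U")

    # orphan CDS check: every CDS must hang off an mRNA
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds, featuretype="mRNA"))
        if not parents:
            raise ValueError(f"CDS feature {cds.id} has no parent mRNA")

    annotations = []
    kept_sequences = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue

        def mrna_len(m):
            return sum(e.end - e.start + 1 for e in db.children(m, featuretype="exon"))

        if not keep_all_transcripts:
            mrnas = [max(mrnas, key=lambda m: (mrna_len(m), m.id))]
        for mrna in mrnas:
            exons = [(e.start, e.end) for e in db.children(mrna, featuretype="exon")]
            if not exons:
                exons = [(mrna.start, mrna.end)]
            convert, tlen = _genomic_to_transcript(exons, mrna.strand)
            tid = mrna.id
            seq = sequences.get(tid)
            if seq is not None and len(seq) != tlen:
                warnings.warn(
                    f"{tid}: FASTA length {len(seq)} != exonic length {tlen}; "
                    "transcript rejected"
                )
                continue
            cds_feats = [(c.start, c.end) for c in db.children(mrna, featuretype="CDS")]
            regions = {}
            if cds_feats:
                tpos = sorted(
                    p
                    for start, end in cds_feats
                    for p in (convert(start), convert(end))
                )
                cds_lo, cds_hi = tpos[0], tpos[-1]
                if cds_lo > 1:
                    regions["five_utr"] = [(1, cds_lo - 1)]
                regions["cds"] = [(cds_lo, cds_hi)]
                if cds_hi < tlen:
                    regions["three_utr"] = [(cds_hi + 1, tlen)]
            else:
                regions["cds"] = [(1, tlen)]
            ann = TranscriptAnnotation(
                gene_id=gene.id,
                transcript_id=tid,
                subgenome=infer_subgenome(mrna.seqid),
                regions=regions,
                intron_count=len(exons) - 1,
            )
            annotations.append(ann)
            if seq is not None:
                kept_sequences[tid] = seq
    return annotations, kept_sequences


def apply_flags(annotations, mirna_targets=()):
    """Set the ``mirna_target`` flag from an externally supplied gene list."""
    targets = set(mirna_targets)
    for ann in annotations:
        if ann.gene_id in targets or ann.transcript_id in targets:
            ann.flags.add("mirna_target")
    return annotations
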