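import numpy as np
import pytest

from wheatdecay.timecourse import DEFAULT_TIMES, TimeCourseTable


@pytest.fixture
def times():
    return np.asarray(DEFAULT_TIMES, dtype=float)


@pytest.fixture
def make_table():
    """Factory for small noiseless time-course tables from decay rates."""

    def _make(alphas, t0=None, times=DEFAULT_TIMES, replicates=3, drift=None):
        alphas = np.asarray(alphas, dtype=float)
        t = np.asarray(times, dtype=float)
        t0 = np.full(len(alphas), 100.0) if t0 is None else np.asarray(t0, float)
        d = np.ones((len(t), replicates)) if drift is None else np.asarray(drift)
        abundance = (
            t0[:, None, None]
            * np.exp(-alphas[:, None] * t[None, :])[:, :, None]
            * d[None, :, :]
        )
        genes = [f"g{i + 1}" for i in range(len(alphas))]
        return TimeCourseTable(genes, t, abundance)

    return _make


@pytest.fixture
def toy_gff3(tmp_path):
    """A small GFF3 + matching FASTA covering UTR inference and introns."""
    gff = """##gff-version 3
1A\t.\tgene\t1\t300\t.\t+\t.\tID=gene1
1A\t.\tmRNA\t1\t300\t.\t+\t.\tID=mrna1;Parent=gene1
1A\t.\texon\t1\t300\t.\t+\t.\tID=exon1;Parent=mrna1
1A\t.\tCDS\t61\t240\t.\t+\t0\tID=cds1;Parent=mrna1
1B\t.\tgene\t400\t800\t.\t-\t.\tID=gene2
1B\t.\tmRNA\t400\t800\t.\t-\t.\tID=mrna2;Parent=gene2
1B\t.\texon\t400\t500\t.\t-\t.\tID=e2a;Parent=mrna2
1B\t.\texon\t600\t700\t.\t-\t.\tID=e2b;Parent=mrna2
1B\t.\texon\t750\t800\t.\t-\t.\tID=e2c;Parent=mrna2
1B\t.\tCDS\t450\t500\t.\t-\t0\tID=c2a;Parent=mrna2
1B\t.\tCDS\t600\t650\t.\t-\t0\tID=c2b;Parent=mrna2
"""
    gff_path = tmp_path / "toy.gff3"
    gff_path.write_text(gff)
    rng = np.random.default_rng(0)
    seq1 = "".join(rng.choice(list("ACGU"), 300))
    seq2 = "".join(rng.choice(list("ACGU"), 253))
    fasta_path = tmp_path / "toy.fasta"
    fasta_path.write_text(f">mrna1\n{seq1}\n>mrna2\n{seq2}\n")
    return gff_path, fasta_path
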