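"""Gene x time x replicate abundance tables from transcription-arrest time courses."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

DEFAULT_TIMES = (0, 15, 30, 60, 120, 240, 480)

_SAMPLE_RE = re.compile(r"^t(\d+)_rep(\d+)$")


class TimeCourseTable:
    """Abundance (RPM) for each gene at each time point and replicate.

    Parameters
    ----------
    genes : sequence of str
    times : sequence of int
        Minutes after transcriptional arrest; strictly increasing, must
        include 0.
    abundance : ndarray, shape (n_genes, n_times, n_replicates)
        Non-negative RPM values.
    library_sizes : ndarray, shape (n_times, n_replicates), optional
        Mapped-read totals per sequencing library.
    """

    def __init__(self, genes, times, abundance, library_sizes=None):
        self.genes = list(genes)
        self.times = np.asarray(times, dtype=float)
        self.abundance = np.asarray(abundance, dtype=float)
        if self.abundance.ndim != 3:
            raise ValueError("abundance must be gene x time x replicate")
        if self.abundance.shape[0] != len(self.genes):
            raise ValueError("gene dimension mismatch")
        if self.abundance.shape[1] != len(self.times):
            raise ValueError("time dimension mismatch")
        if np.any(self.abundance < 0):
            raise ValueError("abundance must be non-negative")
        if self.times[0] != 0:
            raise ValueError("time grid must include 0 as first point")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.library_sizes = (
            None if library_sizes is None else np.asarray(library_sizes, dtype=float)
        )
        if self.library_sizes is not None and self.library_sizes.shape != (
            len(self.times),
            self.n_replicates,
        ):
            raise ValueError("library_sizes must be time x replicate")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self):
        return len(self.genes)

    @property
    def n_replicates(self):
        return self.abundance.shape[2]

    def gene_profile(self, gene):
        """time x replicate abundance for one gene."""
        return self.abundance[self._index[gene]]

    def t0_abundance(self):
        """Mean RPM at t=0 per gene (steady-state abundance proxy)."""
        return pd.Series(self.abundance[:, 0, :].mean(axis=1), index=self.genes)

    def subset(self, genes):
        idx = [self._index[g] for g in genes]
        return TimeCourseTable(
            [self.genes[i] for i in idx], self.times, self.abundance[idx],
            self.library_sizes,
        )

    # --- TSV round trip: columns t<min>_rep<k>, gene rows ---

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for ti, t in enumerate(self.times):
            for r in range(self.n_replicates):
                cols[f"t{int(t)}_rep{r + 1}"] = self.abundance[:, ti, r]
        return pd.DataFrame(cols, index=pd.Index(self.genes, name="gene"))

    def write_tsv(self, path):
        # %.17g keeps the write -> read round trip bit-identical
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, library_sizes=None):
        parsed = []
        for col in frame.columns:
            m = _SAMPLE_RE.match(col)
            if not m:
                raise ValueError(f"unrecognised sample column {col!r}")
            parsed.append((int(m.group(1)), int(m.group(2)), col))
        times = sorted({t for t, _, _ in parsed})
        reps = sorted({r for _, r, _ in parsed})
        if reps != list(range(1, len(reps) + 1)):
            raise ValueError("replicate numbering must be 1..R")
        abundance = np.empty((len(frame), len(times), len(reps)))
        abundance.fill(np.nan)
        for t, r, col in parsed:
            abundance[:, times.index(t), r - 1] = frame[col].to_numpy(dtype=float)
        if np.isnan(abundance).any():
            raise ValueError("replicate count differs across time points")
        return cls(frame.index.tolist(), times, abundance, library_sizes)

    @classmethod
    def read_tsv(cls, path, library_sizes=None):
        frame = pd.read_csv(path, sep="\t", index_col=0,
                            float_precision="round_trip")
        return cls.from_frame(frame, library_sizes)


def compute_rpm(counts: pd.DataFrame, library_sizes) -> TimeCourseTable:
    """Reads-per-million from raw counts.

    ``counts`` is a gene x sample integer table with ``t<min>_rep<k>``
    columns; ``library_sizes`` maps sample name -> mapped-read total.
    rpm = count / library_size * 1e6.
    """
    sizes = pd.Series(library_sizes)
    missing = [c for c in counts.columns if c not in sizes.index]
    if missing:
        raise ValueError(f"library size missing for samples {missing}")
    if (sizes[counts.columns] <= 0).any():
        raise ValueError("library sizes must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rpm = counts / sizes[counts.columns] * 1e6
    table = TimeCourseTable.from_frame(rpm)
    # attach library sizes on the table's (time, replicate) grid
    ls = np.empty((len(table.times), table.n_replicates))
    for ti, t in enumerate(table.times):
        for r in range(table.n_replicates):
            ls[ti, r] = sizes[f"t{int(t)}_rep{r + 1}"]
    table.library_sizes = ls
    return table
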