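"""100-bp half-overlapping window grid over genes and read counting.

Windows of 100 bp step by 50 bp (consecutive windows share their middle)
across each gene's genomic extent; a gene shorter than one window gets a
single window covering it.  Counting follows HTSeq's
``-s no -m union --nonunique all`` convention: a read contributes to every
feature it overlaps, unstranded.  In coverage mode (bedGraph input) the
count is reconstructed as total depth over the feature divided by the read
length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GeneModel, SampleMetadata


@dataclass(frozen=True)
class Window:
    window_id: str
    gene_id: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class WindowCountMatrix:
    """Feature x sample integer read counts with per-sample library sizes."""

    windows: list[Window]
    samples: list[SampleMetadata]
    counts: np.ndarray  # shape (n_windows, n_samples), int
    library_sizes: np.ndarray  # shape (n_samples,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes)
        if self.counts.shape != (len(self.windows), len(self.samples)):
            raise ValueError("count matrix dimensions inconsistent with windows/samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise KeyError(sample_id)

    def library_size(self, sample_id: str) -> int:
        return int(self.library_sizes[self.sample_index(sample_id)])

    def subset_windows(self, mask: np.ndarray) -> "WindowCountMatrix":
        idx = np.flatnonzero(mask)
        return WindowCountMatrix(
            [self.windows[i] for i in idx],
            self.samples,
            self.counts[idx, :],
            self.library_sizes,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[w.window_id for w in self.windows],
            columns=[s.sample_id for s in self.samples],
        )


def generate_windows(genes: Sequence[GeneModel], window_size: int = 100,
                     step: int = 50) -> list[Window]:
    """Sliding windows over each gene's genomic span.

    Offsets run 0, step, 2*step, ... while offset + window_size <= span;
    a gene shorter than *window_size* yields one window covering the gene.
    Window ids are ``gene_id:index``.
    """
    out: list[Window] = []
    for g in genes:
        span = g.span
        if span < window_size:
            out.append(Window(f"{g.gene_id}:0", g.gene_id, g.chrom, g.start, g.end))
            continue
        offset, i = 0, 0
        while offset + window_size <= span:
            out.append(
                Window(
                    f"{g.gene_id}:{i}", g.gene_id, g.chrom,
                    g.start + offset, g.start + offset + window_size,
                )
            )
            offset += step
            i += 1
    return out


def expected_window_count(span: int, window_size: int = 100, step: int = 50) -> int:
    """Closed-form window count for a gene of genomic span >= window_size."""
    return (span - window_size) // step + 1


def count_reads_in_windows(
    tracks: Sequence[CoverageTrack],
    windows: Sequence[Window],
    read_length: int = 65,
) -> WindowCountMatrix:
    """Window x sample count matrix from per-base coverage tracks.

    count = round(sum depth over window / read_length); a read overlapping
    several windows therefore contributes to each of them, mirroring the
    nonunique-all convention of alignment-based counting.
    """
    samples = [
        SampleMetadata(t.sample_id, t.role, t.sample_id, "", "", "", "", t.library_size)
        for t in tracks
    ]
    counts = np.zeros((len(windows), len(tracks)), dtype=np.int64)
    missing: set[str] = set()
    for j, track in enumerate(tracks):
        # cumulative sums per chromosome make each window an O(1) lookup
        csum = {c: np.concatenate([[0], np.cumsum(arr)]) for c, arr in track.depth.items()}
        for i, w in enumerate(windows):
            cs = csum.get(w.chrom)
            if cs is None:
                missing.add(w.chrom)
                continue
            lo = min(w.start, cs.size - 1)
            hi = min(w.end, cs.size - 1)
            total = cs[hi] - cs[lo]
            counts[i, j] = int(round(total / read_length))
    if missing:
        warnings.warn(f"chromosomes absent from some tracks (counts set to 0): {sorted(missing)}")
    return WindowCountMatrix(list(windows), samples, counts,
                             np.array([t.library_size for t in tracks]))


def count_reads_in_windows_bam(
    bam_paths: dict[str, str],
    sample_meta: Sequence[SampleMetadata],
    windows: Sequence[Window],
) -> WindowCountMatrix:
    """Window x sample counts from BAM files (union, nonunique-all).

    Each read is counted once in every window it overlaps by >=1 bp.
    """
    import pysam

    counts = np.zeros((len(windows), len(sample_meta)), dtype=np.int64)
    libs = np.zeros(len(sample_meta), dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    for j, s in enumerate(sample_meta):
        with pysam.AlignmentFile(bam_paths[s.sample_id], "rb") as bam:
            libs[j] = sum(1 for r in bam.fetch() if not r.is_unmapped)
            for chrom, idxs in by_chrom.items():
                if chrom not in bam.references:
                    continue
                starts = np.array([windows[i].start for i in idxs])
                ends = np.array([windows[i].end for i in idxs])
                order = np.argsort(starts)
                for read in bam.fetch(chrom):
                    if read.is_unmapped:
                        continue
                    rs, re = read.reference_start, read.reference_end
                    hit = (starts < re) & (ends > rs)
                    for k in np.flatnonzero(hit):
                        counts[idxs[k], j] += 1
        if s.library_size:
            libs[j] = s.library_size
    return WindowCountMatrix(list(windows), list(sample_meta), counts, libs)


def filter_min_ip_coverage(
    m: WindowCountMatrix,
    ip_sample_id: str,
    min_reads: int = 10,
) -> WindowCountMatrix:
    """Keep windows with strictly more than *min_reads* reads in the given IP sample."""
    return m.subset_windows(m.column(ip_sample_id) > min_reads)


def count_reads_in_features(
    tracks: Sequence[CoverageTrack],
    features: Sequence[tuple[str, str, int, int]],
    read_length: int = 65,
) -> pd.DataFrame:
    """Feature x sample count matrix for arbitrary intervals.

    *features* are (feature_id, chrom, start, end) tuples; same counting
    semantics as the window counter.  Used for the gene-level (Input) and
    peak-level (IP) matrices of the differential stage.
    """
    windows = [Window(fid, fid, chrom, s, e) for fid, chrom, s, e in features]
    m = count_reads_in_windows(tracks, windows, read_length=read_length)
    return m.to_frame()
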