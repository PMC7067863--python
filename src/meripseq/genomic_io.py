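"""Readers and writers for the genomic formats the pipeline touches.

Every interval in the package is 0-based half-open on the forward strand.
GTF is read as 1-based closed (the Gencode dialect), BED/bedGraph/narrowPeak
as 0-based half-open; converting on read and on write makes all round trips
identities.

Strand is carried on gene models but counting is unstranded; it is only used
for metagene coordinates and sense-strand motif scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]

METADATA_COLUMNS = [
    "sample_id",
    "role",
    "pair_id",
    "condition",
    "sequencing_batch",
    "library_batch",
    "ip_procedure",
    "library_size",
]


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the offending line."""


def _merged(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and coalesce overlapping/adjacent intervals."""
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class GeneModel:
    """A protein-coding gene: exon/CDS/UTR intervals in genomic coordinates."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene with zero exons")
        self.exons = sorted(self.exons)
        for s, e in self.exons + self.cds + self.utr5 + self.utr3:
            if not s < e:
                raise ValueError(f"{self.gene_id}: interval start {s} >= end {e}")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        """Genomic extent in bp, introns included."""
        return self.end - self.start

    def exonic_positions(self) -> np.ndarray:
        """Sorted genomic positions covered by at least one exon."""
        return np.concatenate(
            [np.arange(s, e) for s, e in _merged(self.exons)]
        )

    def exonic_length(self) -> int:
        return sum(e - s for s, e in _merged(self.exons))


@dataclass
class SampleMetadata:
    sample_id: str
    role: str  # "IP" or "Input"
    pair_id: str
    condition: str
    sequencing_batch: str
    library_batch: str
    ip_procedure: str
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.role not in {"IP", "Input"}:
            raise ValueError(f"{self.sample_id}: role must be IP or Input")


@dataclass
class CoverageTrack:
    """Per-base read depth per chromosome for one sample."""

    sample_id: str
    role: str
    depth: dict[str, np.ndarray]
    library_size: int

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Depth over [start, end); positions beyond the track are zero."""
        arr = self.depth.get(chrom)
        out = np.zeros(end - start, dtype=np.int64)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, arr.size)
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


@dataclass
class ConsensusPeak:
    """Final 150-bp m6A site with its annotations."""

    chrom: str
    start: int
    end: int
    gene_id: str
    region: str = "."
    motif_score: int = 0
    n_techniques: int = 0
    max_cov_pos: int = -1
    clipped: bool = False

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# GTF

_FEATURE_FIELD = {"exon": "exons", "CDS": "cds", "five_prime_utr": "utr5",
                  "three_prime_utr": "utr3", "UTR": None}


def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gene_models(path: str | Path, keep_gene_type: str | None = "protein_coding") -> list[GeneModel]:
    """Parse a Gencode-dialect GTF into gene models.

    Only genes whose ``gene_type`` equals *keep_gene_type* are retained
    (pass ``None`` to keep all).  Coordinates are converted from GTF
    1-based closed to 0-based half-open.
    """
    raw: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr = fields
            try:
                start = int(start_s) - 1  # 1-based closed -> 0-based half-open
                end = int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if feature not in _FEATURE_FIELD:
                continue
            attrs = _parse_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GtfParseError(f"{path}: line {lineno}: missing gene_id attribute")
            gene_type = attrs.get("gene_type", attrs.get("gene_biotype", ""))
            if keep_gene_type is not None and gene_type != keep_gene_type:
                continue
            rec = raw.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "exons": [], "cds": [],
                 "utr5": [], "utr3": []},
            )
            key = _FEATURE_FIELD[feature]
            if key is not None:
                rec[key].append((start, end))
    genes = []
    for gene_id, rec in raw.items():
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=_merged(rec["exons"]),
                cds=_merged(rec["cds"]),
                utr5=_merged(rec["utr5"]),
                utr3=_merged(rec["utr3"]),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path,
                      gene_type: str = "protein_coding") -> None:
    """Write gene models back to GTF (1-based closed coordinates)."""
    feature_of = {"exons": "exon", "cds": "CDS", "utr5": "five_prime_utr",
                  "utr3": "three_prime_utr"}
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_type "{gene_type}";'
            for field_name, feature in feature_of.items():
                for s, e in getattr(g, field_name):
                    fh.write(
                        f"{g.chrom}\tmeripseq\t{feature}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# coverage

def read_coverage(path: str | Path, sample: SampleMetadata) -> CoverageTrack:
    """Build a per-base coverage track from a bedGraph or a BAM file.

    bedGraph intervals must be non-overlapping per chromosome; the library
    size is taken from *sample* (bedGraph loses read identity).  For BAM
    (with index), depth comes from pileup and library size from the mapped
    read count.
    """
    path = Path(path)
    if path.suffix.lower() == ".bam":
        return _read_coverage_bam(path, sample)
    return _read_coverage_bedgraph(path, sample)


def _read_coverage_bedgraph(path: Path, sample: SampleMetadata) -> CoverageTrack:
    rows: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split()[:4]
            rows.setdefault(chrom, []).append((int(s), int(e), int(round(float(v)))))
    depth: dict[str, np.ndarray] = {}
    for chrom, ivs in rows.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"{path}: overlapping bedGraph intervals on {chrom}")
        arr = np.zeros(max(e for _, e, _ in ivs), dtype=np.int64)
        for s, e, v in ivs:
            arr[s:e] = v
        depth[chrom] = arr
    return CoverageTrack(sample.sample_id, sample.role, depth, sample.library_size)


def _read_coverage_bam(path: Path, sample: SampleMetadata) -> CoverageTrack:
    import pysam

    if not (path.with_suffix(".bam.bai").exists() or Path(str(path) + ".bai").exists()):
        raise ValueError(f"{path}: BAM has no index (.bai)")
    depth: dict[str, np.ndarray] = {}
    n_mapped = 0
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for ref, length in zip(bam.references, bam.lengths):
            arr = np.zeros(length, dtype=np.int64)
            any_read = False
            for read in bam.fetch(ref):
                if read.is_unmapped:
                    continue
                any_read = True
                n_mapped += 1
                for s, e in read.get_blocks():
                    arr[s:e] += 1
            if any_read:
                depth[ref] = arr
    lib = sample.library_size if sample.library_size else n_mapped
    return CoverageTrack(sample.sample_id, sample.role, depth, lib)


def write_coverage_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write non-zero runs of a coverage track as bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depth):
            arr = track.depth[chrom]
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# sample metadata

def read_sample_table(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata table missing columns {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                role=row["role"],
                pair_id=row["pair_id"],
                condition=row["condition"],
                sequencing_batch=row["sequencing_batch"],
                library_batch=row["library_batch"],
                ip_procedure=row["ip_procedure"],
                library_size=int(row["library_size"]),
            )
        )
    return samples


def write_sample_table(samples: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(s, c) for c in METADATA_COLUMNS} for s in samples]
    ).to_csv(path, sep="\t", index=False)


def pair_samples(samples: Sequence[SampleMetadata]) -> list[tuple[SampleMetadata, SampleMetadata]]:
    """Return (IP, Input) pairs joined on pair_id."""
    by_pair: dict[str, dict[str, SampleMetadata]] = {}
    for s in samples:
        by_pair.setdefault(s.pair_id, {})[s.role] = s
    pairs = []
    for pair_id in sorted(by_pair):
        d = by_pair[pair_id]
        if "IP" not in d or "Input" not in d:
            raise ValueError(f"pair {pair_id}: needs both an IP and an Input sample")
        pairs.append((d["IP"], d["Input"]))
    return pairs


# ---------------------------------------------------------------------------
# BED / narrowPeak

def write_peaks_bed(peaks: Sequence[ConsensusPeak], path: str | Path) -> None:
    """Write consensus peaks as BED6+4 (gene_id, region, motif_score, n_techniques)."""
    with open(path, "w") as fh:
        for i, p in enumerate(sorted(peaks, key=lambda p: (p.chrom, p.start))):
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        f"peak_{i + 1}",
                        str(p.motif_score),
                        ".",
                        p.gene_id,
                        p.region,
                        str(p.motif_score),
                        str(p.n_techniques),
                    ]
                )
                + "\n"
            )


def read_peaks_bed(path: str | Path) -> list[ConsensusPeak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            peaks.append(
                ConsensusPeak(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    gene_id=f[6] if len(f) > 6 else ".",
                    region=f[7] if len(f) > 7 else ".",
                    motif_score=int(f[8]) if len(f) > 8 else 0,
                    n_techniques=int(f[9]) if len(f) > 9 else 0,
                    max_cov_pos=(int(f[1]) + int(f[2])) // 2,
                )
            )
    return peaks


def read_narrowpeak(path: str | Path) -> list[dict]:
    """Read an ENCODE narrowPeak file (10 columns) into region dicts.

    A summit column of -1 is accepted; the summit is then ``None``.
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 10:
                raise ValueError(
                    f"{path}: line {lineno}: narrowPeak requires 10 columns, got {len(f)}"
                )
            start, end = int(f[1]), int(f[2])
            summit_off = int(f[9])
            regions.append(
                {
                    "chrom": f[0],
                    "start": start,
                    "end": end,
                    "name": f[3],
                    "qvalue": float(f[8]),
                    "summit": start + summit_off if summit_off >= 0 else None,
                }
            )
    return regions


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read the first three columns of a BED file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split()
            out.append((f[0], int(f[1]), int(f[2])))
    return out
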