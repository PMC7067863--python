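"""From per-sample per-technique window calls to the final consensus peaks.

The funnel: per technique, keep windows detected in >= 3 IP samples; merge
overlapping windows; re-centre each merged region as the 150-bp interval
around its position of maximum median IP coverage (leftmost on ties);
combine the four techniques by keeping genomic positions supported by >= 3
of them, merging, and re-centring once more.  Peaks are then annotated with
their host gene, transcript region (5'UTR > 3'UTR > CDS > intron
precedence), RGACW motif score and metagene coordinate.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .defaults import DEFAULTS
from .detectors import DetectionResult
from .genomic_io import ConsensusPeak, CoverageTrack, GeneModel, _merged
from .windows import Window

# the four scored motif variants share the shape G[AG]AC[AT]
RGACW_RE = re.compile(r"(?=G[AG]AC[AT])")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class CandidateSite:
    """Per-technique merged-and-recentred site before technique consensus."""

    technique: str
    chrom: str
    start: int
    end: int
    occurrence: int  # number of supporting IP samples (max over member windows)
    max_cov_pos: int


def occurrence_filter(
    results: Sequence[DetectionResult],
    min_samples: int = DEFAULTS["min_samples"],
) -> dict[str, set[str]]:
    """Windows passing in >= *min_samples* distinct IP samples, per technique.

    *results* pools every sample's detection results.  Raises if fewer IP
    samples than *min_samples* were run for some technique.
    """
    support: dict[str, dict[str, set[str]]] = {}
    samples_per_technique: dict[str, set[str]] = {}
    for r in results:
        samples_per_technique.setdefault(r.technique, set()).add(r.ip_sample_id)
        if r.passed:
            support.setdefault(r.technique, {}).setdefault(r.window_id, set()).add(
                r.ip_sample_id
            )
    out: dict[str, set[str]] = {}
    for technique, n_samples in samples_per_technique.items():
        if len(n_samples) < min_samples:
            raise ValueError(
                f"{technique}: only {len(n_samples)} IP samples available but "
                f"min_samples={min_samples}; lower the occurrence threshold"
            )
        out[technique] = {
            wid
            for wid, samps in support.get(technique, {}).items()
            if len(samps) >= min_samples
        }
    return out


def window_support(results: Sequence[DetectionResult]) -> dict[str, dict[str, int]]:
    """technique -> window_id -> number of IP samples in which it passed."""
    out: dict[str, dict[str, int]] = {}
    acc: dict[str, dict[str, set[str]]] = {}
    for r in results:
        if r.passed:
            acc.setdefault(r.technique, {}).setdefault(r.window_id, set()).add(
                r.ip_sample_id
            )
    for technique, d in acc.items():
        out[technique] = {wid: len(s) for wid, s in d.items()}
    return out


def median_ip_coverage(tracks: Sequence[CoverageTrack]) -> dict[str, np.ndarray]:
    """Per-base median depth across all IP tracks."""
    chroms: dict[str, int] = {}
    for t in tracks:
        for c, arr in t.depth.items():
            chroms[c] = max(chroms.get(c, 0), arr.size)
    med: dict[str, np.ndarray] = {}
    for c, size in chroms.items():
        stack = np.zeros((len(tracks), size), dtype=np.int64)
        for i, t in enumerate(tracks):
            arr = t.depth.get(c)
            if arr is not None:
                stack[i, : arr.size] = arr
        med[c] = np.median(stack, axis=0)
    return med


def merge_intervals(intervals: Sequence[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Coalesce overlapping and book-ended intervals (bedtools-merge default),
    equivalent to reading maximal runs off a per-base union mask."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    out: list[tuple[str, int, int]] = []
    if not by_chrom:
        return out
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                out.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((c, cur_s, cur_e))
    return out


def max_coverage_position(
    median_cov: Mapping[str, np.ndarray], chrom: str, start: int, end: int
) -> tuple[int, bool]:
    """Leftmost position of maximum median coverage in [start, end).

    Returns (position, defined); with all-zero coverage the region centre is
    used and *defined* is False.
    """
    arr = median_cov.get(chrom)
    if arr is None:
        return (start + end) // 2, False
    seg = np.zeros(end - start)
    lo, hi = max(start, 0), min(end, arr.size)
    if hi > lo:
        seg[lo - start : hi - start] = arr[lo:hi]
    if seg.max() <= 0:
        return (start + end) // 2, False
    return start + int(np.argmax(seg)), True


def recenter(
    chrom: str,
    pos: int,
    peak_width: int = DEFAULTS["peak_width"],
    chrom_length: int | None = None,
) -> tuple[int, int, bool]:
    """150-bp interval centred at *pos*, clipped at chromosome bounds."""
    half = peak_width // 2
    start, end = pos - half, pos - half + peak_width
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    return start, end, clipped


def merge_and_recenter(
    kept_windows: Mapping[str, set[str]],
    windows: Sequence[Window],
    median_cov: Mapping[str, np.ndarray],
    support: Mapping[str, Mapping[str, int]] | None = None,
    peak_width: int = DEFAULTS["peak_width"],
) -> dict[str, list[CandidateSite]]:
    """Merge each technique's occurrence-filtered windows and re-centre.

    Overlapping windows are unioned; the merged region is replaced by the
    *peak_width* interval centred at the leftmost maximum of the median IP
    coverage.
    """
    win_by_id = {w.window_id: w for w in windows}
    out: dict[str, list[CandidateSite]] = {}
    for technique, wids in kept_windows.items():
        ivs = [(win_by_id[w].chrom, win_by_id[w].start, win_by_id[w].end) for w in wids]
        sites: list[CandidateSite] = []
        if ivs:
            for chrom, s, e in merge_intervals(ivs):
                pos, defined = max_coverage_position(median_cov, chrom, s, e)
                if not defined:
                    warnings.warn(
                        f"{technique}: merged region {chrom}:{s}-{e} has all-zero "
                        "median coverage; using its centre"
                    )
                ns, ne, _ = recenter(chrom, pos, peak_width)
                occ = 0
                if support is not None:
                    occ = max(
                        (
                            support.get(technique, {}).get(w, 0)
                            for w in wids
                            if win_by_id[w].chrom == chrom
                            and win_by_id[w].start < e
                            and win_by_id[w].end > s
                        ),
                        default=0,
                    )
                sites.append(CandidateSite(technique, chrom, ns, ne, occ, pos))
        out[technique] = sites
    return out


def combine_techniques(
    sites_per_technique: Mapping[str, Sequence[CandidateSite]],
    median_cov: Mapping[str, np.ndarray],
    min_techniques: int = DEFAULTS["min_techniques"],
    peak_width: int = DEFAULTS["peak_width"],
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[ConsensusPeak]:
    """Genomic positions covered by sites of >= *min_techniques* distinct
    techniques, merged and re-centred once more to *peak_width*."""
    events: dict[str, list[tuple[int, int]]] = {}  # pos -> +/-1 per technique
    for technique, sites in sites_per_technique.items():
        for s in sites:
            events.setdefault(s.chrom, []).append((s.start, 1))
            events.setdefault(s.chrom, []).append((s.end, -1))
    peaks: list[ConsensusPeak] = []
    for chrom in sorted(events):
        # sweep per technique: count distinct techniques covering each base
        cov_events: dict[int, int] = {}
        for technique in sites_per_technique:
            tech_ivs = [
                (s.start, s.end)
                for s in sites_per_technique[technique]
                if s.chrom == chrom
            ]
            for ms, me in _merged(tech_ivs):
                cov_events[ms] = cov_events.get(ms, 0) + 1
                cov_events[me] = cov_events.get(me, 0) - 1
        regions: list[tuple[int, int]] = []
        depth = 0
        region_start: int | None = None
        for pos in sorted(cov_events):
            prev = depth
            depth += cov_events[pos]
            if prev < min_techniques <= depth:
                region_start = pos
            elif prev >= min_techniques > depth and region_start is not None:
                regions.append((region_start, pos))
                region_start = None
        for _c, s, e in merge_intervals([(chrom, s, e) for s, e in regions]):
            # re-centre on the combined region's own maximum
            pos, _ = max_coverage_position(median_cov, chrom, s, e)
            clen = chrom_lengths.get(chrom) if chrom_lengths else None
            ns, ne, clipped = recenter(chrom, pos, peak_width, clen)
            n_tech = _techniques_overlapping(sites_per_technique, chrom, s, e)
            peaks.append(
                ConsensusPeak(chrom, ns, ne, gene_id=".", n_techniques=n_tech,
                              max_cov_pos=pos, clipped=clipped)
            )
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def _techniques_overlapping(sites_per_technique, chrom, start, end) -> int:
    n = 0
    for technique, sites in sites_per_technique.items():
        if any(s.chrom == chrom and s.start < end and s.end > start for s in sites):
            n += 1
    return n


# ---------------------------------------------------------------------------
# annotation

def assign_gene(peak: ConsensusPeak, genes: Sequence[GeneModel]) -> GeneModel | None:
    """Host gene = the gene whose span overlaps the peak by the most bases."""
    best, best_ov = None, 0
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        ov = min(peak.end, g.end) - max(peak.start, g.start)
        if ov > best_ov:
            best, best_ov = g, ov
    return best


def _overlap_bases(start: int, end: int, intervals: Sequence[tuple[int, int]]) -> int:
    return sum(
        max(0, min(end, e) - max(start, s)) for s, e in intervals
    )


def annotate_region(peak: ConsensusPeak, gene: GeneModel | None) -> str:
    """Region label by precedence 5UTR > 3UTR > CDS > intron."""
    if gene is None or gene.chrom != peak.chrom or not (
        peak.start < gene.end and peak.end > gene.start
    ):
        warnings.warn(f"peak {peak.chrom}:{peak.start}-{peak.end} overlaps no gene")
        return "intergenic"
    if _overlap_bases(peak.start, peak.end, gene.utr5) > 0:
        return "5UTR"
    if _overlap_bases(peak.start, peak.end, gene.utr3) > 0:
        return "3UTR"
    if _overlap_bases(peak.start, peak.end, gene.cds) > 0:
        return "CDS"
    if _overlap_bases(peak.start, peak.end, gene.exons) > 0:
        return "CDS"  # exonic but unannotated sub-feature: treat as coding body
    return "intron"


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def motif_score(
    sequence: str,
    weights: Mapping[str, int] = DEFAULTS["motif_weights"],
) -> int:
    """Weighted count of the RGACW motif variants on the sense strand.

    Occurrences are counted with overlap allowed; the default weights are
    GAACA: 2, GGACA: 3, GAACT: 5, GGACT: 8.
    """
    seq = sequence.upper()
    score = 0
    for motif, weight in weights.items():
        start = 0
        while True:
            idx = seq.find(motif, start)
            if idx < 0:
                break
            score += weight
            start = idx + 1
    return score


def rgacw_present(sequence: str) -> bool:
    return RGACW_RE.search(sequence.upper()) is not None


def peak_sequence(peak: ConsensusPeak, genome: Mapping[str, str],
                  strand: str = "+") -> str:
    """Sense-strand sequence of the peak interval."""
    seq = str(genome[peak.chrom][peak.start : peak.end]).upper()
    return reverse_complement(seq) if strand == "-" else seq


def annotate_peaks(
    peaks: Sequence[ConsensusPeak],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str] | None = None,
) -> list[ConsensusPeak]:
    """Fill gene, region and motif score on a peak list, in place."""
    for p in peaks:
        g = assign_gene(p, genes)
        p.gene_id = g.gene_id if g is not None else "."
        p.region = annotate_region(p, g)
        if genome is not None and p.chrom in genome:
            p.motif_score = motif_score(
                peak_sequence(p, genome, g.strand if g else "+")
            )
    return list(peaks)


def reference_overlap(
    peaks: Sequence[ConsensusPeak],
    reference: Sequence[tuple[str, int, int]],
) -> tuple[float, list[bool]]:
    """Fraction (and per-peak flag) of peaks overlapping >=1 reference peak."""
    ref_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in reference:
        ref_by_chrom.setdefault(c, []).append((s, e))
    for ivs in ref_by_chrom.values():
        ivs.sort()
    flags = []
    for p in peaks:
        ivs = ref_by_chrom.get(p.chrom, [])
        flags.append(any(s < p.end and e > p.start for s, e in ivs))
    frac = float(np.mean(flags)) if flags else 0.0
    return frac, flags


# ---------------------------------------------------------------------------
# metagene coordinates

def metagene_position(peak: ConsensusPeak, gene: GeneModel) -> float | None:
    """Scaled transcript coordinate of the peak midpoint.

    The midpoint is mapped onto the spliced transcript and scaled piecewise:
    5'UTR -> [0, 1), CDS -> [1, 2), 3'UTR -> [2, 3); strand-aware.  Returns
    None when the gene lacks a CDS annotation or the midpoint cannot be
    placed in any annotated segment.
    """
    if not gene.cds:
        return None
    mid = peak.midpoint
    exonic = gene.exonic_positions()
    if exonic.size == 0:
        return None
    # snap an intronic midpoint to the nearest exonic base
    idx = int(np.searchsorted(exonic, mid))
    if idx >= exonic.size or exonic[min(idx, exonic.size - 1)] != mid:
        cand = []
        if idx > 0:
            cand.append(exonic[idx - 1])
        if idx < exonic.size:
            cand.append(exonic[idx])
        mid = int(min(cand, key=lambda p: abs(p - mid)))
    for base, intervals in ((0.0, gene.utr5), (1.0, gene.cds), (2.0, gene.utr3)):
        if not intervals:
            continue
        if any(s <= mid < e for s, e in intervals):
            positions = np.concatenate([np.arange(s, e) for s, e in sorted(intervals)])
            offset = int(np.searchsorted(positions, mid))
            length = positions.size
            if gene.strand == "-":
                offset = length - 1 - offset
            return base + offset / length
    return None


def metagene_positions(
    peaks: Sequence[ConsensusPeak], genes: Sequence[GeneModel]
) -> dict[int, float]:
    """Metagene coordinate per peak index; peaks without one are omitted."""
    by_id = {g.gene_id: g for g in genes}
    out: dict[int, float] = {}
    for i, p in enumerate(peaks):
        g = by_id.get(p.gene_id)
        if g is None:
            continue
        pos = metagene_position(p, g)
        if pos is not None:
            out[i] = pos
    return out
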