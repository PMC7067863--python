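"""Per-sample window-level m6A detection techniques.

Each technique maps one (IP, Input) sample pair plus the coverage-filtered
window grid to a set of passing windows:

* ``fisher_detect`` — one-sided Fisher exact test of window enrichment in the
  IP library vs the Input library, BH-corrected, pass at adjusted p < 0.001.
* ``rpmf_detect`` — reads-per-million fold, RPM(IP) − RPM(Input) > 10.
* ``poi_detect`` — peak-over-median / peak-over-input ratios on per-base
  coverage (null positions removed): windows with IP POM < 4 are discarded,
  pass at POI = POM_IP / POM_Input > 2.
* ``poisson_enrich_detect`` — a windowed local-Poisson enrichment test in the
  spirit of MACS2's local-lambda model (the genome-wide expected rate is
  floored by the Input-scaled local rate); external MACS2 narrowPeak output
  can be injected instead via ``narrowpeak_to_results``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .defaults import DEFAULTS
from .genomic_io import CoverageTrack, GeneModel
from .windows import Window, WindowCountMatrix

TECHNIQUES = ("fisher", "rpmf", "poi", "macs2like")


@dataclass
class DetectionResult:
    window_id: str
    technique: str
    ip_sample_id: str
    statistic: float
    passed: bool
    flag: str = ""


def fisher_detect(
    m: WindowCountMatrix,
    ip_sample_id: str,
    input_sample_id: str,
    alpha: float = DEFAULTS["fisher_alpha"],
) -> list[DetectionResult]:
    """One-sided Fisher exact enrichment test per window.

    The 2x2 table contrasts the window against the rest of each library:
    [[ip_win, ip_lib - ip_win], [in_win, in_lib - in_win]]; the one-sided
    p-value is the hypergeometric upper tail P(X >= ip_win).  BH correction
    runs across all tested windows of the sample.
    """
    ip = m.column(ip_sample_id).astype(np.int64)
    inp = m.column(input_sample_id).astype(np.int64)
    ip_lib = m.library_size(ip_sample_id)
    in_lib = m.library_size(input_sample_id)
    if ip_lib <= 0 or in_lib <= 0:
        raise ValueError("library sizes must be positive for the Fisher test")
    p = fisher_pvalues(ip, inp, ip_lib, in_lib)
    from .diffmeth import bh_adjust

    padj = bh_adjust(p)
    return [
        DetectionResult(w.window_id, "fisher", ip_sample_id, float(padj[i]),
                        bool(padj[i] < alpha))
        for i, w in enumerate(m.windows)
    ]


def fisher_pvalues(ip_win: np.ndarray, in_win: np.ndarray,
                   ip_lib: int, in_lib: int) -> np.ndarray:
    """Vectorized one-sided (enrichment) Fisher exact p-values.

    Under the null the window's reads are a hypergeometric draw of
    n = ip_win + in_win reads from ip_lib + in_lib, of which ip_lib sit in
    the IP library; p = P(X >= ip_win).
    """
    ip_win = np.asarray(ip_win, dtype=np.int64)
    in_win = np.asarray(in_win, dtype=np.int64)
    n = ip_win + in_win
    return stats.hypergeom.sf(ip_win - 1, ip_lib + in_lib, ip_lib, n)


def rpmf_detect(
    m: WindowCountMatrix,
    ip_sample_id: str,
    input_sample_id: str,
    threshold: float = DEFAULTS["rpmf_threshold"],
    mode: str = "difference",
) -> list[DetectionResult]:
    """Reads-per-million fold: RPM(IP) − RPM(Input), pass iff > threshold.

    ``mode="ratio"`` divides instead of subtracting (the statistic is called
    a fold but defined by subtraction; both readings are offered).
    """
    ip_lib = m.library_size(ip_sample_id)
    in_lib = m.library_size(input_sample_id)
    if ip_lib <= 0 or in_lib <= 0:
        raise ValueError("library sizes must be positive for RPMF")
    rpm_ip = m.column(ip_sample_id) / ip_lib * 1e6
    rpm_in = m.column(input_sample_id) / in_lib * 1e6
    if mode == "difference":
        rpmf = rpm_ip - rpm_in
    elif mode == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            rpmf = np.where(rpm_in > 0, rpm_ip / rpm_in, np.inf)
    else:
        raise ValueError(f"unknown rpmf mode {mode!r}")
    return [
        DetectionResult(w.window_id, "rpmf", ip_sample_id, float(rpmf[i]),
                        bool(rpmf[i] > threshold))
        for i, w in enumerate(m.windows)
    ]


def _nonzero_median(depth: np.ndarray) -> float:
    nz = depth[depth > 0]
    return float(np.median(nz)) if nz.size else 0.0


def poi_detect(
    ip_track: CoverageTrack,
    input_track: CoverageTrack,
    genes: Sequence[GeneModel],
    windows: Sequence[Window],
    pom_min: float = DEFAULTS["pom_min"],
    poi_min: float = DEFAULTS["poi_min"],
) -> list[DetectionResult]:
    """Peak-over-median / peak-over-input detection on per-base coverage.

    POM = median of non-null depth in the window / median of non-null depth
    over the gene's exonic positions; windows with IP POM < *pom_min* are
    removed before the POI = POM_IP / POM_Input > *poi_min* decision.
    A zero or undefined Input POM gives POI = +inf (pass, flagged
    ``input_empty``); a gene with no non-null exonic IP coverage makes its
    windows unevaluable (skipped with a warning).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    gene_median: dict[str, tuple[float, float]] = {}
    skipped_genes: set[str] = set()
    results: list[DetectionResult] = []
    for w in windows:
        g = gene_by_id[w.gene_id]
        if g.gene_id not in gene_median:
            pos = g.exonic_positions()
            ip_ex = ip_track.get(g.chrom, g.start, g.end)[pos - g.start]
            in_ex = input_track.get(g.chrom, g.start, g.end)[pos - g.start]
            gene_median[g.gene_id] = (_nonzero_median(ip_ex), _nonzero_median(in_ex))
        gmed_ip, gmed_in = gene_median[g.gene_id]
        if gmed_ip == 0.0:
            skipped_genes.add(g.gene_id)
            continue
        wmed_ip = _nonzero_median(ip_track.get(w.chrom, w.start, w.end))
        pom_ip = wmed_ip / gmed_ip
        if pom_ip < pom_min:
            results.append(
                DetectionResult(w.window_id, "poi", ip_track.sample_id,
                                float("nan"), False, flag="low_pom")
            )
            continue
        wmed_in = _nonzero_median(input_track.get(w.chrom, w.start, w.end))
        pom_in = wmed_in / gmed_in if gmed_in > 0 else 0.0
        if pom_in == 0.0:
            results.append(
                DetectionResult(w.window_id, "poi", ip_track.sample_id,
                                float("inf"), True, flag="input_empty")
            )
            continue
        poi = pom_ip / pom_in
        results.append(
            DetectionResult(w.window_id, "poi", ip_track.sample_id,
                            float(poi), bool(poi > poi_min))
        )
    if skipped_genes:
        warnings.warn(
            f"POI: {len(skipped_genes)} gene(s) without non-null exonic IP "
            "coverage; their windows were skipped"
        )
    return results


def poisson_enrich_detect(
    m: WindowCountMatrix,
    ip_sample_id: str,
    input_sample_id: str,
    qmax: float = DEFAULTS["poisson_qmax"],
    effective_size: int | None = None,
) -> list[DetectionResult]:
    """Windowed local-Poisson enrichment test (MACS2-style local lambda).

    lambda = max(genome-wide expected IP rate per window,
    Input count scaled to the IP library); p = Poisson upper tail
    P(X >= ip_win), BH across windows, pass at q < *qmax*.
    """
    ip = m.column(ip_sample_id).astype(np.int64)
    inp = m.column(input_sample_id).astype(np.float64)
    ip_lib = m.library_size(ip_sample_id)
    in_lib = m.library_size(input_sample_id)
    if effective_size is None:
        # unique bases covered by the grid (windows overlap by half)
        effective_size = _grid_footprint(m.windows)
    lam_bg = np.array([ip_lib * w.length / effective_size for w in m.windows])
    lam_local = inp * (ip_lib / in_lib)
    lam = np.maximum(np.maximum(lam_bg, lam_local), 1e-9)
    p = stats.poisson.sf(ip - 1, lam)
    from .diffmeth import bh_adjust

    q = bh_adjust(p)
    return [
        DetectionResult(w.window_id, "macs2like", ip_sample_id, float(q[i]),
                        bool(q[i] < qmax))
        for i, w in enumerate(m.windows)
    ]


def _grid_footprint(windows: Sequence[Window]) -> int:
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end))
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return max(total, 1)


def narrowpeak_to_results(
    regions: Sequence[dict],
    windows: Sequence[Window],
    ip_sample_id: str,
) -> list[DetectionResult]:
    """Map external MACS2 narrowPeak regions onto the window grid.

    Every window overlapping (>=1 bp) any region passes; the statistic is
    the best (smallest) q-value among overlapping regions.
    """
    by_chrom: dict[str, list[dict]] = {}
    for r in regions:
        by_chrom.setdefault(r["chrom"], []).append(r)
    out = []
    for w in windows:
        best = np.inf
        for r in by_chrom.get(w.chrom, []):
            if r["start"] < w.end and r["end"] > w.start:
                best = min(best, r["qvalue"])
        passed = np.isfinite(best)
        out.append(
            DetectionResult(w.window_id, "macs2like", ip_sample_id,
                            float(best) if passed else float("nan"), passed,
                            flag="external")
        )
    return out
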