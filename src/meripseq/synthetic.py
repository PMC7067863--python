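"""Synthetic MeRIP-seq study generator with known ground truth.

Builds a small transcriptome (random genes with 5'UTR/CDS/3'UTR structure on
a random genome), spikes 150-bp m6A sites on exons, and simulates paired
IP/Input per-base coverage: Input reads fall uniformly over a gene's exons
at a rate proportional to its (log-normal) expression; IP reads follow the
same background plus a multiplicative enrichment of fold gamma inside the
spiked sites.  Gene-level counts carry negative-binomial noise; sequencing
batch, library batch and IP procedure act as gene-specific multiplicative
(log-additive) effects; a subset of sites is differentially enriched and a
subset of genes differentially expressed between the two conditions.

Everything is driven by one integer seed and is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GeneModel, SampleMetadata

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the standard conditions.

    Two conditions with three IP/Input pairs each (six pairs), 100 genes,
    50 spiked exonic sites of 150 bp at enrichment fold 8, ~30x exonic
    coverage from single-end 65-bp reads, two sequencing/IP-procedure
    batches with multiplicative effects, 10 differentially methylated sites
    (log2 enrichment difference 2) and 10 differentially expressed genes.
    """

    seed: int = 0
    n_genes: int = 100
    utr5_length: tuple[int, int] = (100, 200)
    cds_length: tuple[int, int] = (600, 1200)
    utr3_length: tuple[int, int] = (300, 600)
    n_exons: tuple[int, int] = (1, 3)
    intron_length: tuple[int, int] = (100, 400)
    intergenic_gap: int = 500
    conditions: tuple[str, ...] = ("CONV", "GF")
    pairs_per_condition: int = 3
    n_spiked_sites: int = 50
    site_width: int = 150
    gamma: float = 8.0
    n_differential_sites: int = 10
    differential_log2fc: float = 2.0
    n_diff_expr_genes: int = 10
    expr_log2fc: float = 2.0
    depth: float = 30.0  # mean exonic coverage per sample
    read_length: int = 65
    expression_sigma: float = 0.7  # log-normal spread of gene expression
    nb_dispersion: float = 0.05
    batch_sigma: float = 0.25  # sd of gene-specific log2 batch effects
    motifs_per_site: int = 3  # GGACT copies implanted per spiked site
    enrichment_shape: str = "flat"  # or "triangular"

    def validate(self) -> None:
        if self.gamma <= 1:
            raise ValueError("enrichment fold gamma must exceed 1")
        if self.n_differential_sites > self.n_spiked_sites:
            raise ValueError("more differential sites than spiked sites")
        if self.site_width < self.read_length:
            raise ValueError("site width must be at least one read length")


@dataclass
class TruthRecord:
    """Ground truth for one spiked site."""

    site_id: str
    chrom: str
    start: int
    end: int
    gene_id: str
    gamma_by_condition: dict[str, float]
    is_differential: bool
    contrast: tuple[str, str] | None
    true_log2fc: float


@dataclass
class Transcriptome:
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: list[TruthRecord]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def simulate_transcriptome(cfg: SimulationConfig) -> Transcriptome:
    """Random genes with UTR/CDS structure plus spiked sites and motifs.

    Genes are laid head-to-tail on one chromosome with fixed gaps; strand
    alternates.  Spiked sites sit fully inside a single exon, and GGACT
    motifs are implanted in each site so that motif scoring has signal.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes: list[GeneModel] = []
    chrom = "chr1"
    cursor = cfg.intergenic_gap
    structures = []
    for i in range(cfg.n_genes):
        u5 = int(rng.integers(*cfg.utr5_length))
        cds = int(rng.integers(*cfg.cds_length))
        u3 = int(rng.integers(*cfg.utr3_length))
        spliced = u5 + cds + u3
        n_ex = int(rng.integers(cfg.n_exons[0], cfg.n_exons[1] + 1))
        # split spliced length into n_ex exons, each at least site_width+20
        min_exon = cfg.site_width + 20
        while n_ex > 1 and spliced < n_ex * min_exon:
            n_ex -= 1
        cuts = np.sort(rng.choice(
            np.arange(min_exon, spliced - min_exon + 1), size=n_ex - 1, replace=False
        )) if n_ex > 1 else np.array([], dtype=int)
        # enforce min exon sizes by rejecting bad cuts
        exon_lens = np.diff(np.concatenate([[0], cuts, [spliced]]))
        if (exon_lens < min_exon).any():
            exon_lens = np.full(n_ex, spliced // n_ex)
            exon_lens[-1] += spliced - exon_lens.sum()
        strand = "+" if i % 2 == 0 else "-"
        exons = []
        pos = cursor
        for el in exon_lens:
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if len(exons) < n_ex:
                pos += int(rng.integers(*cfg.intron_length))
        gene_end = exons[-1][1]
        # annotate UTR/CDS on the spliced sequence, then map back to genome
        # transcript order follows strand
        seg_lens = [u5, cds, u3] if strand == "+" else [u3, cds, u5]
        seg_names = ["utr5", "cds", "utr3"] if strand == "+" else ["utr3", "cds", "utr5"]
        feats: dict[str, list[tuple[int, int]]] = {"utr5": [], "cds": [], "utr3": []}
        offset = 0
        for name, seg in zip(seg_names, seg_lens):
            lo, hi = offset, offset + seg
            # intersect [lo, hi) in spliced coords with each exon
            acc = 0
            for es, ee in exons:
                el = ee - es
                s = max(lo, acc)
                e = min(hi, acc + el)
                if s < e:
                    feats[name].append((es + (s - acc), es + (e - acc)))
                acc += el
            offset += seg
        genes.append(
            GeneModel(f"gene_{i:04d}", chrom, strand, exons,
                      cds=feats["cds"], utr5=feats["utr5"], utr3=feats["utr3"])
        )
        structures.append((u5, cds, u3))
        cursor = gene_end + cfg.intergenic_gap
    genome_len = cursor + cfg.intergenic_gap
    seq = list(_rand_seq(rng, genome_len))

    # spike sites on exons large enough to contain them
    eligible = [
        g for g in genes
        if any(e - s >= cfg.site_width + 10 for s, e in g.exons)
    ]
    host_idx = rng.choice(len(eligible), size=min(cfg.n_spiked_sites, len(eligible)),
                          replace=False)
    truth: list[TruthRecord] = []
    diff_flags = np.zeros(len(host_idx), dtype=bool)
    diff_flags[: cfg.n_differential_sites] = True
    # differential status assigned to a random subset of hosts
    rng.shuffle(diff_flags)
    cond_a, cond_b = cfg.conditions[0], cfg.conditions[1]
    for k, hi_ in enumerate(host_idx):
        g = eligible[int(hi_)]
        big = [iv for iv in g.exons if iv[1] - iv[0] >= cfg.site_width + 10]
        es, ee = big[int(rng.integers(0, len(big)))]
        start = int(rng.integers(es + 5, ee - cfg.site_width - 4))
        end = start + cfg.site_width
        if diff_flags[k]:
            gamma_b = max(1.0 + 1e-9, cfg.gamma / 2.0 ** cfg.differential_log2fc)
            gammas = {cond_a: cfg.gamma, cond_b: gamma_b}
            lfc = float(np.log2(cfg.gamma / gamma_b))
        else:
            gammas = {c: cfg.gamma for c in cfg.conditions}
            lfc = 0.0
        truth.append(
            TruthRecord(
                site_id=f"site_{k:03d}", chrom=g.chrom, start=start, end=end,
                gene_id=g.gene_id, gamma_by_condition=gammas,
                is_differential=bool(diff_flags[k]),
                contrast=(cond_a, cond_b) if diff_flags[k] else None,
                true_log2fc=lfc,
            )
        )
        # implant sense-strand GGACT motifs inside the site; at density 0,
        # scrub chance occurrences so spiked sites carry no motif signal
        motif = "GGACT"
        if cfg.motifs_per_site > 0:
            for _ in range(cfg.motifs_per_site):
                off = int(rng.integers(start, end - len(motif)))
                ins = motif if g.strand == "+" else _revcomp(motif)
                seq[off : off + len(motif)] = list(ins)
        else:
            _scrub_motifs(seq, max(0, start - 4), min(len(seq), end + 4))
    return Transcriptome(genome={chrom: "".join(seq)}, genes=genes, truth=truth)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _scrub_motifs(seq: list[str], start: int, end: int) -> None:
    """Disrupt every scored-motif occurrence (either orientation) in seq[start:end].

    The scored variants are G[AG]AC[AT] on the sense strand; both that
    pattern and its reverse complement are flattened to A-runs.  Each pass
    converts the mandatory G/C cores to A, so the loop terminates.
    """
    import re

    pat = re.compile(r"G[AG]AC[AT]|[AT]GT[CT]C")
    window = "".join(seq[start:end])
    while True:
        m = pat.search(window)
        if m is None:
            break
        seq[start + m.start() : start + m.start() + 5] = list("AAAAA")
        window = "".join(seq[start:end])


# ---------------------------------------------------------------------------
# experiment simulation

def build_metadata(cfg: SimulationConfig) -> list[SampleMetadata]:
    """IP/Input pairs with cyclic (non-collinear) batch assignments.

    A two-level IP-procedure factor needs at least two samples per
    procedure within every condition to survive the per-procedure CPM rule
    and stay estimable, so it is only introduced from four pairs per
    condition upward; smaller studies use a single procedure.
    """
    samples: list[SampleMetadata] = []
    two_procs = cfg.pairs_per_condition >= 4
    i = 0
    for cond in cfg.conditions:
        for r in range(cfg.pairs_per_condition):
            pair = f"{cond}_r{r + 1}"
            seq_b = f"seq{i % 2 + 1}"
            lib_b = f"lib{(i // 2) % 2 + 1}"
            proc = f"proc{(r // 2) % 2 + 1}" if two_procs else "proc1"
            for role in ("IP", "Input"):
                samples.append(
                    SampleMetadata(
                        sample_id=f"{pair}_{role}", role=role, pair_id=pair,
                        condition=cond, sequencing_batch=seq_b,
                        library_batch=lib_b, ip_procedure=proc,
                    )
                )
            i += 1
    return samples


@dataclass
class Experiment:
    tracks: dict[str, CoverageTrack]
    samples: list[SampleMetadata]
    truth: list[TruthRecord]
    expression: pd.DataFrame  # per-gene expected expression per condition
    diff_expr_genes: list[str]


def simulate_experiment(cfg: SimulationConfig, txm: Transcriptome) -> Experiment:
    """Paired IP/Input coverage tracks for the configured study design."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    genes = txm.genes
    n_genes = len(genes)
    chrom_len = {c: len(s) for c, s in txm.genome.items()}
    samples = build_metadata(cfg)

    exonic_pos = {g.gene_id: g.exonic_positions() for g in genes}
    exonic_len = {g.gene_id: int(exonic_pos[g.gene_id].size) for g in genes}
    total_exonic = sum(exonic_len.values())
    reads_per_sample = cfg.depth * total_exonic / cfg.read_length

    # gene expression weights, shared across samples
    w = np.exp(rng.normal(0.0, cfg.expression_sigma * np.log(2), size=n_genes))
    w *= np.array([exonic_len[g.gene_id] for g in genes]) / np.mean(
        list(exonic_len.values())
    )
    diff_genes_idx = rng.choice(n_genes, size=cfg.n_diff_expr_genes, replace=False)
    spiked_hosts = {t.gene_id for t in txm.truth}
    diff_expr_genes = [genes[int(i)].gene_id for i in diff_genes_idx]

    # gene-specific multiplicative batch effects (log2-additive)
    factor_levels = {
        "sequencing_batch": sorted({s.sequencing_batch for s in samples}),
        "library_batch": sorted({s.library_batch for s in samples}),
        "ip_procedure": sorted({s.ip_procedure for s in samples}),
    }
    batch_lfc: dict[tuple[str, str], np.ndarray] = {}
    for factor, levels in factor_levels.items():
        for level in levels[1:]:
            batch_lfc[(factor, level)] = rng.normal(0.0, cfg.batch_sigma, size=n_genes)

    sites_by_gene: dict[str, list[TruthRecord]] = {}
    for t in txm.truth:
        sites_by_gene.setdefault(t.gene_id, []).append(t)

    # spliced-coordinate offsets of each site within its gene
    site_spliced: dict[str, list[tuple[TruthRecord, int, int]]] = {}
    for gid, sites in sites_by_gene.items():
        pos = exonic_pos[gid]
        out = []
        for t in sites:
            s_off = int(np.searchsorted(pos, t.start))
            e_off = int(np.searchsorted(pos, t.end))
            out.append((t, s_off, e_off))
        site_spliced[gid] = out

    tracks: dict[str, CoverageTrack] = {}
    expr_rows = []
    for s in samples:
        depth_arr = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_len.items()}
        total_reads = 0
        # per-gene expected read counts
        lfc2 = np.zeros(n_genes)
        for (factor, level), vec in batch_lfc.items():
            if getattr(s, factor) == level:
                lfc2 = lfc2 + vec
        expr_fold = np.ones(n_genes)
        if s.condition == cfg.conditions[1]:
            expr_fold[diff_genes_idx] = 2.0 ** cfg.expr_log2fc
        mu = reads_per_sample * (w * expr_fold * 2.0 ** lfc2) / np.sum(w)
        # NB noise via gamma-Poisson
        if cfg.nb_dispersion > 0:
            shape = 1.0 / cfg.nb_dispersion
            mu_nb = mu * rng.gamma(shape, 1.0 / shape, size=n_genes)
        else:
            mu_nb = mu
        for gi, g in enumerate(genes):
            gid = g.gene_id
            L = exonic_len[gid]
            if L <= cfg.read_length:
                continue
            base_reads = rng.poisson(mu_nb[gi])
            sites = site_spliced.get(gid, []) if s.role == "IP" else []
            # extra enrichment reads confined to each site
            extra_counts = []
            for t, s_off, e_off in sites:
                gamma_c = t.gamma_by_condition[s.condition]
                extra_mu = mu_nb[gi] * (gamma_c - 1.0) * (e_off - s_off) / L
                extra_counts.append(rng.poisson(extra_mu))
            starts = []
            if base_reads > 0:
                starts.append(rng.integers(0, L - cfg.read_length + 1, size=base_reads))
            for (t, s_off, e_off), k in zip(sites, extra_counts):
                if k > 0:
                    lo = s_off
                    hi = max(lo + 1, e_off - cfg.read_length + 1)
                    if cfg.enrichment_shape == "triangular":
                        u = rng.triangular(lo, (lo + hi) / 2.0, hi, size=k)
                        starts.append(u.astype(np.int64))
                    else:
                        starts.append(rng.integers(lo, hi, size=k))
            if not starts:
                continue
            starts_all = np.concatenate(starts)
            total_reads += starts_all.size
            # start-position histogram -> spliced coverage by boxcar sum
            hist = np.bincount(starts_all, minlength=L)
            cs = np.concatenate([[0], np.cumsum(hist)])
            idx = np.arange(L)
            cov = cs[np.minimum(idx + 1, L)] - cs[np.maximum(idx + 1 - cfg.read_length, 0)]
            np.add.at(depth_arr[g.chrom], exonic_pos[gid], cov)
        s.library_size = int(total_reads)
        tracks[s.sample_id] = CoverageTrack(s.sample_id, s.role, depth_arr, s.library_size)
        for gi, g in enumerate(genes):
            expr_rows.append((s.sample_id, g.gene_id, float(mu[gi])))
    expression = pd.DataFrame(expr_rows, columns=["sample_id", "gene_id", "expected_reads"])
    return Experiment(tracks=tracks, samples=samples, truth=txm.truth,
                      expression=expression, diff_expr_genes=diff_expr_genes)


# ---------------------------------------------------------------------------
# truth I/O and scoring

def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    rows = []
    for t in truth:
        rows.append(
            {
                "site_id": t.site_id, "chrom": t.chrom, "start": t.start,
                "end": t.end, "gene_id": t.gene_id,
                "is_differential": t.is_differential,
                "true_log2fc": t.true_log2fc,
                **{f"gamma_{c}": g for c, g in t.gamma_by_condition.items()},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    gamma_cols = [c for c in df.columns if c.startswith("gamma_")]
    out = []
    for _, r in df.iterrows():
        gbc = {c[len("gamma_"):]: float(r[c]) for c in gamma_cols}
        conds = list(gbc)
        out.append(
            TruthRecord(
                site_id=r["site_id"], chrom=r["chrom"], start=int(r["start"]),
                end=int(r["end"]), gene_id=r["gene_id"], gamma_by_condition=gbc,
                is_differential=bool(r["is_differential"]),
                contrast=(conds[0], conds[1]) if bool(r["is_differential"]) else None,
                true_log2fc=float(r["true_log2fc"]),
            )
        )
    return out


def score_peaks_against_truth(
    peaks: Sequence, truth: Sequence[TruthRecord]
) -> dict[str, float]:
    """Overlap-based (>= 1 bp) sensitivity, precision and FDR of a peak list."""
    hits_truth = 0
    for t in truth:
        if any(p.chrom == t.chrom and p.start < t.end and p.end > t.start for p in peaks):
            hits_truth += 1
    hits_peaks = 0
    for p in peaks:
        if any(p.chrom == t.chrom and p.start < t.end and p.end > t.start for t in truth):
            hits_peaks += 1
    n_truth, n_peaks = len(truth), len(peaks)
    sens = hits_truth / n_truth if n_truth else 0.0
    prec = hits_peaks / n_peaks if n_peaks else 0.0
    return {
        "n_truth": float(n_truth), "n_peaks": float(n_peaks),
        "sensitivity": sens, "precision": prec, "fdr": 1.0 - prec if n_peaks else 0.0,
    }


def score_differential_against_truth(
    results: pd.DataFrame,
    truth_ids: set[str],
) -> dict[str, float]:
    """Id-based power and FDR of differential calls vs the true positives."""
    called = set(results.loc[results["significant"], "feature_id"])
    tp = len(called & truth_ids)
    fp = len(called - truth_ids)
    power = tp / len(truth_ids) if truth_ids else 0.0
    fdr = fp / len(called) if called else 0.0
    return {"power": power, "fdr": fdr, "n_called": float(len(called))}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            s = genome[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# count-level simulators for detector calibration and differential power

def simulate_null_window_counts(
    n_windows: int = 2500,
    ip_library: int = 20_000_000,
    input_library: int = 20_000_000,
    mean_fraction: float = 5e-6,
    sigma_log2: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """IP and Input window counts drawn from the same multinomial.

    Window proportions follow a log-normal abundance profile; both tracks
    sample from identical proportions, so any detector call is a false
    positive.  Library sizes default to the tens of millions of mapped
    reads typical of a MeRIP sequencing run.
    """
    rng = np.random.default_rng(seed)
    p = mean_fraction * 2.0 ** rng.normal(0.0, sigma_log2, size=n_windows)
    p = p / p.sum() * min(1.0, mean_fraction * n_windows)
    rest = 1.0 - p.sum()
    probs = np.concatenate([p, [rest]])
    ip = rng.multinomial(ip_library, probs)[:-1]
    inp = rng.multinomial(input_library, probs)[:-1]
    return ip.astype(np.int64), inp.astype(np.int64)


def simulate_count_matrix(
    n_features: int = 2000,
    n_per_group: int = 6,
    n_true: int = 20,
    log2fc: float = 2.0,
    dispersion: float = 0.1,
    batch_sigma: float = 0.25,
    mean_log2: float = 6.5,
    sd_log2: float = 1.5,
    library_size: int = 1_000_000,
    conditions: tuple[str, str] = ("CONV", "GF"),
    seed: int = 0,
) -> tuple[pd.DataFrame, list[SampleMetadata], set[str]]:
    """Negative-binomial feature x sample counts with batch structure.

    *n_true* features get a true log2 fold change (alternating sign)
    between the two conditions; sequencing batch, library batch and IP
    procedure act as gene-specific multiplicative effects matching the
    linear model's log-additive assumption.  Returns (counts, metadata,
    ids of true positives).
    """
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(conditions=conditions, pairs_per_condition=n_per_group)
    meta_pairs = build_metadata(cfg)
    samples = [s for s in meta_pairs if s.role == "IP"]
    for s in samples:
        s.library_size = library_size
    n_samples = len(samples)
    base = 2.0 ** rng.normal(mean_log2, sd_log2, size=n_features)
    true_idx = rng.choice(n_features, size=n_true, replace=False)
    signs = np.where(np.arange(n_true) % 2 == 0, 1.0, -1.0)
    lfc = np.zeros(n_features)
    lfc[true_idx] = log2fc * signs
    factor_levels = {
        "sequencing_batch": sorted({s.sequencing_batch for s in samples}),
        "library_batch": sorted({s.library_batch for s in samples}),
        "ip_procedure": sorted({s.ip_procedure for s in samples}),
    }
    batch_lfc = {
        (f, lv): rng.normal(0.0, batch_sigma, size=n_features)
        for f, levels in factor_levels.items()
        for lv in levels[1:]
    }
    counts = np.zeros((n_features, n_samples), dtype=np.int64)
    for j, s in enumerate(samples):
        eff = np.zeros(n_features)
        for (factor, level), vec in batch_lfc.items():
            if getattr(s, factor) == level:
                eff = eff + vec
        if s.condition == conditions[1]:
            eff = eff + lfc
        mu = base * 2.0 ** eff
        if dispersion > 0:
            shape = 1.0 / dispersion
            mu = mu * rng.gamma(shape, 1.0 / shape, size=n_features)
        counts[:, j] = rng.poisson(mu)
    ids = [f"peak_{i:04d}" for i in range(n_features)]
    df = pd.DataFrame(counts, index=ids, columns=[s.sample_id for s in samples])
    truth_ids = {ids[i] for i in true_idx}
    return df, samples, truth_ids
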