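"""Peak annotation, peak-gene pairing, GWAS intersection and signal matrices."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ccio import GeneRecord, QbedParseError, _is_header, _open_text
from .peaks import Peak, PeakSet

logger = logging.getLogger(__name__)

NO_GENE = "none"


@dataclass(frozen=True)
class PeakAnnotation:
    """The two closest genes to a peak (edge-to-edge distances)."""

    peak: str
    gene1: str
    distance1: int
    gene2: str
    distance2: int


def _edge_distance(p_start: int, p_end: int, g_start: int, g_end: int) -> int:
    """Gap between two half-open intervals; 0 when they overlap."""
    if p_start < g_end and g_start < p_end:
        return 0
    return g_start - p_end if g_start >= p_end else p_start - g_end


def _tss(gene: GeneRecord) -> int:
    return gene.end - 1 if gene.strand == "-" else gene.start


def annotate_peaks(
    peaks: PeakSet, genes: list[GeneRecord], mode: str = "edge"
) -> list[PeakAnnotation]:
    """Label each peak with its two closest genes.

    ``mode='edge'`` (default) measures the gap between interval edges
    (0 for overlap); ``mode='tss'`` measures distance from the peak
    midpoint to the gene's transcription start site.  Ties broken by
    (distance, gene start, gene name).
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.end, g.name))

    out = []
    for pk in peaks:
        pid = f"{pk.chrom}:{pk.start}-{pk.end}"
        cands = by_chrom.get(pk.chrom, [])
        if not cands:
            out.append(PeakAnnotation(pid, NO_GENE, -1, NO_GENE, -1))
            continue
        scored = []
        for g in cands:
            if mode == "tss":
                mid = (pk.start + pk.end) // 2
                d = abs(_tss(g) - mid)
            else:
                d = _edge_distance(pk.start, pk.end, g.start, g.end)
            scored.append((d, g.start, g.name))
        scored.sort()
        (d1, _, n1) = scored[0]
        if len(scored) > 1:
            (d2, _, n2) = scored[1]
        else:
            n2, d2 = NO_GENE, -1
        out.append(PeakAnnotation(pid, n1, d1, n2, d2))
    return out


@dataclass(frozen=True)
class PeakGenePair:
    peak: str
    gene: str
    gene_rank: int  # 1 = nearest, 2 = next-nearest
    peak_log2fc: float
    peak_padj: float
    gene_log2fc: float
    gene_padj: float
    concordant: bool


def pair_peak_gene(
    diff_results,
    annotations: list[PeakAnnotation],
    de_table,
    lfc_min: float = 3.0,
    padj_max: float = 0.05,
    peak_padj_max: float = 0.05,
    gene_col: str = "gene",
    lfc_col: str = "log2FoldChange",
    padj_col: str = "padj",
) -> tuple[list[PeakGenePair], int]:
    """Pair differentially bound peaks with DE genes among their two
    nearest neighbours.

    A pair is retained when the peak passes ``peak_padj_max`` and the
    gene passes |logFC| >= lfc_min and padj <= padj_max.  Genes missing
    from the DE table are skipped and counted; returns (pairs,
    n_skipped).  ``de_table`` is a pandas DataFrame (DESeq2/PyDESeq2
    export layout, remappable column names).
    """
    de = {}
    for _, row in de_table.iterrows():
        de[str(row[gene_col])] = (float(row[lfc_col]), float(row[padj_col]))
    annot_by_peak = {a.peak: a for a in annotations}
    pairs, skipped = [], 0
    for r in diff_results:
        if r.padj > peak_padj_max:
            continue
        ann = annot_by_peak.get(r.peak)
        if ann is None:
            continue
        for rank, gene in ((1, ann.gene1), (2, ann.gene2)):
            if gene == NO_GENE:
                continue
            if gene not in de:
                skipped += 1
                continue
            g_lfc, g_padj = de[gene]
            if abs(g_lfc) >= lfc_min and g_padj <= padj_max:
                concordant = (r.log2fc > 0) == (g_lfc > 0)
                pairs.append(
                    PeakGenePair(r.peak, gene, rank, r.log2fc, r.padj,
                                 g_lfc, g_padj, concordant)
                )
    return pairs, skipped


def gwas_intersect(peaks: PeakSet, catalog_path) -> tuple[list[dict], int]:
    """All (peak, SNP) pairs with the SNP position inside the peak.

    ``catalog_path`` is a TSV of (chrom, pos, trait, rsid); malformed
    rows are skipped and counted.  Returns (rows, n_malformed) with rows
    ordered by (chrom, peak start, SNP pos).
    """
    snps: dict[str, list[tuple[int, str, str]]] = {}
    n_bad = 0
    with _open_text(catalog_path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or _is_header(line) or line.startswith("chrom\t"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                n_bad += 1
                continue
            try:
                pos = int(f[1])
            except ValueError:
                n_bad += 1
                continue
            snps.setdefault(f[0], []).append((pos, f[2], f[3]))
    for lst in snps.values():
        lst.sort()

    rows = []
    for pk in peaks:
        for pos, trait, rsid in snps.get(pk.chrom, []):
            if pk.start <= pos < pk.end:
                rows.append(
                    dict(peak=f"{pk.chrom}:{pk.start}-{pk.end}", chrom=pk.chrom,
                         pos=pos, trait=trait, rsid=rsid)
                )
    return rows, n_bad


def signal_matrix(
    peaks: PeakSet,
    coverage: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    flank: int = 2000,
    bins: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Length-weighted mean coverage in equal bins around peak centres.

    ``coverage`` is the dict returned by :func:`cckit.ccio.read_bedgraph`.
    Each peak contributes a row over [center - flank, center + flank)
    divided into ``bins`` equal bins.  Returns (matrix, column means).
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    mat = np.zeros((len(peaks), bins))
    for i, pk in enumerate(peaks):
        cov = coverage.get(pk.chrom)
        center = (pk.start + pk.end) // 2
        lo = center - flank
        width = 2 * flank / bins
        for b in range(bins):
            b_lo = lo + b * width
            b_hi = lo + (b + 1) * width
            b_lo_c = max(b_lo, 0.0)
            if cov is None or b_hi <= b_lo_c:
                continue
            mat[i, b] = _mean_coverage(cov, b_lo_c, b_hi)
    return mat, mat.mean(axis=0) if len(peaks) else np.zeros(bins)


def _mean_coverage(cov, lo: float, hi: float) -> float:
    """Length-weighted mean of a non-overlapping interval coverage over [lo, hi)."""
    starts, ends, values = cov
    i0 = int(np.searchsorted(ends, lo, "right"))
    i1 = int(np.searchsorted(starts, hi, "left"))
    total = 0.0
    for j in range(i0, i1):
        seg = min(float(ends[j]), hi) - max(float(starts[j]), lo)
        if seg > 0:
            total += seg * values[j]
    return total / (hi - lo)


def write_annotation_tsv(annotations: list[PeakAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("peak\tgene1\tdistance1\tgene2\tdistance2\n")
        for a in annotations:
            fh.write(f"{a.peak}\t{a.gene1}\t{a.distance1}\t{a.gene2}\t{a.distance2}\n")


def export_peak_fasta(peaks: PeakSet, sequences: dict[str, str], path) -> None:
    """Peak sequences as FASTA (input for external motif finders)."""
    with open(path, "w") as fh:
        for pk in peaks:
            seq = sequences.get(pk.chrom, "")
            sub = seq[pk.start:pk.end]
            fh.write(f">{pk.chrom}:{pk.start}-{pk.end}\n{sub}\n")


def export_browser_tracks(insertions, peaks: PeakSet, out_prefix) -> None:
    """Sorted qbed + BED ready for bgzip/tabix and browser upload."""
    from .ccio import write_bed, write_qbed

    write_qbed(insertions, f"{out_prefix}.qbed")
    write_bed(peaks, f"{out_prefix}.peaks.bed")
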