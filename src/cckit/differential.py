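"""Cells/groups-by-peaks matrices and differential peak testing.

Tables are built from insertion counts (not read counts, not cell
counts).  Two strategies are offered for comparing groups:

* joint — pool all insertions, call one peak set, count per group;
* separate — call peaks per group, merge overlapping intervals into
  union intervals, and test the unions.  This suppresses false positives
  from slightly shifted peak centres between groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ccio import InsertionSet
from .peaks import CallerConfig, Peak, PeakSet, TTAA_WIDTH, adjust_pvalues, call_peaks


def peak_id(peak: Peak) -> str:
    return f"{peak.chrom}:{peak.start}-{peak.end}"


class PeakMatrix:
    """Integer count matrix, rows = cells or groups, columns = peaks."""

    def __init__(self, counts: np.ndarray, row_labels, peaks: PeakSet,
                 n_unassigned: int = 0, clusters=None):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts.shape != (len(row_labels), len(peaks)):
            raise ValueError("counts shape does not match labels/peaks")
        self.counts = counts.astype(np.int64)
        self.row_labels = list(row_labels)
        self.peaks = peaks
        self.n_unassigned = n_unassigned
        self.clusters = list(clusters) if clusters is not None else None
        self._row_index = {lbl: i for i, lbl in enumerate(self.row_labels)}

    @property
    def shape(self):
        return self.counts.shape

    @property
    def peak_ids(self) -> list[str]:
        return [peak_id(p) for p in self.peaks]

    def row(self, label) -> np.ndarray:
        return self.counts[self._row_index[label]]

    def group_counts(self, group) -> np.ndarray:
        """Column counts summed over rows in ``group``.

        ``group`` is a row label (groups-by-peaks) or, when a cluster
        assignment is present, a cluster label (cells-by-peaks).
        """
        if group in self._row_index:
            return self.counts[self._row_index[group]].copy()
        if self.clusters is not None:
            mask = np.array([c == group for c in self.clusters])
            if mask.any():
                return self.counts[mask].sum(axis=0)
        raise KeyError(f"unknown group {group!r}")

    def group_labels(self) -> list[str]:
        if self.clusters is not None:
            seen: dict[str, None] = {}
            for c in self.clusters:
                seen.setdefault(c, None)
            return list(seen)
        return list(self.row_labels)

    def to_anndata(self):
        """Serialize to the h5ad-compatible AnnData layout."""
        import anndata as ad
        import pandas as pd
        from scipy import sparse

        obs = pd.DataFrame(index=pd.Index(map(str, self.row_labels), name="obs"))
        if self.clusters is not None:
            obs["cluster"] = self.clusters
        var = self.peaks.to_dataframe()
        var.index = pd.Index(self.peak_ids, name="peak")
        return ad.AnnData(X=sparse.csr_matrix(self.counts), obs=obs, var=var)

    def write_mtx(self, prefix) -> None:
        """Write counts as MatrixMarket + row/column TSV metadata."""
        from pathlib import Path

        from scipy import io as sio
        from scipy import sparse

        prefix = Path(prefix)
        sio.mmwrite(str(prefix) + ".mtx", sparse.coo_matrix(self.counts))
        with open(str(prefix) + ".rows.tsv", "w") as fh:
            for lbl in self.row_labels:
                fh.write(f"{lbl}\n")
        with open(str(prefix) + ".cols.tsv", "w") as fh:
            for pid in self.peak_ids:
                fh.write(f"{pid}\n")


def assign_insertions(
    insertions: InsertionSet,
    peaks: PeakSet,
    by: str = "group",
    group_of=None,
) -> PeakMatrix:
    """Count insertions per (row, peak).

    ``by='barcode'`` makes one row per cell barcode (records must carry
    barcodes).  ``by='group'`` uses ``group_of``, a mapping from record
    barcode (or a callable on records) to a group label; with neither,
    everything lands in a single row "all".

    An insertion is assigned to the unique peak whose half-open interval
    contains its ``start``; peaks must be sorted and non-overlapping.
    """
    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    for chrom in peaks.chromosomes:
        ps = peaks.on(chrom)
        starts_by_chrom[chrom] = np.array([p.start for p in ps], dtype=np.int64)
        ends_by_chrom[chrom] = np.array([p.end for p in ps], dtype=np.int64)
        if (starts_by_chrom[chrom][1:] < ends_by_chrom[chrom][:-1]).any():
            raise ValueError(f"peaks on {chrom} overlap; assignment is ambiguous")

    col_offset = {}
    off = 0
    for chrom in peaks.chromosomes:
        col_offset[chrom] = off
        off += len(peaks.on(chrom))

    if by == "barcode":
        if not insertions.has_barcodes:
            raise ValueError("barcode mode requested but records lack barcodes")
        labeller = lambda rec: rec.barcode
    elif by == "group":
        if group_of is None:
            labeller = lambda rec: "all"
        elif callable(group_of):
            labeller = group_of
        else:
            labeller = lambda rec: group_of[rec.barcode]
    else:
        raise ValueError("by must be 'barcode' or 'group'")

    row_index: dict[str, int] = {}
    entries: dict[tuple[int, int], int] = {}
    n_unassigned = 0
    for rec in insertions:
        chrom = rec.chrom
        col = None
        if chrom in starts_by_chrom:
            s, e = starts_by_chrom[chrom], ends_by_chrom[chrom]
            i = int(np.searchsorted(s, rec.start, "right")) - 1
            if i >= 0 and rec.start < e[i]:
                col = col_offset[chrom] + i
        if col is None:
            n_unassigned += 1
            continue
        label = labeller(rec)
        r = row_index.setdefault(label, len(row_index))
        entries[(r, col)] = entries.get((r, col), 0) + 1

    counts = np.zeros((len(row_index), len(peaks)), dtype=np.int64)
    for (r, c), v in entries.items():
        counts[r, c] = v
    labels = sorted(row_index, key=row_index.get)
    return PeakMatrix(counts, labels, peaks, n_unassigned=n_unassigned)


@dataclass(frozen=True)
class DiffResult:
    """Differential statistics for one peak and one focal group."""

    peak: str
    group: str
    n_in: int
    n_out: int
    group_total: int
    other_total: int
    log2fc: float
    pvalue: float
    padj: float
    direction: str  # "up" in the focal group, "down", or "none"


def _log2fc(n_a: int, total_a: int, n_b: int, total_b: int, pseudocount: float) -> float:
    """Log2 ratio of library-size-normalized insertion rates."""
    rate_a = (n_a + pseudocount) / total_a
    rate_b = (n_b + pseudocount) / total_b
    return math.log2(rate_a / rate_b)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_diff(
    matrix: PeakMatrix, group_a, group_b, pseudocount: float = 0.5
) -> list[DiffResult]:
    """Two-sided Fisher's exact test per peak between two groups.

    The 2x2 table is [[n_in_a, total_a - n_in_a], [n_in_b, total_b -
    n_in_b]].  Direction reports which group has the higher normalized
    rate; BH adjustment across peaks.
    """
    counts_a = matrix.group_counts(group_a)
    counts_b = matrix.group_counts(group_b)
    total_a, total_b = int(counts_a.sum()), int(counts_b.sum())
    if total_a == 0 or total_b == 0:
        raise ValueError("both groups must have positive insertion totals")
    pvals = np.empty(len(counts_a))
    for i, (na, nb) in enumerate(zip(counts_a, counts_b)):
        pvals[i] = fisher_two_sided(
            int(na), total_a - int(na), int(nb), total_b - int(nb)
        )
    padj = adjust_pvalues(pvals)
    out = []
    for i, pid in enumerate(matrix.peak_ids):
        na, nb = int(counts_a[i]), int(counts_b[i])
        lfc = _log2fc(na, total_a, nb, total_b, pseudocount)
        direction = "up" if lfc > 0 else ("down" if lfc < 0 else "none")
        out.append(
            DiffResult(pid, str(group_a), na, nb, total_a, total_b,
                       lfc, float(pvals[i]), float(padj[i]), direction)
        )
    return out


def binomial_diff(
    matrix: PeakMatrix,
    group,
    background_fraction: float | None = None,
    pseudocount: float = 0.5,
) -> list[DiffResult]:
    """One-sided binomial test of a group's share of each peak's insertions.

    Null p0 is the group's share of all insertions unless
    ``background_fraction`` overrides it; reports P(X >= x).
    """
    counts_in = matrix.group_counts(group)
    counts_all = matrix.counts.sum(axis=0)
    total_in = int(counts_in.sum())
    grand_total = int(counts_all.sum())
    p0 = background_fraction if background_fraction is not None else total_in / grand_total
    if not (0 < p0 < 1):
        raise ValueError(f"null fraction must be in (0, 1), got {p0}")
    pvals, results = [], []
    for i in range(len(counts_in)):
        x, n = int(counts_in[i]), int(counts_all[i])
        if n < 1:
            pvals.append(1.0)
            continue
        pvals.append(stats.binomtest(x, n, p0, alternative="greater").pvalue)
    pvals = np.asarray(pvals)
    padj = adjust_pvalues(pvals)
    other_total = grand_total - total_in
    for i, pid in enumerate(matrix.peak_ids):
        x, n = int(counts_in[i]), int(counts_all[i])
        n_out = n - x
        lfc = (
            _log2fc(x, max(total_in, 1), n_out, max(other_total, 1), pseudocount)
            if other_total > 0
            else float("inf")
        )
        direction = "up" if lfc > 0 else ("down" if lfc < 0 else "none")
        results.append(
            DiffResult(pid, str(group), x, n_out, total_in, other_total,
                       lfc, float(pvals[i]), float(padj[i]), direction)
        )
    return results


def rank_peak_groups(matrix: PeakMatrix, groups=None) -> dict[str, list[DiffResult]]:
    """One-vs-rest binomial test per group, ranked by (p, -|lfc|, peak id)."""
    groups = groups if groups is not None else matrix.group_labels()
    out = {}
    for g in groups:
        res = binomial_diff(matrix, g)
        out[str(g)] = sorted(res, key=lambda r: (r.pvalue, -abs(r.log2fc), r.peak))
    return out


def _count_matrix_for_groups(
    exp_sets: dict[str, InsertionSet], peaks: PeakSet
) -> PeakMatrix:
    rows = []
    labels = []
    n_unassigned = 0
    for name, ins in exp_sets.items():
        m = assign_insertions(ins, peaks)
        rows.append(m.counts.sum(axis=0) if m.shape[0] else np.zeros(len(peaks), dtype=np.int64))
        labels.append(name)
        n_unassigned += m.n_unassigned
    return PeakMatrix(np.vstack(rows) if rows else np.zeros((0, len(peaks)), dtype=np.int64),
                      labels, peaks, n_unassigned=n_unassigned)


def diff_strategy_joint(
    exp_sets: dict[str, InsertionSet],
    ttaa,
    cfg: CallerConfig | None = None,
    bkg: InsertionSet | None = None,
    method: str = "cccaller",
    test: str = "fisher",
) -> tuple[list[DiffResult], PeakSet]:
    """Pool insertions, call one peak set, test per-group counts."""
    if len(exp_sets) < 2:
        raise ValueError("need at least two groups")
    for name, s in exp_sets.items():
        if len(s) == 0:
            raise ValueError(f"group {name!r} has no insertions")
    pooled = InsertionSet.concat(list(exp_sets.values()))
    peaks = call_peaks(method, pooled, bkg, ttaa, cfg)
    matrix = _count_matrix_for_groups(exp_sets, peaks)
    return _run_tests(matrix, test), peaks


def merge_overlapping_peaks(peak_sets: list[PeakSet]) -> PeakSet:
    """Union intervals of peaks overlapping by >= 1 bp across sets.

    Statistics of merged peaks are recomputed downstream; placeholder
    stats are carried (n_exp = sum of members, p = min of members).
    """
    all_peaks = sorted(
        (p for ps in peak_sets for p in ps), key=lambda p: (p.chrom, p.start, p.end)
    )
    merged: list[Peak] = []
    for p in all_peaks:
        if merged and merged[-1].chrom == p.chrom and p.start < merged[-1].end:
            prev = merged[-1]
            merged[-1] = Peak(
                prev.chrom, prev.start, max(prev.end, p.end),
                prev.n_exp + p.n_exp, prev.n_bkg + p.n_bkg,
                max(prev.n_ttaa, p.n_ttaa), max(prev.lam, p.lam),
                min(prev.pvalue, p.pvalue), min(prev.qvalue, p.qvalue),
                prev.center,
            )
        else:
            merged.append(p)
    return PeakSet(merged)


def diff_strategy_separate(
    exp_sets: dict[str, InsertionSet],
    ttaa,
    cfg: CallerConfig | None = None,
    bkg: InsertionSet | None = None,
    method: str = "cccaller",
    test: str = "fisher",
) -> tuple[list[DiffResult], PeakSet]:
    """Call peaks per group, merge overlapping intervals, test the unions."""
    if len(exp_sets) < 2:
        raise ValueError("need at least two groups")
    per_group = []
    for name, s in exp_sets.items():
        if len(s) == 0:
            raise ValueError(f"group {name!r} has no insertions")
        per_group.append(call_peaks(method, s, bkg, ttaa, cfg))
    union = merge_overlapping_peaks(per_group)
    matrix = _count_matrix_for_groups(exp_sets, union)
    return _run_tests(matrix, test), union


def _run_tests(matrix: PeakMatrix, test: str) -> list[DiffResult]:
    labels = matrix.group_labels()
    if test == "fisher":
        if len(labels) == 2:
            return fisher_diff(matrix, labels[0], labels[1])
        out = []
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                out.extend(fisher_diff(matrix, a, b))
        return out
    if test == "binomial":
        out = []
        for g in labels:
            out.extend(binomial_diff(matrix, g))
        return out
    raise ValueError("test must be 'fisher' or 'binomial'")


def diff_to_dataframe(results: list[DiffResult]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in results])


def write_volcano_tsv(results: list[DiffResult], path) -> None:
    """TSV of log2FC vs -log10 adjusted p per peak (volcano-plot data layer)."""
    with open(path, "w") as fh:
        fh.write("peak\tgroup\tlog2fc\tneg_log10_padj\n")
        for r in results:
            neg = -math.log10(r.padj) if r.padj > 0 else 320.0
            fh.write(f"{r.peak}\t{r.group}\t{r.log2fc:.6g}\t{neg:.6g}\n")
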