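"""Synthetic Calling Cards datasets with known ground truth.

Generates a TTAA landscape, plants enriched sites (directed insertions,
normally scattered around each site centre and snapped to the nearest
TTAA) over a uniform background of undirected insertions into TTAAs,
and records every insertion's origin so caller accuracy is measurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .ccio import InsertionRecord, InsertionSet, TTAAIndex
from .peaks import PeakSet, TTAA_WIDTH


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.  ``seed`` is mandatory."""

    seed: int
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chrS1": 1_000_000})
    ttaa_density: float = 0.004          # expected TTAA starts per bp
    ttaa_positions: dict[str, list[int]] | None = None  # overrides density
    n_true_peaks: int = 10
    peak_width_mean: float = 500.0       # bp, exponential-ish width draw
    peak_width_min: float = 100.0
    enrichment: float = 50.0             # expected directed insertions per peak
    n_background: int = 2000             # undirected insertions in the experiment set
    n_bkg_track: int | None = None       # size of the separate background set; default n_background
    directed_sd: float = 50.0            # spread of directed insertions around centre
    reads_geom_p: float = 0.5            # reads = 1 + Geometric(p) - 1
    n_cells: int = 0                     # > 0 turns on single-cell (barcoded) mode
    n_clusters: int = 1
    cluster_peak_mask: np.ndarray | None = None  # bool (n_clusters, n_true_peaks)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_true_peaks", "n_background", "n_cells", "n_clusters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Planted intervals plus per-insertion provenance labels."""

    true_intervals: list[tuple[str, int, int]]
    exp_labels: list[str]      # "directed" / "background", parallel to exp records
    cluster_of_cell: dict[str, str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                dict(
                    true_intervals=[list(t) for t in self.true_intervals],
                    exp_labels=self.exp_labels,
                    cluster_of_cell=self.cluster_of_cell,
                ),
                fh,
                indent=1,
            )

    @staticmethod
    def from_json(path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return GroundTruth(
            [tuple(t) for t in d["true_intervals"]],
            d["exp_labels"],
            d["cluster_of_cell"],
        )


def simulate_genome(cfg: SimConfig) -> TTAAIndex:
    """Place TTAA positions uniformly at ``ttaa_density`` with spacing >= 4 bp."""
    if cfg.ttaa_positions is not None:
        return TTAAIndex(cfg.ttaa_positions)
    if cfg.ttaa_density >= 0.25:
        raise ValueError("ttaa_density too high: 4 bp spacing impossible")
    rng = np.random.default_rng(cfg.seed)
    positions: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chrom_lengths.items():
        n = rng.binomial(length, cfg.ttaa_density)
        raw = np.unique(rng.integers(0, max(length - TTAA_WIDTH, 1), size=n))
        kept = []
        prev = -TTAA_WIDTH
        for p in raw:  # thin to enforce non-overlapping tetranucleotides
            if p - prev >= TTAA_WIDTH:
                kept.append(int(p))
                prev = p
        positions[chrom] = np.array(kept, dtype=np.int64)
    return TTAAIndex({c: p for c, p in positions.items()})


def _draw_reads(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    return rng.geometric(p, size=n) if n else np.empty(0, dtype=np.int64)


def _snap_to_ttaa(ttaa: TTAAIndex, chrom: str, raw_positions) -> list[int]:
    out = []
    for rp in raw_positions:
        snapped = ttaa.nearest(chrom, int(round(rp)))
        if snapped is not None:
            out.append(snapped)
    return out


def simulate_insertions(
    cfg: SimConfig, ttaa: TTAAIndex | None = None
) -> tuple[InsertionSet, InsertionSet, GroundTruth]:
    """Draw (experiment, background) insertion sets plus ground truth.

    Experiment = ``n_background`` undirected insertions uniform over
    TTAAs + ~Poisson(enrichment) directed insertions per planted peak,
    Normal(center, directed_sd)-scattered and snapped to the nearest
    TTAA.  The background set is an independent uniform draw.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if ttaa is None:
        ttaa = simulate_genome(cfg)
    chroms = [c for c in ttaa.chromosomes if len(ttaa.positions(c)) > 0]
    if not chroms:
        raise ValueError("TTAA index is empty; cannot place insertions")
    chrom_lengths = {
        c: cfg.chrom_lengths.get(c, int(ttaa.positions(c)[-1]) + TTAA_WIDTH)
        for c in chroms
    }

    # -- planted sites ----------------------------------------------------
    true_intervals: list[tuple[str, int, int]] = []
    centers: list[tuple[str, int]] = []
    for _ in range(cfg.n_true_peaks):
        for _attempt in range(100):
            chrom = chroms[rng.integers(len(chroms))]
            width = max(cfg.peak_width_min, rng.exponential(cfg.peak_width_mean))
            length = chrom_lengths[chrom]
            center = int(rng.integers(int(width) // 2 + 1, max(length - int(width) // 2 - 1, 2)))
            lo, hi = center - int(width) // 2, center + int(width) // 2
            if ttaa.count(chrom, lo, hi) > 0:
                # keep planted sites disjoint so truth intervals are unambiguous
                if all(c != chrom or hi <= s or e <= lo for c, s, e in true_intervals):
                    true_intervals.append((chrom, lo, hi))
                    centers.append((chrom, center))
                    break
        else:
            raise RuntimeError("could not place a planted peak on a TTAA after 100 tries")

    # -- cells / clusters --------------------------------------------------
    barcoded = cfg.n_cells > 0
    cells_by_cluster: dict[str, list[str]] = {}
    cluster_of_cell: dict[str, str] = {}
    all_cells: list[str] = []
    if barcoded:
        for i in range(cfg.n_cells):
            bc = f"CELL{i:06d}"
            cl = f"cluster{i % cfg.n_clusters}"
            cells_by_cluster.setdefault(cl, []).append(bc)
            cluster_of_cell[bc] = cl
            all_cells.append(bc)
    mask = cfg.cluster_peak_mask
    if barcoded and mask is None:
        mask = np.ones((cfg.n_clusters, cfg.n_true_peaks), dtype=bool)

    def pick_cell(peak_idx: int | None) -> str | None:
        if not barcoded:
            return None
        if peak_idx is None:
            return all_cells[rng.integers(len(all_cells))]
        active = [
            cl for k, cl in enumerate(sorted(cells_by_cluster))
            if mask[k % mask.shape[0], peak_idx]
        ]
        if not active:
            active = sorted(cells_by_cluster)
        cl = active[rng.integers(len(active))]
        cells = cells_by_cluster[cl]
        return cells[rng.integers(len(cells))]

    # -- experiment: background component ---------------------------------
    exp_records: list[InsertionRecord] = []
    labels: list[str] = []

    def uniform_ttaa_draw(n: int) -> list[tuple[str, int]]:
        pool_sizes = np.array([len(ttaa.positions(c)) for c in chroms])
        pool_cum = np.cumsum(pool_sizes)
        idx = rng.integers(0, pool_cum[-1], size=n)
        out = []
        for i in idx:
            ci = int(np.searchsorted(pool_cum, i, "right"))
            offset = i - (pool_cum[ci - 1] if ci else 0)
            out.append((chroms[ci], int(ttaa.positions(chroms[ci])[offset])))
        return out

    for chrom, p in uniform_ttaa_draw(cfg.n_background):
        reads = int(rng.geometric(cfg.reads_geom_p))
        exp_records.append(
            InsertionRecord(chrom, p, p + TTAA_WIDTH, reads, "+", pick_cell(None))
        )
        labels.append("background")

    # -- experiment: directed component -----------------------------------
    for pi, (chrom, center) in enumerate(centers):
        n_dir = int(rng.poisson(cfg.enrichment))
        raw = rng.normal(center, cfg.directed_sd, size=n_dir)
        for p in _snap_to_ttaa(ttaa, chrom, raw):
            reads = int(rng.geometric(cfg.reads_geom_p))
            exp_records.append(
                InsertionRecord(chrom, p, p + TTAA_WIDTH, reads, "+", pick_cell(pi))
            )
            labels.append("directed")

    # -- independent background track -------------------------------------
    n_bkg = cfg.n_bkg_track if cfg.n_bkg_track is not None else cfg.n_background
    bkg_records = [
        InsertionRecord(chrom, p, p + TTAA_WIDTH, int(rng.geometric(cfg.reads_geom_p)), "+",
                        pick_cell(None))
        for chrom, p in uniform_ttaa_draw(n_bkg)
    ]

    # InsertionSet sorts records; keep labels aligned by sorting the same way
    order = sorted(
        range(len(exp_records)),
        key=lambda i: (
            exp_records[i].chrom, exp_records[i].start, exp_records[i].end,
            exp_records[i].strand, exp_records[i].barcode or "",
        ),
    )
    exp_sorted = [exp_records[i] for i in order]
    labels_sorted = [labels[i] for i in order]
    truth = GroundTruth(true_intervals, labels_sorted, cluster_of_cell)
    return InsertionSet(exp_sorted), InsertionSet(bkg_records), truth


@dataclass
class CallerScore:
    recall: float
    precision: float
    n_called: int
    n_true: int
    cumulative_length: int
    insertion_fraction: float  # fraction of insertions under called peaks
    zero_calls: bool
    over_merged: int  # called peaks spanning >= 2 true intervals


def score_caller(
    called: PeakSet, truth: GroundTruth, insertions: InsertionSet | None = None
) -> CallerScore:
    """Recall/precision of called peaks against planted intervals.

    A true interval is recovered if any called peak overlaps it by
    >= 1 bp; a called peak is a true positive if it overlaps any true
    interval.  With zero called peaks precision is reported as 1.0 with
    ``zero_calls`` set.
    """
    def overlaps(chrom, s, e, pk) -> bool:
        return pk.chrom == chrom and pk.start < e and s < pk.end

    n_true = len(truth.true_intervals)
    recovered = sum(
        1 for (c, s, e) in truth.true_intervals if any(overlaps(c, s, e, p) for p in called)
    )
    tp = 0
    over_merged = 0
    for p in called:
        hits = sum(1 for (c, s, e) in truth.true_intervals if overlaps(c, s, e, p))
        if hits >= 1:
            tp += 1
        if hits >= 2:
            over_merged += 1
    zero = len(called) == 0
    precision = 1.0 if zero else tp / len(called)
    recall = recovered / n_true if n_true else 1.0

    frac = 0.0
    if insertions is not None and len(insertions):
        under = sum(
            insertions.count_in(p.chrom, p.start, p.end) for p in called
        )
        frac = under / len(insertions)
    return CallerScore(
        recall=recall, precision=precision, n_called=len(called), n_true=n_true,
        cumulative_length=called.total_length(), insertion_fraction=frac,
        zero_calls=zero, over_merged=over_merged,
    )
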