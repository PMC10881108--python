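"""Peak callers for transposon insertion data.

Three callers share one significance pipeline:

* ``call_cccaller`` — greedy single-pass clustering of sorted insertion
  positions; a candidate block is extended while the gap to the next
  insertion stays within ``maxbetween``.
* ``call_maccs`` — fixed window/step genome scan, enriched windows are
  merged, re-centred on the densest position and trimmed.
* ``call_blockify`` — Bayesian-Blocks dynamic program for event data.

Candidates are then tested against a TTAA-density-corrected Poisson
null: the expected count comes from the background track (with-background
mode) or from flanking lambda windows (background-free mode), and the
p-value is the Poisson upper tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .ccio import InsertionSet, TTAAIndex

logger = logging.getLogger(__name__)

# insertions occupy a TTAA tetranucleotide
TTAA_WIDTH = 4


@dataclass(frozen=True)
class Peak:
    """A called peak with its test statistics."""

    chrom: str
    start: int
    end: int
    n_exp: int
    n_bkg: int
    n_ttaa: int
    lam: float
    pvalue: float
    qvalue: float
    center: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("peak start must be < end")

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """Sorted, per-chromosome collection of non-overlapping peaks."""

    def __init__(self, peaks=()):
        self._peaks = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self):
        return len(self._peaks)

    def __iter__(self):
        return iter(self._peaks)

    def __getitem__(self, i):
        return self._peaks[i]

    @property
    def chromosomes(self):
        return sorted({p.chrom for p in self._peaks})

    def on(self, chrom: str) -> list[Peak]:
        return [p for p in self._peaks if p.chrom == chrom]

    def total_length(self) -> int:
        return sum(p.end - p.start for p in self._peaks)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                dict(
                    chrom=p.chrom, start=p.start, end=p.end, n_exp=p.n_exp,
                    n_bkg=p.n_bkg, n_ttaa=p.n_ttaa, lam=p.lam,
                    pvalue=p.pvalue, qvalue=p.qvalue, center=p.center,
                )
                for p in self._peaks
            ],
            columns=[
                "chrom", "start", "end", "n_exp", "n_bkg", "n_ttaa",
                "lam", "pvalue", "qvalue", "center",
            ],
        )


@dataclass
class CallerConfig:
    """Shared configuration for all three callers.

    ``mode`` is chosen automatically by the callers: "with_background"
    when a background set is supplied, else "background_free".
    """

    mode: str = "background_free"
    window: int = 1000
    step: int = 500
    maxbetween: int = 2000
    lambda_windows: tuple[int, ...] = (1000, 5000, 10000)  # radii, bp
    min_insertions: int = 5
    pvalue_cutoff: float | None = None  # None -> mode-dependent default
    pseudocount: float = 0.5
    multiple_testing: str = "BH"  # {"none", "BH"}
    extend: int = 0
    ncp_prior: float | None = None  # Blockify change-point prior; None -> calibrated

    def __post_init__(self):
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if self.maxbetween <= 0:
            raise ValueError("maxbetween must be > 0")
        if not self.lambda_windows:
            raise ValueError("lambda_windows must be nonempty")
        if self.multiple_testing not in {"none", "BH"}:
            raise ValueError("multiple_testing must be 'none' or 'BH'")

    def cutoff(self) -> float:
        if self.pvalue_cutoff is not None:
            return self.pvalue_cutoff
        return 0.01 if self.mode == "with_background" else 1e-4


# ---------------------------------------------------------------------------
# Significance machinery
# ---------------------------------------------------------------------------

def poisson_upper_tail(x: int, lam: float) -> float:
    """P(X >= x) for X ~ Poisson(lam).

    lam == 0 is the degenerate null: probability 1 at x == 0, else 0.
    """
    if x < 0 or lam < 0:
        raise ValueError("x and lam must be nonnegative")
    if x == 0:
        return 1.0
    if lam == 0:
        return 0.0
    # P(X >= x) = sf(x - 1)
    return float(stats.poisson.sf(x - 1, lam))


def adjust_pvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def expected_count(
    n_bkg_local: float,
    ttaa_peak: int,
    ttaa_local: int,
    total_exp: int,
    total_bkg: int,
    cfg: CallerConfig,
) -> float:
    """Poisson mean for one (background-count, TTAA-count) combination.

    With-background mode: background count is scaled by the library-size
    ratio and by the peak/local TTAA density ratio.  The caller evaluates
    this over the peak itself and over each lambda window and keeps the
    maximum (local-lambda safeguard); this helper computes one term.
    """
    if total_bkg <= 0:
        raise ValueError(
            "background total is 0; use background-free mode instead"
        )
    if total_exp <= 0:
        raise ValueError("experiment total must be > 0")
    return (
        max(n_bkg_local, cfg.pseudocount)
        * (total_exp / total_bkg)
        * (ttaa_peak / max(ttaa_local, 1))
    )


def _lambda_with_background(
    chrom: str, start: int, end: int, bkg: InsertionSet, ttaa: TTAAIndex,
    total_exp: int, total_bkg: int, cfg: CallerConfig,
) -> tuple[float, int]:
    """Max lam over the peak itself and each lambda window centred on it.

    Returns (lam, n_bkg_in_peak).
    """
    ttaa_peak = ttaa.count(chrom, start, end)
    n_bkg_peak = bkg.count_in(chrom, start, end)
    lam = expected_count(n_bkg_peak, ttaa_peak, ttaa_peak, total_exp, total_bkg, cfg)
    mid = (start + end) // 2
    for radius in cfg.lambda_windows:
        w_start, w_end = max(0, mid - radius), mid + radius
        if w_end - w_start <= end - start:
            continue  # window not larger than the peak
        n_bkg_w = bkg.count_in(chrom, w_start, w_end)
        ttaa_w = ttaa.count(chrom, w_start, w_end)
        lam = max(
            lam,
            expected_count(n_bkg_w, ttaa_peak, ttaa_w, total_exp, total_bkg, cfg),
        )
    return lam, n_bkg_peak


def _lambda_background_free(
    chrom: str, start: int, end: int, exp: InsertionSet, ttaa: TTAAIndex,
    cfg: CallerConfig,
) -> float:
    """Background-free null mean from flanking lambda windows.

    lam = max over windows of (window insertions - peak insertions)
    * ttaa_peak / max(window_ttaa - ttaa_peak, 1), floored at pseudocount.
    """
    ttaa_peak = ttaa.count(chrom, start, end)
    n_peak = exp.count_in(chrom, start, end)
    mid = (start + end) // 2
    lam = 0.0
    for radius in cfg.lambda_windows:
        w_start, w_end = max(0, mid - radius), mid + radius
        n_window = exp.count_in(chrom, w_start, w_end)
        ttaa_window = ttaa.count(chrom, w_start, w_end)
        lam = max(
            lam,
            (n_window - n_peak) * ttaa_peak / max(ttaa_window - ttaa_peak, 1),
        )
    return max(lam, cfg.pseudocount)


def _density_center(positions: np.ndarray, start: int, end: int, width: int) -> int:
    """Insertion position maximising the count in a width-bp neighbourhood.

    Ties broken by leftmost position for determinism.
    """
    mask = (positions >= start) & (positions < end)
    pos = positions[mask]
    if pos.size == 0:
        return (start + end) // 2
    half = max(width // 2, 1)
    lo = np.searchsorted(pos, pos - half, "left")
    hi = np.searchsorted(pos, pos + half, "right")
    counts = hi - lo
    return int(pos[int(np.argmax(counts))])


def _resolve_mode(bkg: InsertionSet | None, cfg: CallerConfig) -> tuple[InsertionSet | None, CallerConfig]:
    if bkg is not None and len(bkg) == 0:
        logger.warning("background set is empty; falling back to background-free mode")
        bkg = None
    mode = "with_background" if bkg is not None else "background_free"
    return bkg, replace(cfg, mode=mode)


@dataclass(frozen=True)
class _Candidate:
    chrom: str
    start: int  # first insertion position
    end: int    # last insertion position + TTAA_WIDTH


def _test_candidates(
    candidates: list[_Candidate],
    exp: InsertionSet,
    bkg: InsertionSet | None,
    ttaa: TTAAIndex,
    cfg: CallerConfig,
    keep_all: bool = False,
) -> PeakSet:
    """Score candidate intervals and keep those passing the cutoff.

    With ``keep_all`` every tested candidate is returned regardless of
    its p-value (used for calibration diagnostics).
    """
    total_exp = len(exp)
    total_bkg = len(bkg) if bkg is not None else 0
    known_chroms = set(ttaa.chromosomes)

    tested: list[tuple[_Candidate, int, int, int, float, float, int]] = []
    for cand in candidates:
        if cand.chrom not in known_chroms:
            logger.warning(
                "dropping candidate on %s: chromosome absent from TTAA index",
                cand.chrom,
            )
            continue
        n_exp = exp.count_in(cand.chrom, cand.start, cand.end)
        if n_exp < cfg.min_insertions:
            continue
        n_ttaa = ttaa.count(cand.chrom, cand.start, cand.end)
        if cfg.mode == "with_background":
            lam, n_bkg = _lambda_with_background(
                cand.chrom, cand.start, cand.end, bkg, ttaa, total_exp, total_bkg, cfg
            )
        else:
            lam = _lambda_background_free(
                cand.chrom, cand.start, cand.end, exp, ttaa, cfg
            )
            n_bkg = 0
        p = poisson_upper_tail(n_exp, lam)
        center = _density_center(
            exp.positions(cand.chrom), cand.start, cand.end, cfg.window
        )
        tested.append((cand, n_exp, n_bkg, n_ttaa, lam, p, center))

    if not tested:
        return PeakSet()
    pvals = np.array([t[5] for t in tested])
    qvals = adjust_pvalues(pvals) if cfg.multiple_testing == "BH" else pvals.copy()
    cutoff = cfg.cutoff()
    selector = qvals if cfg.multiple_testing == "BH" else pvals
    peaks = []
    for (cand, n_exp, n_bkg, n_ttaa, lam, p, center), q, sel in zip(
        tested, qvals, selector
    ):
        if keep_all or sel <= cutoff:
            peaks.append(
                Peak(
                    chrom=cand.chrom,
                    start=max(0, cand.start - cfg.extend),
                    end=cand.end + cfg.extend,
                    n_exp=n_exp, n_bkg=n_bkg, n_ttaa=n_ttaa,
                    lam=lam, pvalue=p, qvalue=float(q), center=center,
                )
            )
    return PeakSet(peaks)


# ---------------------------------------------------------------------------
# CCcaller
# ---------------------------------------------------------------------------

def greedy_blocks(positions: np.ndarray, maxbetween: int) -> list[tuple[int, int]]:
    """Partition sorted positions into blocks with gaps <= maxbetween.

    Returns (start_index, end_index) pairs into ``positions`` (half-open).
    Every position lands in exactly one block.
    """
    n = len(positions)
    if n == 0:
        return []
    gaps = np.diff(positions)
    breaks = np.flatnonzero(gaps > maxbetween) + 1
    bounds = np.concatenate(([0], breaks, [n]))
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]


def call_cccaller(
    exp: InsertionSet,
    bkg: InsertionSet | None,
    ttaa: TTAAIndex,
    cfg: CallerConfig | None = None,
    keep_all: bool = False,
) -> PeakSet:
    """Greedy single-pass peak caller.

    Scans sorted insertion positions per chromosome, extending a
    candidate block while the next insertion is within ``maxbetween`` bp,
    then tests each block against the Poisson null.
    """
    cfg = cfg or CallerConfig()
    if len(exp) == 0:
        raise ValueError("experiment insertion set is empty")
    bkg, cfg = _resolve_mode(bkg, cfg)

    candidates = []
    for chrom in exp.chromosomes:
        pos = exp.positions(chrom)
        for i, j in greedy_blocks(pos, cfg.maxbetween):
            candidates.append(
                _Candidate(chrom, int(pos[i]), int(pos[j - 1]) + TTAA_WIDTH)
            )
    return _test_candidates(candidates, exp, bkg, ttaa, cfg, keep_all=keep_all)


# ---------------------------------------------------------------------------
# MACCs
# ---------------------------------------------------------------------------

def _enriched_windows(
    chrom: str,
    exp: InsertionSet,
    bkg: InsertionSet | None,
    ttaa: TTAAIndex,
    cfg: CallerConfig,
) -> list[tuple[int, int]]:
    """Window/step scan; returns enriched windows on one chromosome."""
    pos = exp.positions(chrom)
    if len(pos) == 0:
        return []
    total_exp, total_bkg = len(exp), len(bkg) if bkg is not None else 0
    lo = max(0, (int(pos[0]) // cfg.step) * cfg.step - cfg.window)
    hi = int(pos[-1]) + TTAA_WIDTH
    cutoff = cfg.cutoff()
    out = []
    for w_start in range(lo, hi, cfg.step):
        w_end = w_start + cfg.window
        n = exp.count_in(chrom, w_start, w_end)
        if n < 1:
            continue
        if cfg.mode == "with_background":
            lam, _ = _lambda_with_background(
                chrom, w_start, w_end, bkg, ttaa, total_exp, total_bkg, cfg
            )
        else:
            lam = _lambda_background_free(chrom, w_start, w_end, exp, ttaa, cfg)
        if poisson_upper_tail(n, lam) <= cutoff:
            out.append((w_start, w_end))
    return out


def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent half-open intervals."""
    if not windows:
        return []
    merged = [windows[0]]
    for s, e in windows[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def call_maccs(
    exp: InsertionSet,
    bkg: InsertionSet | None,
    ttaa: TTAAIndex,
    cfg: CallerConfig | None = None,
    keep_all: bool = False,
) -> PeakSet:
    """Window-scan peak caller.

    Enriched windows are merged, each merged candidate is re-centred on
    the position with maximal local insertion density, trimmed to the
    span of its insertions, and re-tested exactly as in CCcaller.
    """
    cfg = cfg or CallerConfig()
    if len(exp) == 0:
        raise ValueError("experiment insertion set is empty")
    bkg, cfg = _resolve_mode(bkg, cfg)

    candidates = []
    for chrom in exp.chromosomes:
        pos = exp.positions(chrom)
        merged = _merge_windows(_enriched_windows(chrom, exp, bkg, ttaa, cfg))
        for m_start, m_end in merged:
            center = _density_center(pos, m_start, m_end, cfg.window)
            half = cfg.window // 2
            sel_lo, sel_hi = center - half, center + half
            lo = np.searchsorted(pos, max(m_start, sel_lo), "left")
            hi = np.searchsorted(pos, min(m_end, sel_hi), "right")
            if hi <= lo:
                lo = np.searchsorted(pos, m_start, "left")
                hi = np.searchsorted(pos, m_end, "left")
                if hi <= lo:
                    continue
            candidates.append(
                _Candidate(chrom, int(pos[lo]), int(pos[hi - 1]) + TTAA_WIDTH)
            )
    # re-centering can produce identical trimmed intervals; deduplicate
    candidates = sorted(set(candidates), key=lambda c: (c.chrom, c.start, c.end))
    candidates = _drop_nested(candidates)
    return _test_candidates(candidates, exp, bkg, ttaa, cfg, keep_all=keep_all)


def _drop_nested(candidates: list[_Candidate]) -> list[_Candidate]:
    """Remove candidates fully contained in (or overlapping) a previous one.

    Keeps the final peak set non-overlapping, a precondition of the
    assignment step downstream.
    """
    out: list[_Candidate] = []
    for cand in candidates:
        if out and out[-1].chrom == cand.chrom and cand.start < out[-1].end:
            prev = out[-1]
            out[-1] = _Candidate(prev.chrom, prev.start, max(prev.end, cand.end))
        else:
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Blockify / Bayesian Blocks
# ---------------------------------------------------------------------------

def default_ncp_prior(n: int, p0: float = 0.05) -> float:
    """Scargle's calibrated change-point prior for event data."""
    return 4.0 - math.log(73.53 * p0 * n ** -0.478)


def bayesian_blocks_events(
    positions: np.ndarray, ncp_prior: float | None = None
) -> list[tuple[int, int]]:
    """Optimal segmentation of 1-D event positions into blocks.

    Dynamic program maximising sum over blocks of N (log N - log T)
    minus ``ncp_prior`` per block, with Voronoi cell edges at midpoints
    between consecutive distinct positions.  Returns (start_idx,
    end_idx) half-open index pairs into the sorted unique positions.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        return []
    uniq, counts = np.unique(pos, return_counts=True)
    n_events = int(counts.sum())
    if ncp_prior is None:
        ncp_prior = default_ncp_prior(n_events)
    m = len(uniq)
    if m == 1:
        return [(0, 1)]
    edges = np.concatenate(
        ([uniq[0]], 0.5 * (uniq[1:] + uniq[:-1]), [uniq[-1]])
    )
    block_len_right = edges[-1] - edges  # length from edge k to the end
    csum = np.concatenate(([0], np.cumsum(counts)))

    best = np.zeros(m)
    last = np.zeros(m, dtype=int)
    for k in range(m):
        # widths of blocks [j..k] and their event counts, vectorized over j
        widths = block_len_right[: k + 1] - block_len_right[k + 1]
        widths = np.maximum(widths, 1.0)  # floor for zero-width degenerate blocks
        ncounts = csum[k + 1] - csum[: k + 1]
        fitness = ncounts * (np.log(ncounts) - np.log(widths)) - ncp_prior
        total = fitness + np.concatenate(([0], best[:k]))
        i_max = int(np.argmax(total))
        best[k] = total[i_max]
        last[k] = i_max

    # backtrack change points
    blocks = []
    k = m
    while k > 0:
        j = last[k - 1]
        blocks.append((int(j), int(k)))
        k = j
    blocks.reverse()
    return blocks


def blocks_score(
    positions: np.ndarray, blocks: list[tuple[int, int]], ncp_prior: float
) -> float:
    """Total fitness of a given segmentation (same convention as the DP)."""
    pos = np.asarray(positions, dtype=float)
    uniq, counts = np.unique(pos, return_counts=True)
    edges = (
        np.concatenate(([uniq[0]], 0.5 * (uniq[1:] + uniq[:-1]), [uniq[-1]]))
        if len(uniq) > 1
        else np.array([uniq[0], uniq[0]])
    )
    csum = np.concatenate(([0], np.cumsum(counts)))
    total = 0.0
    for j, k in blocks:
        n = csum[k] - csum[j]
        t = max(edges[k] - edges[j], 1.0)
        total += n * (math.log(n) - math.log(t)) - ncp_prior
    return total


def call_blockify(
    exp: InsertionSet,
    bkg: InsertionSet | None,
    ttaa: TTAAIndex,
    cfg: CallerConfig | None = None,
    keep_all: bool = False,
) -> PeakSet:
    """Bayesian-Blocks peak caller: segment events, then test each block."""
    cfg = cfg or CallerConfig()
    if len(exp) == 0:
        raise ValueError("experiment insertion set is empty")
    bkg, cfg = _resolve_mode(bkg, cfg)

    candidates = []
    for chrom in exp.chromosomes:
        pos = exp.positions(chrom)
        uniq = np.unique(pos)
        for j, k in bayesian_blocks_events(pos, cfg.ncp_prior):
            candidates.append(
                _Candidate(chrom, int(uniq[j]), int(uniq[k - 1]) + TTAA_WIDTH)
            )
    return _test_candidates(candidates, exp, bkg, ttaa, cfg, keep_all=keep_all)


CALLERS = {
    "cccaller": call_cccaller,
    "maccs": call_maccs,
    "blockify": call_blockify,
}


def call_peaks(method: str, exp, bkg, ttaa, cfg=None, **kw) -> PeakSet:
    """Dispatch to a caller by name ('cccaller', 'maccs' or 'blockify')."""
    try:
        fn = CALLERS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(CALLERS)}"
        ) from None
    return fn(exp, bkg, ttaa, cfg, **kw)
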