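"""Poisson peak calling against a control, blacklist filtering, replicate
reproducibility, and the cross-genotype analysis universe.

The caller is a deliberately simplified fixed-bin analogue of the classic
local-lambda approach: treatment fragment midpoints are counted in fixed-width
bins and tested against a Poisson rate taken as the maximum of the genome-wide
rate and depth-scaled control rates in 5 kb and 10 kb windows centered on the
bin. Significant bins closer than one fragment length are merged; the summit
is the most-occupied treatment bin of the merged region (leftmost on ties).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval, Peak, overlaps, summit_window

MIN_P = 1e-300  # floor keeping emitted p-values inside (0, 1]


@dataclass
class ReproducibilityReport:
    """ENCODE-style pseudo-replicate consistency bookkeeping.

    ``rescue_ratio`` compares the peak yields of the two pooled
    pseudo-replicates; ``self_consistency_ratio`` compares the per-replicate
    self-consistent peak counts. Both are >= 1 by construction and the sample
    is acceptable iff both are < 2.
    """

    n_rep1: int
    n_rep2: int
    n_pooled: int
    n_pooled_pr1: int
    n_pooled_pr2: int
    n_pseudo1: int
    n_pseudo2: int
    rescue_ratio: float
    self_consistency_ratio: float
    acceptable: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _ratio(a: int, b: int) -> float:
    lo, hi = min(a, b), max(a, b)
    if lo == 0:
        return math.inf if hi > 0 else 1.0
    return hi / lo


def _midpoint_counts(
    fragments: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    bin_width: int,
) -> dict[str, np.ndarray]:
    mids: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    for frag in fragments:
        entry = mids.get(frag.chrom)
        if entry is None:
            raise ValueError(f"fragment on unknown chromosome {frag.chrom!r}")
        entry.append((frag.start + frag.end) // 2)
    counts: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        n_bins = -(-size // bin_width)
        bins = np.minimum(
            np.asarray(mids[chrom], dtype=np.int64) // bin_width, n_bins - 1
        )
        counts[chrom] = np.bincount(bins, minlength=n_bins)
    return counts


def _windowed_rate(counts: np.ndarray, half_bins: int) -> np.ndarray:
    """Mean count per bin in a centered window, with edge truncation."""
    n = len(counts)
    c = np.concatenate([[0], np.cumsum(counts)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - half_bins)
    hi = np.minimum(n, idx + half_bins + 1)
    return (c[hi] - c[lo]) / (hi - lo)


def bin_enrichment_pvalues(
    treatment: Sequence[GenomicInterval],
    control: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    bin_width: int = 100,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-bin Poisson upper-tail p-values of treatment midpoint counts
    against the local control rate ``max(genome, 5 kb, 10 kb)``.

    Returns ``(pvalues, treatment_counts)`` keyed by chromosome.
    """
    if not treatment or not control:
        raise ValueError("treatment and control fragment sets must be non-empty")
    t_counts = _midpoint_counts(treatment, chrom_sizes, bin_width)
    c_counts = _midpoint_counts(control, chrom_sizes, bin_width)
    scale = len(treatment) / len(control)
    total_bins = sum(len(v) for v in t_counts.values())
    lam_genome = len(treatment) / total_bins
    half5 = max(1, 2500 // bin_width)
    half10 = max(1, 5000 // bin_width)
    pvalues: dict[str, np.ndarray] = {}
    for chrom in chrom_sizes:
        t = t_counts[chrom]
        c = c_counts[chrom].astype(float) * scale
        lam = np.maximum(
            lam_genome,
            np.maximum(_windowed_rate(c, half5), _windowed_rate(c, half10)),
        )
        pvalues[chrom] = stats.poisson.sf(t - 1, lam)
    return pvalues, t_counts


def call_peaks(
    treatment: Sequence[GenomicInterval],
    control: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    p_threshold: float = 1e-2,
    bin_width: int = 100,
    merge_distance: int | None = None,
) -> list[Peak]:
    """Call enriched bins of ``treatment`` against a depth-scaled ``control``.

    ``merge_distance`` defaults to the mean treatment fragment length.
    Returns peaks sorted by position, each carrying its minimum bin p-value
    and a ``-log10(p)`` score.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError("p_threshold must be in (0, 1]")
    if merge_distance is None:
        merge_distance = int(
            round(sum(f.length for f in treatment) / max(1, len(treatment)))
        )
    pvalues, t_counts = bin_enrichment_pvalues(
        treatment, control, chrom_sizes, bin_width
    )

    peaks: list[Peak] = []
    for chrom in chrom_sizes:
        t = t_counts[chrom]
        p = pvalues[chrom]
        sig = np.flatnonzero(p <= p_threshold)
        if len(sig) == 0:
            continue
        # merge significant bins separated by at most merge_distance
        breaks = np.flatnonzero((np.diff(sig) - 1) * bin_width > merge_distance)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(sig) - 1]])
        size = chrom_sizes[chrom]
        for s, e in zip(starts, ends):
            b0, b1 = int(sig[s]), int(sig[e])
            region = GenomicInterval(
                chrom, b0 * bin_width, min((b1 + 1) * bin_width, size)
            )
            local = t[b0 : b1 + 1]
            summit_bin = b0 + int(np.argmax(local))
            summit = min(
                summit_bin * bin_width + bin_width // 2, region.end - 1
            )
            p_min = max(float(p[b0 : b1 + 1].min()), MIN_P)
            peaks.append(
                Peak(
                    interval=region,
                    summit_offset=summit - region.start,
                    score=-math.log10(p_min),
                    p_value=p_min,
                )
            )
    peaks.sort(key=lambda pk: (pk.interval.chrom, pk.interval.start))
    return peaks


def filter_blacklist(
    peaks: Sequence[Peak], blacklist: Sequence[GenomicInterval]
) -> list[Peak]:
    """Drop peaks overlapping any blacklist interval by >= 1 bp."""
    if not blacklist:
        return list(peaks)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in blacklist:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept = []
    for p in peaks:
        bad = any(overlaps(p.interval, iv) for iv in by_chrom.get(p.chrom, ()))
        if not bad:
            kept.append(p)
    return kept


def _window_index(
    peaks: Sequence[Peak],
    flank: int,
    chrom_sizes: Mapping[str, int] | None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome sorted (starts, ends) arrays of summit windows."""
    windows: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        w = summit_window(p, flank=flank, chrom_sizes=chrom_sizes)
        windows.setdefault(w.chrom, []).append((w.start, w.end))
    out = {}
    for chrom, ivs in windows.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        # running max makes the binary-search overlap test valid even if
        # windows are not end-sorted
        out[chrom] = (starts, np.maximum.accumulate(ends))
    return out


def _hits_window(
    index: Mapping[str, tuple[np.ndarray, np.ndarray]], w: GenomicInterval
) -> bool:
    entry = index.get(w.chrom)
    if entry is None:
        return False
    starts, run_max_ends = entry
    k = int(np.searchsorted(starts, w.end, side="left"))
    if k == 0:
        return False
    return bool(run_max_ends[k - 1] > w.start)


def reproduced_peak_set(
    peaks_rep1: Sequence[Peak],
    peaks_rep2: Sequence[Peak],
    peaks_pooled: Sequence[Peak],
    flank: int = 250,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Peak]:
    """Pooled peaks whose summit windows overlap a window in *both*
    replicates (>= 1 bp). The pooled peak (and its summit) is retained."""
    idx1 = _window_index(peaks_rep1, flank, chrom_sizes)
    idx2 = _window_index(peaks_rep2, flank, chrom_sizes)
    out = []
    for p in peaks_pooled:
        w = summit_window(p, flank=flank, chrom_sizes=chrom_sizes)
        if _hits_window(idx1, w) and _hits_window(idx2, w):
            out.append(p)
    return out


def cross_genotype_peak_set(
    peaks_wt: Sequence[Peak],
    peaks_mut: Sequence[Peak],
    flank: int = 250,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Peak]:
    """Union of the two genotype peak sets with summit-window merging.

    Peaks whose summit windows overlap transitively collapse into one; the
    highest-scoring member of each chain is kept (its summit included).
    """
    pool = sorted(
        list(peaks_wt) + list(peaks_mut),
        key=lambda p: (p.interval.chrom, p.summit),
    )
    merged: list[Peak] = []
    current: Peak | None = None
    current_end = -1
    for p in pool:
        w = summit_window(p, flank=flank, chrom_sizes=chrom_sizes)
        if (
            current is not None
            and w.chrom == current.interval.chrom
            and w.start < current_end
        ):
            current_end = max(current_end, w.end)
            if p.score > current.score:
                current = p
        else:
            if current is not None:
                merged.append(current)
            current = p
            current_end = w.end
    if current is not None:
        merged.append(current)
    return merged


def _split_fragments(
    fragments: Sequence[GenomicInterval], rng: np.random.Generator
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    order = rng.permutation(len(fragments))
    half = len(fragments) // 2
    a = [fragments[i] for i in sorted(order[:half])]
    b = [fragments[i] for i in sorted(order[half:])]
    if not a or not b:
        raise ValueError("pseudo-replicate with zero fragments")
    return a, b


def consistency_ratios(
    fragments_rep1: Sequence[GenomicInterval],
    fragments_rep2: Sequence[GenomicInterval],
    control: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    p_threshold: float = 1e-2,
    bin_width: int = 100,
    flank: int = 250,
    seed: int = 0,
) -> ReproducibilityReport:
    """Rescue and self-consistency ratios from seeded pseudo-replicate splits.

    Pooled pseudo-replicates are random halves of the union of both
    replicates; self pseudo-replicates are random halves of each replicate.
    Self-consistent counts use the pooled-and-both-halves overlap rule.
    """
    rng = np.random.default_rng(seed)

    def _call(frags: Sequence[GenomicInterval]) -> list[Peak]:
        return call_peaks(
            frags, control, chrom_sizes, p_threshold=p_threshold, bin_width=bin_width
        )

    peaks1 = _call(fragments_rep1)
    peaks2 = _call(fragments_rep2)
    pooled_frags = list(fragments_rep1) + list(fragments_rep2)
    peaks_pooled = _call(pooled_frags)

    pr1, pr2 = _split_fragments(pooled_frags, rng)
    n_pooled_pr1 = len(_call(pr1))
    n_pooled_pr2 = len(_call(pr2))

    self_counts = []
    for frags, own_peaks in ((fragments_rep1, peaks1), (fragments_rep2, peaks2)):
        h1, h2 = _split_fragments(frags, rng)
        reproduced = reproduced_peak_set(
            _call(h1), _call(h2), own_peaks, flank=flank, chrom_sizes=chrom_sizes
        )
        self_counts.append(len(reproduced))

    rr = _ratio(n_pooled_pr1, n_pooled_pr2)
    sr = _ratio(self_counts[0], self_counts[1])
    return ReproducibilityReport(
        n_rep1=len(peaks1),
        n_rep2=len(peaks2),
        n_pooled=len(peaks_pooled),
        n_pooled_pr1=n_pooled_pr1,
        n_pooled_pr2=n_pooled_pr2,
        n_pseudo1=self_counts[0],
        n_pseudo2=self_counts[1],
        rescue_ratio=rr,
        self_consistency_ratio=sr,
        acceptable=bool(rr < 2.0 and sr < 2.0),
    )
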