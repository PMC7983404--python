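"""Group-level outputs: summit-centered profile matrices and average
profiles, ranked signal curves, per-group depletion summaries, and partner
co-localization counts."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CoverageTrack, GenomicInterval, Peak, mean_signal, summit_window
from .differential import GROUP1, GROUP2, GROUP3, SIGNAL_COLUMNS, log2_fold_change


@dataclass
class ProfileMatrix:
    """Per-peak signal in fixed bins centered on summits, row-ranked."""

    matrix: np.ndarray  # (n_peaks, n_bins)
    bin_width: int
    window_flank: int
    row_order: list[str]  # peak ids, ranking statistic descending

    @property
    def n_bins(self) -> int:
        return 2 * self.window_flank // self.bin_width


def _window_signal(
    track: CoverageTrack,
    chrom: str,
    start: int,
    end: int,
) -> float:
    """Mean signal over [start, end), zero-padding outside the chromosome."""
    length = end - start
    lo = max(0, start)
    if lo >= end:
        return 0.0
    covered = mean_signal(track, GenomicInterval(chrom, lo, end)) * (end - lo)
    return covered / length


def profile_matrix(
    track: CoverageTrack,
    peaks: Sequence[Peak],
    ranking_values: Sequence[float],
    peak_ids: Sequence[str] | None = None,
    window_flank: int = 1000,
    bin_width: int = 100,
) -> ProfileMatrix:
    """Resample ``track`` into ``2*window_flank/bin_width`` bins centered on
    each peak summit; rows are sorted by ``ranking_values`` descending, ties
    broken by peak id."""
    if len(ranking_values) != len(peaks):
        raise ValueError("ranking_values must align with peaks")
    if peak_ids is None:
        peak_ids = [p.name or f"peak_{i + 1:05d}" for i, p in enumerate(peaks)]
    n_bins = 2 * window_flank // bin_width
    order = sorted(
        range(len(peaks)), key=lambda i: (-ranking_values[i], peak_ids[i])
    )
    mat = np.zeros((len(peaks), n_bins))
    for row, i in enumerate(order):
        p = peaks[i]
        left = p.summit - window_flank
        for k in range(n_bins):
            mat[row, k] = _window_signal(
                track, p.chrom, left + k * bin_width, left + (k + 1) * bin_width
            )
    return ProfileMatrix(
        matrix=mat,
        bin_width=bin_width,
        window_flank=window_flank,
        row_order=[peak_ids[i] for i in order],
    )


def average_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Column-wise mean; permutation-invariant to row order."""
    if matrix.matrix.shape[0] == 0:
        raise ValueError("empty profile matrix")
    return matrix.matrix.mean(axis=0)


def ranked_signal_curve(
    table: pd.DataFrame,
    signal_column: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Peaks ranked by mean binder signal across genotypes (descending);
    emits ``log10(value + pseudocount)`` of the requested column per rank."""
    if signal_column not in SIGNAL_COLUMNS:
        raise ValueError(
            f"unknown signal column {signal_column!r}; expected one of "
            f"{SIGNAL_COLUMNS}"
        )
    ranking = (table["flag_wt"].to_numpy() + table["flag_mut"].to_numpy()) / 2.0
    order = np.lexsort((table["peak_id"].to_numpy(), -ranking))
    values = np.log10(table[signal_column].to_numpy()[order] + pseudocount)
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "peak_id": table["peak_id"].to_numpy()[order],
            "group": table["group"].to_numpy()[order],
            f"log10_{signal_column}": values,
        }
    )


def depletion_summary(table: pd.DataFrame, pseudocount: float = 0.5) -> dict:
    """Per-group signal statistics plus a rank-sum comparison of partner
    fold changes between groups 1 and 2.

    Groups with no peaks are omitted. The rank-sum entry is present only when
    both compared groups are non-empty.
    """
    if "group" not in table.columns or (table["group"] == "").all():
        raise ValueError("groups not assigned; run partition_groups first")
    cp_log2fc = log2_fold_change(
        table["cp190_wt"].to_numpy(), table["cp190_mut"].to_numpy(), pseudocount
    )
    summary: dict = {"groups": {}}
    for group in (GROUP1, GROUP2, GROUP3):
        mask = (table["group"] == group).to_numpy()
        if not mask.any():
            continue
        sub = table[mask]
        entry = {"n": int(mask.sum())}
        for col in SIGNAL_COLUMNS:
            entry[f"mean_{col}"] = float(sub[col].mean())
            entry[f"median_{col}"] = float(sub[col].median())
        entry["mean_cp190_log2fc"] = float(cp_log2fc[mask].mean())
        summary["groups"][group] = entry
    g1 = cp_log2fc[(table["group"] == GROUP1).to_numpy()]
    g2 = cp_log2fc[(table["group"] == GROUP2).to_numpy()]
    if len(g1) > 0 and len(g2) > 0:
        stat, p = stats.ranksums(g1, g2)
        summary["cp190_log2fc_ranksum_g1_vs_g2"] = {
            "statistic": float(stat),
            "p_value": float(p),
        }
    return summary


def _standardize(
    peaks: Sequence[Peak] | Sequence[GenomicInterval],
    flank: int,
    chrom_sizes: Mapping[str, int] | None,
) -> list[GenomicInterval]:
    out = []
    for p in peaks:
        if isinstance(p, Peak):
            out.append(summit_window(p, flank=flank, chrom_sizes=chrom_sizes))
        else:
            out.append(p)
    return out


def _overlap_any(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean per query: overlaps (>= 1 bp) any subject interval."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in subjects:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    index = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        index[chrom] = (starts, ends)
    out = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        entry = index.get(q.chrom)
        if entry is None:
            continue
        starts, run_max_ends = entry
        k = int(np.searchsorted(starts, q.end, side="left"))
        out[i] = k > 0 and bool(run_max_ends[k - 1] > q.start)
    return out


def colocalization_counts(
    reference_peaks: Sequence[Peak],
    cp190_peaks: Sequence[Peak] | Sequence[GenomicInterval],
    partner_sets: Mapping[str, Sequence[GenomicInterval]],
    flank: int = 250,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Split reference peaks by partner-protein co-binding and count overlaps
    with each named partner set plus their union ("either of" semantics).

    Rows: ``with_cp190`` / ``without_cp190``. Columns: split size, per-partner
    overlap counts and fractions, and the union count/fraction.
    """
    if not reference_peaks:
        raise ValueError("empty reference peak set")
    ref_windows = _standardize(reference_peaks, flank, chrom_sizes)
    cp_windows = _standardize(cp190_peaks, flank, chrom_sizes)
    with_cp = _overlap_any(ref_windows, cp_windows)

    rows = {}
    for label, mask in (("with_cp190", with_cp), ("without_cp190", ~with_cp)):
        subset = [w for w, m in zip(ref_windows, mask) if m]
        row: dict = {"n": len(subset)}
        union = np.zeros(len(subset), dtype=bool)
        for name, intervals in partner_sets.items():
            hits = _overlap_any(subset, list(intervals))
            union |= hits
            row[f"n_{name}"] = int(hits.sum())
            row[f"frac_{name}"] = float(hits.mean()) if len(subset) else 0.0
        row["n_any_partner"] = int(union.sum())
        row["frac_any_partner"] = float(union.mean()) if len(subset) else 0.0
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def write_profile_matrix(matrix: ProfileMatrix, tsv_path: str, meta_path: str) -> None:
    df = pd.DataFrame(matrix.matrix, index=matrix.row_order)
    df.columns = [
        f"bin_{-matrix.window_flank + k * matrix.bin_width}"
        for k in range(matrix.matrix.shape[1])
    ]
    df.to_csv(tsv_path, sep="\t", index_label="peak_id", float_format="%.10g")
    with open(meta_path, "w") as fh:
        json.dump(
            {
                "bin_width": matrix.bin_width,
                "window_flank": matrix.window_flank,
                "n_peaks": int(matrix.matrix.shape[0]),
                "n_bins": int(matrix.matrix.shape[1]),
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def plot_profiles(
    profiles: Mapping[str, np.ndarray],
    bin_width: int,
    window_flank: int,
    path: str,
) -> None:
    """Optional PNG/SVG export of average profiles (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(-window_flank, window_flank, bin_width) + bin_width / 2
    for label, prof in profiles.items():
        ax.plot(x, prof, label=label)
    ax.set_xlabel("distance from summit (bp)")
    ax.set_ylabel("mean signal (RPKM)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
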