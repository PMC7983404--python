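"""Per-peak signal table, log2 fold changes, iterative one-sided Grubbs
outlier detection, and the three-group partition.

The partition groups a universe of peaks by two flags:

* ``GROUP1`` — peaks with a motif whose wild-type/mutant fold change is an
  upper outlier (binding depends on the interaction under study),
* ``GROUP2`` — motif peaks that are not outliers,
* ``GROUP3`` — peaks without a motif (outliers among them are flagged but
  stay in group 3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import RPKM, CoverageTrack, Peak, mean_signal, summit_window

logger = logging.getLogger(__name__)

GROUP1 = "GROUP1"
GROUP2 = "GROUP2"
GROUP3 = "GROUP3"

SIGNAL_COLUMNS = ("flag_wt", "flag_mut", "cp190_wt", "cp190_mut")

#: column order of the signal-table TSV
TABLE_COLUMNS = (
    "peak_id",
    "chrom",
    "start",
    "end",
    "summit",
    "flag_wt",
    "flag_mut",
    "cp190_wt",
    "cp190_mut",
    "log2fc_flag",
    "has_motif",
    "is_outlier",
    "group",
)


@dataclass
class GrubbsResult:
    """Trace of the iterative procedure, in detection order."""

    outlier_indices: list[int] = field(default_factory=list)
    statistics: list[float] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)


def grubbs_upper(values: Sequence[float]) -> tuple[float, int]:
    """One-sided upper Grubbs statistic ``(max - mean) / sd`` (sd with N-1
    denominator) and the index of the maximum (leftmost on ties)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"Grubbs test needs N >= 3, got {n}")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("sample standard deviation is zero; untestable sample")
    idx = int(np.argmax(x))
    g = (x[idx] - x.mean()) / sd
    return float(g), idx


def grubbs_p_value(g: float, n: int) -> float:
    """p-value of the one-sided upper statistic for sample size ``n``.

    Inverts the critical-value relation
    ``G_crit(alpha, n) = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2))`` with ``t``
    the upper ``alpha/n`` quantile of Student's t with ``n-2`` degrees of
    freedom, so that ``p < alpha`` exactly when ``g > G_crit(alpha, n)``.
    The result is clipped to [0, 1].
    """
    if n < 3:
        raise ValueError(f"Grubbs test needs N >= 3, got {n}")
    if g <= 0.0:
        return 1.0
    u = g * math.sqrt(n) / (n - 1)
    if u >= 1.0:
        return 0.0
    t = math.sqrt((n - 2) * u * u / (1.0 - u * u))
    p = n * stats.t.sf(t, n - 2)
    return float(min(1.0, max(0.0, p)))


def iterative_grubbs(
    values: Sequence[float],
    alpha: float = 0.05,
    max_iter: int | None = None,
) -> GrubbsResult:
    """Repeatedly detect and remove the upper outlier while ``p < alpha``.

    Indices refer to positions in the original input; removed values never
    re-enter. Iteration stops cleanly when fewer than 3 values remain or the
    remaining values are constant.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError(f"Grubbs test needs N >= 3, got {len(x)}")
    if max_iter is None:
        max_iter = len(x)
    remaining = list(range(len(x)))
    result = GrubbsResult(alpha=alpha)
    while len(remaining) >= 3 and len(result.outlier_indices) < max_iter:
        sub = x[remaining]
        if sub.std(ddof=1) == 0.0:
            break
        g, local_idx = grubbs_upper(sub)
        p = grubbs_p_value(g, len(sub))
        if not p < alpha:
            break
        result.outlier_indices.append(remaining.pop(local_idx))
        result.statistics.append(g)
        result.p_values.append(p)
    return result


def log2_fold_change(
    numerator: np.ndarray, denominator: np.ndarray, pseudocount: float = 0.5
) -> np.ndarray:
    return np.log2((numerator + pseudocount) / (denominator + pseudocount))


def build_signal_table(
    peaks: Sequence[Peak],
    tracks: Mapping[str, CoverageTrack],
    motif_flags: Sequence[bool],
    pseudocount: float = 0.5,
    flank: int = 250,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """One row per peak: mean RPKM over the summit window in each of the four
    samples, the wild-type/mutant fold change of the binder signal, and the
    motif flag. Group assignment is left to :func:`partition_groups`."""
    missing = [k for k in SIGNAL_COLUMNS if k not in tracks]
    if missing:
        raise ValueError(f"missing tracks: {missing}")
    for name in SIGNAL_COLUMNS:
        if tracks[name].normalization != RPKM:
            raise ValueError(f"track {name!r} must be RPKM-normalized")
    if len(motif_flags) != len(peaks):
        raise ValueError("need exactly one motif flag per peak")

    rows = []
    for i, peak in enumerate(peaks):
        w = summit_window(peak, flank=flank, chrom_sizes=chrom_sizes)
        signals = {name: mean_signal(tracks[name], w) for name in SIGNAL_COLUMNS}
        rows.append(
            {
                "peak_id": peak.name or f"peak_{i + 1:05d}",
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "summit": peak.summit,
                **signals,
                "has_motif": bool(motif_flags[i]),
            }
        )
    table = pd.DataFrame(rows)
    table["log2fc_flag"] = log2_fold_change(
        table["flag_wt"].to_numpy(), table["flag_mut"].to_numpy(), pseudocount
    )
    table["is_outlier"] = False
    table["group"] = ""
    table.attrs["pseudocount"] = pseudocount
    return table[list(TABLE_COLUMNS)]


def assign_groups(has_motif: Sequence[bool], is_outlier: Sequence[bool]) -> list[str]:
    """Group labels from the two per-peak flags (see module docstring)."""
    labels = []
    for m, o in zip(has_motif, is_outlier, strict=True):
        if not m:
            labels.append(GROUP3)
        elif o:
            labels.append(GROUP1)
        else:
            labels.append(GROUP2)
    return labels


def group_sizes(table: pd.DataFrame) -> dict[str, int]:
    """Bookkeeping summary: per-group counts plus the universe total."""
    counts = table["group"].value_counts()
    return {
        GROUP1: int(counts.get(GROUP1, 0)),
        GROUP2: int(counts.get(GROUP2, 0)),
        GROUP3: int(counts.get(GROUP3, 0)),
        "total": int(len(table)),
    }


def partition_groups(
    table: pd.DataFrame,
    alpha: float = 0.05,
    min_fold: float | None = None,
) -> tuple[pd.DataFrame, dict[str, GrubbsResult]]:
    """Run iterative Grubbs separately on the fold-change distributions of the
    motif and the no-motif subsets and assign groups.

    Motif-subset outliers become group 1. No-motif outliers are flagged in
    ``is_outlier`` but remain group 3. ``min_fold``, if given, additionally
    requires ``(flag_wt + c) / (flag_mut + c) >= min_fold`` for group 1
    membership (an optional stricter reading of "depleted").
    """
    table = table.copy()
    results: dict[str, GrubbsResult] = {}
    outlier = np.zeros(len(table), dtype=bool)
    for label, mask in (
        ("motif", table["has_motif"].to_numpy()),
        ("non_motif", ~table["has_motif"].to_numpy()),
    ):
        idx = np.flatnonzero(mask)
        if len(idx) < 3:
            logger.warning(
                "subset %r has %d peaks (< 3); no outlier test run", label, len(idx)
            )
            results[label] = GrubbsResult(alpha=alpha)
            continue
        values = table["log2fc_flag"].to_numpy()[idx]
        try:
            res = iterative_grubbs(values, alpha=alpha)
        except ValueError:
            logger.warning("subset %r untestable; no outliers flagged", label)
            res = GrubbsResult(alpha=alpha)
        results[label] = res
        outlier[idx[res.outlier_indices]] = True

    if min_fold is not None:
        c = table.attrs.get("pseudocount", 0.5)
        fold = (table["flag_wt"].to_numpy() + c) / (table["flag_mut"].to_numpy() + c)
        outlier &= fold >= min_fold

    table["is_outlier"] = outlier
    table["group"] = assign_groups(
        table["has_motif"].to_numpy(), table["is_outlier"].to_numpy()
    )
    table.attrs["grubbs"] = {k: v.to_dict() for k, v in results.items()}
    return table, results


def write_signal_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_signal_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
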