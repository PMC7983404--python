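"""Position weight matrix scoring, exact tail-probability thresholds, and
double-strand scanning.

Scores are log2 odds against an i.i.d. background. To make the threshold
machinery exact and conservative, per-position scores are discretized onto an
``epsilon``-grid by rounding *down*; the same discretized scores are used both
to build the score distribution (dynamic programming over positions) and to
score scanned windows, so the achieved tail probability of any returned
threshold is exactly the DP tail and is <= the requested p-value whenever that
is attainable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GenomicInterval, ParseError, Peak, summit_window

ALPHABET = "ACGT"
DEFAULT_EPSILON = 1e-3

_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass(frozen=True)
class PWM:
    """Count-based position weight matrix with a background model.

    ``log_odds[i, n] = log2(((counts[i, n] + pseudocount * background[n]) /
    (sum_n counts[i, n] + pseudocount)) / background[n])``.
    """

    counts: np.ndarray  # (L, 4), order A C G T
    background: np.ndarray  # (4,)
    pseudocount: float = 1.0
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "background", background)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be an (L, 4) matrix in A,C,G,T order")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if background.shape != (4,) or np.any(background <= 0):
            raise ValueError("background must be 4 positive frequencies")
        if abs(background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        row_tot = self.counts.sum(axis=1, keepdims=True)
        probs = (self.counts + self.pseudocount * self.background) / (
            row_tot + self.pseudocount
        )
        return np.log2(probs / self.background)

    @property
    def quantized(self) -> np.ndarray:
        """Integer scores: ``floor(log_odds / epsilon)`` per position/base."""
        return np.floor(self.log_odds / self.epsilon).astype(np.int64)

    @property
    def discretized_log_odds(self) -> np.ndarray:
        return self.quantized * self.epsilon

    @property
    def max_score(self) -> float:
        return float(self.discretized_log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.discretized_log_odds.min(axis=1).sum())

    def consensus(self) -> str:
        """Highest-scoring word (leftmost base on ties)."""
        return "".join(ALPHABET[n] for n in np.argmax(self.log_odds, axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            counts=self.counts[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            epsilon=self.epsilon,
        )


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    score: float


def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def load_pwm(
    path: str,
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
) -> PWM:
    """Load a whitespace-separated count matrix.

    Rows are positions and columns A C G T; a 4-row matrix with more than 4
    columns is transposed. An optional non-numeric header line is skipped.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", ">")):
                continue
            fields = line.split()
            try:
                values = [float(x) for x in fields]
            except ValueError:
                if not rows:
                    continue  # header line (e.g. "A C G T")
                raise ParseError(f"non-numeric matrix entry in {line!r}", path, i)
            rows.append(values)
    if not rows:
        raise ParseError("empty PWM file", path)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError("ragged PWM matrix", path)
    mat = np.asarray(rows, dtype=float)
    if mat.shape[1] != 4:
        if mat.shape[0] == 4:
            mat = mat.T
        else:
            raise ParseError(
                f"PWM matrix must have 4 columns (A,C,G,T), got {mat.shape[1]}", path
            )
    if np.any(mat < 0):
        raise ParseError("negative PWM counts", path)
    bg = uniform_background() if background is None else np.asarray(background, float)
    return PWM(counts=mat, background=bg, pseudocount=pseudocount)


def write_pwm(pwm: PWM, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: A C G T; rows: motif positions\n")
        for row in pwm.counts:
            fh.write("\t".join(f"{x:.17g}" for x in row) + "\n")


def score_distribution(pwm: PWM) -> tuple[np.ndarray, int]:
    """Exact distribution of the discretized word score under the background.

    Returns ``(probs, offset)`` where ``probs[k]`` is the probability of
    integer score ``k + offset`` for a word drawn i.i.d. from the background.
    """
    q = pwm.quantized
    bg = pwm.background
    dist = np.array([1.0])
    offset = 0
    for i in range(pwm.length):
        qi = q[i]
        lo, hi = int(qi.min()), int(qi.max())
        new = np.zeros(len(dist) + hi - lo)
        for n in range(4):
            shift = int(qi[n]) - lo
            new[shift : shift + len(dist)] += dist * bg[n]
        dist = new
        offset += lo
    return dist, offset


def score_threshold(pwm: PWM, p_value: float) -> float:
    """Smallest discretized score whose background tail probability is
    <= ``p_value``; the maximum attainable score if no score qualifies."""
    t, _ = score_threshold_with_pvalue(pwm, p_value)
    return t


def score_threshold_with_pvalue(pwm: PWM, p_value: float) -> tuple[float, float]:
    """As :func:`score_threshold`, also returning the achieved tail
    probability at the threshold."""
    if not (0.0 < p_value <= 1.0):
        raise ValueError("p_value must be in (0, 1]")
    dist, offset = score_distribution(pwm)
    tail = np.cumsum(dist[::-1])[::-1]
    ok = np.flatnonzero((tail <= p_value) & (dist > 0))
    if len(ok) == 0:
        # even the best word exceeds the requested tail mass
        best = int(np.flatnonzero(dist > 0)[-1])
        return (best + offset) * pwm.epsilon, float(tail[best])
    k = int(ok[0])
    return (k + offset) * pwm.epsilon, float(tail[k])


_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a nucleotide string to indices 0..3 (A,C,G,T); other symbols -> 4."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _window_scores(idx: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Discretized score of every length-L window; NaN where a window has N."""
    L = scores.shape[0]
    n_win = len(idx) - L + 1
    if n_win <= 0:
        return np.empty(0)
    # per-position score rows get a 5th NaN entry so index 4 (non-ACGT)
    # poisons every window that contains it
    total = np.zeros(n_win)
    for i in range(L):
        row = np.append(scores[i], np.nan)  # index 4 -> NaN
        total += row[idx[i : i + n_win]]
    return total


def scan(
    sequence: str,
    pwm: PWM,
    threshold: float,
    strands: str = "both",
    chrom: str = "seq",
) -> list[MotifHit]:
    """Report every window scoring >= ``threshold`` on the requested strands.

    Reverse-strand windows are scored on the reverse complement and reported
    in forward coordinates. Windows containing non-ACGT symbols are skipped.
    Sequences shorter than the motif yield an empty list.
    """
    if strands not in ("both", "+", "-"):
        raise ValueError(f"strands must be 'both', '+' or '-', got {strands!r}")
    idx = encode_sequence(sequence)
    L = pwm.length
    if len(idx) < L:
        return []
    hits: list[MotifHit] = []
    strand_list = ["+", "-"] if strands == "both" else [strands]
    for strand in strand_list:
        mat = (
            pwm.discretized_log_odds
            if strand == "+"
            else pwm.reverse_complement().discretized_log_odds
        )
        total = _window_scores(idx, mat)
        pos = np.flatnonzero(~np.isnan(total) & (total >= threshold))
        for j in pos:
            hits.append(
                MotifHit(
                    GenomicInterval(chrom, int(j), int(j) + L),
                    strand,
                    float(total[j]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def annotate_motif_peaks(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    pwm: PWM,
    p_value: float = 1e-4,
    search_flank: int = 250,
    window_flank: int = 250,
    chrom_sizes: Mapping[str, int] | None = None,
    threshold: float | None = None,
) -> list[bool]:
    """Flag each peak true iff a motif hit overlaps its summit window extended
    by ``search_flank`` on both sides."""
    if threshold is None:
        threshold = score_threshold(pwm, p_value)
    sizes = chrom_sizes or {c: len(s) for c, s in genome.items()}
    L = pwm.length
    flags: list[bool] = []
    for peak in peaks:
        if peak.chrom not in genome:
            raise ValueError(f"peak chromosome {peak.chrom!r} absent from genome")
        w = summit_window(peak, flank=window_flank, chrom_sizes=sizes)
        lo = max(0, w.start - search_flank)
        hi = min(sizes[peak.chrom], w.end + search_flank)
        # scan a margin so hits merely overlapping [lo, hi) are found
        scan_lo = max(0, lo - (L - 1))
        scan_hi = min(sizes[peak.chrom], hi + (L - 1))
        seq = genome[peak.chrom][scan_lo:scan_hi]
        found = False
        for hit in scan(seq, pwm, threshold):
            s = scan_lo + hit.interval.start
            e = scan_lo + hit.interval.end
            if s < hi and e > lo:
                found = True
                break
        flags.append(found)
    return flags


def write_hits_bed(hits: Iterable[MotifHit], path: str) -> None:
    with open(path, "w") as fh:
        for k, h in enumerate(hits):
            fh.write(
                f"{h.interval.chrom}\t{h.interval.start}\t{h.interval.end}"
                f"\tmotif_{k + 1}\t{h.score:.6g}\t{h.strand}\n"
            )
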