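"""Synthetic ChIP-seq experiment generator with ground-truth annotations.

Produces a random genome with planted motif words, per-peak expected fragment
intensities for two pull-down targets ("flag" for the tagged binder, "cp190"
for its recruited partner) in two genotypes, and aligned, deduplicated
fragment intervals for every sample/genotype/replicate plus genotype-matched
input controls. Everything is a pure function of ``(scenario, seed)``.

Fragment midpoints follow a mixture of a uniform background and Gaussian
bumps at peak centers. Per-peak intensities are stored in the truth table so
downstream recovery can be scored against a known answer:

* depleted peaks: ``flag_mut = factor * flag_wt`` with a per-peak realized
  ``factor <= depletion_factor`` (heterogeneous severities: peaks lose *at
  least* the nominal fold), and
  ``cp190_mut = cp190_wt * (1 - cp190_coupling * (1 - factor))``
* all other peaks: genotype-independent intensities.

Setting ``depletion_severity = 0`` makes every depleted peak lose exactly
``depletion_factor``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval, write_bed, write_chrom_sizes
from .motif import ALPHABET, PWM, uniform_background, write_pwm

SAMPLES = ("flag", "cp190", "input")
GENOTYPES = ("wt", "mut")

# minimum center-to-center spacing between planted peaks
PEAK_SPACING = 2_000
EDGE_MARGIN = 1_000
# Gaussian bump SD as a fraction of the mean fragment length
BUMP_SD_FACTOR = 0.5
# half-width of the nominal peak footprint used both for truth intervals and
# for calibrating the mean fold-enrichment over the footprint
PEAK_HALF_WIDTH = 250
# per-peak extra depletion severity (log2 units) is Exponential(depletion
# _severity) capped here; severity 0 reproduces the exact depletion_factor
MAX_DEPLETION_SEVERITY = 6.0


@dataclass
class SyntheticScenario:
    """Full parameterization of a simulated two-genotype ChIP experiment."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr2L": 2_000_000, "chr2R": 2_000_000}
    )
    n_peaks: int = 300
    motif_fraction: float = 0.5
    depleted_fraction: float = 0.1
    flag_enrichment: float = 8.0
    depletion_factor: float = 0.25
    cp190_coupling: float = 0.9
    background_rate: float = 0.04
    fragment_length_mean: float = 156.0
    fragment_length_sd: float = 30.0
    read_depth: int = 200_000
    n_replicates: int = 2
    intensity_spread: float = 0.25  # lognormal sigma of per-peak intensity
    depletion_severity: float = 1.5  # mean extra log2 depletion per peak
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("motif_fraction", "depleted_fraction", "cp190_coupling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.flag_enrichment <= 1.0:
            raise ValueError("flag_enrichment must be > 1")
        if not (0.0 < self.depletion_factor < 1.0):
            raise ValueError("depletion_factor must be in (0, 1)")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be > 0")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        if self.n_peaks < 0 or self.n_replicates < 1:
            raise ValueError("n_peaks must be >= 0 and n_replicates >= 1")
        if self.depletion_severity < 0:
            raise ValueError("depletion_severity must be >= 0")

    @property
    def bump_sd(self) -> float:
        return self.fragment_length_mean * BUMP_SD_FACTOR

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticScenario":
        return cls(**dict(d))


@dataclass(frozen=True)
class TruePeakRecord:
    """Ground-truth annotation of one planted peak."""

    interval: GenomicInterval
    has_motif: bool
    is_depleted: bool
    flag_lambda_wt: float
    flag_lambda_mut: float
    cp190_lambda_wt: float
    cp190_lambda_mut: float

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


def default_pwm() -> PWM:
    """Deterministic, strongly informative 15-position count matrix."""
    consensus = "TGCGTGGCCACGTAC"
    counts = np.full((len(consensus), 4), 5.0)
    for i, base in enumerate(consensus):
        counts[i, ALPHABET.index(base)] = 85.0
    return PWM(counts=counts, background=uniform_background())


def _footprint_capture(scenario: SyntheticScenario) -> float:
    """Expected coverage (bp) a single peak fragment contributes inside the
    nominal +-``PEAK_HALF_WIDTH`` footprint, for midpoints drawn from the
    Gaussian bump. Computed by deterministic numeric integration."""
    sigma = scenario.bump_sd
    half_len = scenario.fragment_length_mean / 2.0
    f = PEAK_HALF_WIDTH
    m = np.linspace(-f - 2 * half_len, f + 2 * half_len, 4001)
    overlap = np.clip(
        np.minimum(m + half_len, f) - np.maximum(m - half_len, -f), 0.0, None
    )
    pdf = np.exp(-0.5 * (m / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))
    return float(np.trapezoid(overlap * pdf, m))


def _peak_intensity(scenario: SyntheticScenario) -> float:
    """Expected fragments per peak such that the mean fragment depth over the
    +-``PEAK_HALF_WIDTH`` footprint is ``flag_enrichment``-fold the uniform
    background depth."""
    excess_depth = (
        (scenario.flag_enrichment - 1.0)
        * scenario.background_rate
        * scenario.fragment_length_mean
    )
    return excess_depth * 2 * PEAK_HALF_WIDTH / _footprint_capture(scenario)


def simulate_genome(
    scenario: SyntheticScenario,
    seed: int | None = None,
    pwm: PWM | None = None,
) -> tuple[dict[str, str], list[TruePeakRecord]]:
    """Random genome plus ground-truth peak records.

    Peak centers sit on a lattice of ``PEAK_SPACING``-wide slots, which
    guarantees the minimum center spacing. Motif peaks get the PWM's
    maximum-score word planted at the peak center.
    """
    if seed is None:
        seed = scenario.seed
    if pwm is None:
        pwm = default_pwm()
    rng = np.random.default_rng([int(seed), 0x47])  # genome substream
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)

    # allocate peaks to chromosomes proportionally to length
    chroms = list(scenario.chrom_sizes)
    lengths = np.array([scenario.chrom_sizes[c] for c in chroms], dtype=float)
    raw = scenario.n_peaks * lengths / lengths.sum()
    alloc = np.floor(raw).astype(int)
    for i in np.argsort(raw - alloc)[::-1][: scenario.n_peaks - alloc.sum()]:
        alloc[i] += 1

    genome: dict[str, str] = {}
    truth: list[TruePeakRecord] = []
    base_intensity = _peak_intensity(scenario)
    consensus_idx = np.array(
        [ALPHABET.index(b) for b in pwm.consensus()], dtype=np.int64
    )
    for chrom, n_here in zip(chroms, alloc):
        size = scenario.chrom_sizes[chrom]
        seq = rng.integers(0, 4, size=size, dtype=np.int64)
        n_slots = (size - 2 * EDGE_MARGIN) // PEAK_SPACING
        if n_here > n_slots:
            raise ValueError(
                f"{n_here} peaks do not fit on {chrom} "
                f"({n_slots} slots at {PEAK_SPACING} bp spacing)"
            )
        slots = np.sort(rng.choice(n_slots, size=n_here, replace=False))
        centers = EDGE_MARGIN + slots * PEAK_SPACING + PEAK_SPACING // 2
        for center in centers:
            has_motif = bool(rng.random() < scenario.motif_fraction)
            is_depleted = bool(
                has_motif and rng.random() < scenario.depleted_fraction
            )
            if has_motif:
                L = pwm.length
                start = int(center) - L // 2
                seq[start : start + L] = consensus_idx
            lam_wt = base_intensity * rng.lognormal(0.0, scenario.intensity_spread)
            cp_wt = lam_wt
            if is_depleted:
                # per-peak realized factor <= depletion_factor: depleted peaks
                # lose *at least* the nominal fold, with heterogeneous severity
                severity = min(
                    rng.exponential(scenario.depletion_severity)
                    if scenario.depletion_severity > 0
                    else 0.0,
                    MAX_DEPLETION_SEVERITY,
                )
                factor = scenario.depletion_factor * 2.0 ** (-severity)
                lam_mut = factor * lam_wt
                cp_mut = cp_wt * (1.0 - scenario.cp190_coupling * (1.0 - factor))
            else:
                lam_mut = lam_wt
                cp_mut = cp_wt
            truth.append(
                TruePeakRecord(
                    interval=GenomicInterval(
                        chrom,
                        max(0, int(center) - PEAK_HALF_WIDTH),
                        min(size, int(center) + PEAK_HALF_WIDTH),
                    ),
                    has_motif=has_motif,
                    is_depleted=is_depleted,
                    flag_lambda_wt=lam_wt,
                    flag_lambda_mut=lam_mut,
                    cp190_lambda_wt=cp_wt,
                    cp190_lambda_mut=cp_mut,
                )
            )
        genome[chrom] = lookup[seq].tobytes().decode("ascii")
    return genome, truth


def _sample_scale(scenario: SyntheticScenario, truth: Sequence[TruePeakRecord],
                  sample: str) -> float:
    """Depth factor making the expected fragment count equal ``read_depth``.

    The factor is computed from the wild-type intensities for both genotypes,
    so expected per-peak mut/wt depth ratios equal the truth-table ratios.
    """
    background = scenario.background_rate * scenario.genome_length
    if sample == "input":
        expected = background
    elif sample == "flag":
        expected = background + sum(t.flag_lambda_wt for t in truth)
    else:
        expected = background + sum(t.cp190_lambda_wt for t in truth)
    return scenario.read_depth / expected


def simulate_fragments(
    scenario: SyntheticScenario,
    truth: Sequence[TruePeakRecord],
    sample: str,
    genotype: str,
    replicate: int = 1,
    seed: int | None = None,
) -> list[GenomicInterval]:
    """Aligned fragment intervals for one sample/genotype/replicate."""
    if sample not in SAMPLES:
        raise ValueError(f"unknown sample {sample!r}; expected one of {SAMPLES}")
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(
        [int(seed), SAMPLES.index(sample), GENOTYPES.index(genotype), int(replicate)]
    )
    scale = _sample_scale(scenario, truth, sample)
    sd = scenario.bump_sd
    lo, hi = 50.0, 2.0 * scenario.fragment_length_mean
    a = (lo - scenario.fragment_length_mean) / scenario.fragment_length_sd
    b = (hi - scenario.fragment_length_mean) / scenario.fragment_length_sd

    fragments: list[GenomicInterval] = []
    for chrom, size in scenario.chrom_sizes.items():
        n_bg = rng.poisson(scale * scenario.background_rate * size)
        mids = [rng.uniform(0, size, size=n_bg)]
        if sample != "input":
            for rec in truth:
                if rec.interval.chrom != chrom:
                    continue
                if sample == "flag":
                    lam = (
                        rec.flag_lambda_wt if genotype == "wt"
                        else rec.flag_lambda_mut
                    )
                else:
                    lam = (
                        rec.cp190_lambda_wt if genotype == "wt"
                        else rec.cp190_lambda_mut
                    )
                n = rng.poisson(scale * lam)
                if n:
                    mids.append(rng.normal(rec.center, sd, size=n))
        midpoints = np.concatenate(mids)
        lengths = stats.truncnorm.rvs(
            a, b,
            loc=scenario.fragment_length_mean,
            scale=scenario.fragment_length_sd,
            size=len(midpoints),
            random_state=rng,
        )
        starts = np.maximum(0, np.rint(midpoints - lengths / 2.0).astype(np.int64))
        ends = np.minimum(
            size, starts + np.maximum(1, np.rint(lengths).astype(np.int64))
        )
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
        order = np.argsort(starts, kind="stable")
        fragments.extend(
            GenomicInterval(chrom, s, e)
            for s, e in zip(starts[order].tolist(), ends[order].tolist())
        )
    return fragments


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_genome_fasta(genome: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_tsv(truth: Sequence[TruePeakRecord], path: str) -> None:
    cols = (
        "chrom\tstart\tend\thas_motif\tis_depleted\t"
        "flag_lambda_wt\tflag_lambda_mut\tcp190_lambda_wt\tcp190_lambda_mut\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for t in truth:
            fh.write(
                f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}\t"
                f"{int(t.has_motif)}\t{int(t.is_depleted)}\t"
                f"{t.flag_lambda_wt:.17g}\t{t.flag_lambda_mut:.17g}\t"
                f"{t.cp190_lambda_wt:.17g}\t{t.cp190_lambda_mut:.17g}\n"
            )


def read_truth_tsv(path: str) -> list[TruePeakRecord]:
    truth: list[TruePeakRecord] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            truth.append(
                TruePeakRecord(
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    has_motif=bool(int(f[3])),
                    is_depleted=bool(int(f[4])),
                    flag_lambda_wt=float(f[5]),
                    flag_lambda_mut=float(f[6]),
                    cp190_lambda_wt=float(f[7]),
                    cp190_lambda_mut=float(f[8]),
                )
            )
    return truth


def fragment_file_name(sample: str, genotype: str, replicate: int | None) -> str:
    if sample == "input":
        return f"input_{genotype}.bed"
    return f"{sample}_{genotype}_rep{replicate}.bed"


def write_fixture_set(
    scenario: SyntheticScenario,
    out_dir: str,
    pwm: PWM | None = None,
) -> dict:
    """Write a complete on-disk fixture: genome FASTA, PWM, chrom sizes,
    truth TSV, scenario JSON, and one fragment BED per sample/genotype/
    replicate plus one input control per genotype. Returns a manifest with
    per-file SHA-256 checksums and record counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if pwm is None:
        pwm = default_pwm()
    genome, truth = simulate_genome(scenario, pwm=pwm)

    files: dict[str, dict] = {}

    def _register(name: str, n_records: int | None = None) -> None:
        entry: dict = {"sha256": _sha256(out / name)}
        if n_records is not None:
            entry["n_records"] = n_records
        files[name] = entry

    write_genome_fasta(genome, str(out / "genome.fa"))
    _register("genome.fa", len(genome))
    write_chrom_sizes(scenario.chrom_sizes, str(out / "chrom.sizes"))
    _register("chrom.sizes", len(scenario.chrom_sizes))
    write_pwm(pwm, str(out / "pwm.txt"))
    _register("pwm.txt", pwm.length)
    write_truth_tsv(truth, str(out / "truth.tsv"))
    _register("truth.tsv", len(truth))
    with open(out / "scenario.json", "w") as fh:
        json.dump(scenario.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    _register("scenario.json")

    for sample in ("flag", "cp190"):
        for genotype in GENOTYPES:
            for rep in range(1, scenario.n_replicates + 1):
                frags = simulate_fragments(scenario, truth, sample, genotype, rep)
                name = fragment_file_name(sample, genotype, rep)
                write_bed(frags, str(out / name))
                _register(name, len(frags))
    for genotype in GENOTYPES:
        frags = simulate_fragments(scenario, truth, "input", genotype, 1)
        name = fragment_file_name("input", genotype, None)
        write_bed(frags, str(out / name))
        _register(name, len(frags))

    manifest = {"seed": scenario.seed, "files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
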