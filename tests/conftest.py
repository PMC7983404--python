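"""Shared fixtures and the in-memory end-to-end pipeline helper."""

from __future__ import annotations

import numpy as np
import pytest

from chipdelta.core import coverage_from_fragments, rpkm_normalize
from chipdelta.differential import build_signal_table, partition_groups
from chipdelta.motif import annotate_motif_peaks, score_threshold
from chipdelta.peaks import (
    call_peaks,
    cross_genotype_peak_set,
    reproduced_peak_set,
)
from chipdelta.simulate import (
    SyntheticScenario,
    default_pwm,
    simulate_fragments,
    simulate_genome,
)


@pytest.fixture(scope="session")
def pwm():
    return default_pwm()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_scenario():
    """Desk-scale scenario: fast but large enough for peak statistics."""
    return SyntheticScenario(
        chrom_sizes={"chrA": 400_000},
        n_peaks=40,
        read_depth=40_000,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_simulation(small_scenario):
    genome, truth = simulate_genome(small_scenario)
    return small_scenario, genome, truth


def run_end_to_end(scenario: SyntheticScenario, seed: int | None = None):
    """Full in-memory pipeline on a synthetic scenario.

    Returns ``(table, truth, genome)`` where ``table`` is the partitioned
    signal table of the cross-genotype universe.
    """
    if seed is not None:
        scenario = SyntheticScenario.from_dict(
            {**scenario.to_dict(), "seed": seed}
        )
    genome, truth = simulate_genome(scenario)
    pwm = default_pwm()
    frags = {
        (s, g): [
            simulate_fragments(scenario, truth, s, g, r)
            for r in range(1, scenario.n_replicates + 1)
        ]
        for s in ("flag", "cp190")
        for g in ("wt", "mut")
    }
    controls = {
        g: simulate_fragments(scenario, truth, "input", g, 1) for g in ("wt", "mut")
    }
    reproduced = {}
    for g in ("wt", "mut"):
        reps = frags[("flag", g)]
        calls = [call_peaks(r, controls[g], scenario.chrom_sizes) for r in reps]
        pooled = call_peaks(
            [f for r in reps for f in r], controls[g], scenario.chrom_sizes
        )
        reproduced[g] = reproduced_peak_set(
            calls[0], calls[1], pooled, chrom_sizes=scenario.chrom_sizes
        )
    universe = cross_genotype_peak_set(
        reproduced["wt"], reproduced["mut"], chrom_sizes=scenario.chrom_sizes
    )
    threshold = score_threshold(pwm, 1e-4)
    motif_flags = annotate_motif_peaks(
        universe, genome, pwm, chrom_sizes=scenario.chrom_sizes, threshold=threshold
    )
    tracks = {
        f"{s}_{g}": rpkm_normalize(
            coverage_from_fragments(
                [f for r in frags[(s, g)] for f in r], scenario.chrom_sizes
            )
        )
        for s in ("flag", "cp190")
        for g in ("wt", "mut")
    }
    table = build_signal_table(
        universe, tracks, motif_flags, chrom_sizes=scenario.chrom_sizes
    )
    table, _ = partition_groups(table)
    return table, truth, genome


def match_truth_groups(table, truth, tolerance: int = 300):
    """Map each truth record to the group of the nearest table row.

    Returns a list of (record, group-or-None) pairs.
    """
    mids = ((table["start"] + table["end"]) // 2).to_numpy()
    chroms = table["chrom"].to_numpy()
    groups = table["group"].to_numpy()
    out = []
    for rec in truth:
        mask = (chroms == rec.interval.chrom) & (
            np.abs(mids - rec.center) < tolerance
        )
        out.append((rec, groups[mask][0] if mask.any() else None))
    return out
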