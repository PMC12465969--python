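"""Crossover detection from phased trio haplotype tracks, and DNM to
crossover-breakpoint proximity with a trio-matched expectation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def detect_crossovers(positions, origins, min_block: int = 500):
    """Breakpoints from grandparental-origin switches along a chromosome.

    ``positions`` are sorted marker coordinates; ``origins`` label each
    marker's grandparental haplotype (any hashable, typically 0/1).
    Runs of identical origin shorter than ``min_block`` markers are
    treated as noise and masked.  Remaining same-origin neighbours are
    merged; each boundary between adjacent blocks of different origin
    yields a breakpoint at the midpoint of (last marker of the left
    block, first marker of the right block).
    """
    positions = np.asarray(positions)
    origins = np.asarray(origins)
    if len(positions) != len(origins):
        raise ValueError("positions and origins must align")
    if len(positions) == 0:
        return []
    if np.any(np.diff(positions) < 0):
        raise ValueError("marker positions must be sorted")

    # runs of identical origin
    change = np.flatnonzero(origins[1:] != origins[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(origins)]])
    blocks = [
        (positions[s], positions[e - 1], origins[s], e - s)
        for s, e in zip(starts, ends)
        if e - s >= min_block
    ]
    # merge adjacent valid blocks of identical origin (noise runs masked)
    merged = []
    for blk in blocks:
        if merged and merged[-1][2] == blk[2]:
            prev = merged[-1]
            merged[-1] = (prev[0], blk[1], prev[2], prev[3] + blk[3])
        else:
            merged.append(blk)
    if len(merged) < 2:
        return []
    return [
        (merged[i][1] + merged[i + 1][0]) / 2.0
        for i in range(len(merged) - 1)
    ]


def dnm_crossover_proximity(
    dnm_positions_by_trio: dict,
    breakpoints_by_trio: dict,
    genome_size: float,
    window_bp: float = 10_000,
):
    """Observed vs expected DNMs within a window of same-trio breakpoints.

    The expectation is trio-matched: each trio contributes
    n_dnm * n_breakpoints * 2*window / genome_size, the chance placement
    rate of its own mutations into its own breakpoint windows.  Returns
    (observed, expected, one-sided Poisson tail p).
    """
    max_bp = max((len(b) for b in breakpoints_by_trio.values()), default=0)
    if genome_size <= 2 * window_bp * max_bp:
        raise ValueError("breakpoint windows saturate the genome")
    observed = 0
    expected = 0.0
    for trio_id, dnms in dnm_positions_by_trio.items():
        bps = np.asarray(breakpoints_by_trio.get(trio_id, []), dtype=float)
        dnms = np.asarray(dnms, dtype=float)
        if len(bps) and len(dnms):
            near = np.abs(dnms[:, None] - bps[None, :]) <= window_bp
            observed += int(near.any(axis=1).sum())
        expected += len(dnms) * len(bps) * 2.0 * window_bp / genome_size
    p = float(stats.poisson.sf(observed - 1, expected)) if expected > 0 else 1.0
    return observed, expected, p
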