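"""GC-content computation, quintile binning and intron-level bootstrap.

Introns are ordered by GC content (of the full 8-30 bp region, in one
species' reference or as the mean of the two species) and split into k
near-equal bins; confidence intervals for any statistic are obtained by
resampling *introns* (not sites) with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["BinAssignment", "BootstrapResult", "compute_gc", "assign_bins", "bootstrap_ci"]


@dataclass
class BinAssignment:
    strategy: str  # "mean" or a species name
    bin_index: int  # 1-based, ordered by increasing GC
    intron_ids: list
    gc_range: tuple[float, float]


@dataclass
class BootstrapResult:
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_skipped: int = 0


def compute_gc(sequence_or_record, selector: str = "mean") -> float:
    """GC fraction of an SI region.

    Accepts a plain sequence (selector ignored) or an object with a
    ``gc_species`` mapping (an :class:`~sispec.annotation.IntronRecord`), for
    which ``selector`` is either a species name or ``"mean"`` (arithmetic
    mean of the two species' values).
    """
    if isinstance(sequence_or_record, str):
        seq = sequence_or_record.upper()
        counts = {b: seq.count(b) for b in "ACGT"}
        denom = sum(counts.values())
        if denom == 0:
            raise ValueError("GC content undefined: no unambiguous bases")
        return (counts["G"] + counts["C"]) / denom
    record = sequence_or_record
    if selector == "mean":
        vals = list(record.gc_species.values())
        if len(vals) != 2:
            raise ValueError("mean selector requires exactly two species GC values")
        return float(np.mean(vals))
    return float(record.gc_species[selector])


def assign_bins(
    introns: Sequence, strategy: str = "mean", k: int = 5
) -> list[BinAssignment]:
    """Split introns into ``k`` contiguous GC bins of near-equal size.

    Introns are stably sorted by the chosen GC value (ties broken by
    ``intron_id`` for determinism), cut into k groups of ``floor(N / k)``
    with the remainder appended to the final (highest-GC) bin — the split
    that yields four bins of 1865 and a final bin of 1867 from 9327.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(introns) < k:
        raise ValueError("need at least k introns")
    keyed = sorted(
        ((compute_gc(r, strategy), r.intron_id) for r in introns),
        key=lambda t: (t[0], t[1]),
    )
    base = len(keyed) // k
    bins = []
    start = 0
    for b in range(k):
        stop = start + base if b < k - 1 else len(keyed)
        members = keyed[start:stop]
        bins.append(
            BinAssignment(
                strategy=strategy,
                bin_index=b + 1,
                intron_ids=[m[1] for m in members],
                gc_range=(members[0][0], members[-1][0]),
            )
        )
        start = stop
    return bins


def bootstrap_ci(
    introns: Sequence,
    statistic: Callable[[Sequence], float],
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Percentile bootstrap CI, resampling introns with replacement.

    Replicates on which the statistic is undefined (raises or returns NaN)
    are skipped and counted; more than 10% skipped is an error.
    """
    rng = np.random.default_rng(seed)
    introns = list(introns)
    point = float(statistic(introns))
    values = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(introns), size=len(introns))
        sample = [introns[i] for i in idx]
        try:
            v = float(statistic(sample))
        except (ValueError, ZeroDivisionError, FloatingPointError):
            v = np.nan
        if np.isnan(v):
            skipped += 1
        else:
            values.append(v)
    if skipped > 0.1 * n_boot:
        raise RuntimeError(
            f"statistic undefined on {skipped}/{n_boot} bootstrap replicates"
        )
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        point=point, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot, n_skipped=skipped
    )
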