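"""Repetition partitioning, signal averaging and variability tables.

A repeated acquisition with R repetitions is partitioned into floor(R/k)
disjoint averaged images of k *consecutive* repetitions each (leftovers
dropped), so R=20 yields 20/10/6/5/4 images for k=1..5 — 45 averaged images in
total over that k range.  Coefficient-of-variation (CoV = SD/mean) tables per
(b value, k) and population standard deviations of fitted parameter maps are
the quantities every downstream comparison of acquisition schemes is built on.

SD convention: population (divide-by-n) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ivim import PARAM_NAMES, ParameterMaps
from .phantom import TraceStack

__all__ = [
    "AveragePartition",
    "partition_repetitions",
    "average_stack",
    "cov_table",
    "parameter_map_sd",
    "count_total_images",
]


@dataclass(frozen=True)
class AveragePartition:
    """Disjoint consecutive blocks of k repetitions each."""

    k: int
    total_reps: int
    blocks: tuple  # tuple of (start, stop) repetition index ranges

    @property
    def n_images(self) -> int:
        return len(self.blocks)


def partition_repetitions(total_reps: int, k: int) -> AveragePartition:
    """Split total_reps into floor(total_reps/k) consecutive k-blocks."""
    if not 1 <= k <= total_reps:
        raise ValueError(f"k must lie in [1, {total_reps}], got {k}")
    n_images = total_reps // k
    blocks = tuple((i * k, (i + 1) * k) for i in range(n_images))
    return AveragePartition(k=int(k), total_reps=int(total_reps), blocks=blocks)


def count_total_images(total_reps: int, k_range) -> int:
    """Total number of averaged images over a range of k (sum of floors)."""
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    return sum(total_reps // k for k in ks)


def average_stack(stack: TraceStack, partition: AveragePartition) -> TraceStack:
    """Arithmetic mean within each block, per voxel and b value."""
    if partition.total_reps != stack.n_reps:
        raise ValueError(
            f"partition assumes {partition.total_reps} repetitions, "
            f"stack has {stack.n_reps}"
        )
    out = np.stack(
        [stack.data[..., start:stop].mean(axis=-1) for start, stop in partition.blocks],
        axis=-1,
    )
    return TraceStack(data=out, bvalues=stack.bvalues)


def cov_table(
    stack: TraceStack,
    mask: np.ndarray,
    ks=None,
) -> pd.DataFrame:
    """CoV per (b value, number of averages k).

    For each k, the stack is partitioned and averaged, and masked voxel
    intensities of all averaged images are pooled per b value; the cell is the
    population SD divided by the mean of that pool.  Cells with non-positive
    mean are NaN (undefined CoV).  Returns a DataFrame indexed by b with one
    column per k.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape:
        raise ValueError(f"mask shape {mask.shape} != stack shape {stack.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    ks = list(ks) if ks is not None else list(range(1, stack.n_reps + 1))
    table = np.full((stack.bvalues.size, len(ks)), np.nan)
    for j, k in enumerate(ks):
        avg = average_stack(stack, partition_repetitions(stack.n_reps, k))
        pooled = avg.data[mask]  # (nvox, nb, n_images)
        mean = pooled.mean(axis=(0, 2))
        sd = pooled.std(axis=(0, 2))  # population convention
        valid = mean > 0
        table[valid, j] = sd[valid] / mean[valid]
    return pd.DataFrame(table, index=pd.Index(stack.bvalues, name="b"),
                        columns=pd.Index(ks, name="n_averages"))


def parameter_map_sd(maps, mask: np.ndarray) -> pd.DataFrame:
    """Population SD (and mean) of each IVIM parameter over masked voxels.

    ``maps`` is a single ParameterMaps or a sequence of them (one per averaged
    image); voxel values are pooled across all supplied maps before the SD is
    taken, matching the pooled-over-averaged-images evaluation grid.
    """
    if isinstance(maps, ParameterMaps):
        maps = [maps]
    if len(maps) == 0:
        raise ValueError("no parameter maps supplied")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rows = []
    for name in PARAM_NAMES:
        pooled = np.concatenate([m.get(name)[mask] for m in maps])
        rows.append(
            {"param": name, "sd": float(pooled.std()), "mean": float(pooled.mean()),
             "n_values": int(pooled.size)}
        )
    return pd.DataFrame(rows)
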