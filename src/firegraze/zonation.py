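"""Stratigraphically constrained zonation (CONISS) with broken-stick testing.

CONISS agglomerates depth-adjacent clusters, at each step merging the
neighbouring pair whose union least increases the total within-cluster sum
of squares.  For clusters A and B the increase is the Ward increment

    dSS = (n_A * n_B) / (n_A + n_B) * ||mean_A - mean_B||^2 .

Proportions are square-root transformed by default before clustering.  The
number of significant zones follows the broken-stick comparison: the k-th
split (splits taken in reverse merge order) is significant while the share
of total dispersion it explains exceeds

    b_k = (1/n) * sum_{i=k..n} 1/i ,

counted from the first split down to the first failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ComputationError, ConfigError, Chronology


@dataclass
class ZonationResult:
    #: ordered merges: (left-block start, right-block start, dispersion increase)
    merges: list
    n_significant_zones: int
    #: ages of significant zone boundaries (midpoints between adjacent samples)
    boundary_ages: list


def _transform(props: np.ndarray, transform: str) -> np.ndarray:
    if transform == "sqrt":
        return np.sqrt(props)
    if transform == "none":
        return props
    raise ConfigError(f"unknown transform {transform!r}")


def coniss(proportions, transform: str = "sqrt") -> list[tuple[int, int, float]]:
    """Constrained incremental sum-of-squares clustering.

    ``proportions`` is a taxa x samples matrix (samples in stratigraphic
    order).  Returns the merge sequence as tuples
    ``(left_first_sample, right_first_sample, dispersion_increase)``.
    """
    x = np.asarray(proportions, dtype=float).T  # samples x taxa
    n = x.shape[0]
    if n < 2:
        raise ComputationError("need at least 2 samples to cluster")
    x = _transform(x, transform)

    # contiguous blocks: (first sample index, size, sum vector)
    starts = list(range(n))
    sizes = [1] * n
    sums = [x[i].copy() for i in range(n)]
    merges: list[tuple[int, int, float]] = []

    def cost(i: int) -> float:
        na, nb = sizes[i], sizes[i + 1]
        diff = sums[i] / na - sums[i + 1] / nb
        return na * nb / (na + nb) * float(diff @ diff)

    while len(starts) > 1:
        costs = [cost(i) for i in range(len(starts) - 1)]
        i = int(np.argmin(costs))
        merges.append((starts[i], starts[i + 1], costs[i]))
        sums[i] = sums[i] + sums[i + 1]
        sizes[i] += sizes[i + 1]
        del starts[i + 1], sizes[i + 1], sums[i + 1]
    return merges


def broken_stick_expectation(n: int) -> np.ndarray:
    """b_k for k = 1..n: expected dispersion shares under the broken-stick null."""
    inv = 1.0 / np.arange(1, n + 1)
    return inv[::-1].cumsum()[::-1] / n


def broken_stick_zones(merges) -> int:
    """Number of significant zones from a CONISS merge sequence.

    Splits are the merges in reverse order; the k-th split is significant
    while its share of total dispersion exceeds the broken-stick value b_k.
    Counting stops at the first failure; identical samples give one zone.
    """
    costs = np.asarray([m[2] for m in merges], dtype=float)
    total = costs.sum()
    if total == 0:
        return 1
    shares = costs[::-1] / total
    b = broken_stick_expectation(len(costs) + 1)
    k = 0
    while k < len(shares) and shares[k] > b[k]:
        k += 1
    return k + 1


def zonation(
    proportions: pd.DataFrame,
    chron: Chronology,
    transform: str = "sqrt",
) -> ZonationResult:
    """Full zonation of a taxa x samples proportion table.

    Boundary ages are midpoints between the adjacent samples separated by
    each of the significant splits (the last ``n_zones - 1`` merges).
    """
    merges = coniss(proportions.to_numpy(), transform=transform)
    n_zones = broken_stick_zones(merges)
    ages = chron.table.loc[list(proportions.columns), "age_calBP"].to_numpy()
    boundaries = []
    for left, right, _cost in merges[-(n_zones - 1):] if n_zones > 1 else []:
        boundaries.append(0.5 * (ages[right - 1] + ages[right]))
    return ZonationResult(
        merges=merges,
        n_significant_zones=n_zones,
        boundary_ages=sorted(boundaries),
    )
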