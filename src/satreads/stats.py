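"""Array-length distributions.

Because a read samples the genome uniformly, pooling the arrays detected
across all reads and histogramming their lengths estimates how the total
satellite content of the genome is partitioned among array-length classes.
Weighted histograms (each array contributes its length in bp) answer "how
much satellite DNA sits in arrays of this size"; count histograms answer
"how many arrays of this size were seen".  Truncated arrays are tallied
separately: their observed lengths are lower bounds on the genomic array
lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import RepeatArray

DEFAULT_BIN_WIDTH = 5_000
DEFAULT_LAST_BIN_FLOOR = 120_000


@dataclass
class LengthHistogram:
    """Per-bin array-length tallies for one repeat family.

    Bins are half-open ``[k*bin_width, (k+1)*bin_width)``; every array of
    length >= ``last_bin_floor`` pools into the terminal bin.  Weights are
    summed bp, counts are numbers of arrays; complete and truncated arrays
    are tallied separately (truncated lengths are lower bounds).
    """

    family_id: str
    bin_width: int
    last_bin_floor: int
    bin_starts: np.ndarray
    weight_complete: np.ndarray
    weight_truncated: np.ndarray
    count_complete: np.ndarray
    count_truncated: np.ndarray

    @property
    def total_bp(self) -> int:
        return int(self.weight_complete.sum() + self.weight_truncated.sum())

    def to_frame(self) -> pd.DataFrame:
        bin_ends = self.bin_starts + self.bin_width
        # the terminal bin is open-ended
        bin_ends = bin_ends.astype(object)
        if len(bin_ends):
            bin_ends[-1] = np.inf
        return pd.DataFrame(
            {
                "family_id": self.family_id,
                "bin_start": self.bin_starts,
                "bin_end": bin_ends,
                "weight_complete": self.weight_complete,
                "weight_truncated": self.weight_truncated,
                "count_complete": self.count_complete,
                "count_truncated": self.count_truncated,
            }
        )


def length_histogram(
    arrays: Sequence[RepeatArray],
    bin_width: int = DEFAULT_BIN_WIDTH,
    last_bin_floor: int = DEFAULT_LAST_BIN_FLOOR,
) -> LengthHistogram:
    """Weighted + count length histogram for the arrays of one family.

    Each array contributes weight equal to its length (bp) and count 1 to
    the bin containing its length; arrays of ``last_bin_floor`` bp or more
    pool into the terminal bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    families = {a.family_id for a in arrays}
    if len(families) > 1:
        raise ValueError(f"arrays span multiple families: {sorted(families)}")
    family_id = families.pop() if families else ""

    n_bins = last_bin_floor // bin_width + 1
    bin_starts = np.arange(n_bins, dtype=np.int64) * bin_width
    weight_c = np.zeros(n_bins)
    weight_t = np.zeros(n_bins)
    count_c = np.zeros(n_bins, dtype=np.int64)
    count_t = np.zeros(n_bins, dtype=np.int64)
    for a in arrays:
        idx = min(a.length // bin_width, n_bins - 1)
        if a.complete:
            weight_c[idx] += a.length
            count_c[idx] += 1
        else:
            weight_t[idx] += a.length
            count_t[idx] += 1
    return LengthHistogram(
        family_id, bin_width, last_bin_floor, bin_starts,
        weight_c, weight_t, count_c, count_t,
    )


def length_histograms(
    arrays: Iterable[RepeatArray],
    bin_width: int = DEFAULT_BIN_WIDTH,
    last_bin_floor: int = DEFAULT_LAST_BIN_FLOOR,
) -> dict[str, LengthHistogram]:
    """One :func:`length_histogram` per family present in ``arrays``."""
    by_family: dict[str, list[RepeatArray]] = {}
    for a in arrays:
        by_family.setdefault(a.family_id, []).append(a)
    return {
        family: length_histogram(group, bin_width, last_bin_floor)
        for family, group in sorted(by_family.items())
    }


def read_length_distribution(
    arrays: Iterable[RepeatArray],
    read_lengths: Mapping[str, int],
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> pd.DataFrame:
    """Histogram of the lengths of reads carrying each family.

    A control for length-distribution artifacts: if a family's arrays were
    preferentially observed on short reads, its apparent array lengths
    would be biased downward.  Each read counts once per family it carries,
    binned by ``bin_width`` into half-open bins keyed by bin start.
    """
    seen: set[tuple[str, str]] = set()
    rows = []
    for a in arrays:
        key = (a.family_id, a.read_id)
        if key in seen:
            continue
        seen.add(key)
        length = read_lengths[a.read_id]
        rows.append((a.family_id, (length // bin_width) * bin_width))
    if not rows:
        return pd.DataFrame(columns=["family_id", "bin_start", "n_reads"])
    frame = pd.DataFrame(rows, columns=["family_id", "bin_start"])
    out = (
        frame.groupby(["family_id", "bin_start"])
        .size()
        .rename("n_reads")
        .reset_index()
    )
    return out


def histograms_to_frame(histograms: Mapping[str, LengthHistogram]) -> pd.DataFrame:
    if not histograms:
        return pd.DataFrame(
            columns=["family_id", "bin_start", "bin_end", "weight_complete",
                     "weight_truncated", "count_complete", "count_truncated"]
        )
    return pd.concat([h.to_frame() for h in histograms.values()], ignore_index=True)
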