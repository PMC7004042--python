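"""Composition of the sequence flanking satellite arrays.

For every array of a focal family the 10-kb regions upstream (positions
-1..-10000) and downstream (1..10000) are read off the coded reads, after
rotating into the array's own frame: for a reverse-oriented array the
genomic right flank becomes upstream and the letter cases of the flank
codes are swapped, so all profiles are expressed relative to a
forward-oriented array.  Per-position proportions use as denominator the
number of arrays whose read actually extends that far (flanks cut short by
read ends shrink the denominator, they do not dilute the signal).

The same machinery profiles retroelement protein-domain hits (GAG, PROT,
RT, RH, aRH, INT) around the arrays, split by the domain's orientation
relative to the array; a fixed, ordered, orientation-consistent domain
layout demonstrates that the arrays sit at a defined position inside a
retrotransposon rather than being random neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import CodedRead, RepeatArray
from .io import DOMAINS, DomainHit

DEFAULT_WINDOW = 10_000
DEFAULT_REPORT_THRESHOLD = 0.05


@dataclass(frozen=True)
class DomainCutoffs:
    """Quality cutoffs applied to protein-domain hits before profiling."""

    min_identity: float = 0.3
    min_similarity: float = 0.4
    min_aln_length_proportion: float = 0.7
    max_interruptions: int = 10
    max_length_proportion: float = 1.2


def _positions(window: int) -> np.ndarray:
    """Relative positions -window..-1, 1..window (no position 0)."""
    return np.concatenate([np.arange(-window, 0), np.arange(1, window + 1)])


@dataclass
class FlankProfile:
    """Per-position repeat composition of the oriented flanks of one family."""

    focal_family: str
    window: int
    positions: np.ndarray          # length 2*window, -window..-1, 1..window
    counts: dict[str, np.ndarray]  # code -> per-position counts
    n_available: np.ndarray        # per-position denominator
    n_arrays: int = 0

    def proportions(self) -> pd.DataFrame:
        """Wide table of per-position proportions, one column per code."""
        denom = np.where(self.n_available > 0, self.n_available, 1)
        data = {code: c / denom for code, c in sorted(self.counts.items())}
        frame = pd.DataFrame(data, index=pd.Index(self.positions, name="position"))
        return frame

    def report(self, threshold: float = DEFAULT_REPORT_THRESHOLD) -> pd.DataFrame:
        """Proportions restricted to codes exceeding ``threshold`` somewhere."""
        props = self.proportions()
        keep = [c for c in props.columns if props[c].max() > threshold]
        return props[keep]

    def to_frame(self) -> pd.DataFrame:
        props = self.proportions()
        long = props.reset_index().melt(
            id_vars="position", var_name="repeat_code", value_name="proportion"
        )
        long.insert(0, "focal_family", self.focal_family)
        avail = pd.Series(self.n_available, index=self.positions)
        long["n_available"] = long["position"].map(avail)
        return long


@dataclass
class DomainProfile:
    """Per-position, per-domain, per-relative-orientation hit proportions."""

    focal_family: str
    window: int
    positions: np.ndarray
    counts: dict[tuple[str, str], np.ndarray]  # (domain, "same"|"opposite")
    n_available: np.ndarray
    n_arrays: int = 0

    def proportions(self) -> pd.DataFrame:
        denom = np.where(self.n_available > 0, self.n_available, 1)
        data = {
            f"{domain}:{orient}": c / denom
            for (domain, orient), c in sorted(self.counts.items())
        }
        return pd.DataFrame(data, index=pd.Index(self.positions, name="position"))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        denom = np.where(self.n_available > 0, self.n_available, 1)
        for (domain, orient), c in sorted(self.counts.items()):
            for pos, count, avail in zip(self.positions, c, self.n_available):
                rows.append(
                    (self.focal_family, int(pos), domain, orient,
                     count / max(avail, 1), int(avail))
                )
        return pd.DataFrame(
            rows,
            columns=["focal_family", "position", "domain",
                     "relative_orientation", "proportion", "n_available"],
        )


# ---------------------------------------------------------------------------
# flank extraction


def _swapcase_array(chars: np.ndarray) -> np.ndarray:
    return np.char.swapcase(chars)


def _oriented_flanks(
    array: RepeatArray, read_len: int, window: int
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Genomic slices feeding the oriented upstream / downstream windows.

    Returns ((up_g0, up_g1, up_step_sign), (down_g0, down_g1, ...)) where the
    upstream window covers oriented positions -1..-window in that order and
    downstream covers 1..window.  For a forward array upstream is the genomic
    left flank walked leftwards; for a reverse array it is the genomic right
    flank walked rightwards.
    """
    if array.orientation == "forward":
        up = (array.start - 1, array.start - 1 - window, -1)
        down = (array.end, array.end + window, 1)
    else:
        up = (array.end, array.end + window, 1)
        down = (array.start - 1, array.start - 1 - window, -1)
    return up, down


def _extract_window(
    chars: np.ndarray, g0: int, g1: int, step: int, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Codes at oriented offsets 1..window along one flank, plus validity mask."""
    read_len = len(chars)
    genomic = g0 + step * np.arange(window)
    valid = (genomic >= 0) & (genomic < read_len)
    codes = np.full(window, "", dtype="<U1")
    codes[valid] = chars[genomic[valid]]
    return codes, valid


def flank_composition(
    coded_reads: Mapping[str, CodedRead] | Iterable[CodedRead],
    arrays: Sequence[RepeatArray],
    window: int = DEFAULT_WINDOW,
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> FlankProfile:
    """Per-position repeat composition of the flanks of the focal arrays.

    ``arrays`` must all belong to one (focal) family; ``coded_reads`` must
    cover every read carrying one of them.  Reverse arrays are mirrored and
    their flank codes case-swapped so the profile refers to forward-oriented
    arrays.  ``report_threshold`` is stored for :meth:`FlankProfile.report`.
    """
    if not isinstance(coded_reads, Mapping):
        coded_reads = {cr.read_id: cr for cr in coded_reads}
    families = {a.family_id for a in arrays}
    if len(families) > 1:
        raise ValueError(f"arrays span multiple families: {sorted(families)}")
    focal = families.pop() if families else ""

    positions = _positions(window)
    n_available = np.zeros(2 * window, dtype=np.int64)
    counts: dict[str, np.ndarray] = {}
    char_cache: dict[str, np.ndarray] = {}

    for array in arrays:
        if array.read_id not in coded_reads:
            raise KeyError(f"read {array.read_id!r} missing from coded reads")
        if array.read_id not in char_cache:
            cr = coded_reads[array.read_id]
            char_cache[array.read_id] = np.array(list(cr.to_string()), dtype="<U1")
        chars = char_cache[array.read_id]
        (u0, _u1, ustep), (d0, _d1, dstep) = _oriented_flanks(
            array, len(chars), window
        )
        up_codes, up_valid = _extract_window(chars, u0, _u1, ustep, window)
        down_codes, down_valid = _extract_window(chars, d0, _d1, dstep, window)
        if array.orientation == "reverse":
            up_codes = _swapcase_array(up_codes)
            down_codes = _swapcase_array(down_codes)

        # upstream positions -1..-window occupy indices window-1..0
        up_idx = window - 1 - np.arange(window)
        down_idx = window + np.arange(window)
        n_available[up_idx[up_valid]] += 1
        n_available[down_idx[down_valid]] += 1
        for codes, idx, valid in (
            (up_codes, up_idx, up_valid),
            (down_codes, down_idx, down_valid),
        ):
            for code in np.unique(codes[valid]):
                track = counts.setdefault(code, np.zeros(2 * window, dtype=np.int64))
                track[idx[valid & (codes == code)]] += 1

    return FlankProfile(focal, window, positions, counts, n_available, len(arrays))


# ---------------------------------------------------------------------------
# protein domains


def filter_domain_hits(
    hits: Iterable[DomainHit], cutoffs: DomainCutoffs | None = None
) -> list[DomainHit]:
    """Keep domain hits meeting all five quality cutoffs."""
    c = cutoffs or DomainCutoffs()
    return [
        h
        for h in hits
        if h.identity >= c.min_identity
        and h.similarity >= c.min_similarity
        and h.aln_length_proportion >= c.min_aln_length_proportion
        and h.interruptions <= c.max_interruptions
        and h.length_proportion <= c.max_length_proportion
    ]


def _relative_positions(
    array: RepeatArray, g_start: int, g_end: int, window: int
) -> np.ndarray:
    """Oriented relative positions covered by genomic interval [g_start, g_end).

    Positions inside the array or beyond the window are dropped; the result
    is a subset of -window..-1, 1..window.
    """
    genomic = np.arange(g_start, g_end)
    if array.orientation == "forward":
        rel = np.where(
            genomic < array.start,
            genomic - array.start,          # -1 just left of the array
            genomic - array.end + 1,        # +1 just right of the array
        )
        inside = (genomic >= array.start) & (genomic < array.end)
    else:
        rel = np.where(
            genomic >= array.end,
            -(genomic - array.end + 1),     # genomic right flank is upstream
            array.start - genomic,          # genomic left flank is downstream
        )
        inside = (genomic >= array.start) & (genomic < array.end)
    keep = ~inside & (np.abs(rel) <= window)
    return rel[keep]


def domain_profile(
    domain_hits: Iterable[DomainHit],
    arrays: Sequence[RepeatArray],
    read_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
) -> DomainProfile:
    """Domain-hit coverage around the oriented focal arrays.

    A domain's relative orientation is "same" when its strand matches the
    array's orientation ('+' vs forward), "opposite" otherwise.  The
    denominators are the same per-position available-flank counts used by
    :func:`flank_composition`.
    """
    families = {a.family_id for a in arrays}
    if len(families) > 1:
        raise ValueError(f"arrays span multiple families: {sorted(families)}")
    focal = families.pop() if families else ""

    positions = _positions(window)
    n_available = np.zeros(2 * window, dtype=np.int64)
    counts: dict[tuple[str, str], np.ndarray] = {}
    hits_by_read: dict[str, list[DomainHit]] = {}
    for h in domain_hits:
        hits_by_read.setdefault(h.read_id, []).append(h)

    for array in arrays:
        read_len = read_lengths[array.read_id]
        left_margin = array.start
        right_margin = read_len - array.end
        if array.orientation == "forward":
            up_margin, down_margin = left_margin, right_margin
        else:
            up_margin, down_margin = right_margin, left_margin
        up_extent = min(window, up_margin)
        down_extent = min(window, down_margin)
        n_available[window - up_extent : window] += 1
        n_available[window : window + down_extent] += 1

        for hit in hits_by_read.get(array.read_id, ()):
            rel = _relative_positions(array, hit.read_start, hit.read_end, window)
            if rel.size == 0:
                continue
            same = (hit.strand == "+") == (array.orientation == "forward")
            key = (hit.domain, "same" if same else "opposite")
            track = counts.setdefault(key, np.zeros(2 * window, dtype=np.int64))
            idx = np.where(rel < 0, rel + window, rel + window - 1)
            track[idx] += 1

    return DomainProfile(focal, window, positions, counts, n_available, len(arrays))
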