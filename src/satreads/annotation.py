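"""From filtered similarity hits to oriented repeat arrays and coded reads.

A satellite array on a read is a contiguous region covered by overlapping
similarity hits to the same repeat family.  Arrays carry an orientation
(majority strand of the covering hits, base-weighted), truncation flags
(does the array run into a read end, in which case its recorded length is a
lower bound on the genomic array length) and can be rendered as a *coded
read*: the read re-expressed base by base as repeat codes, with uppercase /
lowercase distinguishing forward / reverse arrays, '0' for unannotated
bases and 'X' for annotation conflicts.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ReferenceEntry, SimilarityHit

#: Minimum array length per repeat class, in bp: short spurious regions are
#: dropped.  rDNA and telomeric references recur internally, so a higher
#: floor is used for them.
DEFAULT_MIN_LENGTH_BY_CLASS: dict[str, int] = {
    "satellite": 300,
    "rDNA": 500,
    "telomere": 500,
}

DEFAULT_MIN_SCORE = 7000.0
DEFAULT_MAX_LENGTH_RATIO = 1.23
DEFAULT_EDGE_TOLERANCE = 100

ARRAY_TABLE_COLUMNS = [
    "read_id", "family_id", "start", "end", "length", "orientation",
    "orientation_purity", "truncated_left", "truncated_right",
]


@dataclass
class RepeatArray:
    """A contiguous, oriented repeat region on one read."""

    read_id: str
    family_id: str
    start: int
    end: int
    orientation: str  # "forward" | "reverse"
    orientation_purity: float = 1.0
    truncated_left: bool = False
    truncated_right: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad array interval [{self.start}, {self.end})")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def complete(self) -> bool:
        return not (self.truncated_left or self.truncated_right)


@dataclass
class CodedRead:
    """A read as a run-length list of per-base repeat codes.

    Codes: uppercase letter = forward array, lowercase = reverse array,
    digit = dispersed repeat (no orientation semantics), '0' = no repeat,
    'X' = annotation conflict.  Run lengths sum exactly to the read length.
    """

    read_id: str
    runs: list[tuple[str, int]]
    code_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, run in self.runs:
            if len(code) != 1 or run <= 0:
                raise ValueError(f"bad run ({code!r}, {run})")

    @property
    def length(self) -> int:
        return sum(run for _, run in self.runs)

    def to_string(self) -> str:
        """Expand to one character per base."""
        return "".join(code * run for code, run in self.runs)

    @classmethod
    def from_string(
        cls, read_id: str, coded: str, code_map: dict[str, str] | None = None
    ) -> "CodedRead":
        runs = [(ch, sum(1 for _ in group)) for ch, group in itertools.groupby(coded)]
        return cls(read_id, runs, dict(code_map or {}))


def make_code_map(entries: Sequence[ReferenceEntry]) -> dict[str, str]:
    """Assign single-character codes to reference families.

    Array-forming families (satellite/rDNA/telomere) get letters A-Z in
    reference order; dispersed families get digits 1-9.  '0' and 'X' are
    reserved for "no repeat" and "conflict".
    """
    letters = iter(string.ascii_uppercase)
    digits = iter("123456789")
    code_map: dict[str, str] = {}
    for entry in entries:
        if entry.family_id in code_map:
            continue
        if entry.repeat_class in ("satellite", "rDNA", "telomere"):
            try:
                code_map[entry.family_id] = next(letters)
            except StopIteration:
                raise ValueError("more than 26 array-forming families") from None
        elif entry.repeat_class == "dispersed":
            try:
                code_map[entry.family_id] = next(digits)
            except StopIteration:
                raise ValueError("more than 9 dispersed families") from None
    return code_map


# ---------------------------------------------------------------------------
# hit filtering and merging


def filter_hits(
    hits: Iterable[SimilarityHit],
    min_score: float = DEFAULT_MIN_SCORE,
    max_length_ratio: float = DEFAULT_MAX_LENGTH_RATIO,
) -> Iterator[SimilarityHit]:
    """Drop weak and over-long hits.

    A hit survives iff its score is >= ``min_score`` and its length on the
    read does not exceed ``max_length_ratio`` times the reference length
    (over-long hits typically bridge unrelated sequence inserted between
    two genuine matches).
    """
    for hit in hits:
        if hit.ref_length <= 0:
            raise ValueError(f"hit on {hit.read_id} has non-positive ref_length")
        if hit.score >= min_score and hit.length <= max_length_ratio * hit.ref_length:
            yield hit


def _merge_intervals(
    intervals: list[tuple[int, int, str]], max_gap: int
) -> Iterator[tuple[int, int, list[tuple[int, int, str]]]]:
    """Union of intervals, merging when overlapping or separated by <= max_gap."""
    intervals = sorted(intervals)
    cur_start, cur_end = intervals[0][0], intervals[0][1]
    members = [intervals[0]]
    for iv in intervals[1:]:
        if iv[0] <= cur_end + max_gap:
            cur_end = max(cur_end, iv[1])
            members.append(iv)
        else:
            yield cur_start, cur_end, members
            cur_start, cur_end = iv[0], iv[1]
            members = [iv]
    yield cur_start, cur_end, members


def _orientation_of(members: list[tuple[int, int, str]]) -> tuple[str, float]:
    """Base-weighted majority strand; ties break toward forward."""
    forward = sum(e - s for s, e, strand in members if strand == "+")
    reverse = sum(e - s for s, e, strand in members if strand == "-")
    total = forward + reverse
    if forward >= reverse:
        return "forward", forward / total
    return "reverse", reverse / total


def merge_hits_to_arrays(
    hits: Iterable[SimilarityHit],
    family_classes: Mapping[str, str] | None = None,
    min_length_by_class: Mapping[str, int] | None = None,
    max_gap: int = 0,
) -> list[RepeatArray]:
    """Merge same-family hits on each read into contiguous repeat regions.

    Regions are the interval union of the hits (merged when overlapping or
    separated by <= ``max_gap`` bp); regions shorter than their class
    minimum (300 bp for satellites, 500 bp for rDNA/telomere by default)
    are dropped.  Orientation is the base-weighted majority strand of the
    contributing hits, with the supporting fraction recorded as
    ``orientation_purity``.  Truncation flags are left unset; apply
    :func:`classify_truncation` with the read length afterwards.
    """
    if min_length_by_class is None:
        min_length_by_class = DEFAULT_MIN_LENGTH_BY_CLASS
    family_classes = family_classes or {}

    grouped: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for hit in hits:
        grouped.setdefault((hit.read_id, hit.family_id), []).append(
            (hit.read_start, hit.read_end, hit.strand)
        )

    arrays: list[RepeatArray] = []
    for (read_id, family_id), intervals in grouped.items():
        repeat_class = family_classes.get(family_id, "satellite")
        min_length = min_length_by_class.get(repeat_class, 300)
        for start, end, members in _merge_intervals(intervals, max_gap):
            if end - start < min_length:
                continue
            orientation, purity = _orientation_of(members)
            arrays.append(
                RepeatArray(read_id, family_id, start, end, orientation, purity)
            )
    arrays.sort(key=lambda a: (a.read_id, a.start, a.family_id))
    return arrays


def classify_truncation(
    array: RepeatArray,
    read_length: int,
    edge_tolerance: int = DEFAULT_EDGE_TOLERANCE,
) -> RepeatArray:
    """Flag arrays cut by read ends.

    An array is truncated on the left iff it starts within ``edge_tolerance``
    bp of the read start, and on the right iff it ends within
    ``edge_tolerance`` bp of the read end.  A truncated array's recorded
    length is a lower bound on the genomic array length.  The default
    tolerance of 100 bp absorbs ragged alignment ends on noisy reads; 0
    demands exact contact with the read end.
    """
    if array.end > read_length:
        raise ValueError(
            f"array [{array.start}, {array.end}) exceeds read length {read_length}"
        )
    return replace(
        array,
        truncated_left=array.start <= edge_tolerance,
        truncated_right=(read_length - array.end) <= edge_tolerance,
    )


# ---------------------------------------------------------------------------
# coded reads


def encode_read(
    read_length: int,
    arrays: Sequence[RepeatArray],
    dispersed_hits: Sequence[SimilarityHit] = (),
    code_map: Mapping[str, str] | None = None,
) -> CodedRead:
    """Render one read as a per-base coded string, run-length compressed.

    Array-forming repeats are painted with their letter code, uppercase for
    forward and lowercase for reverse arrays.  Bases claimed by two or more
    equal-priority families become 'X'.  Dispersed repeats are painted with
    digit codes but always lose to satellites ("scored with lower
    priority"); unclaimed bases are '0'.
    """
    if code_map is None:
        raise ValueError("code_map is required")
    read_id = arrays[0].read_id if arrays else (
        dispersed_hits[0].read_id if dispersed_hits else ""
    )

    base = np.full(read_length, "0", dtype="<U1")

    # dispersed tier first (lowest priority); conflicts within the tier -> X
    disp_cover = np.zeros(read_length, dtype=np.int32)
    disp_family = np.full(read_length, "", dtype="<U1")
    for hit in dispersed_hits:
        if hit.family_id not in code_map:
            raise KeyError(f"code_map missing dispersed family {hit.family_id!r}")
        if hit.read_end > read_length:
            raise ValueError("dispersed hit exceeds read bounds")
        code = code_map[hit.family_id]
        sl = slice(hit.read_start, hit.read_end)
        newly = disp_family[sl] != code
        disp_cover[sl] += newly
        disp_family[sl] = code
    base[disp_cover == 1] = disp_family[disp_cover == 1]
    base[disp_cover > 1] = "X"

    # array tier overrides; conflicts between distinct families -> X
    arr_cover = np.zeros(read_length, dtype=np.int32)
    arr_code = np.full(read_length, "", dtype="<U1")
    arr_family = np.full(read_length, "", dtype="<U2")
    for array in arrays:
        if array.family_id not in code_map:
            raise KeyError(f"code_map missing family {array.family_id!r}")
        if array.end > read_length:
            raise ValueError("array exceeds read bounds")
        code = code_map[array.family_id]
        code = code.upper() if array.orientation == "forward" else code.lower()
        sl = slice(array.start, array.end)
        newly = arr_family[sl] != code_map[array.family_id]
        arr_cover[sl] += newly
        arr_family[sl] = code_map[array.family_id]
        arr_code[sl] = code
    base[arr_cover == 1] = arr_code[arr_cover == 1]
    base[arr_cover > 1] = "X"

    coded = CodedRead.from_string(read_id, "".join(base), dict(code_map))
    assert coded.length == read_length
    return coded


# ---------------------------------------------------------------------------
# tables


def arrays_to_frame(arrays: Iterable[RepeatArray]) -> pd.DataFrame:
    rows = [
        (a.read_id, a.family_id, a.start, a.end, a.length, a.orientation,
         a.orientation_purity, a.truncated_left, a.truncated_right)
        for a in arrays
    ]
    return pd.DataFrame(rows, columns=ARRAY_TABLE_COLUMNS)


def frame_to_arrays(frame: pd.DataFrame) -> list[RepeatArray]:
    return [
        RepeatArray(
            row.read_id, row.family_id, int(row.start), int(row.end),
            row.orientation, float(row.orientation_purity),
            bool(row.truncated_left), bool(row.truncated_right),
        )
        for row in frame.itertuples()
    ]


def coded_reads_to_frame(coded_reads: Iterable[CodedRead]) -> pd.DataFrame:
    rows = []
    for cr in coded_reads:
        rows.extend((cr.read_id, code, run) for code, run in cr.runs)
    return pd.DataFrame(rows, columns=["read_id", "code", "run_length"])


def frame_to_coded_reads(
    frame: pd.DataFrame, code_map: Mapping[str, str]
) -> list[CodedRead]:
    out = []
    for read_id, group in frame.groupby("read_id", sort=False):
        runs = [(str(r.code), int(r.run_length)) for r in group.itertuples()]
        out.append(CodedRead(str(read_id), runs, dict(code_map)))
    return out
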