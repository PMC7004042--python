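"""Seeded generator of ultra-long reads with planted satellite arrays.

The generator emulates the data regime the analysis is built for: reads of
30 to 348 kb; satellite arrays from under 5 kb to over 120 kb, complete or
cut by read ends; monomers in the 32-660 bp range carrying substitution and
indel noise; optional higher-order repeat (HOR) structure; and short arrays
embedded downstream of the ordered GAG-PROT-RT-RH-aRH-INT coding cassette
of an Ogre-like LTR-retrotransposon, between two direct repeats.  Every
planted feature is recorded in a truth table whose coordinates refer to the
final noisy read, and similarity-hit / protein-domain tables can be emitted
from the truth in the exact dialects the ingestion layer parses, so the
whole pipeline is testable without an aligner or a download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DOMAINS, DomainHit, ReadRecord, ReferenceEntry, SimilarityHit
from .periodicity import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

#: Approximate lengths (bp) of the coding regions for the six protein
#: domains, in element order, and the spacer between consecutive domains.
DOMAIN_LENGTHS = {
    "GAG": 1_200, "PROT": 450, "RT": 2_100, "RH": 540, "aRH": 540, "INT": 900,
}
DOMAIN_SPACER = 200

#: LASTZ-like score per aligned base at full identity (the large default
#: match score makes bit scores roughly 90 x matched bases).
SCORE_PER_BASE = 90.0


@dataclass(frozen=True)
class HORSpec:
    """Higher-order repeat structure: a cycle of diverged monomer variants.

    ``multimer`` variants alternate (A B A B ... for multimer 2), each
    differing from the base monomer at a ``variant_divergence`` fraction of
    its positions, so the array is periodic both at the monomer length and
    at multimer x monomer.
    """

    multimer: int = 2
    variant_divergence: float = 0.08


@dataclass(frozen=True)
class FamilySimSpec:
    """Planted-array model for one satellite family.

    Array lengths are drawn from a mixture of a short mode (< 5 kb,
    lognormal) and an expanded tail (uniform over ``expanded_range``),
    matching the two regimes observed in real genomes: retroelement-borne
    short arrays and expanded satellite arrays.
    """

    family_id: str
    monomer_length: int
    gc: float = 0.45
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    expanded_weight: float = 0.2
    expanded_range: tuple[int, int] = (30_000, 120_000)
    short_mode_median: float = 1_500.0
    short_mode_sigma: float = 0.6
    hor: HORSpec | None = None
    context: str = "free"  # "free" | "ogre_embedded"

    def __post_init__(self) -> None:
        if self.monomer_length < 2:
            raise ValueError("monomer_length must be >= 2")
        if not 0 <= self.substitution_rate < 1 or not 0 <= self.indel_rate < 1:
            raise ValueError("noise rates must be in [0, 1)")
        if self.context not in ("free", "ogre_embedded"):
            raise ValueError(f"unknown context {self.context!r}")


@dataclass(frozen=True)
class SimSpec:
    """Full synthetic-read specification.

    Defaults reproduce the study regime: reads uniform over 30-348 kb, two
    planted features per read, and a 0.3 chance that a read begins inside
    an array (left truncation); right truncations arise whenever a feature
    overruns the read end.
    """

    families: tuple[FamilySimSpec, ...]
    seed: int = 0
    n_reads: int = 12
    read_length_range: tuple[int, int] = (30_000, 348_000)
    arrays_per_read: int = 2
    truncation_prob: float = 0.3
    background_gc: float = 0.40
    background_range: tuple[int, int] = (2_000, 15_000)
    ltr_length: int = 1_500
    min_recorded_array: int = 300

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("at least one family is required")
        if self.read_length_range[0] > self.read_length_range[1]:
            raise ValueError("bad read_length_range")
        if self.truncation_prob == 0.0:
            for fam in self.families:
                longest = (
                    fam.expanded_range[1] if fam.expanded_weight > 0 else 5_000
                )
                if longest > self.read_length_range[1]:
                    raise ValueError(
                        f"family {fam.family_id}: arrays up to {longest} bp "
                        f"cannot fit in reads of at most "
                        f"{self.read_length_range[1]} bp with truncation disabled"
                    )


@dataclass
class TruthTable:
    """Ground truth for the planted features, on final-read coordinates."""

    arrays: pd.DataFrame    # read_id, family_id, start, end, orientation,
                            # monomer_length, hor_period, context,
                            # truncated_left, truncated_right
    domains: pd.DataFrame   # read_id, domain, start, end, strand
    elements: pd.DataFrame  # read_id, start, end, strand (Ogre-like bodies)

ARRAY_TRUTH_COLUMNS = [
    "read_id", "family_id", "start", "end", "orientation", "monomer_length",
    "hor_period", "context", "truncated_left", "truncated_right",
]
DOMAIN_TRUTH_COLUMNS = ["read_id", "domain", "start", "end", "strand"]
ELEMENT_TRUTH_COLUMNS = ["read_id", "start", "end", "strand"]


# ---------------------------------------------------------------------------
# sequence primitives


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def mutate(
    sequence: str,
    substitution_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> str:
    """Independent per-base substitutions plus geometric-length indels."""
    if substitution_rate > 0 and sequence:
        raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
        mask = rng.random(len(raw)) < substitution_rate
        idx = np.flatnonzero(mask)
        if idx.size:
            base_idx = _BASE_INDEX[raw[idx]]
            known = base_idx >= 0
            shift = rng.integers(1, 4, size=idx.size)
            new_idx = (base_idx + shift) % 4
            raw[idx[known]] = _BASES[new_idx[known]]
        sequence = raw.tobytes().decode("ascii")
    if indel_rate > 0 and sequence:
        positions = np.flatnonzero(rng.random(len(sequence)) < indel_rate)
        if positions.size:
            pieces: list[str] = []
            prev = 0
            for pos in positions:
                if pos < prev:
                    continue
                pieces.append(sequence[prev:pos])
                size = int(rng.geometric(0.5))
                if rng.random() < 0.5:  # insertion
                    pieces.append(random_sequence(rng, size))
                    prev = pos
                else:  # deletion
                    prev = min(pos + size, len(sequence))
            pieces.append(sequence[prev:])
            sequence = "".join(pieces)
    return sequence


def _monomer_variants(
    fam: FamilySimSpec, rng: np.random.Generator
) -> list[str]:
    """The family's monomer, plus diverged variants when a HOR is planted."""
    monomer = random_sequence(rng, fam.monomer_length, fam.gc)
    if fam.hor is None:
        return [monomer]
    n_mut = max(1, round(fam.hor.variant_divergence * fam.monomer_length))
    variants = [monomer]
    for _ in range(fam.hor.multimer - 1):
        raw = np.frombuffer(monomer.encode("ascii"), dtype=np.uint8).copy()
        pos = rng.choice(len(raw), size=min(n_mut, len(raw)), replace=False)
        shift = rng.integers(1, 4, size=pos.size)
        raw[pos] = _BASES[(_BASE_INDEX[raw[pos]] + shift) % 4]
        variants.append(raw.tobytes().decode("ascii"))
    return variants


def tandem_array(
    fam: FamilySimSpec,
    length: int,
    rng: np.random.Generator,
    variants: Sequence[str] | None = None,
) -> str:
    """A tandem array of ~``length`` bp: tiled monomers (HOR cycle if any)
    with the family's substitution/indel noise applied."""
    if variants is None:
        variants = _monomer_variants(fam, rng)
    n_units = length // fam.monomer_length + 1
    cycle = [variants[i % len(variants)] for i in range(n_units)]
    clean = "".join(cycle)[:length]
    return mutate(clean, fam.substitution_rate, fam.indel_rate, rng)


# ---------------------------------------------------------------------------
# feature assembly


@dataclass
class _Feature:
    """One planted feature in its own forward frame."""

    sequence: str
    arrays: list[dict]     # rel coords + metadata
    domains: list[dict]
    elements: list[dict]

    def reversed(self) -> "_Feature":
        L = len(self.sequence)
        def flip(rows: list[dict]) -> list[dict]:
            out = []
            for row in rows:
                new = dict(row)
                new["start"], new["end"] = L - row["end"], L - row["start"]
                if "orientation" in new:
                    new["orientation"] = (
                        "reverse" if row["orientation"] == "forward" else "forward"
                    )
                if "strand" in new:
                    new["strand"] = "-" if row["strand"] == "+" else "+"
                out.append(new)
            return out
        return _Feature(
            reverse_complement(self.sequence),
            flip(self.arrays), flip(self.domains), flip(self.elements),
        )


def _draw_array_length(fam: FamilySimSpec, rng: np.random.Generator) -> int:
    if fam.expanded_weight > 0 and rng.random() < fam.expanded_weight:
        return int(rng.integers(fam.expanded_range[0], fam.expanded_range[1] + 1))
    length = rng.lognormal(np.log(fam.short_mode_median), fam.short_mode_sigma)
    return int(np.clip(length, 400, 4_999))


def _build_feature(
    fam: FamilySimSpec,
    spec: SimSpec,
    rng: np.random.Generator,
    variants: Sequence[str],
) -> _Feature:
    """Assemble one feature (array, optionally inside an Ogre-like element)
    in forward orientation; noise is applied segment-wise so all recorded
    coordinates are exact on the final sequence."""
    array_length = _draw_array_length(fam, rng)
    array_seq = tandem_array(fam, array_length, rng, variants)
    hor_period = (
        fam.hor.multimer * fam.monomer_length if fam.hor is not None else 0
    )
    array_row = {
        "family_id": fam.family_id,
        "orientation": "forward",
        "monomer_length": fam.monomer_length,
        "hor_period": hor_period,
        "context": fam.context,
    }

    if fam.context == "free":
        array_row.update(start=0, end=len(array_seq))
        return _Feature(array_seq, [array_row], [], [])

    # Ogre-like element: LTR - GAG..INT cassette - tandem array - LTR
    noise = (fam.substitution_rate, fam.indel_rate)
    ltr = random_sequence(rng, spec.ltr_length, spec.background_gc)
    pieces: list[str] = []
    domains: list[dict] = []
    pos = 0

    def push(segment: str) -> tuple[int, int]:
        nonlocal pos
        pieces.append(segment)
        start, pos_end = pos, pos + len(segment)
        pos = pos_end
        return start, pos_end

    push(mutate(ltr, *noise, rng))
    push(random_sequence(rng, DOMAIN_SPACER, spec.background_gc))
    for domain in DOMAINS:
        seg = mutate(
            random_sequence(rng, DOMAIN_LENGTHS[domain], 0.45), *noise, rng
        )
        start, end = push(seg)
        domains.append({"domain": domain, "start": start, "end": end,
                        "strand": "+"})
        push(random_sequence(rng, DOMAIN_SPACER, spec.background_gc))
    a_start, a_end = push(array_seq)
    push(random_sequence(rng, DOMAIN_SPACER, spec.background_gc))
    push(mutate(ltr, *noise, rng))  # second direct repeat

    array_row.update(start=a_start, end=a_end)
    element_row = {"start": 0, "end": pos, "strand": "+"}
    return _Feature("".join(pieces), [array_row], domains, [element_row])


# ---------------------------------------------------------------------------
# read assembly


def _place(
    feature: _Feature,
    read_pos: int,
    read_len: int,
    skip_left: int,
    truth_arrays: list[dict],
    truth_domains: list[dict],
    truth_elements: list[dict],
    read_id: str,
    min_recorded_array: int,
) -> tuple[str, int]:
    """Append (a window of) a feature at ``read_pos``, clipping at the read
    end, and record the surviving truth rows.  Returns the appended sequence
    and the number of bases kept."""
    seq = feature.sequence[skip_left:]
    keep = min(len(seq), read_len - read_pos)
    seq = seq[:keep]
    window_lo, window_hi = skip_left, skip_left + keep

    def clip(row: dict) -> tuple[int, int, bool, bool] | None:
        s, e = row["start"], row["end"]
        cs, ce = max(s, window_lo), min(e, window_hi)
        if ce - cs <= 0:
            return None
        return cs - window_lo + read_pos, ce - window_lo + read_pos, cs > s, ce < e

    for row in feature.arrays:
        clipped = clip(row)
        if clipped is None:
            continue
        start, end, cut_left, cut_right = clipped
        if end - start < min_recorded_array:
            continue
        truth_arrays.append(
            {
                "read_id": read_id, "family_id": row["family_id"],
                "start": start, "end": end,
                "orientation": row["orientation"],
                "monomer_length": row["monomer_length"],
                "hor_period": row["hor_period"], "context": row["context"],
                "truncated_left": cut_left, "truncated_right": cut_right,
            }
        )
    for row in feature.domains:
        clipped = clip(row)
        if clipped is None:
            continue
        start, end, cut_left, cut_right = clipped
        if cut_left or cut_right:  # partial domains are not annotated
            continue
        truth_domains.append(
            {"read_id": read_id, "domain": row["domain"],
             "start": start, "end": end, "strand": row["strand"]}
        )
    for row in feature.elements:
        clipped = clip(row)
        if clipped is None:
            continue
        start, end, _cl, _cr = clipped
        truth_elements.append(
            {"read_id": read_id, "start": start, "end": end,
             "strand": row["strand"]}
        )
    return seq, keep


def simulate(spec: SimSpec) -> tuple[list[ReadRecord], TruthTable]:
    """Generate reads and their truth table.  Identical specs (same seed)
    produce byte-identical output."""
    rng = np.random.default_rng(spec.seed)
    variants_by_family = {
        fam.family_id: _monomer_variants(fam, rng) for fam in spec.families
    }

    reads: list[ReadRecord] = []
    truth_arrays: list[dict] = []
    truth_domains: list[dict] = []
    truth_elements: list[dict] = []

    for read_index in range(spec.n_reads):
        read_id = f"read_{read_index:05d}"
        read_len = int(
            rng.integers(spec.read_length_range[0], spec.read_length_range[1] + 1)
        )
        chunks: list[str] = []
        pos = 0
        start_truncated = (
            spec.truncation_prob > 0 and rng.random() < spec.truncation_prob
        )
        for feat_index in range(spec.arrays_per_read):
            if pos >= read_len:
                break
            fam = spec.families[int(rng.integers(len(spec.families)))]
            feature = _build_feature(
                fam, spec, rng, variants_by_family[fam.family_id]
            )
            if rng.random() < 0.5:
                feature = feature.reversed()
            if feat_index == 0 and start_truncated:
                skip = int(rng.integers(1, max(2, len(feature.sequence) // 2)))
            else:
                skip = 0
                bg = int(
                    rng.integers(spec.background_range[0],
                                 spec.background_range[1] + 1)
                )
                bg = min(bg, read_len - pos)
                chunks.append(random_sequence(rng, bg, spec.background_gc))
                pos += bg
            if pos >= read_len:
                break
            seq, kept = _place(
                feature, pos, read_len, skip, truth_arrays, truth_domains,
                truth_elements, read_id, spec.min_recorded_array,
            )
            chunks.append(seq)
            pos += kept
        if pos < read_len:
            chunks.append(
                random_sequence(rng, read_len - pos, spec.background_gc)
            )
        reads.append(ReadRecord(read_id, "".join(chunks)))

    truth = TruthTable(
        arrays=pd.DataFrame(truth_arrays, columns=ARRAY_TRUTH_COLUMNS),
        domains=pd.DataFrame(truth_domains, columns=DOMAIN_TRUTH_COLUMNS),
        elements=pd.DataFrame(truth_elements, columns=ELEMENT_TRUTH_COLUMNS),
    )
    return reads, truth


# ---------------------------------------------------------------------------
# reference database and emitted hit tables


def make_reference_database(
    spec: SimSpec, monomers_per_reference: int = 10, ogre_ref_length: int = 5_000
) -> list[ReferenceEntry]:
    """Reference entries matching the simulation: one multi-monomer
    consensus per satellite family (forward orientation) plus one dispersed
    'Ogre' entry for element bodies."""
    rng = np.random.default_rng(spec.seed)
    entries = []
    for fam in spec.families:
        variants = _monomer_variants(fam, rng)
        cycle = [variants[i % len(variants)] for i in range(monomers_per_reference)]
        entries.append(
            ReferenceEntry(fam.family_id, "satellite", "".join(cycle), 0)
        )
    entries.append(
        ReferenceEntry("Ogre", "dispersed",
                       random_sequence(rng, ogre_ref_length, 0.45), 10)
    )
    return entries


@dataclass(frozen=True)
class FragmentationModel:
    """How emitted hits tile each planted array.

    With ``fragment=True`` arrays are covered by overlapping windows of the
    reference length (stride = half a window), as a real aligner reports
    them against a multi-monomer reference; with ``fragment=False`` each
    array yields a single exact hit.  ``identity`` and ``score_jitter``
    shape the reported identities/scores.
    """

    fragment: bool = True
    identity: float = 0.90
    score_jitter: float = 0.0


def _tile(start: int, end: int, window: int, stride: int) -> list[tuple[int, int]]:
    """Overlapping windows covering [start, end); the last window is
    right-aligned so boundaries are exact."""
    length = end - start
    if length <= window:
        return [(start, end)]
    tiles = []
    pos = start
    while pos + window < end:
        tiles.append((pos, pos + window))
        pos += stride
    tiles.append((end - window, end))
    return tiles


def emit_hit_tables(
    truth: TruthTable,
    reference: Sequence[ReferenceEntry],
    model: FragmentationModel | None = None,
    seed: int = 0,
) -> tuple[list[SimilarityHit], list[DomainHit]]:
    """Similarity-hit and domain-hit rows implied by the truth table.

    Satellite arrays produce same-family hits whose union reproduces the
    planted interval exactly; Ogre-like element bodies (minus the embedded
    arrays) produce dispersed 'Ogre' hits; planted domains produce rows
    passing the default quality cutoffs.
    """
    model = model or FragmentationModel()
    rng = np.random.default_rng(seed)
    ref_lengths = {e.family_id: len(e.sequence) for e in reference}

    def score(length: int) -> float:
        s = SCORE_PER_BASE * length * model.identity
        if model.score_jitter > 0:
            s *= 1.0 + model.score_jitter * (rng.random() - 0.5)
        return round(s, 1)

    hits: list[SimilarityHit] = []
    for row in truth.arrays.itertuples():
        ref_len = ref_lengths[row.family_id]
        strand = "+" if row.orientation == "forward" else "-"
        if model.fragment:
            tiles = _tile(row.start, row.end, ref_len, max(ref_len // 2, 1))
        else:
            tiles = [(row.start, row.end)]
        for t_start, t_end in tiles:
            hits.append(
                SimilarityHit(
                    row.read_id, t_start, t_end, strand, row.family_id,
                    ref_len, model.identity, score(t_end - t_start),
                )
            )

    if "Ogre" in ref_lengths and len(truth.elements):
        ogre_len = ref_lengths["Ogre"]
        for el in truth.elements.itertuples():
            overlapping = truth.arrays[
                (truth.arrays.read_id == el.read_id)
                & (truth.arrays.start < el.end)
                & (truth.arrays.end > el.start)
            ]
            cuts = sorted(
                (max(int(a.start), el.start), min(int(a.end), el.end))
                for a in overlapping.itertuples()
            )
            intervals = []
            prev = el.start
            for c_start, c_end in cuts:
                if c_start > prev:
                    intervals.append((prev, c_start))
                prev = max(prev, c_end)
            if el.end > prev:
                intervals.append((prev, el.end))
            for i_start, i_end in intervals:
                if i_end - i_start < 100:
                    continue
                for t_start, t_end in _tile(
                    i_start, i_end, ogre_len, max(ogre_len // 2, 1)
                ):
                    hits.append(
                        SimilarityHit(
                            el.read_id, t_start, t_end, el.strand, "Ogre",
                            ogre_len, model.identity, score(t_end - t_start),
                        )
                    )

    domain_hits = [
        DomainHit(
            row.read_id, row.start, row.end, row.strand, row.domain,
            identity=0.62, similarity=0.75, aln_length_proportion=0.95,
            interruptions=1, length_proportion=1.0,
        )
        for row in truth.domains.itertuples()
    ]
    return hits, domain_hits


def default_spec(seed: int = 0, **overrides) -> SimSpec:
    """A ready-made specification mirroring the worked example's regime.

    Three families spanning the observed monomer range: a 49-bp monomer
    with a two-unit HOR (centromeric-satellite-like), an 80-bp free
    satellite with an expanded tail, and a 104-bp satellite embedded in
    Ogre-like elements with occasional expansion.
    """
    families = (
        FamilySimSpec(
            "FabTR-2", 49, gc=0.29, substitution_rate=0.02,
            expanded_weight=0.8, hor=HORSpec(2, 0.08),
        ),
        FamilySimSpec(
            "FabTR-51-LAS-A", 80, gc=0.54, substitution_rate=0.02,
            expanded_weight=0.4,
        ),
        FamilySimSpec(
            "FabTR-54", 104, gc=0.49, substitution_rate=0.02,
            expanded_weight=0.15, context="ogre_embedded",
        ),
    )
    return SimSpec(families=families, seed=seed, **overrides)
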