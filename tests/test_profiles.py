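"""Flank composition and protein-domain context profiles."""

import numpy as np
import pytest

import satreads as sr
from satreads.annotation import CodedRead
from satreads.profiles import DomainCutoffs, _positions

CODE_MAP = {"FabTR-2": "A", "FabTR-54": "B", "Ogre": "1"}


def coded(read_id, coded_string):
    return CodedRead.from_string(read_id, coded_string, CODE_MAP)


def prof(value_frame, code):
    return value_frame[code] if code in value_frame.columns else None


# ---------------------------------------------------------------------------
# flank_composition


def test_reverse_array_right_flank_becomes_upstream():
    """For a reverse-oriented array the genomic right flank is its upstream
    side, and the flank codes' cases are swapped into the array's frame."""
    # read: 100 bp Ogre, 100 bp reverse FabTR-2 array, 100 bp forward FabTR-54
    s = "1" * 100 + "a" * 100 + "B" * 100
    arrays = [sr.RepeatArray("r", "FabTR-2", 100, 200, "reverse")]
    profile = sr.flank_composition({"r": coded("r", s)}, arrays, window=100)
    props = profile.proportions()
    upstream = props.loc[-100:-1]
    downstream = props.loc[1:100]
    # genomic right (forward B) is upstream, case-swapped to b
    assert upstream["b"].eq(1.0).all()
    # genomic left (Ogre) is downstream; digits have no case
    assert downstream["1"].eq(1.0).all()


def test_array_surrounded_by_itself_scores_one():
    """An array with the same forward satellite on both sides has
    self-family proportion 1.0 across the whole window."""
    s = "A" * 30_000
    arrays = [sr.RepeatArray("r", "FabTR-2", 10_000, 20_000, "forward")]
    profile = sr.flank_composition({"r": coded("r", s)}, arrays, window=10_000)
    props = profile.proportions()
    assert props["A"].eq(1.0).all()


def test_positions_beyond_read_end_shrink_denominator():
    s = "0" * 500 + "A" * 1_000 + "0" * 200
    arrays = [sr.RepeatArray("r", "FabTR-2", 500, 1_500, "forward")]
    profile = sr.flank_composition({"r": coded("r", s)}, arrays, window=1_000)
    avail = dict(zip(profile.positions, profile.n_available))
    assert avail[-1] == 1 and avail[-500] == 1 and avail[-501] == 0
    assert avail[1] == 1 and avail[200] == 1 and avail[201] == 0


def test_missing_coded_read_errors():
    arrays = [sr.RepeatArray("r", "FabTR-2", 0, 500, "forward")]
    with pytest.raises(KeyError, match="r"):
        sr.flank_composition({}, arrays, window=10)


def test_flank_profile_matches_brute_force_tally():
    """Random placements: profile equals a direct per-array, per-position
    code count divided by the per-position availability."""
    rng = np.random.default_rng(12)
    window = 50
    codes = np.array(list("0AaBb1X"))
    reads = {}
    arrays = []
    for i in range(30):
        read_len = int(rng.integers(200, 2_000))
        chars = rng.choice(codes, size=read_len)
        start = int(rng.integers(0, read_len - 50))
        end = int(rng.integers(start + 30, min(start + 500, read_len)))
        orientation = "forward" if rng.random() < 0.5 else "reverse"
        rid = f"r{i}"
        reads[rid] = coded(rid, "".join(chars))
        arrays.append(sr.RepeatArray(rid, "FabTR-2", start, end, orientation))

    profile = sr.flank_composition(reads, arrays, window=window)

    # oracle: walk each array's oriented flank positions one by one
    positions = _positions(window)
    counts = {}
    avail = np.zeros(len(positions), dtype=int)
    for a in arrays:
        chars = np.array(list(reads[a.read_id].to_string()))
        for j, p in enumerate(positions):
            if a.orientation == "forward":
                g = a.start + p if p < 0 else a.end + p - 1
            else:
                g = a.end - 1 - p if p < 0 else a.start - p
            if not (0 <= g < len(chars)):
                continue
            avail[j] += 1
            ch = chars[g]
            if a.orientation == "reverse":
                ch = ch.swapcase()
            counts.setdefault(ch, np.zeros(len(positions), dtype=int))[j] += 1

    np.testing.assert_array_equal(profile.n_available, avail)
    assert set(profile.counts) == set(counts)
    for ch in counts:
        np.testing.assert_array_equal(profile.counts[ch], counts[ch])


def test_report_suppresses_rare_codes_but_full_table_keeps_them():
    """A repeat seen in 1/21 flanks (proportion < 0.05) is dropped from the
    report but kept in the full proportion table."""
    reads, arrays = {}, []
    for i in range(21):
        flank = ("1" if i == 0 else "0") * 1_000
        rid = f"r{i}"
        reads[rid] = coded(rid, flank + "A" * 500)
        arrays.append(sr.RepeatArray(rid, "FabTR-2", 1_000, 1_500, "forward"))
    profile = sr.flank_composition(reads, arrays, window=1_000)
    assert "1" in profile.proportions().columns
    assert "1" not in profile.report(threshold=0.05).columns
    assert "0" in profile.report(threshold=0.05).columns


# ---------------------------------------------------------------------------
# filter_domain_hits


def domain(identity=0.62, similarity=0.75, aln=0.95, interruptions=1,
           len_prop=1.0, strand="+", start=100, end=900, name="RT"):
    return sr.DomainHit("r", start, end, strand, name, identity, similarity,
                        aln, interruptions, len_prop)


@pytest.mark.parametrize(
    "kwargs,kept",
    [
        ({"identity": 0.29}, False),
        ({"identity": 0.30}, True),
        ({"similarity": 0.39}, False),
        ({"aln": 0.65}, False),
        ({"interruptions": 11}, False),
        ({"interruptions": 10}, True),
        ({"len_prop": 1.21}, False),
        ({}, True),
    ],
)
def test_domain_quality_cutoffs(kwargs, kept):
    hits = sr.filter_domain_hits([domain(**kwargs)], DomainCutoffs())
    assert (len(hits) == 1) is kept


# ---------------------------------------------------------------------------
# domain_profile


def test_planted_cassette_order_and_orientation(noise_free_sim, annotated):
    """Arrays embedded in elements see the GAG..INT cassette upstream, in
    element order (GAG outermost, INT innermost), all same-orientation."""
    truth = noise_free_sim["truth"]
    arrays = [a for a in annotated["arrays"] if a.family_id == "FabTR-54"]
    hits = sr.filter_domain_hits(noise_free_sim["domain_hits"])
    profile = sr.domain_profile(hits, arrays, annotated["read_lengths"])
    props = profile.proportions()

    centroids = {}
    for name in ("GAG", "PROT", "RT", "RH", "aRH", "INT"):
        col = f"{name}:same"
        assert col in props.columns, f"{name} absent from same-orientation"
        values = props[col].to_numpy()
        upstream = values[: profile.window]
        assert upstream.sum() > 0, f"{name} not seen upstream"
        positions = profile.positions[: profile.window]
        centroids[name] = (positions * upstream).sum() / upstream.sum()
        # nothing from the cassette shows up in opposite orientation
        assert f"{name}:opposite" not in props.columns or \
            props[f"{name}:opposite"].sum() == 0
    order = sorted(centroids, key=centroids.get)
    assert order == ["GAG", "PROT", "RT", "RH", "aRH", "INT"]


def test_domain_outside_window_excluded():
    arrays = [sr.RepeatArray("r", "FabTR-2", 20_000, 30_000, "forward")]
    far = domain(start=8_000, end=8_900)  # 11.1 kb upstream of the array
    profile = sr.domain_profile([far], arrays, {"r": 60_000})
    assert profile.counts == {}


def test_no_domain_hits_gives_zero_profile():
    arrays = [sr.RepeatArray("r", "FabTR-2", 20_000, 30_000, "forward")]
    profile = sr.domain_profile([], arrays, {"r": 60_000})
    assert profile.counts == {}
    assert profile.n_available.max() == 1


def test_denominators_match_margin_oracle(annotated):
    """n_available at position p equals the number of arrays whose read
    extends at least |p| bases beyond the relevant oriented end."""
    arrays = [a for a in annotated["arrays"] if a.family_id == "FabTR-51-LAS-A"]
    read_lengths = annotated["read_lengths"]
    profile = sr.domain_profile([], arrays, read_lengths)
    for j, p in enumerate(profile.positions):
        expected = 0
        for a in arrays:
            left = a.start
            right = read_lengths[a.read_id] - a.end
            up, down = (left, right) if a.orientation == "forward" else (right, left)
            margin = up if p < 0 else down
            if margin >= abs(p):
                expected += 1
        assert profile.n_available[j] == expected, f"position {p}"


# ---------------------------------------------------------------------------
# strand symmetry


def _mirror_dataset(reads, arrays, domain_hits):
    """Reverse-complement every read: coded strings reverse + case-swap,
    coordinates flip, orientations and strands invert."""
    m_reads = {}
    for rid, cr in reads.items():
        m_reads[rid] = CodedRead.from_string(
            rid, cr.to_string().swapcase()[::-1], cr.code_map
        )
    lengths = {rid: cr.length for rid, cr in reads.items()}
    m_arrays = [
        sr.RepeatArray(
            a.read_id, a.family_id,
            lengths[a.read_id] - a.end, lengths[a.read_id] - a.start,
            "reverse" if a.orientation == "forward" else "forward",
            a.orientation_purity, a.truncated_right, a.truncated_left,
        )
        for a in arrays
    ]
    m_domains = [
        sr.DomainHit(
            h.read_id, lengths[h.read_id] - h.read_end,
            lengths[h.read_id] - h.read_start,
            "-" if h.strand == "+" else "+", h.domain, h.identity,
            h.similarity, h.aln_length_proportion, h.interruptions,
            h.length_proportion,
        )
        for h in domain_hits
    ]
    return m_reads, m_arrays, m_domains


def test_profiles_invariant_under_reverse_complement(noise_free_sim, annotated):
    """Reverse-complementing all reads (flipping every recorded orientation)
    leaves both flank and domain profiles exactly unchanged."""
    coded_reads = annotated["coded"]
    read_lengths = annotated["read_lengths"]
    domain_hits = sr.filter_domain_hits(noise_free_sim["domain_hits"])
    for family in ("FabTR-2", "FabTR-54"):
        arrays = [a for a in annotated["arrays"] if a.family_id == family]
        if not arrays:
            continue
        fwd_flank = sr.flank_composition(coded_reads, arrays, window=2_000)
        fwd_dom = sr.domain_profile(domain_hits, arrays, read_lengths,
                                    window=2_000)
        m_reads, m_arrays, m_domains = _mirror_dataset(
            coded_reads, arrays, domain_hits
        )
        rev_flank = sr.flank_composition(m_reads, m_arrays, window=2_000)
        rev_dom = sr.domain_profile(m_domains, m_arrays, read_lengths,
                                    window=2_000)

        np.testing.assert_array_equal(fwd_flank.n_available,
                                      rev_flank.n_available)
        assert set(fwd_flank.counts) == set(rev_flank.counts)
        for code in fwd_flank.counts:
            np.testing.assert_array_equal(fwd_flank.counts[code],
                                          rev_flank.counts[code])
        assert set(fwd_dom.counts) == set(rev_dom.counts)
        for key in fwd_dom.counts:
            np.testing.assert_array_equal(fwd_dom.counts[key],
                                          rev_dom.counts[key])
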