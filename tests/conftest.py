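import numpy as np
import pytest

import satreads as sr
from satreads.simulate import FamilySimSpec, HORSpec, SimSpec


def noise_free_families() -> tuple[FamilySimSpec, ...]:
    """Three families spanning the monomer range, no sequencing noise."""
    return (
        FamilySimSpec("FabTR-2", 49, gc=0.29, expanded_weight=0.8,
                      hor=HORSpec(2, 0.08)),
        FamilySimSpec("FabTR-51-LAS-A", 80, gc=0.54, expanded_weight=0.4),
        FamilySimSpec("FabTR-54", 104, gc=0.49, expanded_weight=0.15,
                      context="ogre_embedded"),
    )


@pytest.fixture(scope="session")
def noise_free_sim():
    """Noise-free simulation with emitted hit/domain tables and reference."""
    spec = SimSpec(
        families=noise_free_families(), seed=11, n_reads=10,
        read_length_range=(30_000, 150_000),
    )
    reads, truth = sr.simulate_reads(spec)
    reference = sr.make_reference_database(spec)
    hits, domain_hits = sr.emit_hit_tables(truth, reference, seed=11)
    return {
        "spec": spec, "reads": reads, "truth": truth,
        "reference": reference, "hits": hits, "domain_hits": domain_hits,
    }


@pytest.fixture(scope="session")
def annotated(noise_free_sim):
    """Arrays + coded reads recovered from the emitted noise-free tables."""
    sim = noise_free_sim
    classes = {e.family_id: e.repeat_class for e in sim["reference"]}
    code_map = sr.make_code_map(sim["reference"])
    read_lengths = {r.read_id: r.length for r in sim["reads"]}
    filtered = list(sr.filter_hits(sim["hits"]))
    array_tier = [h for h in filtered if classes[h.family_id] != "dispersed"]
    dispersed = [h for h in filtered if classes[h.family_id] == "dispersed"]
    arrays = sr.merge_hits_to_arrays(array_tier, classes)
    arrays = [
        sr.classify_truncation(a, read_lengths[a.read_id], edge_tolerance=0)
        for a in arrays
    ]
    by_read: dict[str, list] = {}
    for a in arrays:
        by_read.setdefault(a.read_id, []).append(a)
    disp_by_read: dict[str, list] = {}
    for h in dispersed:
        disp_by_read.setdefault(h.read_id, []).append(h)
    coded = {
        r.read_id: sr.encode_read(
            r.length, by_read.get(r.read_id, []),
            disp_by_read.get(r.read_id, []), code_map,
        )
        for r in sim["reads"]
    }
    return {
        "arrays": arrays, "coded": coded, "code_map": code_map,
        "classes": classes, "read_lengths": read_lengths,
        "dispersed": dispersed,
    }


def random_hits(rng: np.random.Generator, n: int, read_len: int = 10_000,
                n_families: int = 3) -> list[sr.SimilarityHit]:
    """Random small hit sets for oracle comparisons."""
    hits = []
    for _ in range(n):
        start = int(rng.integers(0, read_len - 50))
        length = int(rng.integers(50, 2_000))
        end = min(start + length, read_len)
        hits.append(
            sr.SimilarityHit(
                "r", start, end, "+" if rng.random() < 0.5 else "-",
                f"fam{int(rng.integers(n_families))}", 1_000, 0.9,
                float(rng.integers(7_000, 50_000)),
            )
        )
    return hits


def coverage_oracle_arrays(hits, min_length=300, max_gap=0):
    """Brute-force per-base coverage oracle for interval merging."""
    out = []
    by_family: dict[str, list] = {}
    for h in hits:
        by_family.setdefault(h.family_id, []).append(h)
    for family, group in by_family.items():
        read_len = max(h.read_end for h in group)
        covered = np.zeros(read_len + max_gap + 1, dtype=bool)
        for h in group:
            covered[h.read_start : h.read_end] = True
        if max_gap > 0:
            # close gaps of <= max_gap uncovered bases between covered runs
            idx = np.flatnonzero(covered)
            for a, b in zip(idx[:-1], idx[1:]):
                if 1 < b - a <= max_gap + 1:
                    covered[a:b] = True
        padded = np.concatenate([[False], covered, [False]])
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_length:
                out.append((family, int(s), int(e)))
    return sorted(out)
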