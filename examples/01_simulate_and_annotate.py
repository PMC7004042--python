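"""Plant satellite arrays in synthetic ultra-long reads, emit the hit
tables an aligner would produce, and recover the arrays.

Prints the planted vs. detected array table: on noise-free hits the
detection is exact (same boundaries, orientations and truncation flags),
which is the baseline guarantee behind every downstream statistic.
"""

import satreads as sr

spec = sr.default_spec(seed=1, n_reads=8, read_length_range=(30_000, 120_000))
reads, truth = sr.simulate_reads(spec)
reference = sr.make_reference_database(spec)
hits, _ = sr.emit_hit_tables(truth, reference, seed=1)

classes = {e.family_id: e.repeat_class for e in reference}
read_lengths = {r.read_id: r.length for r in reads}

filtered = list(sr.filter_hits(hits))  # score >= 7000, length <= 1.23 x ref
satellite_hits = [h for h in filtered if classes[h.family_id] != "dispersed"]
arrays = sr.merge_hits_to_arrays(satellite_hits, classes)
arrays = [sr.classify_truncation(a, read_lengths[a.read_id]) for a in arrays]

print(f"{len(reads)} reads, {len(hits)} raw hits, {len(filtered)} filtered, "
      f"{len(arrays)} arrays detected ({len(truth.arrays)} planted)\n")
print(f"{'read':<12}{'family':<16}{'start':>8}{'end':>8}{'orient':>9}"
      f"{'complete':>10}")
for a in arrays:
    print(f"{a.read_id:<12}{a.family_id:<16}{a.start:>8}{a.end:>8}"
          f"{a.orientation:>9}{str(a.complete):>10}")
print("\nTruncated arrays touch a read end: their length is a lower bound "
      "on the genomic array length.")
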