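"""Render a read as a coded read: per-base repeat codes, run-length
compressed.

Uppercase = forward array, lowercase = reverse array, digits = dispersed
repeats (e.g. retrotransposon bodies), '0' = unannotated, 'X' = conflict.
The run lengths always sum exactly to the read length.
"""

import satreads as sr

spec = sr.default_spec(seed=4, n_reads=4, read_length_range=(30_000, 80_000))
reads, truth = sr.simulate_reads(spec)
reference = sr.make_reference_database(spec)
hits, _ = sr.emit_hit_tables(truth, reference, seed=4)

classes = {e.family_id: e.repeat_class for e in reference}
code_map = sr.make_code_map(reference)
print("code map:", code_map, "\n")

filtered = list(sr.filter_hits(hits))
arrays = sr.merge_hits_to_arrays(
    [h for h in filtered if classes[h.family_id] != "dispersed"], classes
)
for read in reads:
    own = [a for a in arrays if a.read_id == read.read_id]
    disp = [h for h in filtered
            if h.read_id == read.read_id and classes[h.family_id] == "dispersed"]
    coded = sr.encode_read(read.length, own, disp, code_map)
    runs = "  ".join(f"{code}x{length}" for code, length in coded.runs)
    print(f"{read.read_id} ({read.length} bp): {runs}")
    assert coded.length == read.length
print("\nEach run is (code x bases); e.g. 'Bx41310' is a 41.3 kb forward "
      "array of the family coded B.")
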