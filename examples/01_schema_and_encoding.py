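"""Inspect the 17-item clinical schema and the global ordinal encoding.

Builds the default schema, prints the item taxonomy, and shows how one
tooth's ten categorical options map to global integer codes 1..30.
"""

from tsfnn import build_codebook, default_schema, encode_categorical, generate, study_spec

schema = default_schema()
n_cat = sum(s.kind == "categorical" for s in schema)
n_num = len(schema) - n_cat
print(f"{len(schema)} items: {n_cat} categorical, {n_num} numerical\n")

codebook = build_codebook(schema)
print(f"global ordinal codes span {codebook.min_code}..{codebook.max_code}")
for item_id, option in [(1, "Male"), (7, "Mandibular premolar"), (10, "Root amputation")]:
    print(f"  item {item_id:2d} {option!r:28s} -> code {codebook.code(item_id, option)}")

record = generate(study_spec(seed=1))[0]
codes = encode_categorical(record, codebook)
print(f"\nfirst synthetic record encodes to {codes.tolist()}")
print("(one global code per categorical item; codes never collide across items)")
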