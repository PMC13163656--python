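"""Encode barcode proteins as fixed-length 5-bit genetic images.

Builds one organism record, fits its two proteins to reference lengths and
prints the resulting bit-vector sizes plus the first residues' codes.
"""

import geneimage as g

record = g.OrganismRecord(
    common_name="Human", latin_name="Homo sapiens",
    cytb_seq="MTPMRKTNPLMKLINHSFIDLPTPSNISAWWNFGSLLG",  # leading residues only
    coi_seq="MFADRWLFSTNHKDIGTLYLLFGAWAGVLGTALSLLIRAELGQP",
)

ref = g.ReferenceLengths()  # human lengths: cytochrome b 380, COI 513
for mode in ("concat", "cytb", "coi"):
    image = g.build_genetic_image(record, ref, mode)
    print(f"{mode:>6}: {image.bits.size} bits ({image.residue_len} residues x 5)")

print()
for sym in "MTPA-":
    print(f"residue {sym!r} -> {g.residue_code(sym)}")

image = g.build_genetic_image(record, ref, "cytb")
print("\nfirst 30 bits:", image.to_bitstring()[:30])
print("decoded head: ", g.decode_image(image)[:10], "(pads fill the fitted tail)")
# The concat image always has 4465 bits: 5 x (380 + 513). Any organism's
# proteins, shorter or longer, are end-padded or truncated to this frame.
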