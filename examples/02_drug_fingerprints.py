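"""Drug fingerprints as 256 hexadecimal nibbles.

A 1024-bit FP2 path fingerprint arrives as a 256-character hex string
(e.g. from Open Babel); each character becomes one feature in 0..15.
"""

from dtipred import parse_fp2_hex

hex_string = "a0f" + "0" * 253
fp = parse_fp2_hex("DB00201", hex_string)
print(f"drug {fp.drug_id}: {len(fp.values)} nibble features")
print(f"  first three nibbles: {fp.values[:3].tolist()}  (hex 'a','0','f')")
print(f"  round-trip hex prefix: {fp.to_hex()[:6]}")
# Each nibble aggregates 4 fingerprint bits, so the vector is a coarse
# substructure-occurrence profile of the molecule.
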