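"""Fragment-based average nucleotide identity on an ANI-calibrated clade.

Three ~1-Mb genomes are generated with branch substitution rates solved so
the expected pairwise identities are 99.37 / 98.93 / 98.88 percent; the ANI
measurement (1,020-nt fragments, 30% identity over 70% length retention)
should land within ~0.1 of those values.
"""

from microevo import ani, synthetic_clade as sc

clade = sc.generate_clade(sc.ani_calibration_config(seed=0))
matrix = ani.ani_matrix(clade.genomes)
print(matrix.round(2).to_string())
print("\nexpected from the generating branch rates:")
for pair, p in sorted(clade.manifest.expected_pair_identity.items()):
    print(f"  {pair}: {100 * p:.2f}")
print("\nANI >= ~95-96% is the conventional conspecificity boundary; all three")
print("pairs sit far above it, and the ordering (m4_4:m2_6 highest,")
print("m4_4:p1_1_43 lowest) matches the calibration.")
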