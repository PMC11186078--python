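"""Why 2D fingerprints cannot tell enantiomers apart — and what can.

Standardizes the two penicillamine enantiomers (the classic case where
one form is a drug and the other is toxic), shows their InChIKey layers,
embeds one ETKDG/MMFF94 conformer each, and contrasts the stereo-blind
circular fingerprint with the chirality-aware 3D shape descriptor.
"""

from stereobind import (
    cosine_distance,
    descriptor_3d,
    fingerprint_2d,
    generate_conformer,
    standardize_molecule,
)

pen_s = standardize_molecule("penicillamine_S", "CC(C)(S)[C@@H](N)C(=O)O")
pen_r = standardize_molecule("penicillamine_R", "CC(C)(S)[C@H](N)C(=O)O")

print(f"(S): {pen_s.inchikey}")
print(f"(R): {pen_r.inchikey}")
print(
    f"connectivity layers equal: {pen_s.connectivity_key == pen_r.connectivity_key}; "
    f"stereo layers equal: {pen_s.stereo_block == pen_r.stereo_block}"
)

fp_dist = cosine_distance(fingerprint_2d(pen_s), fingerprint_2d(pen_r))
print(f"fp2d cosine distance:  {fp_dist}")

conf_s = generate_conformer(pen_s, embed_seed=42)
conf_r = generate_conformer(pen_r, embed_seed=42)
geo_dist = cosine_distance(descriptor_3d(conf_s), descriptor_3d(conf_r))
print(f"geo3d cosine distance: {geo_dist:.5f}")
# fp2d is computed on the stereo-stripped constitution, so the distance is
# exactly 0: the 2D view cannot separate the safe drug from the toxin.
# geo3d's signed-volume chirality block differs between the mirror forms,
# so its distance is strictly positive.
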