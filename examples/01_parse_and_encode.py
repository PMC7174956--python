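"""Parse an .hhm profile and encode it as a 420-dimensional AATP vector.

Uses the built-in 3-residue worked example whose emission probabilities are
simple fractions, so every feature value can be checked by hand.
"""

import numpy as np

import hmmstack as hs

profile = hs.worked_example_profile()
print(f"profile {profile.protein_id!r}: L={profile.length}, "
      f"alphabet={profile.alphabet}")

# write it out and read it back: .hhm round trip
hs.write_hhm(profile, "/tmp/worked_example.hhm")
again = hs.parse_hhm("/tmp/worked_example.hhm")
print("round trip equal:", again == profile)

# scores -> probabilities: 0 -> 1.0, 1000 -> 0.5, '*' -> 0.0
norm = hs.normalize_profile(profile)
print("emission probabilities (nonzero entries):")
for i in range(norm.length):
    nz = {norm.alphabet[j]: norm.matrix[i, j]
          for j in np.flatnonzero(norm.matrix[i])}
    print(f"  state {i + 1}: {nz}")

aac = hs.compute_aac(norm)
tpc = hs.compute_tpc(norm)
vec = hs.encode_aatp(norm)
print(f"AAC (first 4 of 20): {np.round(aac.values[:4], 4)}")
print(f"TPC row 'A' nonzero: "
      f"{ {norm.alphabet[j]: round(tpc.values[0, j], 4) for j in np.flatnonzero(tpc.values[0])} }")
print(f"AATP feature vector length: {vec.values.shape[0]} (20 AAC + 400 TPC)")
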