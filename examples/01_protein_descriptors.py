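"""Protein descriptors from an evolutionary profile.

Writes a synthetic PSI-BLAST ASCII profile to disk, reads it back, maps the
integer log-odds scores through the logistic function, and computes the two
fixed-length descriptors: the pseudo-PSSM (column means + lagged squared
differences) and the 190 pairwise detrended cross-correlation coefficients.
"""

import tempfile
from pathlib import Path

import numpy as np

from dtipred import read_pssm, write_pssm, normalize_profile, psepssm, dcca_vector
from dtipred.dataset import generate_raw_fixture

bundle = generate_raw_fixture(n_targets=1, n_drugs=1, n_positives=1, seed=42)
with tempfile.TemporaryDirectory() as tmp:
    path = write_pssm(bundle.profiles[0], Path(tmp) / "T0000.pssm")
    profile = read_pssm(path)

print(f"profile: {profile.length} residues, scores in "
      f"[{profile.scores.min()}, {profile.scores.max()}]")

norm = normalize_profile(profile)
pse = psepssm(norm, lambda_order=3)
dcca = dcca_vector(norm, s=36)

print(f"PsePSSM descriptor: {len(pse.values)} features "
      f"(20 column means + 20 x 3 lag blocks)")
print(f"  first column means: {np.round(pse.values[:4], 3)}")
print(f"DCCA descriptor: {len(dcca.values)} column-pair coefficients, "
      f"range [{dcca.values.min():.3f}, {dcca.values.max():.3f}]")
# The means summarise overall substitution propensity per amino acid; the
# lag blocks capture sequence-order fluctuation; each DCCA entry measures
# how strongly two amino-acid score series co-fluctuate along the chain.
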