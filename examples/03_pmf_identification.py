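"""Identify a protein from a synthetic peptide-mass fingerprint.

Builds a 200-protein database, simulates a MALDI-TOF peak list for one of
its entries (tryptic peptides with 5 ppm mass scatter plus 10 contaminant
peaks), and runs the five-criterion PMF acceptance check: significant
MOWSE-style score, >=4 matched peptides, >10% coverage, 25 ppm peptide
tolerance, 0.2 Da parent tolerance.
"""

import numpy as np

from heterospot import (
    SearchParams,
    SpectrumConfig,
    identify,
    search_database,
    simulate_pmf_spectrum,
    simulate_protein_db,
)
from heterospot.pmf import MowseIndex

db = simulate_protein_db(200, seed=8)
index = MowseIndex(db, SearchParams())

target = list(db)[17]
spectrum = simulate_pmf_spectrum(db[target], SpectrumConfig(seed=99))
print(f"spectrum of {target}: {spectrum.shape[0]} peaks")

result = identify(spectrum, target, index, np.random.default_rng(0))
print(
    f"{result.n_matched} peptides matched, coverage {result.coverage:.1%}, "
    f"score {result.score:.3g} vs decoy 95% threshold {result.threshold:.3g}"
)
print("verdict:", "ACCEPTED" if result.accepted else "rejected")

ranked = search_database(spectrum, index)
print(f"best database hit: {ranked[0][0]} (true source: {target})")
# The score weights each matched peptide by how rare its mass bin is in the
# database; the threshold is the score a shuffled decoy beats 5% of the time.
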