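"""Small published data tables used in worked examples and checks.

The no-hit EST table gives, for eight duck EST markers with no BLAST hit in
the chicken assembly (candidates for the smallest microchromosomes missing
from that assembly), the number of positive hybrids out of the 90-hybrid
panel under each genotyping method: conventional PCR on WGA DNA (WGA-PCR),
microfluidic qPCR on WGA DNA (WGA-FLDMqPCR), and microfluidic qPCR on
pre-amplified standard DNA (Pre-ampFLDMqPCR).  WGA fails outright for some
of these regions, which is why the WGA-based methods show far lower counts.
"""

from __future__ import annotations

import numpy as np

from .io import ABSENT, PRESENT, GenotypeMatrix

N_HYBRIDS = 90

NO_HIT_EST_MARKERS = [
    "EstCtg11412",
    "EstCtg23833",
    "EstCtg2805",
    "EstCtg293",
    "EstCtg727",
    "EstCtg8099",
    "Y03G5XE5",
    "Y04H5QRB",
]

#: positive hybrids per marker (order as NO_HIT_EST_MARKERS) per method
NO_HIT_EST_POSITIVES = {
    "wga_pcr": [11, 0, 18, 24, 14, 1, 7, 13],
    "wga_fldm_qpcr": [3, 0, 3, 16, 1, 2, 0, 11],
    "preamp_fldm_qpcr": [25, 25, 24, 30, 44, 29, 25, 43],
}


def no_hit_est_matrix(method: str) -> GenotypeMatrix:
    """Genotype matrix consistent with the printed positive counts.

    Only marginal counts are published, so each row is ``n_pos`` present
    calls followed by absent calls — exactly what per-marker retention
    estimation consumes.
    """
    positives = NO_HIT_EST_POSITIVES[method]
    calls = np.full((len(NO_HIT_EST_MARKERS), N_HYBRIDS), ABSENT, dtype=np.int8)
    for i, n_pos in enumerate(positives):
        calls[i, :n_pos] = PRESENT
    return GenotypeMatrix(
        marker_ids=list(NO_HIT_EST_MARKERS),
        hybrid_ids=[f"H{j:03d}" for j in range(N_HYBRIDS)],
        calls=calls,
    )
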