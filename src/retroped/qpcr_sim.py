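"""Simulated genomic-DNA qPCR for insertion prevalence.

The model is the standard exponential-amplification picture with 100%
efficiency: the target Ct falls by one cycle per doubling of template,
so ``Ct = base - log2(template fraction) + noise``; the single-copy
reference-gene Ct is ``base' + noise``.  A template fraction of zero emits
a no-amplification sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NO_AMPLIFICATION = float("nan")

TARGET_BASE_CT = 24.0
REFERENCE_BASE_CT = 22.0
MAX_CYCLES = 45.0


@dataclass
class QpcrMeasurement:
    """Replicate Ct values for one sample: insertion assay + reference gene."""

    sample_id: str
    target_ct: list[float]
    reference_ct: list[float]

    def __post_init__(self) -> None:
        if not self.target_ct or not self.reference_ct:
            raise ValueError("need >= 1 replicate for target and reference")

    @property
    def no_amplification(self) -> bool:
        return all(np.isnan(self.target_ct))


def simulate_qpcr(fraction: float, ct_noise_sd: float, replicates: int,
                  rng: np.random.Generator,
                  sample_id: str = "sample") -> QpcrMeasurement:
    """Simulate one measurement of a template present at ``fraction``.

    ``fraction`` is the per-haploid-genome template fraction (1.0 = one
    copy per haploid genome; a heterozygote assayed on the insertion allele
    is 0.5).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if fraction < 0 or fraction > 1:
        raise ValueError("fraction must be in [0, 1]")
    ref = [float(REFERENCE_BASE_CT + rng.normal(0.0, ct_noise_sd))
           for _ in range(replicates)]
    if fraction == 0:
        tgt = [NO_AMPLIFICATION] * replicates
    else:
        tgt = [float(TARGET_BASE_CT - np.log2(fraction)
                     + rng.normal(0.0, ct_noise_sd))
               for _ in range(replicates)]
        if min(tgt) > MAX_CYCLES:
            tgt = [NO_AMPLIFICATION] * replicates
    return QpcrMeasurement(sample_id=sample_id, target_ct=tgt, reference_ct=ref)
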