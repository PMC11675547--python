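"""Maximum-tolerated allele-count test for population-frequency evidence.

BA1/BS1/PM2 decisions compare the *observed* allele count in a reference
population against the largest count still consistent, at a chosen
confidence, with a disease-compatible allele frequency.  Sampling of a rare
allele from ``allele_number`` chromosomes is modelled as Poisson with mean
``af_threshold * allele_number`` (the standard filtering-allele-frequency
approximation used by the CardioDB allele-frequency calculator): the
tolerated count is the one-sided confidence-level quantile of that
distribution.  An observed count strictly above the tolerated count means
the variant is too common for the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


class InsufficientFrequencyData(Exception):
    """Observed allele count/number are missing; the test cannot be run.

    Deliberately distinct from a ``False`` result: absence of population
    data must never count as benign frequency evidence.
    """


@dataclass(frozen=True)
class FrequencyThresholds:
    """Allele-frequency thresholds for stand-alone and strong benign evidence.

    Defaults are the BRCA1 maximum-tolerated allele frequencies: 0.1% for
    BA1 and 0.01% for BS1, tested at one-sided 95% confidence.
    """

    ba1_af: float = 0.001
    bs1_af: float = 0.0001
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.bs1_af < self.ba1_af < 1):
            raise ValueError(
                f"need 0 < bs1_af < ba1_af < 1, got ba1={self.ba1_af}, bs1={self.bs1_af}"
            )
        if not (0 < self.confidence < 1):
            raise ValueError(f"confidence must be in (0, 1), got {self.confidence}")


def max_tolerated_allele_count(
    af_threshold: float, allele_number: int, confidence: float = 0.95
) -> int:
    """Largest allele count consistent with ``af_threshold`` at ``confidence``.

    The count is the ``confidence`` quantile of Poisson(mean =
    ``af_threshold * allele_number``): the smallest c whose cumulative
    probability reaches the confidence level.  As the threshold tends to
    zero the tolerated count tends to zero.
    """
    if not (math.isfinite(af_threshold) and 0 < af_threshold < 1):
        raise ValueError(f"af_threshold must be a fraction in (0, 1), got {af_threshold}")
    if allele_number < 1 or allele_number != int(allele_number):
        raise ValueError(f"allele_number must be a positive integer, got {allele_number}")
    if not (0 < confidence < 1):
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    mean = af_threshold * allele_number
    return int(stats.poisson.ppf(confidence, mean))


def exceeds_frequency_threshold(
    allele_count: int | None,
    allele_number: int | None,
    af_threshold: float,
    confidence: float = 0.95,
) -> bool:
    """True iff the observed count strictly exceeds the tolerated count.

    Raises :class:`InsufficientFrequencyData` when either observation is
    missing — that outcome must not be conflated with "not exceeded".
    """
    if allele_count is None or allele_number is None:
        raise InsufficientFrequencyData(
            "allele_count and allele_number are required for the frequency test"
        )
    if allele_count < 0 or allele_count > allele_number:
        raise ValueError(
            f"need 0 <= allele_count <= allele_number, got AC={allele_count}, AN={allele_number}"
        )
    return allele_count > max_tolerated_allele_count(
        af_threshold, allele_number, confidence
    )
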