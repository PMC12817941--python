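"""Bench quantification: ddCt relative expression and Western densitometry.

``ddct_relative_expression`` implements the comparative-Ct method for qPCR:
each sample's target Ct is normalized to a reference gene (dCt = Ct_target
- Ct_reference), then to the mean dCt of a calibrator group (ddCt), and
expressed as a fold change 2**(-ddCt).  The calibrator group averages to a
relative expression of 1 on the log scale by construction.

``densitometry_fc`` quantifies sense/antisense pull-down Western blots:
per replicate, band densities are normalized to the input lane and the fold
change is (sense/input) / (antisense/input); the mean fold change over
replicates is reported with a two-sample t-test (Student's equal-variance
by default, matching the usual figure-legend convention; Welch optional)
on the input-normalized sense vs antisense values.  For proteins showing
several bands, densities are summed per lane before normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "DensitometryTriple",
    "ddct_relative_expression",
    "densitometry_fc",
]


class BenchError(ValueError):
    """Invalid bench-quantification input."""


@dataclass(frozen=True)
class QpcrMeasurement:
    """One sample's target and reference-gene Ct values."""

    sample: str
    ct_target: float
    ct_reference: float
    group: str = "test"  # "calibrator" or "test"

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not math.isfinite(ct):
                raise BenchError(f"{self.sample}: {name} must be finite")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class DensitometryTriple:
    """Background-subtracted band densities of one blot replicate."""

    sense_density: float
    antisense_density: float
    input_density: float
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.input_density <= 0:
            raise BenchError(f"replicate {self.replicate!r}: input density must be positive")
        if self.sense_density < 0 or self.antisense_density < 0:
            raise BenchError(f"replicate {self.replicate!r}: negative band density")


def ddct_relative_expression(
    test: Iterable[QpcrMeasurement], calibrator: Iterable[QpcrMeasurement]
) -> dict[str, float]:
    """Relative expression 2**(-ddCt) per test sample against the calibrator mean."""
    test = list(test)
    calibrator = list(calibrator)
    if not calibrator:
        raise BenchError("calibrator group is empty")
    if not test:
        raise BenchError("test group is empty")
    cal_mean = sum(m.dct for m in calibrator) / len(calibrator)
    return {m.sample: 2.0 ** -(m.dct - cal_mean) for m in test}


def densitometry_fc(
    replicates: Sequence[DensitometryTriple], equal_var: bool = True
) -> tuple[list[float], float, float]:
    """Per-replicate and mean sense/antisense fold change plus a t-test p-value.

    Returns ``(per_replicate_fc, mean_fc, p_value)``.  A zero antisense band
    makes the fold change undefined and is reported as an error rather than
    silently dropped.
    """
    if len(replicates) < 2:
        raise BenchError("need >= 2 replicates for a fold-change estimate with a p-value")
    zero = [r.replicate or str(i) for i, r in enumerate(replicates) if r.antisense_density == 0]
    if zero:
        raise BenchError(f"antisense density is zero in replicate(s) {zero}: fold change undefined")
    sense_norm = [r.sense_density / r.input_density for r in replicates]
    anti_norm = [r.antisense_density / r.input_density for r in replicates]
    fcs = [s / a for s, a in zip(sense_norm, anti_norm)]
    mean_fc = sum(fcs) / len(fcs)
    t = stats.ttest_ind(sense_norm, anti_norm, equal_var=equal_var)
    p = float(t.pvalue) if math.isfinite(t.pvalue) else 1.0
    return fcs, mean_fc, p
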