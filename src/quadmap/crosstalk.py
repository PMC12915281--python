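"""Spectral-separation validation: trace-similarity tests and bleed-through.

Whether exogenous voltage/calcium dyes contaminate the cAMP FRET readout is
assessed by comparing ΔFRET traces acquired under different dye loadings
with a two-sample Kolmogorov–Smirnov test; channel bleed-through (e.g. the
calcium dye's emission leaking into the voltage channel) is quantified as
the least-squares slope of the contaminated channel on the source channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AnalysisError, ConfigurationError

MODES = ("values", "paired_difference")


@dataclass
class ComparisonResult:
    """Kolmogorov–Smirnov comparison of two ΔFRET traces.

    ``statistic`` is the KS D in [0, 1] (0 iff the empirical distributions
    are identical); ``mode`` records whether raw value distributions or the
    symmetry of time-paired differences was tested.
    """

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mode: str


def ks_compare(trace_a, trace_b, mode: str = "values") -> ComparisonResult:
    """Two-sample KS comparison of two traces with asymptotic p-values.

    ``mode="values"`` compares the two value distributions directly.
    ``mode="paired_difference"`` compares the time-paired differences
    ``d = a - b`` against their mirror ``-d`` (a test of symmetry of the
    paired differences about zero; requires equal lengths).
    """
    a = np.asarray(trace_a, dtype=float).ravel()
    b = np.asarray(trace_b, dtype=float).ravel()
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}")
    if len(a) < 3 or len(b) < 3:
        raise AnalysisError("both traces must have at least 3 samples")
    if mode == "values":
        res = stats.ks_2samp(a, b, method="asymp")
        return ComparisonResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                                len(a), len(b), mode)
    if len(a) != len(b):
        raise AnalysisError("paired_difference mode requires equal-length traces")
    d = a - b
    if np.all(d == 0):
        return ComparisonResult(0.0, 1.0, len(a), len(b), mode)
    res = stats.ks_2samp(d, -d, method="asymp")
    return ComparisonResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                            len(a), len(b), mode)


def bleedthrough_fraction(source_trace, target_trace) -> float:
    """Fraction of the source channel's signal leaking into the target.

    The least-squares slope of the (time-aligned, baseline-corrected)
    target on the source, clipped to [0, 1].

    Raises
    ------
    AnalysisError
        If the source trace has zero variance or lengths differ.
    """
    s = np.asarray(source_trace, dtype=float).ravel()
    t = np.asarray(target_trace, dtype=float).ravel()
    if len(s) != len(t):
        raise AnalysisError("traces must be time-aligned (equal length)")
    if len(s) < 2 or np.var(s) == 0:
        raise AnalysisError("source trace has zero variance")
    slope = float(np.polyfit(s, t, 1)[0])
    return float(np.clip(slope, 0.0, 1.0))
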