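"""Population-genetic duration estimator and monomorphic-site assurance.

Under sustained artificial selection the expected number of mutations fixed
along a lineage is m = 2 v Ne P T, with v the per-generation mutation rate,
Ne the effective population size, T the generations spent in the lineage and
P the Kimura diffusion fixation probability

    P = (1 - exp(-4 s q Ne)) / (1 - exp(-4 s Ne)),

where s is the selection intensity and q the initial mutant frequency.  In a
fully selfing crop Ne = N/2, and for a new mutant (q = 1/(2N)) P ~ 1 - e^-s.
Because the rate terms cancel when mutation and selection conditions are
assumed constant across phases, the relative duration of the early phase is
estimated directly from fixed-mutation counts:

    T_e / T_w  =  m_e / (m_e + m_lineage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError

S_ZERO_TOLERANCE = 1e-8  # |4 s Ne| below this switches to the neutral limit


def fixation_probability(s: float, q: float, ne: float) -> float:
    """Kimura diffusion fixation probability; the s -> 0 removable singularity
    returns the continuous limit q."""
    if ne <= 0:
        raise EstimationError("Ne must be positive")
    if not 0.0 < q < 1.0:
        raise EstimationError("initial frequency q must be in (0, 1)")
    a = 4.0 * s * ne
    if abs(a) < S_ZERO_TOLERANCE:
        return q
    # guard the deleterious tail against overflow in exp(-a) for large -a
    if a < -700:
        return 0.0
    num = -math.expm1(-a * q)
    den = -math.expm1(-a)
    return num / den


def selfing_fixation_approx(s: float) -> float:
    """P ~ 1 - e^-s for a new mutant in a fully selfing population."""
    if s < 0:
        raise EstimationError("selfing approximation requires s >= 0")
    return -math.expm1(-s)


def expected_fixed_mutations(v: float, ne: float, p: float, t: float) -> float:
    """m = 2 v Ne P T."""
    if min(v, ne, p, t) < 0:
        raise EstimationError("all duration parameters must be non-negative")
    return 2.0 * v * ne * p * t


def relative_duration(m_e: int, m_lineage: int) -> float:
    """T_e / T_w = m_e / (m_e + m_lineage); scale-invariant in the counts."""
    denom = m_e + m_lineage
    if denom <= 0:
        raise EstimationError("relative duration undefined: zero mutation total")
    return m_e / denom


def monomorphic_assurance(n: int) -> float:
    """Probability that agreement among n independent genomes at a site marks
    a truly monomorphic site, under the equal-frequency binomial model:
    1 - (1/2)^n."""
    if n < 1:
        raise EstimationError("need at least one genome")
    return 1.0 - 0.5**n


# ---------------------------------------------------------------------------
# Locus selection and the pooled estimate
# ---------------------------------------------------------------------------

OUTLIER_IQR_MULTIPLIER = 3.0  # lineage count above Q3 + 3*IQR excludes a locus


def select_duration_loci(
    phase_counts: pd.DataFrame,
    manual_exclude: Sequence[str] = (),
    iqr_multiplier: float = OUTLIER_IQR_MULTIPLIER,
) -> tuple[list[str], list[str]]:
    """Pick loci usable for the duration estimate.

    ``phase_counts`` is indexed by locus with integer columns
    ``early``/``indica``/``japonica``.  A locus qualifies when it accumulated
    at least one mutation in each of the three periods; qualifying loci whose
    indica or japonica count exceeds Q3 + ``iqr_multiplier`` * IQR of the
    qualifying distribution are then dropped as outliers (the rule that
    formalizes the published AGO2-style exclusion), as are loci named in
    ``manual_exclude``.  Returns (included, excluded) locus lists.
    """
    excluded: list[str] = []
    qualifying: list[str] = []
    for locus, row in phase_counts.iterrows():
        if str(locus) in manual_exclude:
            excluded.append(str(locus))
        elif min(row["early"], row["indica"], row["japonica"]) >= 1:
            qualifying.append(str(locus))
        else:
            excluded.append(str(locus))
    if qualifying and iqr_multiplier is not None:
        sub = phase_counts.loc[qualifying]
        outliers: set[str] = set()
        for col in ("indica", "japonica"):
            vals = sub[col].to_numpy(dtype=float)
            q1, q3 = np.percentile(vals, [25, 75])
            cutoff = q3 + iqr_multiplier * (q3 - q1)
            outliers |= {
                str(locus) for locus, v in zip(sub.index, vals) if v > cutoff
            }
        excluded.extend(sorted(outliers))
        qualifying = [l for l in qualifying if l not in outliers]
    return qualifying, excluded


@dataclass
class DurationEstimate:
    region_basis: str
    loci_included: list[str]
    loci_excluded: list[str]
    m_e: int
    m_i: int
    m_j: int
    fraction_by_indica: float
    fraction_by_japonica: float

    def as_dict(self) -> dict:
        return {
            "region_basis": self.region_basis,
            "n_loci": len(self.loci_included),
            "loci_included": self.loci_included,
            "loci_excluded": self.loci_excluded,
            "m_e": self.m_e,
            "m_i": self.m_i,
            "m_j": self.m_j,
            "fraction_by_indica": round(self.fraction_by_indica, 3),
            "fraction_by_japonica": round(self.fraction_by_japonica, 3),
            "percent_by_indica": round(100 * self.fraction_by_indica, 1),
            "percent_by_japonica": round(100 * self.fraction_by_japonica, 1),
        }


def estimate_duration(
    phase_counts: pd.DataFrame,
    region_basis: str = "five_prime",
    manual_exclude: Sequence[str] = (),
    iqr_multiplier: float = OUTLIER_IQR_MULTIPLIER,
) -> DurationEstimate:
    """Pooled relative-duration estimate over the selected loci."""
    included, excluded = select_duration_loci(
        phase_counts, manual_exclude=manual_exclude, iqr_multiplier=iqr_multiplier
    )
    if not included:
        raise EstimationError("no loci qualify for the duration estimate")
    sub = phase_counts.loc[included]
    m_e = int(sub["early"].sum())
    m_i = int(sub["indica"].sum())
    m_j = int(sub["japonica"].sum())
    return DurationEstimate(
        region_basis=region_basis,
        loci_included=included,
        loci_excluded=excluded,
        m_e=m_e,
        m_i=m_i,
        m_j=m_j,
        fraction_by_indica=relative_duration(m_e, m_i),
        fraction_by_japonica=relative_duration(m_e, m_j),
    )
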