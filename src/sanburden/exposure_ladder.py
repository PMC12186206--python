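"""Sanitation-ladder normalization: raw survey counts -> three-rung exposure shares.

The ladder has three rungs: connection to sewerage or a septic tank (the
referent, lowest-risk rung), other improved facilities, and unimproved
facilities / open defecation.  Survey microdata report (a) respondents with
a non-missing facility response, (b) respondents with a sewer or septic
connection, and (c) respondents using an improved facility among those
*without* such a connection.  Normalization:

    sewer      = sewer_respondents / nonmissing
    improved   = (improved_among_nonsewer / (nonmissing - sewer_respondents))
                 * (1 - sewer)
    unimproved = 1 - (sewer + improved)

so the triple lies on the unit simplex by construction.  When every
respondent is sewered the improved ratio is 0/0; its limit is 0 (the
(1 - sewer) factor vanishes) and that convention is applied rather than
raising, so fully-sewered country-years normalize to (1, 0, 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel_io import (
    EXPOSURE_CATEGORIES,
    SanitationRawPanel,
    SanitationShares,
)


class UndefinedExposureError(ValueError):
    """No non-missing respondents: the exposure distribution is undefined."""


def normalize_ladder(nonmissing: float, sewer: float,
                     improved_among_nonsewer: float) -> tuple[float, float, float]:
    """Normalize one row of respondent counts to (sewer, improved, unimproved)."""
    if nonmissing <= 0:
        raise UndefinedExposureError(
            "nonmissing_respondents must be > 0 to define an exposure distribution"
        )
    if sewer < 0 or improved_among_nonsewer < 0:
        raise ValueError("respondent counts must be non-negative")
    if sewer > nonmissing:
        raise ValueError("sewer_respondents exceeds nonmissing_respondents")
    nonsewer = nonmissing - sewer
    if improved_among_nonsewer > nonsewer:
        raise ValueError("improved respondents exceed non-sewer respondents")
    p_sewer = sewer / nonmissing
    if nonsewer == 0:
        p_improved = 0.0  # 0/0 limit: (1 - sewer) factor is exactly 0
    else:
        p_improved = (improved_among_nonsewer / nonsewer) * (1.0 - p_sewer)
    p_unimproved = 1.0 - (p_sewer + p_improved)
    return p_sewer, p_improved, max(p_unimproved, 0.0)


def normalize_panel(raw: SanitationRawPanel) -> SanitationShares:
    """Vectorized ladder normalization of a whole respondent-count panel."""
    df = raw.data
    n = df["nonmissing_respondents"].to_numpy(float)
    if (n <= 0).any():
        bad = df.loc[n <= 0, ["country", "year"]].to_dict("records")[:5]
        raise UndefinedExposureError(f"zero nonmissing respondents at {bad}")
    s = df["sewer_respondents"].to_numpy(float)
    imp = df["improved_respondents_among_nonsewer"].to_numpy(float)
    p_sewer = s / n
    nonsewer = n - s
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(nonsewer > 0, imp / np.where(nonsewer > 0, nonsewer, 1.0), 0.0)
    p_improved = ratio * (1.0 - p_sewer)
    p_unimproved = np.clip(1.0 - (p_sewer + p_improved), 0.0, 1.0)
    out = pd.DataFrame(
        {
            "country": df["country"].to_numpy(),
            "year": df["year"].to_numpy(),
            "sewer": p_sewer,
            "improved": p_improved,
            "unimproved": p_unimproved,
        }
    )
    return SanitationShares(out)


def unsafe_fraction(shares: pd.Series | dict, definition: set[str] | frozenset[str]) -> float:
    """Summed share of the categories counted as exposed for a PAF factor.

    ``definition`` may cover {unimproved} alone or {unimproved, improved},
    depending on whether "unsafe sanitation" is read narrowly or broadly;
    the referent (sewer) can never be part of an exposure definition.
    """
    unknown = set(definition) - set(EXPOSURE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown exposure categories {sorted(unknown)}")
    if "sewer" in definition:
        raise ValueError("the referent category cannot be counted as exposed")
    return float(sum(shares[c] for c in definition))
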