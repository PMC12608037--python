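"""Cassette-type x pathotype association: 2x2 table, odds ratio, Fisher's exact test.

The table layout is rows = {short, long}, columns = {pathogenic,
non-pathogenic}:

        a = short & pathogenic      b = short & non-pathogenic
        c = long  & pathogenic      d = long  & non-pathogenic

The two-sided p-value uses the point-probability method: with margins fixed,
sum the hypergeometric probabilities of all tables whose point probability is
<= that of the observed table (a relative guard of 1e-7 absorbs float ties).
All hypergeometric mass is computed in log space so tables with n in the
thousands remain exact to float precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

_TIE_GUARD = 1e-7

PATHOGENIC = "pathogenic"
NON_PATHOGENIC = "non-pathogenic"


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # short, pathogenic
    b: int  # short, non-pathogenic
    c: int  # long, pathogenic
    d: int  # long, non-pathogenic

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or cell != int(cell):
                raise ValueError("contingency cells must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    p_value: float
    n: int
    correction_applied: bool


def build_contingency(
    variants: Mapping[str, str],
    pathotypes: Mapping[str, str],
) -> tuple[ContingencyTable, dict]:
    """Count strains into the 2x2 table.

    Only SHORT/LONG strains with a known pathotype are counted; PARTIAL/NONE
    variants and strains lacking metadata are excluded (counts returned).
    """
    if not variants:
        raise ValueError("empty panel: no strains to tabulate")
    a = b = c = d = 0
    excluded_variant = 0
    excluded_metadata = 0
    for strain, variant in variants.items():
        if variant not in ("SHORT", "LONG"):
            excluded_variant += 1
            continue
        ptype = pathotypes.get(strain)
        if ptype not in (PATHOGENIC, NON_PATHOGENIC):
            excluded_metadata += 1
            logger.warning("strain %s has variant %s but no pathotype; excluded",
                           strain, variant)
            continue
        patho = ptype == PATHOGENIC
        if variant == "SHORT":
            a += patho
            b += not patho
        else:
            c += patho
            d += not patho
    table = ContingencyTable(a, b, c, d)
    if table.n == 0:
        raise ValueError("no strains left after exclusions; cannot test")
    return table, {
        "excluded_variant": excluded_variant,
        "excluded_metadata": excluded_metadata,
    }


def odds_ratio(table: ContingencyTable) -> tuple[float, bool]:
    """Sample odds ratio (a*d)/(b*c); Haldane-Anscombe +0.5 on any zero cell.

    Returns (odds_ratio, correction_applied).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c), True
    return (a * d) / (b * c), False


def _log_hypergeom_pmf(k: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(table with top-left cell k | margins r1, r2, c1)."""
    n = r1 + r2
    return (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - (c1 - k) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_two_sided(table: ContingencyTable) -> tuple[float, bool]:
    """Two-sided Fisher exact p by the point-probability method.

    Returns (p_value, degenerate_margins). Degenerate margins (a zero row or
    column total) give p = 1.0 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if table.n == 0:
        raise ValueError("cannot test an empty table")
    if 0 in (r1, r2, c1, c2):
        logger.debug("degenerate margins %s: p = 1.0 by convention",
                     (r1, r2, c1, c2))
        return 1.0, True
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logp = _log_hypergeom_pmf(k, r1, r2, c1)
    logp_obs = _log_hypergeom_pmf(np.array([a]), r1, r2, c1)[0]
    include = logp <= logp_obs + math.log1p(_TIE_GUARD)
    p = float(np.exp(logp[include]).sum())
    return min(p, 1.0), False


def associate(
    variants: Mapping[str, str],
    pathotypes: Mapping[str, str],
) -> tuple[AssociationResult, dict]:
    """Build the table and compute OR + exact p in one step."""
    table, excluded = build_contingency(variants, pathotypes)
    or_value, corrected = odds_ratio(table)
    p, degenerate = fisher_exact_two_sided(table)
    result = AssociationResult(
        odds_ratio=or_value, p_value=p, n=table.n, correction_applied=corrected,
    )
    report = {
        "counts": {"short_pathogenic": table.a, "short_nonpathogenic": table.b,
                   "long_pathogenic": table.c, "long_nonpathogenic": table.d},
        "odds_ratio": or_value,
        "p_value": p,
        "n": table.n,
        "correction_applied": corrected,
        "degenerate_margins": degenerate,
        **excluded,
    }
    return result, report
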