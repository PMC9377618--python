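"""Dyadic association indices from daily group co-membership.

The half-weight index (HWI) of a dyad is

    HWI = x / (x + y_AB + (y_A + y_B) / 2)

where, over all sampling periods, ``x`` counts periods in which the two were
in the same group at least once, ``y_AB`` periods in which both were
identified but never together, and ``y_A`` / ``y_B`` periods in which only one
of the two was identified.  HWI ranges from 0 (never associated) to 1 (always
associated) and discounts for the halves of the time each member of a pair is
sighted without the other being identified.

Population summaries derived from the matrix:

* social differentiation ``S`` — coefficient of variation of the dyadic HWI
  values, a measure of how heterogeneous association probabilities are
  (S < 0.3 homogeneous; S > 0.5 well differentiated);
* ``H`` — mean number of observed associates per individual;
* the power rule for detecting preferred companionship: the null hypothesis
  of no preferred associates can be rejected when S²·H > 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sightings import SamplingPeriods

__all__ = [
    "DyadTallies",
    "AssociationMatrix",
    "AssociationSummary",
    "dyad_tallies",
    "half_weight_index",
    "association_matrix",
    "summarize",
    "preferred_power_rule",
]


@dataclass
class DyadTallies:
    """Symmetric per-dyad period tallies (n, n); diagonals are zero.

    x:   periods the dyad was grouped together at least once
    yab: periods both were identified but never in the same group
    ya:  periods only the row individual was identified
    yb:  periods only the column individual was identified
    (``ya[i, j] == yb[j, i]`` by construction.)
    """

    ids: list[str]
    x: np.ndarray
    yab: np.ndarray
    ya: np.ndarray
    yb: np.ndarray
    n_periods_seen: np.ndarray  # per individual


def dyad_tallies(periods: SamplingPeriods) -> DyadTallies:
    """Accumulate x / y_AB / y_A / y_B over all sampling periods."""
    n = periods.n_individuals
    x = np.zeros((n, n), dtype=int)
    both_seen = np.zeros((n, n), dtype=int)
    seen = periods.seen_matrix()
    for p in range(periods.n_periods):
        x += periods.together_matrix(p)
        s = seen[p]
        both_seen += np.outer(s, s)
    np.fill_diagonal(both_seen, 0)
    counts = seen.sum(axis=0)
    yab = both_seen - x
    ya = counts[:, None] - both_seen
    yb = counts[None, :] - both_seen
    np.fill_diagonal(ya, 0)
    np.fill_diagonal(yb, 0)
    return DyadTallies(
        ids=list(periods.ids), x=x, yab=yab, ya=ya, yb=yb, n_periods_seen=counts
    )


@dataclass
class AssociationMatrix:
    """Half-weight index matrix plus the tallies it was computed from.

    ``hwi`` is symmetric with zero diagonal; dyads never co-sampled (all
    tallies zero) are assigned HWI 0 and flagged in ``never_cosampled``.
    """

    ids: list[str]
    hwi: np.ndarray
    tallies: DyadTallies
    never_cosampled: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    def offdiag_values(self) -> np.ndarray:
        """Dyadic HWI values, each dyad once (upper triangle)."""
        iu = np.triu_indices(self.n, k=1)
        return self.hwi[iu]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format dyad table (idA, idB, x, yA, yB, yAB, HWI)."""
        iu = np.triu_indices(self.n, k=1)
        t = self.tallies
        return pd.DataFrame(
            {
                "idA": [self.ids[i] for i in iu[0]],
                "idB": [self.ids[j] for j in iu[1]],
                "x": t.x[iu],
                "yA": t.ya[iu],
                "yB": t.yb[iu],
                "yAB": t.yab[iu],
                "HWI": self.hwi[iu],
            }
        )

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.hwi, index=self.ids, columns=self.ids)


def half_weight_index(tallies: DyadTallies) -> AssociationMatrix:
    """HWI matrix from dyadic tallies; all-zero dyads get HWI 0."""
    denom = tallies.x + tallies.yab + 0.5 * (tallies.ya + tallies.yb)
    with np.errstate(invalid="ignore", divide="ignore"):
        hwi = np.where(denom > 0, tallies.x / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(hwi, 0.0)
    never = denom == 0
    np.fill_diagonal(never, False)
    return AssociationMatrix(
        ids=list(tallies.ids), hwi=hwi, tallies=tallies, never_cosampled=never
    )


def association_matrix(periods: SamplingPeriods) -> AssociationMatrix:
    """Convenience: tallies then HWI in one call."""
    return half_weight_index(dyad_tallies(periods))


@dataclass
class AssociationSummary:
    per_individual: pd.DataFrame  # mean_hwi, max_hwi, strength, n_associates
    mean_hwi: float               # over all dyads (canonical)
    mean_hwi_nonzero: float       # over dyads with HWI > 0
    sd_hwi: float
    social_differentiation: float  # S = CV of dyadic HWI (all dyads)
    mean_associates: float         # H


def summarize(matrix: AssociationMatrix) -> AssociationSummary:
    """Per-individual and population association summaries.

    ``S`` is the coefficient of variation (sample SD / mean) of the dyadic
    HWI values over all dyads; ``H`` is the mean, over individuals, of the
    number of associates observed at least once together (x ≥ 1).
    """
    if matrix.n < 2:
        raise ValueError("association summary requires at least two individuals")
    vals = matrix.offdiag_values()
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    nz = vals[vals > 0]
    hwi = matrix.hwi
    mask = ~np.eye(matrix.n, dtype=bool)
    per = pd.DataFrame(
        {
            "individual_id": matrix.ids,
            "mean_hwi": hwi.sum(axis=1) / (matrix.n - 1),
            "max_hwi": np.where(mask, hwi, -np.inf).max(axis=1),
            "strength": hwi.sum(axis=1),
            "n_associates": (matrix.tallies.x >= 1).sum(axis=1),
        }
    )
    s = sd / mean if mean > 0 else 0.0
    return AssociationSummary(
        per_individual=per,
        mean_hwi=mean,
        mean_hwi_nonzero=float(nz.mean()) if nz.size else 0.0,
        sd_hwi=sd,
        social_differentiation=float(s),
        mean_associates=float(per["n_associates"].mean()),
    )


def preferred_power_rule(s: float, h: float) -> tuple[float, bool]:
    """Power rule for rejecting 'no preferred associates': S²·H > 5.

    Returns the product and whether the null is rejected (strict inequality).
    """
    if s < 0 or h < 0:
        raise ValueError("S and H must be nonnegative")
    product = s * s * h
    return product, product > 5.0
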