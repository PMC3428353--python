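"""Tests on cysteine-loss events: bond-pair bias and site-model LRTs.

The classic OBP fold pairs its six canonical cysteines into three
disulphide bonds (C1-C3, C2-C5, C4-C6).  If losing one cysteine relaxes
selection on its bonded partner, two-cysteine loss events should hit a
bond pair more often than chance predicts.  After one cysteine is lost,
one of the five remaining is the partner, so under the null a second loss
lands on the partner with probability q = 1/5; the observed number of
bond-pair events among the two-cysteine events is then binomial, and the
upper tail gives the test p-value.

The module also provides the chi-square arithmetic for likelihood-ratio
tests between nested codon site models (M1a vs M2a, M7 vs M8, M8a vs M8),
operating on reported log-likelihoods and statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

__all__ = [
    "BondTopology",
    "BondBiasResult",
    "LrtComparison",
    "is_bond_pair",
    "bond_bias_pvalue",
    "count_bond_events",
    "lrt_pvalue",
    "compare_site_models",
]


def _pairs(*pairs: tuple[str, str]) -> frozenset[frozenset[str]]:
    return frozenset(frozenset(p) for p in pairs)


@dataclass(frozen=True)
class BondTopology:
    """Disulphide connectivity of the canonical cysteines.

    Default is the classic OBP fold: C1-C3, C2-C5, C4-C6.
    """

    pairs: frozenset[frozenset[str]] = field(
        default_factory=lambda: _pairs(("C1", "C3"), ("C2", "C5"), ("C4", "C6"))
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pair in self.pairs:
            if len(pair) != 2:
                raise ValueError(f"bond pair must have two cysteines: {sorted(pair)}")
            if pair & seen:
                raise ValueError("bond pairs must be disjoint")
            seen |= pair


@dataclass(frozen=True)
class BondBiasResult:
    """Outcome of the bond-pair bias test.

    x two-cysteine events, y of them hitting a bond pair, null success
    probability q, and the binomial upper-tail p-value P(Y >= y).
    """

    x: int
    y: int
    q: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.y <= self.x:
            raise ValueError(f"need 0 <= y <= x, got x={self.x}, y={self.y}")
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q must lie in (0, 1), got {self.q}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def is_bond_pair(lost: frozenset | set, topology: Optional[BondTopology] = None) -> bool:
    """True iff the two lost cysteines form a disulphide bond."""
    lost = frozenset(lost)
    if len(lost) != 2:
        raise ValueError(f"lost set must have exactly two cysteines, got {sorted(lost)}")
    topology = topology or BondTopology()
    return lost in topology.pairs


def bond_bias_pvalue(x: int, y: int, q: float = 0.2) -> BondBiasResult:
    """Binomial upper-tail probability that >= y of x two-cysteine loss
    events hit a disulphide-bond pair when each does so with probability q.

    p = sum_{k=y..x} C(x,k) q^k (1-q)^(x-k), via the binomial survival
    function (regularised incomplete beta), which is numerically stable
    in the far tail.
    """
    if x < 0 or not 0 <= y <= x:
        raise ValueError(f"need 0 <= y <= x, got x={x}, y={y}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    # sf(y-1) = P(Y >= y); exact for y = 0 as well
    p = float(stats.binom.sf(y - 1, x, q))
    return BondBiasResult(x=x, y=y, q=q, p_value=min(p, 1.0))


def count_bond_events(table, topology: Optional[BondTopology] = None) -> tuple[int, int]:
    """Count (x, y) from an event table: x = events losing exactly two
    cysteines, y = those whose pair forms a disulphide bond.  Events losing
    one or three cysteines do not enter the test.
    """
    topology = topology or BondTopology()
    x = 0
    y = 0
    for lost in table.lost_sets():
        if len(lost) != 2:
            continue
        x += 1
        if is_bond_pair(lost, topology):
            y += 1
    return x, y


def lrt_pvalue(statistic: float, df: int) -> float:
    """Chi-square upper-tail p-value of a likelihood-ratio statistic.

    For df = 2 this is exp(-statistic/2).
    """
    if statistic < 0:
        raise ValueError(f"likelihood-ratio statistic must be >= 0, got {statistic}")
    if df < 1:
        raise ValueError(f"df must be a positive integer, got {df}")
    return float(stats.chi2.sf(statistic, df))


@dataclass(frozen=True)
class LrtComparison:
    """A nested site-model comparison from reported numbers.

    Carries the reported log-likelihoods and likelihood-ratio statistic,
    the p-value computed from the *reported* statistic, and a consistency
    flag: ``statistic_consistent`` is False when 2*(lnL_alt - lnL_null)
    disagrees with the reported statistic beyond ``tol`` — the comparison
    then still uses the reported statistic but makes the discrepancy
    visible rather than silently resolving it.
    """

    null_model: str
    alt_model: str
    lnL_null: float
    lnL_alt: float
    statistic: float
    df: int
    p_value: float
    statistic_consistent: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def compare_site_models(
    null_model: str,
    alt_model: str,
    lnL_null: float,
    lnL_alt: float,
    statistic: float,
    df: int,
    tol: float = 0.05,
) -> LrtComparison:
    """Build an :class:`LrtComparison` from reported values, flagging any
    mismatch between the reported statistic and 2*(lnL_alt - lnL_null)."""
    recomputed = 2.0 * (lnL_alt - lnL_null)
    consistent = abs(recomputed - statistic) <= tol
    return LrtComparison(
        null_model=null_model,
        alt_model=alt_model,
        lnL_null=lnL_null,
        lnL_alt=lnL_alt,
        statistic=statistic,
        df=df,
        p_value=lrt_pvalue(statistic, df),
        statistic_consistent=consistent,
    )
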