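"""Trophic-guild structure: tallies and chi-square homogeneity tests.

Taxa carry one of three feeding-guild labels (herbivore, predator,
scavenger); "unknown" records are excluded from the tests but counted.
The omnibus test compares the three guild abundances against an equal
N/3 expectation (df = 2); the three pairwise tests compare each guild pair
against an equal split (df = 1) at the Bonferroni-corrected level
``alpha' = alpha/3``.  The same battery runs on family richness per guild.
Equal expected counts are an explicit, overridable assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .table import CommunityTable

__all__ = [
    "TEST_GUILDS",
    "GuildTally",
    "GuildTestReport",
    "tally_guilds",
    "chisq_gof",
    "guild_tests",
]

TEST_GUILDS = ("herbivore", "predator", "scavenger")


@dataclass(frozen=True)
class GuildTally:
    """Abundance and family richness per trophic guild.

    ``family_richness[g]`` counts distinct families with at least one
    individual of guild ``g``; a family whose species span several guilds
    contributes to each of them.
    """

    abundance: dict
    family_richness: dict
    n_unknown: int = 0

    def abundances(self) -> np.ndarray:
        return np.array([self.abundance[g] for g in TEST_GUILDS])

    def richnesses(self) -> np.ndarray:
        return np.array([self.family_richness[g] for g in TEST_GUILDS])


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    p: float
    valid: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        d = {"X2": self.statistic, "df": self.df, "p": self.p, "valid": self.valid}
        if self.note:
            d["note"] = self.note
        return d


@dataclass(frozen=True)
class GuildTestReport:
    """Omnibus + Bonferroni-corrected pairwise chi-square tests."""

    quantity: str  # "abundance" or "family_richness"
    observed: dict
    omnibus: ChisqResult
    pairwise: dict  # (guild, guild) -> ChisqResult
    alpha: float
    alpha_corrected: float

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [
            pair
            for pair, res in self.pairwise.items()
            if res.valid and res.p < self.alpha_corrected
        ]

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "observed": dict(self.observed),
            "alpha": self.alpha,
            "alpha_corrected": self.alpha_corrected,
            "omnibus": self.omnibus.to_dict(),
            "pairwise": {
                f"{a}_vs_{b}": {
                    **res.to_dict(),
                    "significant": bool(res.valid and res.p < self.alpha_corrected),
                }
                for (a, b), res in self.pairwise.items()
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def tally_guilds(table: CommunityTable) -> GuildTally:
    """Sum abundance and count distinct families per trophic guild.

    Records labelled "unknown" are excluded from the tallies and reported
    in ``n_unknown`` (individuals).  Raises if no record carries a known
    guild.
    """
    abundance = {g: 0 for g in TEST_GUILDS}
    families: dict[str, set] = {g: set() for g in TEST_GUILDS}
    n_unknown = 0
    for r in table.records:
        if r.guild == "unknown":
            n_unknown += r.count
            continue
        abundance[r.guild] += r.count
        if r.count > 0:
            families[r.guild].add(r.family)
    if all(v == 0 for v in abundance.values()):
        raise ValueError("no records with a known trophic guild")
    return GuildTally(
        abundance=abundance,
        family_richness={g: len(families[g]) for g in TEST_GUILDS},
        n_unknown=n_unknown,
    )


def chisq_gof(observed, expected) -> ChisqResult:
    """Pearson chi-square goodness of fit: ``X2 = sum (O-E)^2/E``, df = c-1."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise ValueError("observed and expected must be 1-d and equal length")
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be > 0")
    x2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    return ChisqResult(statistic=x2, df=df, p=float(stats.chi2.sf(x2, df)))


def _battery(observed: np.ndarray, alpha: float, quantity: str) -> GuildTestReport:
    total = observed.sum()
    omnibus = chisq_gof(observed, np.full(3, total / 3.0))
    pairwise = {}
    for i, j in ((0, 1), (0, 2), (1, 2)):
        pair = (TEST_GUILDS[i], TEST_GUILDS[j])
        o = observed[[i, j]]
        if min(o) == 0:
            pairwise[pair] = ChisqResult(np.nan, 1, np.nan, valid=False,
                                         note=f"zero {quantity} in one guild")
        else:
            pairwise[pair] = chisq_gof(o, np.full(2, o.sum() / 2.0))
    return GuildTestReport(
        quantity=quantity,
        observed={g: int(n) for g, n in zip(TEST_GUILDS, observed)},
        omnibus=omnibus,
        pairwise=pairwise,
        alpha=alpha,
        alpha_corrected=alpha / 3.0,
    )


def guild_tests(tally: GuildTally, alpha: float = 0.05
                ) -> tuple[GuildTestReport, GuildTestReport]:
    """Run the chi-square battery on guild abundances and family richness.

    Returns ``(abundance_report, richness_report)``.  A guild with zero
    abundance invalidates its pairwise comparisons (flagged, the rest
    proceed).  ``alpha_corrected`` is ``alpha/3`` for the three pairwise
    tests.
    """
    return (
        _battery(tally.abundances().astype(float), alpha, "abundance"),
        _battery(tally.richnesses().astype(float), alpha, "family_richness"),
    )
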