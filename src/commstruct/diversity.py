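"""Shannon-Wiener diversity, evenness, and Hutcheson's two-sample t-test.

All indices use natural logarithms (nats).  The sampling variance of H
follows Hutcheson's (1970) approximation,

    Var(H) = (sum p_i (ln p_i)^2 - (sum p_i ln p_i)^2) / N + (S-1)/(2 N^2),

and two communities are compared with the t-type statistic
``t = (H_a - H_b)/sqrt(Var_a + Var_b)`` on Welch-style degrees of freedom
``(Var_a + Var_b)^2 / (Var_a^2/N_a + Var_b^2/N_b)``; p-values are
two-sided.  Proportions use observed counts without bias correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sad import _as_counts

__all__ = [
    "DiversitySummary",
    "HutchesonResult",
    "shannon",
    "evenness",
    "shannon_variance",
    "hutcheson_test",
]


@dataclass(frozen=True)
class DiversitySummary:
    """Shannon index H (nats), its variance, richness S, total N, evenness J.

    ``J`` is ``H/ln(S)``; it is None (undefined) for a single-group sample,
    where ln(S) = 0.
    """

    H: float
    varH: float
    S: int
    N: int
    J: float | None

    def to_dict(self) -> dict:
        return {
            "H": self.H,
            "varH": self.varH,
            "S": self.S,
            "N": self.N,
            "J": self.J,
        }


@dataclass(frozen=True)
class HutchesonResult:
    t_stat: float
    df: float
    p_two_sided: float

    def to_dict(self) -> dict:
        return {"t": self.t_stat, "df": self.df, "p": self.p_two_sided}


def _hp(counts) -> tuple[np.ndarray, int, int]:
    n = _as_counts(counts)
    return n / n.sum(), int(n.size), int(n.sum())


def shannon(counts) -> DiversitySummary:
    """Shannon-Wiener diversity of a ranked abundance vector (natural log).

    Fills H, Var(H), S, N and evenness J in one pass.
    """
    p, S, N = _hp(counts)
    lp = np.log(p)
    H = float(-(p * lp).sum())
    var = shannon_variance(counts) if N >= 2 else 0.0
    J = float(H / np.log(S)) if S >= 2 else None
    return DiversitySummary(H=H, varH=var, S=S, N=N, J=J)


def evenness(summary: DiversitySummary) -> float | None:
    """Shannon evenness ``J = H/ln(S)``; None (undefined) when S = 1."""
    if summary.S < 2:
        return None
    return float(summary.H / np.log(summary.S))


def shannon_variance(counts) -> float:
    """Hutcheson's approximate sampling variance of the Shannon index."""
    p, S, N = _hp(counts)
    if N < 2:
        raise ValueError("variance of H needs N >= 2 individuals")
    lp = np.log(p)
    first = float(((p * lp**2).sum() - (p * lp).sum() ** 2) / N)
    return first + (S - 1) / (2.0 * N * N)


def hutcheson_test(a, b) -> HutchesonResult:
    """Hutcheson's modified t-test comparing two Shannon indices.

    Degenerate when both samples have zero variance of H (two single-group
    samples), which raises a ValueError.
    """
    sa, sb = shannon(a), shannon(b)
    va, vb = shannon_variance(a), shannon_variance(b)
    pooled = va + vb
    if pooled == 0.0:
        raise ValueError(
            "both samples have zero Var(H) (single-group communities); "
            "the Hutcheson test is undefined"
        )
    t = (sa.H - sb.H) / np.sqrt(pooled)
    df = pooled**2 / (va**2 / sa.N + vb**2 / sb.N)
    p = 1.0 if t == 0 else float(2.0 * stats.t.sf(abs(t), df))
    return HutchesonResult(t_stat=float(t), df=float(df), p_two_sided=min(p, 1.0))
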