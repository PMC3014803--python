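"""AIC-based ranking of competing SAD fits with a ΔAIC equivalence rule.

Fits are sorted by AIC (lower is better); every fit whose AIC lies within
``delta_threshold`` of the minimum is flagged as statistically equivalent
to the winner.  The default threshold of 2 is the conventional reading of
ΔAIC under which two models are taken to describe the data equally well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

__all__ = ["FitSummary", "ModelRanking", "select_model"]


class FitSummary(NamedTuple):
    """Minimal stand-in for a full fit when only name and AIC are known."""

    name: str
    aic: float
    nobs: int | None = None


@dataclass(frozen=True)
class ModelRanking:
    """Fits ordered by AIC, with ΔAIC and equivalence flags."""

    names: tuple[str, ...]
    aics: tuple[float, ...]
    delta_aics: tuple[float, ...]
    equivalent: tuple[bool, ...]
    delta_threshold: float

    @property
    def best(self) -> str:
        return self.names[0]

    @property
    def equivalent_set(self) -> tuple[str, ...]:
        return tuple(n for n, e in zip(self.names, self.equivalent) if e)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.names,
                "aic": self.aics,
                "delta_aic": self.delta_aics,
                "equivalent": self.equivalent,
            }
        )

    def to_dict(self) -> dict:
        return {
            "best_model": self.best,
            "delta_threshold": self.delta_threshold,
            "ranking": [
                {
                    "model": n,
                    "aic": a,
                    "delta_aic": d,
                    "equivalent": bool(e),
                }
                for n, a, d, e in zip(
                    self.names, self.aics, self.delta_aics, self.equivalent
                )
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def select_model(fits: Sequence, delta_threshold: float = 2.0) -> ModelRanking:
    """Rank fits of the same data by AIC and flag ΔAIC-equivalent models.

    ``fits`` may be SADFitResult objects or :class:`FitSummary` tuples; each
    needs ``name`` and ``aic`` attributes.  Fits carrying ``nobs`` must all
    refer to the same number of ranked groups, otherwise the comparison is
    meaningless and a ValueError is raised.  Ties keep input order (stable
    sort).
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to select among")
    nobs_seen = {f.nobs for f in fits if getattr(f, "nobs", None) is not None}
    if len(nobs_seen) > 1:
        raise ValueError(f"fits are for differing data lengths: {sorted(nobs_seen)}")
    order = sorted(range(len(fits)), key=lambda i: fits[i].aic)  # stable
    names = tuple(fits[i].name for i in order)
    aics = tuple(float(fits[i].aic) for i in order)
    deltas = tuple(a - aics[0] for a in aics)
    equiv = tuple(d < delta_threshold for d in deltas)
    return ModelRanking(
        names=names,
        aics=aics,
        delta_aics=deltas,
        equivalent=equiv,
        delta_threshold=float(delta_threshold),
    )
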