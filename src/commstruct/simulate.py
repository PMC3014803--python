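"""Synthetic community tables with the structure the analyses assume.

The generator emulates a pooled pitfall-trap survey of ground-dwelling
arthropods: S lowest-level taxa whose counts follow a configurable
species-abundance distribution, nested uniformly into families and orders,
with per-species trophic-guild labels and, optionally, one hyper-dominant
"recruiter" species (mass-recruiting colonial taxa such as ants fall into
traps in numbers far beyond their rank-abundance expectation).

Counts always sum exactly to the configured N: the recruiter receives
``round(recruiter_fraction * N)`` individuals and the remainder is
distributed over the other species by a multinomial draw on the SAD's
(realised or expected) proportions.  Everything is reproducible from the
integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .sad import (
    brokenstick_expected_props,
    logseries_x_for_mean,
    preemption_expected_props,
)
from .table import CommunityTable, TaxonRecord, write_table

__all__ = ["CommunitySimConfig", "simulate_community", "generate_fixture_suite",
           "valdes_like_config"]

GUILD_NAMES = ("herbivore", "predator", "scavenger")


@dataclass(frozen=True)
class CommunitySimConfig:
    """Parameters of one synthetic community.

    ``model`` is one of "logseries" (params: x), "preemption" (params: k),
    "brokenstick" (no params) or "lognormal" (params: mu, sigma).
    ``guild_probs`` are the per-species probabilities of the three guilds
    (herbivore, predator, scavenger).  ``recruiter_fraction`` > 0 injects a
    dominant species holding that share of N.
    """

    model: str
    S: int
    N: int
    params: dict = field(default_factory=dict)
    n_families: int = 20
    n_orders: int = 8
    guild_probs: tuple[float, float, float] = (0.25, 0.55, 0.20)
    recruiter_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("logseries", "preemption", "brokenstick", "lognormal"):
            raise ValueError(f"unknown SAD model {self.model!r}")
        if self.S > self.N:
            raise ValueError(f"infeasible: S={self.S} > N={self.N}")
        if not 0.0 <= self.recruiter_fraction < 1.0:
            raise ValueError("recruiter_fraction must be in [0, 1)")
        if abs(sum(self.guild_probs) - 1.0) > 1e-12:
            raise ValueError("guild_probs must sum to 1")
        if not 1 <= self.n_orders <= self.n_families <= self.S:
            raise ValueError("need 1 <= n_orders <= n_families <= S")


_COND_CACHE: dict = {}


def _logseries_conditional_counts(x: float, S: int, N: int,
                                  rng: np.random.Generator) -> np.ndarray:
    """Exact sample of S iid log-series counts conditioned on their sum N.

    The partial-sum distributions ``P(n_1+...+n_s = m)`` for s = 1..S are
    built once per (x, S, N) by FFT convolution of the (N-truncated) pmf and
    cached; counts are then drawn backwards, each from its exact conditional
    given the remaining total.  Conditioning keeps S and N exactly at their
    configured values while leaving the counts genuinely log-series
    distributed — a multinomial rescale of unconstrained draws would not
    (the rescale factor is heavy-tailed and distorts the realised shape).
    """
    if S == 1:
        return np.array([N], dtype=np.int64)
    key = (round(float(x), 12), S, N)
    if key not in _COND_CACHE:
        n = np.arange(1, N + 1)
        logpmf = n * np.log(x) - np.log(n)
        pmf = np.exp(logpmf - logpmf.max())
        pmf /= pmf.sum()
        size = 1
        while size < 2 * N + 2:
            size *= 2
        step = np.fft.rfft(pmf, size)
        cur = step.copy()
        partial = [None, pmf]
        for _ in range(2, S + 1):
            cur = cur * step
            partial.append(np.clip(np.fft.irfft(cur, size)[: N + 1], 0.0, None))
        while len(_COND_CACHE) >= 4:
            _COND_CACHE.pop(next(iter(_COND_CACHE)))
        _COND_CACHE[key] = (pmf, partial)
    pmf, partial = _COND_CACHE[key]
    counts = np.empty(S, dtype=np.int64)
    rem = N
    for s in range(S, 1, -1):
        nmax = rem - (s - 1)  # leave >= 1 for each remaining species
        cdf = np.cumsum(pmf[:nmax] * partial[s - 1][rem - np.arange(1, nmax + 1)])
        nval = int(np.searchsorted(cdf, rng.random() * cdf[-1])) + 1
        counts[s - 1] = nval
        rem -= nval
    counts[0] = rem
    return counts


def _sad_probs(model: str, params: dict, S: int, rng: np.random.Generator
               ) -> np.ndarray:
    """Relative species abundances for S species under the configured SAD."""
    if model == "preemption":
        return preemption_expected_props(S, params["k"]).expected_props
    if model == "brokenstick":
        return brokenstick_expected_props(S).expected_props
    # lognormal: Poisson draws on lognormal intensities, rescaled
    for _ in range(100):
        lam = np.exp(rng.normal(params["mu"], params["sigma"], size=S))
        draws = rng.poisson(lam).astype(float)
        if draws.sum() > 0:
            return draws / draws.sum()
    raise RuntimeError("lognormal intensities produced no individuals")


def simulate_community(config: CommunitySimConfig) -> CommunityTable:
    """Draw one community table from the configured SAD.

    Species counts: log-series communities are sampled exactly as iid
    log-series counts conditioned on summing to N (so S, N and the count
    shape are all preserved); the other models draw a multinomial over the
    model's proportions.  The optional recruiter species takes round(f*N)
    first and the remainder is distributed over the other S-1 species.
    Species are nested into families and families into orders uniformly at
    random, with every family and order guaranteed non-empty; guilds are
    iid draws from ``guild_probs``.  Species that receive zero individuals
    are kept as zero-count records (aggregation drops them).
    """
    rng = np.random.default_rng(config.seed)
    S = config.S

    def _draw(n_species: int, total: int) -> np.ndarray:
        if n_species > total:
            raise ValueError(
                f"infeasible: {n_species} species cannot share {total} individuals"
            )
        if config.model == "logseries":
            return _logseries_conditional_counts(
                config.params["x"], n_species, total, rng)
        probs = _sad_probs(config.model, config.params, n_species, rng)
        return rng.multinomial(total, probs)

    if config.recruiter_fraction > 0:
        n_dom = int(round(config.recruiter_fraction * config.N))
        counts = np.concatenate([[n_dom], _draw(S - 1, config.N - n_dom)])
    else:
        counts = _draw(S, config.N)

    # nested taxonomy: first n labels pinned to distinct groups (so the
    # configured family/order richness is realised), remainder uniform
    def _nest(n_children: int, n_parents: int) -> np.ndarray:
        assign = np.empty(n_children, dtype=int)
        pinned = rng.permutation(n_children)[:n_parents]
        assign[pinned] = np.arange(n_parents)
        rest_idx = np.setdiff1d(np.arange(n_children), pinned)
        assign[rest_idx] = rng.integers(0, n_parents, size=rest_idx.size)
        return assign

    fam_of_species = _nest(S, config.n_families)
    ord_of_family = _nest(config.n_families, config.n_orders)
    guilds = rng.choice(GUILD_NAMES, size=S, p=config.guild_probs)

    width = len(str(S))
    records = []
    for i in range(S):
        fam = fam_of_species[i]
        records.append(
            TaxonRecord(
                taxon_id=f"t{i + 1:0{width}d}",
                species=f"sp{i + 1:0{width}d}",
                family=f"fam{fam + 1:03d}",
                order=f"ord{ord_of_family[fam] + 1:02d}",
                guild=str(guilds[i]),
                count=int(counts[i]),
            )
        )
    meta = {
        "simulated": {
            "model": config.model,
            "params": dict(config.params),
            "S": S,
            "N": config.N,
            "recruiter_fraction": config.recruiter_fraction,
            "seed": config.seed,
        }
    }
    return CommunityTable(records=tuple(records), metadata=meta)


def valdes_like_config(seed: int = 0) -> CommunitySimConfig:
    """Study conditions of an arid-steppe pitfall survey: 160 species in
    52 families and 18 orders, 28,111 individuals, one colonial recruiter
    species holding 83% of the catch, log-series decay among the rest, and
    predator-dominated guilds."""
    n_rest = 28_111 - round(0.83 * 28_111)
    x = logseries_x_for_mean(n_rest / 159)
    return CommunitySimConfig(
        model="logseries",
        S=160,
        N=28_111,
        params={"x": x},
        n_families=52,
        n_orders=18,
        guild_probs=(0.25, 0.55, 0.20),
        recruiter_fraction=0.83,
        seed=seed,
    )


def generate_fixture_suite(seed: int, out_dir) -> dict:
    """Write one CSV fixture per SAD model plus a Valdés-like table.

    Returns (and writes as ``manifest.json``) the mapping fixture name ->
    file, model, true parameters and seed.  The four per-model fixtures use
    S=150, N=25,000 with parameters consistent with that mean count (the
    multinomial rescale to N pins the realised mean at N/S).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    S, N = 150, 25_000
    x = logseries_x_for_mean(N / S)
    sigma = 1.2
    mu = float(np.log(N / S) - sigma**2 / 2)
    base = dict(S=S, N=N, n_families=20, n_orders=8)
    configs = {
        "logseries": CommunitySimConfig(model="logseries", params={"x": x},
                                        seed=seed, **base),
        "preemption": CommunitySimConfig(model="preemption", params={"k": 0.05},
                                         seed=seed + 1, **base),
        "brokenstick": CommunitySimConfig(model="brokenstick", params={},
                                          seed=seed + 2, **base),
        "lognormal": CommunitySimConfig(model="lognormal",
                                        params={"mu": mu, "sigma": sigma},
                                        seed=seed + 3, **base),
        "valdes_like": replace(valdes_like_config(), seed=seed + 4),
    }
    manifest = {}
    for name, cfg in configs.items():
        path = out / f"{name}.csv"
        write_table(simulate_community(cfg), path)
        manifest[name] = {
            "file": path.name,
            "model": cfg.model,
            "true_params": {k: float(v) for k, v in cfg.params.items()},
            "S": cfg.S,
            "N": cfg.N,
            "recruiter_fraction": cfg.recruiter_fraction,
            "seed": cfg.seed,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
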