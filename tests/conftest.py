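import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from commstruct.table import CommunityTable, TaxonRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

GUILDS = ("herbivore", "predator", "scavenger", "unknown")


def make_random_table(rng: np.random.Generator, n_taxa=None,
                      allow_zero=True) -> CommunityTable:
    """Small random community table for property tests."""
    n = int(n_taxa or rng.integers(2, 15))
    n_fam = int(rng.integers(1, max(2, n // 2 + 1)))
    n_ord = int(rng.integers(1, n_fam + 1))
    records = []
    for i in range(n):
        fam = int(rng.integers(0, n_fam))
        count = int(rng.integers(0 if allow_zero else 1, 50))
        records.append(
            TaxonRecord(
                taxon_id=f"t{i}",
                species=f"sp{i}",
                family=f"f{fam}",
                order=f"o{fam % n_ord}",
                guild=str(rng.choice(GUILDS)),
                count=count,
            )
        )
    if all(r.count == 0 for r in records):
        records[0] = TaxonRecord("t0", "sp0", records[0].family,
                                 records[0].order, records[0].guild, 1)
    return CommunityTable(records=tuple(records))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def four_row_csv(tmp_path):
    """The canonical 4-taxon fixture file: counts 10, 5, 3, 2."""
    p = tmp_path / "four.csv"
    p.write_text(
        "taxon_id,species,family,order,guild,count\n"
        "a,spA,famX,ordI,predator,10\n"
        "b,spB,famX,ordI,herbivore,5\n"
        "c,spC,famY,ordI,scavenger,3\n"
        "d,spD,famZ,ordII,predator,2\n"
    )
    return p
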