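"""Calorie trade network: data model, validation, baseline accounting and I/O.

The central object is :class:`TradeNetwork`, a directed weighted graph whose
nodes are countries and whose edge weights are the calories (kcal/year)
embedded in bilateral food exports.  Country ordering is the sorted order of
the country codes everywhere, so all derived vectors and tables are
deterministic.

Baseline accounting: a country's pre-shock demand is

    dem_i = prod_i + imp_i - exp_i

with exports the out-going weight sum and imports the in-coming weight sum.
Domestic production is not observed directly; it is derived from the domestic
food supply by adding the net trade balance,

    prod_i = supply_i + exp_i - imp_i,

which makes dem_i identically equal to supply_i at baseline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: days used to convert kcal/year to kcal/person/day
DAYS_PER_YEAR = 365


class NetworkValidationError(ValueError):
    """Raised when a trade network violates a structural invariant."""


@dataclass(frozen=True)
class Country:
    """A node of the trade network.

    Parameters
    ----------
    id : str
        Short unique code (ISO-3 style).
    name : str
        Human readable name.
    gdp : float
        Economy size in arbitrary (but network-wide consistent) currency
        units; only relative GDP matters for the cascade rationing rule.
    population : float
        Persons, > 0.
    supply : float
        Domestic food supply in kcal/year, >= 0.
    """

    id: str
    name: str
    gdp: float
    population: float
    supply: float

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("country id must be non-empty")
        if not np.isfinite(self.gdp) or self.gdp <= 0:
            raise NetworkValidationError(f"country {self.id}: gdp must be > 0")
        if not np.isfinite(self.population) or self.population <= 0:
            raise NetworkValidationError(
                f"country {self.id}: population must be > 0"
            )
        if not np.isfinite(self.supply) or self.supply < 0:
            raise NetworkValidationError(
                f"country {self.id}: supply must be >= 0"
            )


@dataclass(frozen=True)
class BaselineAccounts:
    """Pre-shock exports, imports and demand, as Series indexed by country."""

    exp: pd.Series
    imp: pd.Series
    dem: pd.Series


class TradeNetwork:
    """Directed weighted calorie trade network with country attributes.

    Edges with zero weight are treated as absent (the cascade model defines
    neighborhoods over strictly positive weights).  Self-loops and negative
    weights are rejected.
    """

    def __init__(
        self,
        countries: Iterable[Country],
        edges: Iterable[tuple[str, str, float]],
    ) -> None:
        countries = list(countries)
        ids = [c.id for c in countries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate country ids: {dupes}")
        order = sorted(range(len(countries)), key=lambda k: countries[k].id)
        self.countries: list[Country] = [countries[k] for k in order]
        self.codes: list[str] = [c.id for c in self.countries]
        self._index = {c: i for i, c in enumerate(self.codes)}
        n = len(self.codes)

        self.gdp = np.array([c.gdp for c in self.countries], dtype=float)
        self.population = np.array(
            [c.population for c in self.countries], dtype=float
        )
        self.supply = np.array([c.supply for c in self.countries], dtype=float)

        W = np.zeros((n, n), dtype=float)
        for o, d, w in edges:
            if o not in self._index:
                raise NetworkValidationError(
                    f"edge references unknown country id {o!r}"
                )
            if d not in self._index:
                raise NetworkValidationError(
                    f"edge references unknown country id {d!r}"
                )
            if o == d:
                raise NetworkValidationError(f"self-loop on {o!r} not allowed")
            if not np.isfinite(w) or w < 0:
                raise NetworkValidationError(
                    f"edge {o}->{d}: weight must be finite and >= 0, got {w}"
                )
            if w == 0:
                continue  # zero weight == no link
            i, j = self._index[o], self._index[d]
            if W[i, j] != 0:
                raise NetworkValidationError(f"duplicate edge {o}->{d}")
            W[i, j] = w
        self.weights: np.ndarray = W

        prod = self.supply + W.sum(axis=1) - W.sum(axis=0)
        bad = np.where(prod < 0)[0]
        if bad.size:
            names = [self.codes[i] for i in bad]
            raise NetworkValidationError(
                "derived production negative (imports exceed supply plus "
                f"exports) for: {names}"
            )
        self.production: np.ndarray = prod

    # -- basic protocol ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        try:
            return self._index[code]
        except KeyError:
            raise KeyError(f"unknown country id {code!r}") from None

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Positive-weight edges in deterministic (origin, dest) order."""
        rows, cols = np.nonzero(self.weights)
        return [
            (self.codes[i], self.codes[j], float(self.weights[i, j]))
            for i, j in zip(rows.tolist(), cols.tolist())
        ]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.weights))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.codes)
        g.add_weighted_edges_from(self.edge_list())
        return g

    def attribute_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.codes,
                "name": [c.name for c in self.countries],
                "gdp": self.gdp,
                "population": self.population,
                "supply": self.supply,
            }
        )

    def content_hash(self) -> str:
        """SHA-256 over a canonical text serialization (order-independent input)."""
        h = hashlib.sha256()
        for c in self.countries:
            h.update(
                f"{c.id},{c.name},{c.gdp!r},{c.population!r},{c.supply!r}\n".encode()
            )
        for o, d, w in self.edge_list():
            h.update(f"{o},{d},{w!r}\n".encode())
        return h.hexdigest()

    def rescaled(self, factor: float) -> "TradeNetwork":
        """Rescale every calorie quantity (weights and supply) by ``factor``.

        The cascade model is homogeneous of degree one in calories, so this
        rescales all deficits by the same factor while leaving GDP-based
        rationing untouched.
        """
        if factor <= 0:
            raise ValueError("factor must be > 0")
        countries = [
            Country(c.id, c.name, c.gdp, c.population, c.supply * factor)
            for c in self.countries
        ]
        edges = [(o, d, w * factor) for o, d, w in self.edge_list()]
        return TradeNetwork(countries, edges)


def estimate_production(network: TradeNetwork) -> pd.Series:
    """Per-country production: supply plus net trade balance (kcal/year)."""
    return pd.Series(network.production, index=network.codes, name="production")


def baseline_accounts(network: TradeNetwork) -> BaselineAccounts:
    """Exports (row sums), imports (column sums) and baseline demand."""
    exp = network.weights.sum(axis=1)
    imp = network.weights.sum(axis=0)
    dem = network.production + imp - exp
    idx = pd.Index(network.codes, name="id")
    return BaselineAccounts(
        exp=pd.Series(exp, index=idx, name="exp"),
        imp=pd.Series(imp, index=idx, name="imp"),
        dem=pd.Series(dem, index=idx, name="dem"),
    )


def per_capita_daily(network: TradeNetwork, annual: np.ndarray) -> np.ndarray:
    """Convert per-country kcal/year to kcal/person/day."""
    return np.asarray(annual, dtype=float) / (
        network.population * DAYS_PER_YEAR
    )


# -- file I/O ---------------------------------------------------------------

EDGE_COLUMNS = ["origin_id", "dest_id", "kcal_per_year"]
ATTR_COLUMNS = ["id", "name", "gdp", "population", "supply"]


def read_network(edge_file, attr_file) -> TradeNetwork:
    """Load a network from a delimited edge list plus attribute table.

    Both files are comma-separated UTF-8 with a header row.  Every edge
    endpoint must appear in the attribute table; zero-weight edges are
    dropped; negative weights, self-loops and inconsistent production are
    rejected.
    """
    attrs = pd.read_csv(
        attr_file, dtype={"id": str, "name": str},
        float_precision="round_trip",
    )
    missing = [c for c in ATTR_COLUMNS if c not in attrs.columns]
    if missing:
        raise NetworkValidationError(
            f"attribute file missing columns: {missing}"
        )
    edges_df = pd.read_csv(
        edge_file, dtype={"origin_id": str, "dest_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in EDGE_COLUMNS if c not in edges_df.columns]
    if missing:
        raise NetworkValidationError(f"edge file missing columns: {missing}")

    countries = [
        Country(
            id=row.id,
            name=row.name_,
            gdp=float(row.gdp),
            population=float(row.population),
            supply=float(row.supply),
        )
        for row in attrs.rename(columns={"name": "name_"}).itertuples()
    ]
    edges = [
        (row.origin_id, row.dest_id, float(row.kcal_per_year))
        for row in edges_df.itertuples()
    ]
    return TradeNetwork(countries, edges)


def write_network(network: TradeNetwork, edge_file, attr_file) -> None:
    """Write the two-file delimited form; full float precision round-trips."""
    attrs = network.attribute_frame()
    attrs.to_csv(attr_file, index=False, float_format="%.17g")
    edges = pd.DataFrame(network.edge_list(), columns=EDGE_COLUMNS)
    edges.to_csv(edge_file, index=False, float_format="%.17g")
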