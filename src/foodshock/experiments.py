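"""Batch shock experiments and the derived country-level risk measures.

One cascade is run per (origin country, alpha) pair; the resulting grid of
final per-capita daily demand deficits feeds four summary measures:

exposure
    a country's mean final deficit over shocks originating everywhere;
hedging share
    the fraction of its own domestic shock a country passes on to the
    network (1 minus retained deficit over shock);
reserve level
    the 95th percentile of a country's deficits pooled across all origins
    and all alpha values — the stock shielding it from all but the worst 5%
    of simulated shocks;
vulnerability
    counts of deficits at or above a critical threshold (250 / 500
    kcal/person/day) and a log rank-sum score over simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cascade import ShockSpec, run_cascade
from .network import DAYS_PER_YEAR, TradeNetwork

DEFAULT_ALPHAS = (0.0, 0.5, 1.0)
DEFAULT_SHOCK_FRACTION = 0.3
DEFAULT_THRESHOLDS = (250.0, 500.0)
DEFAULT_POP_MIN = 1e6
DEFAULT_PERCENTILE = 95.0


@dataclass
class ExperimentGrid:
    """Final deficits for every (origin, destination, alpha) triple.

    ``dd`` is indexed [alpha, origin, destination] in kcal/person/day of the
    destination's population.  ``shock`` holds per-origin shock sizes in
    kcal/year; ``converged`` flags each (alpha, origin) run.
    """

    network: TradeNetwork
    alphas: tuple[float, ...]
    shock_fraction: float
    dd: np.ndarray  # (n_alpha, n, n) kcal/person/day
    shock: np.ndarray  # (n,) kcal/year
    converged: np.ndarray  # (n_alpha, n) bool
    network_hash: str = ""

    def __post_init__(self) -> None:
        if not self.network_hash:
            self.network_hash = self.network.content_hash()

    @property
    def codes(self) -> list[str]:
        return self.network.codes

    def alpha_index(self, alpha: float) -> int:
        for k, a in enumerate(self.alphas):
            if np.isclose(a, alpha):
                return k
        raise KeyError(f"alpha {alpha} not in grid (has {self.alphas})")

    @property
    def n_entries(self) -> int:
        return int(np.prod(self.dd.shape))

    def to_frame(self) -> pd.DataFrame:
        """Long form: one row per (origin, destination, alpha)."""
        n = self.network.n
        recs = []
        for k, a in enumerate(self.alphas):
            for i, o in enumerate(self.codes):
                for j, d in enumerate(self.codes):
                    recs.append((o, d, a, self.dd[k, i, j]))
        return pd.DataFrame(
            recs, columns=["origin", "dest", "alpha", "dd_percap"]
        )

    def annual(self) -> np.ndarray:
        """Deficits back in kcal/year (destination population scaled)."""
        pop = self.network.population
        return self.dd * (pop * DAYS_PER_YEAR)[None, None, :]


def run_grid(
    network: TradeNetwork,
    shock_fraction: float = DEFAULT_SHOCK_FRACTION,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    tol: float | None = None,
    max_steps: int | None = None,
) -> ExperimentGrid:
    """Run one cascade per (origin, alpha); deterministic given the network."""
    n = network.n
    alphas = tuple(alphas)
    dd = np.zeros((len(alphas), n, n))
    shock = shock_fraction * network.production
    converged = np.zeros((len(alphas), n), dtype=bool)
    kwargs = {}
    if max_steps is not None:
        kwargs["max_steps"] = max_steps
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-run fallbacks logged in bulk
        for k, a in enumerate(alphas):
            for i, origin in enumerate(network.codes):
                if network.production[i] == 0:
                    converged[k, i] = True
                    continue
                res = run_cascade(
                    network,
                    ShockSpec(origin, shock_fraction, a),
                    tol=tol,
                    **kwargs,
                )
                dd[k, i, :] = res.final_dd_percap.values
                converged[k, i] = res.converged
    if not converged.all():
        bad = int((~converged).sum())
        warnings.warn(f"{bad} cascade runs did not converge", stacklevel=2)
    return ExperimentGrid(
        network=network,
        alphas=alphas,
        shock_fraction=shock_fraction,
        dd=dd,
        shock=shock,
        converged=converged,
    )


def exposure(
    grid: ExperimentGrid, alpha: float, include_domestic: bool = True
) -> pd.Series:
    """Mean final deficit per destination over all shock origins.

    By default the average includes the destination's own domestic-shock
    simulation; ``include_domestic=False`` drops the diagonal.
    """
    k = grid.alpha_index(alpha)
    D = grid.dd[k]
    if include_domestic:
        vals = D.mean(axis=0)
    else:
        n = D.shape[0]
        vals = (D.sum(axis=0) - np.diag(D)) / (n - 1)
    return pd.Series(
        vals, index=pd.Index(grid.codes, name="id"), name="exposure"
    )


def hedging_share(grid: ExperimentGrid, alpha: float) -> pd.Series:
    """Fraction of its own domestic shock each origin passes to the network.

    share_i = 1 - retained_i / shock_i, clipped to [0, 1]; NaN where the
    shock is zero (no production to lose).
    """
    k = grid.alpha_index(alpha)
    pop = grid.network.population
    retained = np.diag(grid.dd[k]) * pop * DAYS_PER_YEAR  # kcal/year
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(
            grid.shock > 0, 1.0 - retained / grid.shock, np.nan
        )
    share = np.clip(share, 0.0, 1.0)
    return pd.Series(
        share, index=pd.Index(grid.codes, name="id"), name="hedging_share"
    )


def reserves_p95(
    grid: ExperimentGrid,
    pop_min: float = DEFAULT_POP_MIN,
    percentile: float = DEFAULT_PERCENTILE,
) -> pd.DataFrame:
    """Worst-case reserve table: per-country deficit percentile.

    For each destination the given percentile (linear interpolation between
    order statistics) of its deficits pooled over every origin and every
    alpha, in kcal/person/day and as a percentage of per-capita daily
    domestic supply.  Restricted to population >= pop_min, sorted
    descending by deficit.
    """
    pooled = grid.dd.reshape(-1, grid.network.n)  # (n_alpha * n, n)
    p = np.percentile(pooled, percentile, axis=0, method="linear")
    net = grid.network
    daily_supply = net.supply / (net.population * DAYS_PER_YEAR)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(daily_supply > 0, 100.0 * p / daily_supply, np.nan)
    df = pd.DataFrame(
        {
            "deficit_kcal_percap_day": p,
            "pct_of_supply": pct,
            "population": net.population,
        },
        index=pd.Index(grid.codes, name="id"),
    )
    df = df[df["population"] >= pop_min]
    return df.sort_values("deficit_kcal_percap_day", ascending=False)


def vulnerability_counts(
    grid: ExperimentGrid, threshold: float
) -> pd.DataFrame:
    """Per (country, alpha): how many origins push its deficit >= threshold."""
    recs = []
    for k, a in enumerate(grid.alphas):
        counts = (grid.dd[k] >= threshold).sum(axis=0)
        for j, c in enumerate(grid.codes):
            recs.append((c, a, int(counts[j])))
    return pd.DataFrame(recs, columns=["id", "alpha", "count"])


def vulnerability_rank(grid: ExperimentGrid) -> pd.DataFrame:
    """Log rank-sum vulnerability score per (country, alpha).

    Within each single simulation, destinations are ranked ascending by
    deficit (smallest = 1, ties get average ranks); ranks are summed over
    the origins of that alpha and log-transformed.
    """
    recs = []
    for k, a in enumerate(grid.alphas):
        ranks = rankdata(grid.dd[k], axis=1, method="average")
        sums = ranks.sum(axis=0)
        for j, c in enumerate(grid.codes):
            recs.append((c, a, float(np.log(sums[j]))))
    return pd.DataFrame(recs, columns=["id", "alpha", "log_rank_sum"])
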