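"""Shock-cascade engine on the calorie trade network.

Model
-----
A single origin country loses a fraction of its domestic production
(``shock = shock_fraction * prod_origin``).  It compensates by cutting its
exports (a fraction ``alpha`` of the shock) and by raising its imports (the
remaining ``1 - alpha``), import increases being pro-rata to baseline
supplier shares.  A country holding a demand deficit

    dd_i(t) = dem_i(0) - prod_i(t) - imp_i(t) + exp_i(t)

passes it on by cutting its exports.  The cut is rationed across current
positive out-neighbors inversely to their GDP:

    F_ij = [(S - GDP_j) / S] / (k_out - 1)   if k_out >= 2, else F = 1,

with S the GDP sum over positive out-neighbors, so poorer partners absorb a
larger share.  Per-edge cuts truncate at zero weight; a truncated residue is
retried on the surviving edges in later steps.  Updates are synchronous; the
process stops once no country holds both a positive deficit and positive
export capacity.  Calories are conserved: final deficits sum to the shock.

Demand deficits are always recomputed from the current state, never
accumulated, so no numerical drift enters the dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import DAYS_PER_YEAR, TradeNetwork

DEFAULT_MAX_STEPS = 10_000
#: convergence tolerance, relative to the shock size
DEFAULT_REL_TOL = 1e-6


class CascadeWarning(UserWarning):
    """Non-fatal fallback taken during a cascade run."""


@dataclass(frozen=True)
class ShockSpec:
    """A single-origin production shock.

    shock_fraction is the fraction of the origin's production lost (the
    reference experiments use 0.30); alpha in [0, 1] is the share of the
    shock compensated through export cuts, the rest through import raises.
    """

    origin: str
    shock_fraction: float = 0.3
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.shock_fraction <= 1:
            raise ValueError("shock_fraction must be in (0, 1]")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class CascadeState:
    """Mutable cascade state at step t (weights in kcal/year)."""

    network: TradeNetwork
    t: int
    weights: np.ndarray
    production: np.ndarray
    dem0: np.ndarray
    origin_idx: int
    shock: float
    tol: float

    @property
    def dd(self) -> np.ndarray:
        """Demand deficits recomputed from the current state."""
        exp = self.weights.sum(axis=1)
        imp = self.weights.sum(axis=0)
        return self.dem0 - self.production - imp + exp

    @property
    def k_out(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)


@dataclass(frozen=True)
class CascadeResult:
    """Outcome of one cascade run."""

    origin: str
    alpha: float
    shock: float  # kcal/year
    final_dd: pd.Series  # kcal/year per country
    final_dd_percap: pd.Series  # kcal/person/day
    final_weights: np.ndarray
    steps: int
    converged: bool
    residual: float  # |sum(final_dd) - shock| / shock

    @property
    def origin_retained(self) -> float:
        """Origin's final deficit as a fraction of the shock."""
        if self.shock == 0:
            return 0.0
        return float(self.final_dd[self.origin] / self.shock)


def export_reduction_shares(
    gdp: np.ndarray, out_weights: np.ndarray
) -> np.ndarray:
    """GDP-inverse rationing shares over positive out-edges.

    Returns a vector aligned with ``out_weights`` that is zero on absent
    edges and sums to one over positive edges.  Raises if there is no
    positive out-edge (such a country is a pure absorber).
    """
    pos = out_weights > 0
    k = int(pos.sum())
    if k == 0:
        raise ValueError("country has no positive out-edges")
    F = np.zeros_like(out_weights)
    if k == 1:
        F[pos] = 1.0
        return F
    S = gdp[pos].sum()
    F[pos] = (S - gdp[pos]) / S / (k - 1)
    return F


def apply_initial_shock(
    network: TradeNetwork, spec: ShockSpec, tol: float | None = None
) -> CascadeState:
    """Apply the t=1 shock split between export cuts and import raises.

    The export-side target ``min(alpha * shock, exp_origin)`` is met by
    repeated share-rationed rounds (shares recomputed whenever an edge
    truncates to zero); the import side raises every inbound edge pro-rata to
    its baseline share.  If the origin has no baseline imports and
    ``alpha < 1``, the import portion is rerouted through the export channel
    (with a warning); whatever cannot be offloaded stays as origin deficit.
    """
    s = network.index(spec.origin)
    W = network.weights.copy()
    prod = network.production.copy()
    dem0 = prod + W.sum(axis=0) - W.sum(axis=1)

    shock = spec.shock_fraction * prod[s]
    if shock == 0:
        warnings.warn(
            f"origin {spec.origin} has zero production; zero-shock run",
            CascadeWarning,
            stacklevel=2,
        )
    if tol is None:
        tol = DEFAULT_REL_TOL * shock

    prod[s] = prod[s] - shock

    exp0_s = W[s].sum()
    imp0_s = W[:, s].sum()

    export_share = spec.alpha * shock
    import_share = (1.0 - spec.alpha) * shock
    if import_share > 0 and imp0_s == 0:
        warnings.warn(
            f"origin {spec.origin} has no baseline imports; routing the "
            "import share of the shock through export cuts",
            CascadeWarning,
            stacklevel=2,
        )
        export_share += import_share
        import_share = 0.0

    # import side: pro-rata to baseline supplier shares
    if import_share > 0:
        W[:, s] += import_share * network.weights[:, s] / imp0_s

    # export side: iterate GDP-inverse rationing until the target is met or
    # all out-edges are exhausted; each round zeroes an edge or finishes
    target = min(export_share, exp0_s)
    remaining = target
    guard = network.n + 1
    while remaining > 0 and (W[s] > 0).any() and guard > 0:
        F = export_reduction_shares(network.gdp, W[s])
        cut = np.minimum(remaining * F, W[s])
        W[s] -= cut
        W[s][W[s] < 0] = 0.0
        done = cut.sum()
        if done <= 0:
            break
        remaining -= done
        if remaining <= tol:
            remaining = max(remaining, 0.0)
            break
        guard -= 1

    return CascadeState(
        network=network,
        t=1,
        weights=W,
        production=prod,
        dem0=dem0,
        origin_idx=s,
        shock=shock,
        tol=tol,
    )


def step(state: CascadeState) -> bool:
    """One synchronous propagation step; returns whether anything changed.

    Every country holding dd > tol and positive exports cuts each of its
    positive out-edges by dd * F (truncated at zero), all using the weights
    at the start of the step.
    """
    W = state.weights
    dd = state.dd
    out_strength = W.sum(axis=1)
    active = np.where((dd > state.tol) & (out_strength > state.tol))[0]
    if active.size == 0:
        return False
    gdp = state.network.gdp
    Wa = W[active]
    pos = Wa > 0
    k = pos.sum(axis=1)
    S = pos @ gdp
    # GDP-inverse shares, rows with a single out-edge handled separately
    F = np.zeros_like(Wa)
    multi = k >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        F[multi] = (
            (S[multi, None] - gdp[None, :])
            / S[multi, None]
            / (k[multi, None] - 1.0)
        )
    F[~pos] = 0.0
    single = k == 1
    F[single] = pos[single].astype(float)
    cut = np.minimum(dd[active, None] * F, Wa)
    newW = W.copy()
    newW[active] = Wa - cut
    newW[newW < 0] = 0.0
    state.weights = newW
    state.t += 1
    return True


def run_cascade(
    network: TradeNetwork,
    spec: ShockSpec,
    tol: float | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> CascadeResult:
    """Run a full cascade to termination.

    Terminates when no country holds both a positive deficit and positive
    export capacity (up to ``tol``, default 1e-6 relative to the shock), or
    after ``max_steps`` (flagged not-converged).  Never raises on a valid
    network/spec.
    """
    state = apply_initial_shock(network, spec, tol=tol)
    converged = False
    while state.t - 1 < max_steps:
        if not step(state):
            converged = True
            break
    dd = np.maximum(state.dd, 0.0)
    shock = state.shock
    residual = abs(dd.sum() - shock) / shock if shock > 0 else 0.0
    idx = pd.Index(network.codes, name="id")
    dd_percap = dd / (network.population * DAYS_PER_YEAR)
    return CascadeResult(
        origin=spec.origin,
        alpha=spec.alpha,
        shock=shock,
        final_dd=pd.Series(dd, index=idx, name="dd"),
        final_dd_percap=pd.Series(dd_percap, index=idx, name="dd_percap"),
        final_weights=state.weights,
        steps=state.t - 1,
        converged=converged,
        residual=float(residual),
    )
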