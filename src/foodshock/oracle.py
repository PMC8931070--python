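"""Deliberately naive reference implementation of the shock cascade.

This module re-implements the cascade with plain Python dictionaries and
loops, recomputing every quantity from first principles at every step.  It
shares no code with :mod:`foodshock.cascade` and exists solely as an
independent cross-check on tiny networks; a size guard refuses anything
larger than 25 countries.
"""

from __future__ import annotations

from .cascade import DEFAULT_MAX_STEPS, DEFAULT_REL_TOL, CascadeResult, ShockSpec
from .network import DAYS_PER_YEAR, TradeNetwork

import numpy as np
import pandas as pd

_MAX_N = 25


def oracle_cascade(
    network: TradeNetwork,
    spec: ShockSpec,
    tol: float | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> CascadeResult:
    """Brute-force cascade on a small network (n <= 25)."""
    if network.n > _MAX_N:
        raise ValueError(f"oracle limited to {_MAX_N} countries, got {network.n}")

    codes = list(network.codes)
    gdp = {c: network.countries[k].gdp for k, c in enumerate(codes)}
    pop = {c: network.countries[k].population for k, c in enumerate(codes)}
    supply = {c: network.countries[k].supply for k, c in enumerate(codes)}

    # dense weight table as nested dicts
    w = {a: {b: 0.0 for b in codes} for a in codes}
    for o, d, x in network.edge_list():
        w[o][d] = x

    def exports(t):
        return {a: sum(t[a][b] for b in codes) for a in codes}

    def imports(t):
        return {a: sum(t[b][a] for b in codes) for a in codes}

    exp0 = exports(w)
    imp0 = imports(w)
    prod = {c: supply[c] + exp0[c] - imp0[c] for c in codes}
    dem0 = {c: prod[c] + imp0[c] - exp0[c] for c in codes}

    origin = spec.origin
    shock = spec.shock_fraction * prod[origin]
    if tol is None:
        tol = DEFAULT_REL_TOL * shock
    prod = dict(prod)
    prod[origin] = prod[origin] - shock

    alpha = spec.alpha
    exp_cut = alpha * shock
    imp_raise = (1.0 - alpha) * shock
    if imp_raise > 0 and imp0[origin] == 0:
        exp_cut += imp_raise
        imp_raise = 0.0

    if imp_raise > 0:
        base_in = {h: network.weights[network.index(h), network.index(origin)]
                   for h in codes}
        for h in codes:
            if base_in[h] > 0:
                w[h][origin] += imp_raise * base_in[h] / imp0[origin]

    def shares(row):
        """GDP-inverse rationing over positive entries of one weight row."""
        nbrs = [b for b in codes if row[b] > 0]
        k = len(nbrs)
        if k == 0:
            return {}
        if k == 1:
            return {nbrs[0]: 1.0}
        S = gdp_sum = 0.0
        for b in nbrs:
            gdp_sum += gdp[b]
        S = gdp_sum
        return {b: (S - gdp[b]) / S / (k - 1) for b in nbrs}

    # initial export cut, re-rationed whenever an edge empties
    remaining = min(exp_cut, exp0[origin])
    for _ in range(network.n + 1):
        if remaining <= 0:
            break
        F = shares(w[origin])
        if not F:
            break
        done = 0.0
        for b, f in F.items():
            cut = min(remaining * f, w[origin][b])
            w[origin][b] -= cut
            if w[origin][b] < 0:
                w[origin][b] = 0.0
            done += cut
        if done <= 0:
            break
        remaining -= done
        if remaining <= tol:
            break

    def deficits(t):
        e, m = exports(t), imports(t)
        return {c: dem0[c] - prod[c] - m[c] + e[c] for c in codes}

    steps = 0
    converged = False
    while steps < max_steps:
        dd = deficits(w)
        e = exports(w)
        active = [c for c in codes if dd[c] > tol and e[c] > tol]
        if not active:
            converged = True
            break
        new_w = {a: dict(w[a]) for a in codes}
        for c in active:
            F = shares(w[c])
            for b, f in F.items():
                cut = min(dd[c] * f, w[c][b])
                new_w[c][b] = w[c][b] - cut
                if new_w[c][b] < 0:
                    new_w[c][b] = 0.0
        w = new_w
        steps += 1

    dd = deficits(w)
    final = {c: max(dd[c], 0.0) for c in codes}
    total = sum(final[c] for c in codes)
    residual = abs(total - shock) / shock if shock > 0 else 0.0
    idx = pd.Index(codes, name="id")
    final_w = np.array([[w[a][b] for b in codes] for a in codes])
    return CascadeResult(
        origin=origin,
        alpha=alpha,
        shock=shock,
        final_dd=pd.Series([final[c] for c in codes], index=idx, name="dd"),
        final_dd_percap=pd.Series(
            [final[c] / (pop[c] * DAYS_PER_YEAR) for c in codes],
            index=idx,
            name="dd_percap",
        ),
        final_weights=final_w,
        steps=steps,
        converged=converged,
        residual=float(residual),
    )
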