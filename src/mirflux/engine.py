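"""Discrete-time hybrid Petri-net simulator.

Semantics per time step (synchronous update):

1. every transition's flux is evaluated on the step's starting marking —
   mass-action-like by default, ``k * prod(substrate^w) * prod(enzyme^w) /
   (1 + k_inh * sum(inhibitors))``, or an explicit per-reaction override;
2. if the joint demand on a place exceeds its marking, every flux drawing
   from that place is scaled down proportionally (order-independent
   truncation; nothing ever goes negative);
3. each input arc loses ``weight * flux`` and each output arc gains it.
   Enzyme arcs are consumed too under the default catalyst-consuming
   convention (the printed worked example has the kinase losing exactly the
   reaction flux); ``KineticConfig.consume_enzymes=False`` restores
   conventional catalysis;
4. the multi-timescale background decay fires: ordinary species lose
   ``rate * base`` every step (rate 0.09) and ligand-receptor complexes lose
   ``rate * base`` every 10th step (rate 0.2), where the decay base is the
   step's *starting* concentration for pre-existing species and the
   post-firing concentration for species created this step;
5. clamped species are reset to their clamp values.

The update is deterministic, so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import (
    ArcRole,
    DecayClass,
    KineticConfig,
    DEFAULT_CONFIG,
    ModelNetwork,
    Reaction,
    UnknownEntityError,
)

__all__ = [
    "Marking",
    "Trajectory",
    "transition_flux",
    "firing_state",
    "fire",
    "apply_decay",
    "step",
    "simulate",
    "compile_network",
]

Marking = dict  # entity id -> concentration (nM)


# ---------------------------------------------------------------------------
# scalar (reference) operations on dict markings

def transition_flux(reaction: Reaction, m: Mapping[str, float],
                    cfg: KineticConfig = DEFAULT_CONFIG) -> float:
    """Evaluate the transition speed of one reaction on a marking.

    Returns the per-reaction flux override if one is set; otherwise the
    mass-action-like default.  The flux is zero whenever any substrate or
    enzyme is absent, and never negative.
    """
    for place, _w in reaction.substrates + reaction.enzymes + reaction.inhibitors:
        if place not in m:
            raise UnknownEntityError(f"{reaction.id}: place {place!r} missing from marking")
    if reaction.flux_override is not None:
        return float(reaction.flux_override)
    flux = reaction.k
    for place, w in reaction.substrates:
        flux *= max(float(m[place]), 0.0) ** w
    for place, w in reaction.enzymes:
        flux *= max(float(m[place]), 0.0) ** w
    inh = sum(max(float(m[place]), 0.0) * w for place, w in reaction.inhibitors)
    if inh:
        flux /= 1.0 + cfg.k_inhibitory * inh
    return max(flux, 0.0)


def _consuming_arcs(reaction: Reaction, cfg: KineticConfig) -> list[tuple[str, float]]:
    arcs = list(reaction.substrates)
    if cfg.consume_enzymes:
        arcs += reaction.enzymes
    return arcs


def _reverse(reaction: Reaction) -> Reaction:
    """The backward direction of a reversible reaction (products <-> substrates)."""
    rev = Reaction(id=f"{reaction.id}__rev", rtype=reaction.rtype, k=reaction.k,
                   flux_override=reaction.flux_override)
    rev.arcs = []
    for a in reaction.arcs:
        if a.role is ArcRole.SUBSTRATE:
            rev.arcs.append(type(a)(a.place, rev.id, "output", ArcRole.PRODUCT, a.weight))
        elif a.role is ArcRole.PRODUCT:
            rev.arcs.append(type(a)(a.place, rev.id, "input", ArcRole.SUBSTRATE, a.weight))
        else:
            rev.arcs.append(type(a)(a.place, rev.id, a.direction, a.role, a.weight))
    return rev


def firing_state(reaction: Reaction, m: Mapping[str, float],
                 cfg: KineticConfig = DEFAULT_CONFIG) -> str:
    """Classify a transition as ``forward``, ``backward`` or ``inactive``.

    Forward when the forward flux is positive (a flux exceeding the supply of
    an input place is truncated, not deactivated); backward when the reaction
    is reversible, the forward direction is dead and the mirrored condition
    holds on the products.
    """
    if transition_flux(reaction, m, cfg) > 0:
        return "forward"
    if reaction.reversible and transition_flux(_reverse(reaction), m, cfg) > 0:
        return "backward"
    return "inactive"


def fire(reaction: Reaction, m: Mapping[str, float], flux: float,
         cfg: KineticConfig = DEFAULT_CONFIG) -> Marking:
    """Fire one transition: inputs lose ``w*flux``, outputs gain ``w*flux``.

    The flux is truncated so that no place goes negative.
    """
    out = dict(m)
    if flux <= 0:
        return out
    for place, w in _consuming_arcs(reaction, cfg):
        avail = float(out[place])
        if w * flux > avail:
            flux = avail / w
    for place, w in _consuming_arcs(reaction, cfg):
        out[place] = float(out[place]) - w * flux
    for place, w in reaction.products:
        out[place] = float(out.get(place, 0.0)) + w * flux
    return out


def apply_decay(m: Mapping[str, float], step_index: int,
                model: ModelNetwork,
                cfg: KineticConfig = DEFAULT_CONFIG,
                base: Optional[Mapping[str, float]] = None) -> Marking:
    """Apply the multi-timescale background decay to a marking.

    ``base`` is the marking the decay amount is computed on (the worked
    example uses the step's starting concentration for pre-existing species);
    when omitted the current marking is its own base, which yields the
    ordinary geometric decay ``m * (1 - rate)`` per due step.
    """
    if step_index < 0:
        raise ValueError("step_index must be >= 0")
    out = dict(m)
    for eid, ent in model.entities.items():
        if eid not in out:
            continue
        if ent.decay_class is DecayClass.STANDARD:
            rate, period = cfg.decay_protein_rate, cfg.decay_protein_period
        elif ent.decay_class is DecayClass.LIGAND_RECEPTOR:
            rate, period = cfg.decay_ligand_receptor_rate, cfg.decay_ligand_receptor_period
        else:
            continue
        if step_index % period != 0:
            continue
        b = float(base[eid]) if base is not None and base.get(eid, 0.0) > 0 else float(out[eid])
        out[eid] = max(float(out[eid]) - rate * b, 0.0)
    return out


def step(model: ModelNetwork, m: Mapping[str, float], step_index: int = 0,
         cfg: KineticConfig = DEFAULT_CONFIG) -> Marking:
    """Advance the marking by one synchronous time step.

    All fluxes are computed on the starting marking, jointly truncated per
    place, applied, then the decay policy runs and clamps are re-imposed.
    """
    start = {eid: float(m.get(eid, 0.0)) for eid in model.entities}
    fluxes: dict[str, float] = {}
    for rid, r in model.reactions.items():
        f = transition_flux(r, start, cfg)
        if f <= 0 and r.reversible:
            b = transition_flux(_reverse(r), start, cfg)
            if b > 0:
                fluxes[rid] = -b
                continue
        fluxes[rid] = f

    # iterative proportional rationing: whenever the joint demand on a place
    # exceeds its marking, every flux drawing from the *most* oversubscribed
    # place is scaled down first, then demands are recomputed — a reaction
    # throttled by one scarce substrate no longer claims mass on its others
    cons_of = {}
    for rid, r in model.reactions.items():
        rr = _reverse(r) if fluxes[rid] < 0 else r
        cons_of[rid] = _consuming_arcs(rr, cfg)
    scale = {rid: 1.0 for rid in model.reactions}
    for _ in range(len(model.entities)):
        demand: dict[str, float] = {}
        for rid in model.reactions:
            for place, w in cons_of[rid]:
                demand[place] = demand.get(place, 0.0) + w * abs(fluxes[rid]) * scale[rid]
        worst, worst_ratio = None, 1.0 + 1e-12
        for place, d in sorted(demand.items()):
            if place in model.clamps:  # clamped pools are held reservoirs
                continue
            avail = start[place]
            ratio = float("inf") if avail <= 0.0 and d > 0.0 else (d / avail if avail > 0 else 0.0)
            if ratio > worst_ratio:
                worst, worst_ratio = place, ratio
        if worst is None:
            break
        s = 0.0 if worst_ratio == float("inf") else start[worst] / demand[worst]
        for rid in model.reactions:
            if any(place == worst for place, _w in cons_of[rid]):
                scale[rid] *= s

    post = dict(start)
    for rid, r in model.reactions.items():
        f = fluxes[rid] * scale[rid]
        if f == 0:
            continue
        rr = _reverse(r) if f < 0 else r
        f = abs(f)
        for place, w in _consuming_arcs(rr, cfg):
            post[place] -= w * f
        for place, w in rr.products:
            post[place] += w * f
    for eid in post:
        if post[eid] < 0:  # numerical guard
            post[eid] = 0.0

    out = apply_decay(post, step_index, model, cfg, base=start)
    for eid, value in model.clamps.items():
        out[eid] = value
    return out


# ---------------------------------------------------------------------------
# compiled network + trajectories

class _Compiled:
    """Index-based view of a network for the fast simulation loop."""

    def __init__(self, model: ModelNetwork, cfg: KineticConfig) -> None:
        self.ids = list(model.entities)
        self.index = {eid: i for i, eid in enumerate(self.ids)}
        ix = self.index
        self.reactions = []
        for r in model.reactions.values():
            cons = [(ix[p], w) for p, w in _consuming_arcs(r, cfg)]
            self.reactions.append((
                [(ix[p], w) for p, w in r.substrates],
                [(ix[p], w) for p, w in r.enzymes],
                [(ix[p], w) for p, w in r.inhibitors],
                cons,
                [(ix[p], w) for p, w in r.products],
                r.k, r.flux_override,
            ))
        rates = np.zeros(len(self.ids))
        periods = np.ones(len(self.ids), dtype=int)
        for eid, ent in model.entities.items():
            if ent.decay_class is DecayClass.STANDARD:
                rates[ix[eid]] = cfg.decay_protein_rate
                periods[ix[eid]] = cfg.decay_protein_period
            elif ent.decay_class is DecayClass.LIGAND_RECEPTOR:
                rates[ix[eid]] = cfg.decay_ligand_receptor_rate
                periods[ix[eid]] = cfg.decay_ligand_receptor_period
        self.decay_rates = rates
        self.decay_periods = periods
        self.clamp_idx = np.array([ix[c] for c in model.clamps], dtype=int)
        self.clamp_val = np.array([model.clamps[c] for c in model.clamps])

    def initial(self, model: ModelNetwork,
                overrides: Optional[Mapping[str, float]] = None) -> np.ndarray:
        m = np.zeros(len(self.ids))
        for eid, v in model.initial_marking.items():
            m[self.index[eid]] = v
        if overrides:
            for eid, v in overrides.items():
                m[self.index[eid]] = v
        m[self.clamp_idx] = self.clamp_val
        return m

    def step(self, m: np.ndarray, step_index: int) -> np.ndarray:
        n_r = len(self.reactions)
        fluxes = np.empty(n_r)
        for j, (subs, enzs, inhs, _cons, _prods, k, override) in enumerate(self.reactions):
            if override is not None:
                fluxes[j] = override
                continue
            f = k
            for i, w in subs:
                mi = m[i]
                if mi <= 0.0:
                    f = 0.0
                    break
                f *= mi if w == 1.0 else mi ** w
            if f > 0.0:
                for i, w in enzs:
                    mi = m[i]
                    if mi <= 0.0:
                        f = 0.0
                        break
                    f *= mi if w == 1.0 else mi ** w
            if f > 0.0 and inhs:
                inh = sum(m[i] * w for i, w in inhs)
                f /= 1.0 + self._k_inh * inh
            fluxes[j] = f

        # iterative proportional rationing (see `step` for rationale): fix the
        # most oversubscribed place first, recompute demands, repeat
        scale = np.ones(n_r)
        for _ in range(len(m)):
            demand = np.zeros(len(m))
            for j, (_s, _e, _i, cons, _p, _k, _o) in enumerate(self.reactions):
                fj = fluxes[j] * scale[j]
                if fj > 0.0:
                    for i, w in cons:
                        demand[i] += w * fj
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(demand > 0.0,
                                 np.where(m > 0.0, demand / np.maximum(m, 1e-300),
                                          np.inf),
                                 0.0)
            ratio[self.clamp_idx] = 0.0  # clamped pools are held reservoirs
            worst = int(np.argmax(ratio))
            if ratio[worst] <= 1.0 + 1e-12:
                break
            s = 0.0 if not np.isfinite(ratio[worst]) else m[worst] / demand[worst]
            for j, (_s, _e, _i, cons, _p, _k, _o) in enumerate(self.reactions):
                if any(i == worst for i, _w in cons):
                    scale[j] *= s
        post = m.copy()
        for j, (_s, _e, _i, cons, prods, _k, _o) in enumerate(self.reactions):
            fj = fluxes[j] * scale[j]
            if fj <= 0.0:
                continue
            for i, w in cons:
                post[i] -= w * fj
            for i, w in prods:
                post[i] += w * fj
        np.maximum(post, 0.0, out=post)

        due = (step_index % self.decay_periods) == 0
        base = np.where(m > 0.0, m, post)
        post = post - np.where(due, self.decay_rates * base, 0.0)
        np.maximum(post, 0.0, out=post)
        post[self.clamp_idx] = self.clamp_val
        return post

    _k_inh = DEFAULT_CONFIG.k_inhibitory


def compile_network(model: ModelNetwork, cfg: KineticConfig = DEFAULT_CONFIG) -> _Compiled:
    c = _Compiled(model, cfg)
    c._k_inh = cfg.k_inhibitory
    return c


@dataclass
class Trajectory:
    """Recorded simulation output: markings over time plus run metadata."""

    ids: list[str]
    steps: list[int]
    markings: np.ndarray  # shape (n_recorded, n_entities)
    clamps: dict[str, float] = field(default_factory=dict)
    converged: bool = False
    n_steps_run: int = 0

    @property
    def final(self) -> Marking:
        return dict(zip(self.ids, self.markings[-1]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.markings, columns=self.ids)
        df.insert(0, "step", self.steps)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate(model: ModelNetwork, n_steps: Optional[int] = None,
             cfg: KineticConfig = DEFAULT_CONFIG, record_every: int = 1,
             initial: Optional[Mapping[str, float]] = None,
             compiled: Optional[_Compiled] = None) -> Trajectory:
    """Run the network to ``n_steps`` (default from config) and record markings.

    Default initial conditions: clamped species at their clamp values, every
    other species at the model's configured initial marking (0 unless set).
    The run stops early once the largest per-step concentration change falls
    below ``cfg.steady_tol`` (quasi-steady state).
    """
    if n_steps is None:
        n_steps = cfg.max_steps
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    net = compiled or compile_network(model, cfg)
    m = net.initial(model, initial)
    recorded = [m.copy()]
    steps = [0]
    converged = False
    # quasi-steady state is judged over one full decay-policy cycle: with a
    # slow decay arm firing every Nth step the attractor is an N-periodic
    # orbit, so per-step deltas never vanish
    period = int(np.max(net.decay_periods))
    cycle: list[np.ndarray] = [m.copy()]
    i = 0
    for i in range(n_steps):
        m_next = net.step(m, i)
        m = m_next
        if (i + 1) % record_every == 0 or i == n_steps - 1:
            recorded.append(m.copy())
            steps.append(i + 1)
        cycle.append(m.copy())
        if len(cycle) > period:
            delta = float(np.max(np.abs(m - cycle.pop(0))))
            if delta < cfg.steady_tol and (i + 1) % period == 0:
                converged = True
                if steps[-1] != i + 1:
                    recorded.append(m.copy())
                    steps.append(i + 1)
                break
    return Trajectory(ids=net.ids, steps=steps, markings=np.array(recorded),
                      clamps=dict(model.clamps), converged=converged,
                      n_steps_run=i + 1)


def steady_state(model: ModelNetwork, cfg: KineticConfig = DEFAULT_CONFIG,
                 initial: Optional[Mapping[str, float]] = None,
                 compiled: Optional[_Compiled] = None) -> Marking:
    """Convenience: final marking of a default-length simulation."""
    traj = simulate(model, cfg=cfg, record_every=10**9, initial=initial,
                    compiled=compiled)
    return traj.final
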