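"""The six sub-models of the droplet-growth dynamics.

Each function performs one synchronous pass over the world, reading the
start-of-pass state and applying all updates together.  ``run_trial`` in
:mod:`antdrip.simulate` sequences them per model variant.
"""

from __future__ import annotations

import numpy as np

from .lattice import (STABLE, UNSTABLE, UNDEFINED, Agent, DropletEvent,
                      WeightAssignment, World, compute_weights)
from .params import SimParams

# movement offsets, indexed by the sampled direction: -y, +x, -x
_MOVES = ((0, -1), (1, 0), (-1, 0))


def spawn_agents(world: World, params: SimParams, rng: np.random.Generator):
    """Inject ``phi`` new active agents at uniformly drawn entry positions."""
    n_entry = len(params.entry_positions)
    for _ in range(params.phi):
        if n_entry == 1:
            pos = params.entry_positions[0]
        else:
            pos = params.entry_positions[rng.integers(n_entry)]
        world.new_agent(*pos)


def move_down_step(world: World, params: SimParams, rng: np.random.Generator):
    """One synchronous movement step for every active agent.

    Each agent samples one direction (-y / +x / -x).  If the target site
    lies strictly below the rod row and holds no inactive agent, the agent
    settles there and becomes inactive with the initial threshold;
    otherwise it moves onto the target and stays active.  The rod row
    itself is the entry corridor: agents may walk along it but never attach
    there, so the hanging structure starts one row down.  When several
    agents would settle on the same empty site in the same step, a
    uniformly drawn winner settles and the others remain active on that
    site.
    """
    if not world.active:
        return
    rod = world.rod
    rod_y = rod[1]
    probs = (params.prob_y_minus, params.prob_x_plus, params.prob_x_minus)
    dirs = rng.choice(3, size=len(world.active), p=probs)

    occupied = world.inactive  # start-of-step occupancy (not mutated below)
    settlers: dict[tuple, list[Agent]] = {}
    for a, d in zip(world.active, dirs):
        dx, dy = _MOVES[d]
        tx, ty = a.x + dx, a.y + dy
        if ty > rod_y:          # boundary: never above the rod row
            continue
        a.x, a.y = tx, ty
        if ty < rod_y and (tx, ty) not in occupied:
            settlers.setdefault((tx, ty), []).append(a)

    for site, cands in settlers.items():
        winner = cands[0] if len(cands) == 1 else cands[rng.integers(len(cands))]
        winner.active = False
        winner.threshold = params.threshold0
        winner.weight = 0.0
        winner.moved_up = False
        world.active.remove(winner)
        world.inactive[site] = winner


def remove_unsupported(world: World) -> list[int]:
    """Remove inactive agents at the loose end of a horizontal structure.

    One synchronous pass: an inactive agent survives iff some inactive agent
    sits one row above it within one column (|dx| <= 1), or it hangs
    directly beneath the rod site (|dx| <= 1 on the row just below the rod).
    Removals are structural corrections, never droplet events.
    """
    rod_x, rod_y = world.rod
    snapshot = list(world.inactive.items())
    occupied = world.inactive
    removed = []
    for (x, y), agent in snapshot:
        if y == rod_y - 1 and abs(x - rod_x) <= 1:
            continue
        if any((x + dx, y + 1) in occupied for dx in (-1, 0, 1)):
            continue
        removed.append(agent.id)
    if removed:
        removed_set = set(removed)
        world.inactive = {s: a for s, a in world.inactive.items()
                          if a.id not in removed_set}
        world.n_removed_eq4 += len(removed)
        world.removed_log.extend((world.t, i) for i in removed)
    return removed


def _inactive_sorted(world: World) -> list[Agent]:
    # deterministic iteration order regardless of dict history
    return [world.inactive[s] for s in sorted(world.inactive)]


def warning_signal_step(world: World, rng: np.random.Generator):
    """Signalling supporters push the active agents directly below upward.

    An inactive agent signals when its weight reaches threshold - 1.  Each
    active agent sitting one site below a signalling agent climbs to one of
    the three sites diagonally/straight above, drawn uniformly among those
    occupied by an inactive agent (the rod counts as occupied); with no
    occupied candidate it stays put.  Climbers carry a ``moved_up`` flag for
    the rest of the time step.
    """
    for a in world.active:
        a.moved_up = False
    rod = world.rod
    by_site = world.active_by_site()
    occupied = world.inactive
    for k in _inactive_sorted(world):
        if k.weight < k.threshold - 1:
            continue
        below = by_site.get((k.x, k.y - 1))
        if not below:
            continue
        for a in below:
            cands = []
            for dx in (0, 1, -1):
                site = (a.x + dx, a.y + 1)
                if site in occupied or site == rod:
                    cands.append(site)
            if not cands:
                continue
            site = cands[0] if len(cands) == 1 else cands[rng.integers(len(cands))]
            a.x, a.y = site
            a.moved_up = True


def threshold_coordination_step(world: World, params: SimParams):
    """Adapt thresholds of supporters near climbing agents.

    An inactive agent with at least one ``moved_up`` active agent within
    Chebyshev distance 1 re-tunes its threshold once, using its local
    pattern estimate from the previous step: a perceived-unstable agent
    collapses its threshold to its current weight; a perceived-stable agent
    raises it by one.  The TM variant applies both rules, TM_STABLE only the
    raise, TM_UNSTABLE only the collapse; NTM never calls this pass.
    """
    variant = params.variant
    if variant == "NTM":
        return
    moved_sites = {(a.x, a.y) for a in world.active if a.moved_up}
    if not moved_sites:
        return
    for k in world.inactive.values():
        near = any((k.x + dx, k.y + dy) in moved_sites
                   for dx in (-1, 0, 1) for dy in (-1, 0, 1))
        if not near:
            continue
        if k.last_pattern == UNSTABLE and variant in ("TM", "TM_UNSTABLE"):
            k.threshold = k.weight
        elif k.last_pattern == STABLE and variant in ("TM", "TM_STABLE"):
            k.threshold = k.threshold + 1


def local_pattern_step(world: World):
    """Each inactive agent classifies its local pattern.

    Stable iff another inactive agent occupies a laterally adjacent site on
    the same row (|dx| = 1, same y); the rod is not a lateral neighbour.
    The estimate is consumed by the NEXT step's threshold coordination.
    """
    occupied = world.inactive
    for (x, y), k in world.inactive.items():
        if (x - 1, y) in occupied or (x + 1, y) in occupied:
            k.last_pattern = STABLE
        else:
            k.last_pattern = UNSTABLE


def fall_step(world: World, rng: np.random.Generator) -> list[DropletEvent]:
    """Detach the sets borne by overloaded supporters.

    Agents whose threshold is breached (threshold <= weight) are processed
    in random order.  A still-breached trigger sheds every agent (active or
    inactive) on the occupied sites of its supporting area; actives left on
    a site whose inactive occupant fell go with the droplet.  The trigger
    survives with weight reset to 0, and every surviving supporter whose
    area contained a removed agent also has its weight reset to 0 (their
    links to the fallen set break too, which can satisfy later breaches in
    the same pass).  All removals of one time step merge into a single
    droplet event.
    """
    breached = [k for k in _inactive_sorted(world) if k.threshold <= k.weight]
    if not breached:
        return []
    rng.shuffle(breached)

    removed_ids: set[int] = set()
    total_removed = 0
    trigger_id = None

    for k in breached:
        if k.id in removed_ids:
            continue
        if k.weight < k.threshold:      # satisfied by an earlier removal
            continue
        kx, ky = k.x, k.y
        area_sites = [s for s in world.inactive
                      if abs(s[0] - kx) <= 1 and s[1] < ky]
        fallen_inactive = [world.inactive[s] for s in area_sites]
        fallen_sites = set(area_sites)
        # actives inside the area, including riders on fallen supporters
        fallen_active = [a for a in world.active
                         if abs(a.x - kx) <= 1 and a.y < ky]
        n_removed = len(fallen_inactive) + len(fallen_active)
        k.weight = 0.0
        if n_removed == 0:
            continue
        for a in fallen_inactive:
            removed_ids.add(a.id)
            del world.inactive[(a.x, a.y)]
        for a in fallen_active:
            removed_ids.add(a.id)
            world.active.remove(a)
        # supporters sharing any removed agent lose their links: weight -> 0
        all_fallen = fallen_sites | {(a.x, a.y) for a in fallen_active}
        for j in world.inactive.values():
            if j.weight > 0.0 and any(
                    abs(sx - j.x) <= 1 and sy < j.y for sx, sy in all_fallen):
                j.weight = 0.0
        total_removed += n_removed
        if trigger_id is None:
            trigger_id = k.id

    if total_removed == 0:
        return []
    world.n_removed_droplet += total_removed
    event = DropletEvent(t=world.t, size=total_removed, trigger_id=trigger_id)
    world.droplet_events.append(event)
    return [event]
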