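"""Lattice world state: agents, occupancy, weight assignments, droplet events.

The world is a 2-D integer lattice hanging from a single-site rod.  Active
agents move over the structure (several may share a site); inactive agents
are embedded in it (at most one per site) and bear the weight of everything
inside their supporting area — the three-column region strictly below them.
"""

from __future__ import annotations

from dataclasses import dataclass

STABLE = "stable"
UNSTABLE = "unstable"
UNDEFINED = "undefined"


class Agent:
    """One artificial ant.

    ``weight`` and ``threshold`` are meaningful while the agent is inactive;
    ``moved_up`` is a per-step flag set by the warning-signal sub-model;
    ``last_pattern`` holds the previous step's local-pattern estimate
    (``"undefined"`` until the first estimate).
    """

    __slots__ = ("id", "x", "y", "active", "threshold", "weight",
                 "moved_up", "last_pattern")

    def __init__(self, id: int, x: int, y: int):
        self.id = id
        self.x = x
        self.y = y
        self.active = True
        self.threshold = 0.0
        self.weight = 0.0
        self.moved_up = False
        self.last_pattern = UNDEFINED

    @property
    def pos(self):
        return (self.x, self.y)

    def __repr__(self):
        state = "A" if self.active else "I"
        return f"Agent({self.id}, ({self.x},{self.y}), {state})"


@dataclass
class DropletEvent:
    """A fall event: all removals of one time step merged into one droplet."""
    t: int
    size: int
    trigger_id: int


@dataclass
class WeightAssignment:
    """Result of one weight-calculation pass.

    ``weights`` maps inactive-agent id to borne weight; ``multiplicity``
    maps each occupied site inside at least one supporting area to the
    number of supporters sharing it; ``n_supported_agents`` counts agents
    lying inside >= 1 supporting area (the conserved total:
    ``sum(weights.values()) == n_supported_agents`` exactly up to float
    rounding, because each such agent's unit mass is split among its
    supporters).
    """
    weights: dict
    multiplicity: dict
    n_supported_agents: int


class World:
    """Mutable lattice state for one trial."""

    def __init__(self, rod=(500, 500)):
        self.rod = tuple(rod)
        self.inactive: dict[tuple, Agent] = {}   # site -> agent (<=1 per site)
        self.active: list[Agent] = []
        self.t = 0
        self._next_id = 0
        # bookkeeping for conservation checks and logs
        self.n_entered = 0
        self.n_removed_droplet = 0
        self.n_removed_eq4 = 0
        self.removed_log: list[tuple] = []       # (t, agent_id) structural removals
        self.droplet_events: list[DropletEvent] = []

    # -- helpers -----------------------------------------------------------

    def new_agent(self, x: int, y: int) -> Agent:
        a = Agent(self._next_id, x, y)
        self._next_id += 1
        self.active.append(a)
        self.n_entered += 1
        return a

    def n_agents(self) -> int:
        return len(self.active) + len(self.inactive)

    def active_by_site(self) -> dict:
        by_site: dict[tuple, list[Agent]] = {}
        for a in self.active:
            by_site.setdefault((a.x, a.y), []).append(a)
        return by_site

    def extent(self):
        """(width, height) of the inactive structure.

        Width is the horizontal extent of inactive agents; height is how far
        the structure reaches below the rod row.  (0, 0) when empty.
        """
        if not self.inactive:
            return 0, 0
        xs = [x for x, _ in self.inactive]
        ys = [y for _, y in self.inactive]
        return max(xs) - min(xs) + 1, self.rod[1] - min(ys)

    def check_invariants(self):
        """Assert structural invariants; used by tests, cheap enough to call."""
        rod_y = self.rod[1]
        assert self.rod not in self.inactive, "rod site holds an inactive agent"
        for (x, y), a in self.inactive.items():
            assert (a.x, a.y) == (x, y)
            assert not a.active
            assert y <= rod_y, "inactive agent above the rod row"
            assert a.weight >= 0
        for a in self.active:
            assert a.active
            assert a.y <= rod_y, "active agent above the rod row"
            assert a.weight == 0, "active agent carries weight"
        total = self.n_agents() + self.n_removed_droplet + self.n_removed_eq4
        assert total == self.n_entered, "agent conservation violated"


def compute_weights(world: World) -> WeightAssignment:
    """Weight-sharing pass over all inactive agents.

    The supporting area of an inactive agent at (x, y) is the 3-wide column
    strictly below it: {(x', y'): |x' - x| <= 1, y' < y}.  Each agent
    (active or inactive) on an occupied site s hangs from the TOPMOST
    inactive agents whose area covers s: with a single such supporter the
    whole site mass goes to it, and when several sit on that topmost row
    they share it equally (1/m(s) each).  Supporters lower down belong to
    the hanging set itself and bear none of s's mass.  Total borne weight
    therefore equals the number of supported agents exactly.

    Also writes the per-agent weights onto the Agent records (active agents
    keep weight 0).
    """
    # occupant counts per site
    site_counts: dict[tuple, int] = {}
    for site in world.inactive:
        site_counts[site] = 1
    for a in world.active:
        site_counts[(a.x, a.y)] = site_counts.get((a.x, a.y), 0) + 1

    # per-column topmost inactive y, for supporter queries
    col_top: dict[int, int] = {}
    for (x, y) in world.inactive:
        if y > col_top.get(x, -10**9):
            col_top[x] = y

    inactive = world.inactive
    weights: dict[int, float] = {a.id: 0.0 for a in inactive.values()}
    mult: dict[tuple, int] = {}
    n_supported = 0
    for (x, y), n in site_counts.items():
        # topmost row holding a covering supporter (strictly above s)
        top = None
        for cx in (x - 1, x, x + 1):
            cy = col_top.get(cx)
            if cy is not None and cy > y and (top is None or cy > top):
                top = cy
        if top is None:
            continue
        supporters = [inactive[(cx, top)] for cx in (x - 1, x, x + 1)
                      if (cx, top) in inactive]
        mult[(x, y)] = len(supporters)
        n_supported += n
        share = n / len(supporters)
        for a in supporters:
            weights[a.id] += share

    for agent in inactive.values():
        agent.weight = weights[agent.id]
    return WeightAssignment(weights=weights, multiplicity=mult,
                            n_supported_agents=n_supported)


def compute_weights_bruteforce(world: World) -> dict:
    """Independent O(sites x agents) reference for the weight-sharing rule.

    Enumerates, for every occupied site, all inactive agents whose area
    covers it, keeps the topmost row of them, and splits the site's mass
    equally among those; used as a cross-check oracle in tests, never in
    the simulation loop.
    """
    sites: dict[tuple, int] = {}
    for site in world.inactive:
        sites[site] = sites.get(site, 0) + 1
    for a in world.active:
        sites[(a.x, a.y)] = sites.get((a.x, a.y), 0) + 1
    weights = {a.id: 0.0 for a in world.inactive.values()}
    for (sx, sy), n in sites.items():
        covering = [a for a in world.inactive.values()
                    if abs(a.x - sx) <= 1 and sy < a.y]
        if not covering:
            continue
        top = max(a.y for a in covering)
        supporters = [a for a in covering if a.y == top]
        for a in supporters:
            weights[a.id] += n / len(supporters)
    return weights
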