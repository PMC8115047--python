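"""Event-based multi-deme demographic scenarios.

A :class:`DemographicScenario` describes, backward in time, a set of demes
with diploid effective sizes, an optional lineage migration matrix, and an
ordered list of merge events.  At a merge the source deme's lineages move into
the destination deme, the source closes, and the destination is resized by a
multiplicative factor (its size backward of the event becomes
``resize * size``).  After the final event exactly one ancestral deme remains.

The catalogue holds the six postglacial-recolonisation templates for a
four-region latitudinal transect (south to north: Skane, Uppland,
Vasterbotten, Norrbotten):

* **M1** — single colonisation route entering from the north
  (forward: Norrbotten -> Vasterbotten -> Uppland -> Skane);
* **M2** — single route entering from the south (the mirror of M1);
* **M3** — dual routes from a common ancestral population, with Uppland
  attached to the southern route;
* **M4** — M3 plus secondary-contact migration between the two central
  regions (Uppland and Vasterbotten);
* **M5** — dual routes with Uppland attached to the northern route;
* **M6** — M5 plus central-contact migration.

Free parameters per template: four contemporary diploid sizes (uniform
priors), three resize factors (log-uniform) and three divergence times
(T1 plus positive increments, so T1 <= T2 <= T3); M4/M6 add two directed
contact-zone migration rates (log-uniform), giving k = 10 or k = 12 free
parameters.  Migration/time parameters that are functions of others (complex
parameters) are counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default region labels, ordered south to north.
REGIONS = ["Skane", "Uppland", "Vasterbotten", "Norrbotten"]

#: Generation time in years.
GENERATION_TIME = 3.0

#: Per-site per-generation mutation rate (anuran estimate).
MUTATION_RATE = 7.7e-10


@dataclass(frozen=True)
class MergeEvent:
    """Backward-time merge: at ``time`` (generations) all lineages of
    ``source`` move to ``dest``; ``dest``'s size is multiplied by ``resize``."""

    time: float
    source: str
    dest: str
    resize: float = 1.0


@dataclass
class DemographicScenario:
    """A validated multi-deme coalescent model.

    Parameters
    ----------
    demes : list of str
        Deme labels.
    ne : dict
        Contemporary diploid effective size per deme; all positive.
    events : list of MergeEvent
        Ordered backward in time, times positive and non-decreasing.
    migration : dict, optional
        ``(from_deme, to_deme) -> per-generation lineage migration
        probability`` (backward in time); migration involving a deme stops
        when that deme closes.
    n_free_params : int, optional
        Number of free parameters k of the template this scenario was built
        from (complex parameters counted once); used for AIC.
    """

    demes: list[str]
    ne: dict[str, float]
    events: list[MergeEvent] = field(default_factory=list)
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    generation_time: float = GENERATION_TIME
    mutation_rate: float = MUTATION_RATE
    n_free_params: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(set(self.demes)) != len(self.demes):
            raise ValueError("duplicate deme labels")
        for d in self.demes:
            if self.ne.get(d, 0) <= 0:
                raise ValueError(f"deme {d!r} needs a positive diploid size")
        last_t = 0.0
        open_demes = set(self.demes)
        for ev in self.events:
            if ev.time <= 0:
                raise ValueError(f"event time {ev.time} must be positive")
            if ev.time < last_t:
                raise ValueError("event times must be non-decreasing")
            last_t = ev.time
            if ev.resize <= 0:
                raise ValueError("resize factor must be positive")
            if ev.source not in open_demes:
                raise ValueError(f"merge source {ev.source!r} not open at t={ev.time}")
            if ev.dest not in open_demes or ev.dest == ev.source:
                raise ValueError(f"invalid merge destination {ev.dest!r}")
            open_demes.discard(ev.source)
        if len(open_demes) != 1:
            raise ValueError(
                f"{len(open_demes)} demes remain after the final event; "
                "exactly one ancestral deme must remain"
            )
        for (a, b), m in self.migration.items():
            if a not in self.demes or b not in self.demes or a == b:
                raise ValueError(f"invalid migration pair ({a}, {b})")
            if m < 0:
                raise ValueError("negative migration rate")

    # --- array form consumed by the coalescent engine -------------------
    def arrays(self):
        """(sizes, migration matrix, event arrays) in deme-index space."""
        idx = {d: i for i, d in enumerate(self.demes)}
        sizes = np.array([float(self.ne[d]) for d in self.demes])
        mig = np.zeros((len(self.demes), len(self.demes)))
        for (a, b), m in self.migration.items():
            mig[idx[a], idx[b]] = m
        ev_time = np.array([ev.time for ev in self.events], dtype=float)
        ev_src = np.array([idx[ev.source] for ev in self.events], dtype=np.int64)
        ev_dst = np.array([idx[ev.dest] for ev in self.events], dtype=np.int64)
        ev_resize = np.array([ev.resize for ev in self.events], dtype=float)
        return sizes, mig, ev_time, ev_src, ev_dst, ev_resize


@dataclass(frozen=True)
class Prior:
    """Marginal prior for one free parameter: 'uniform' or 'loguniform'."""

    kind: str
    low: float
    high: float

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "uniform":
            return float(rng.uniform(self.low, self.high))
        if self.kind == "loguniform":
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        raise ValueError(f"unknown prior kind {self.kind!r}")

    def from_unit(self, u: float) -> float:
        u = min(max(u, 0.0), 1.0)
        if self.kind == "uniform":
            return self.low + u * (self.high - self.low)
        return float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))

    def to_unit(self, x: float) -> float:
        if self.kind == "uniform":
            return (x - self.low) / (self.high - self.low)
        return (np.log(x) - np.log(self.low)) / (np.log(self.high) - np.log(self.low))


@dataclass
class ScenarioTemplate:
    """A named, parameterised scenario family (one of M1..M6)."""

    name: str
    param_names: list[str]
    priors: dict[str, Prior]
    builder: "callable"
    description: str = ""

    @property
    def k(self) -> int:
        return len(self.param_names)

    def build(self, params: dict[str, float]) -> DemographicScenario:
        missing = [p for p in self.param_names if p not in params]
        if missing:
            raise ValueError(f"{self.name}: missing parameters {missing}")
        sc = self.builder(params)
        sc.n_free_params = self.k
        sc.name = self.name
        return sc

    def draw_params(self, rng: np.random.Generator) -> dict[str, float]:
        return {p: self.priors[p].draw(rng) for p in self.param_names}


def _base_priors(ne_low=500.0, ne_high=50_000.0, t_low=50.0, t_high=5_000.0) -> dict[str, Prior]:
    pri = {f"ne_{d.lower()}": Prior("uniform", ne_low, ne_high) for d in REGIONS}
    pri.update(
        t1=Prior("uniform", t_low, t_high),
        dt2=Prior("uniform", t_low, t_high),
        dt3=Prior("uniform", t_low, t_high),
        r1=Prior("loguniform", 0.01, 100.0),
        r2=Prior("loguniform", 0.01, 100.0),
        r3=Prior("loguniform", 0.01, 100.0),
    )
    return pri


_MIG_PRIOR = Prior("loguniform", 1e-5, 1e-2)

_BASE_PARAMS = [f"ne_{d.lower()}" for d in REGIONS] + ["t1", "dt2", "dt3", "r1", "r2", "r3"]


def _ne(params):
    return {d: params[f"ne_{d.lower()}"] for d in REGIONS}


def _times(params):
    t1 = params["t1"]
    return t1, t1 + params["dt2"], t1 + params["dt2"] + params["dt3"]


def _serial(params, order):
    """Serial colonisation: backward, order[0] merges into order[1] at T1,
    order[1] into order[2] at T2, order[2] into order[3] at T3."""
    t1, t2, t3 = _times(params)
    ev = [
        MergeEvent(t1, order[0], order[1], params["r1"]),
        MergeEvent(t2, order[1], order[2], params["r2"]),
        MergeEvent(t3, order[2], order[3], params["r3"]),
    ]
    return DemographicScenario(demes=list(REGIONS), ne=_ne(params), events=ev)


def _build_m1(params):
    # forward colonisation north -> south; backward the southmost merges first
    return _serial(params, ["Skane", "Uppland", "Vasterbotten", "Norrbotten"])


def _build_m2(params):
    # forward colonisation south -> north
    return _serial(params, ["Norrbotten", "Vasterbotten", "Uppland", "Skane"])


def _dual(params, southern_has_uppland: bool, migration: dict | None = None):
    """Dual routes from one ancestral population (rooted in the south deme).

    Southern route: Skane (+ Uppland if ``southern_has_uppland``); northern
    route enters from the north: Norrbotten first, then Vasterbotten
    (+ Uppland otherwise).  Backward: the route-internal merges happen at
    T1/T2 and the two routes join at T3.
    """
    t1, t2, t3 = _times(params)
    if southern_has_uppland:
        ev = [
            MergeEvent(t1, "Uppland", "Skane", params["r1"]),
            MergeEvent(t2, "Vasterbotten", "Norrbotten", params["r2"]),
            MergeEvent(t3, "Norrbotten", "Skane", params["r3"]),
        ]
    else:
        ev = [
            MergeEvent(t1, "Uppland", "Vasterbotten", params["r1"]),
            MergeEvent(t2, "Vasterbotten", "Norrbotten", params["r2"]),
            MergeEvent(t3, "Norrbotten", "Skane", params["r3"]),
        ]
    return DemographicScenario(
        demes=list(REGIONS), ne=_ne(params), events=ev, migration=migration or {}
    )


def _build_m3(params):
    return _dual(params, southern_has_uppland=True)


def _build_m4(params):
    mig = {
        ("Uppland", "Vasterbotten"): params["m_uv"],
        ("Vasterbotten", "Uppland"): params["m_vu"],
    }
    return _dual(params, southern_has_uppland=True, migration=mig)


def _build_m5(params):
    return _dual(params, southern_has_uppland=False)


def _build_m6(params):
    mig = {
        ("Uppland", "Vasterbotten"): params["m_uv"],
        ("Vasterbotten", "Uppland"): params["m_vu"],
    }
    return _dual(params, southern_has_uppland=False, migration=mig)


def scenario_catalogue(**prior_overrides) -> dict[str, ScenarioTemplate]:
    """The six named colonisation templates M1..M6.

    ``prior_overrides`` may replace individual priors by name (e.g.
    ``t1=Prior('uniform', 100, 1000)``); prior bounds are a required part of
    the configuration with the documented defaults used otherwise.
    """

    def make(name, builder, with_migration, description):
        priors = _base_priors()
        names = list(_BASE_PARAMS)
        if with_migration:
            priors["m_uv"] = _MIG_PRIOR
            priors["m_vu"] = _MIG_PRIOR
            names += ["m_uv", "m_vu"]
        for key, p in prior_overrides.items():
            if key in priors:
                priors[key] = p
        return ScenarioTemplate(name, names, priors, builder, description)

    return {
        "M1": make("M1", _build_m1, False, "single route entering from the north"),
        "M2": make("M2", _build_m2, False, "single route entering from the south"),
        "M3": make("M3", _build_m3, False, "dual routes, Uppland on the southern route"),
        "M4": make("M4", _build_m4, True, "dual routes + central contact migration"),
        "M5": make("M5", _build_m5, False, "dual routes, Uppland on the northern route"),
        "M6": make("M6", _build_m6, True, "dual routes (Uppland north) + contact migration"),
    }
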