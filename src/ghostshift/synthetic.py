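"""Synthetic dated trees, hand-specified donor spaces, and the brute-force oracle.

Everything the test suite needs runs from here with no downloads: a
crown-start birth–death sampler emitting dated ultrametric trees of extant
tips, fixture donor spaces declared directly as (birth, death, label)
intervals, and an independent Monte Carlo estimator of the shift
probability for a two-branch configuration. The oracle deliberately shares
no code with the main simulator — it re-derives the sampling intervals from
their definitions with Python's stdlib RNG — so agreement between the two
is a meaningful correctness check, not a tautology.

The canonical *symmetric fixture* is a single donor branch born exactly at
the window's older bound and surviving to the present. Both ghost births
are then iid uniform over the window, each transfer is uniform between the
window's younger bound and its ghost's birth, and the shift probability has
the closed form

    P(shift) = E[min(g1, g2) / (2 * max(g1, g2))] = 1/4

(for g scaled to U(0,1]: conditional on g1 > g2, a reversal needs
tau1 < tau2, with probability g2/(2*g1); the expectation of min/max for two
iid uniforms is 1/2). The constant 1/4 used in tests was re-derived with
:func:`shift_probability_oracle` before being frozen.
"""

from __future__ import annotations

import json
import random as _pyrandom
from dataclasses import dataclass, field

import numpy as np
import yaml

from .branch_space import AcceptorWindow, BranchSpace, build_branch_space
from .errors import GhostShiftError, InputError
from .tree import BranchRecord, DatedTree, read_dated_tree

__all__ = [
    "BirthDeathSpec",
    "FixtureSpec",
    "FullExtinctionError",
    "simulate_bd_tree",
    "make_fixture_space",
    "load_fixture",
    "symmetric_fixture",
    "shift_probability_oracle",
]


class FullExtinctionError(GhostShiftError):
    """The birth–death process died out before reaching its stop condition."""


@dataclass(frozen=True)
class BirthDeathSpec:
    """Crown-start birth–death simulation settings.

    Exactly one stop condition applies: ``n_tips`` (stop when that many
    lineages are extant, then extend tip edges by one exponential waiting
    time so no edge has zero length) or ``max_time`` (sample the extant tree
    at that absolute time). Rates are events per lineage per time unit.
    """

    birth_rate: float
    death_rate: float = 0.0
    n_tips: int | None = None
    max_time: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth_rate <= 0:
            raise InputError("birth_rate must be > 0")
        if self.death_rate < 0:
            raise InputError("death_rate must be >= 0")
        if (self.n_tips is None) == (self.max_time is None):
            raise InputError("specify exactly one of n_tips / max_time")
        if self.n_tips is not None and self.n_tips < 2:
            raise InputError("n_tips must be >= 2")
        if self.max_time is not None and self.max_time <= 0:
            raise InputError("max_time must be > 0")


class _Lineage:
    __slots__ = ("t_birth", "children", "extinct")

    def __init__(self, t_birth: float):
        self.t_birth = t_birth
        self.children: list[_Lineage] = []
        self.extinct = False


def _simulate_once(spec: BirthDeathSpec, rng: np.random.Generator) -> str:
    lam, mu = spec.birth_rate, spec.death_rate
    root = _Lineage(0.0)
    root.children = [_Lineage(0.0), _Lineage(0.0)]  # crown start
    active = list(root.children)
    t = 0.0
    while True:
        n = len(active)
        if n == 0:
            raise FullExtinctionError("all lineages went extinct")
        if spec.n_tips is not None and n >= spec.n_tips:
            # extend past the stopping event by one waiting time so tip
            # edges are strictly positive
            t += rng.exponential(1.0 / (n * (lam + mu))) if (lam + mu) > 0 else 1.0
            break
        dt = rng.exponential(1.0 / (n * (lam + mu)))
        if spec.max_time is not None and t + dt > spec.max_time:
            t = spec.max_time
            break
        t += dt
        k = int(rng.integers(n))
        lin = active[k]
        if rng.uniform() < lam / (lam + mu):
            lin.children = [_Lineage(t), _Lineage(t)]
            active[k] = lin.children[0]
            active.append(lin.children[1])
        else:
            lin.extinct = True
            active[k] = active[-1]
            active.pop()
    if len(active) < 2:
        raise FullExtinctionError("fewer than 2 extant lineages at stop time")

    t_final = t
    counter = [0]

    def render(lin: _Lineage, t_parent: float) -> str | None:
        """Newick for the extant part below *lin*; suppresses unary nodes."""
        if lin.extinct:
            return None
        if not lin.children:
            counter[0] += 1
            return f"T{counter[0]}:{t_final - t_parent:.12g}"
        parts = [render(c, lin.children[0].t_birth) for c in lin.children]
        parts = [p for p in parts if p is not None]
        if not parts:
            return None
        if len(parts) == 1:  # extinct sibling: splice through
            name, _, length = parts[0].rpartition(":")
            spliced = float(length) + (lin.children[0].t_birth - t_parent)
            return f"{name}:{spliced:.12g}"
        return f"({','.join(parts)}):{lin.children[0].t_birth - t_parent:.12g}"

    parts = [render(c, 0.0) for c in root.children]
    parts = [p for p in parts if p is not None]
    if len(parts) < 2:
        raise FullExtinctionError("one crown lineage left no extant descendants")
    return f"({','.join(parts)});"


def simulate_bd_tree(spec: BirthDeathSpec, max_retries: int = 100) -> DatedTree:
    """Simulate a dated ultrametric tree of extant tips under birth–death.

    Extinct lineages are pruned (ghosts are modeled analytically downstream,
    not as tree tips). Full extinction triggers a retry on a fresh RNG
    substream, up to ``max_retries``; output is reproducible from
    ``spec.seed``. Tips are named T1, T2, … in tree traversal order.
    """
    last: FullExtinctionError | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(attempt,))
        )
        try:
            return read_dated_tree(_simulate_once(spec, rng))
        except FullExtinctionError as exc:
            last = exc
    raise FullExtinctionError(
        f"process went extinct in all {max_retries} attempts "
        f"(birth {spec.birth_rate}, death {spec.death_rate}): {last}"
    )


@dataclass(frozen=True)
class FixtureSpec:
    """A donor space declared directly, bypassing tree construction.

    ``branches`` is a list of (birth_age, death_age, clade_label) tuples;
    every branch must pass the standard eligibility filters against the
    window.
    """

    feca_age: float
    leca_age: float
    branches: tuple[tuple[float, float, str], ...] = field(default_factory=tuple)

    @property
    def window(self) -> AcceptorWindow:
        return AcceptorWindow(self.feca_age, self.leca_age)


def random_two_branch_fixture(
    rng: np.random.Generator, feca_age: float = 2.42, leca_age: float = 1.89
) -> FixtureSpec:
    """A random valid two-donor-branch configuration for a given window.

    Births are uniform between just above the window's younger bound and
    roughly twice the window's older age; deaths uniform below both the
    branch birth and the older bound, so every draw passes the eligibility
    filters. Used for randomized simulator-vs-oracle comparisons.
    """
    branches = []
    for _ in range(2):
        birth = rng.uniform(leca_age + 0.05, 2 * feca_age - 0.8)
        death = rng.uniform(0.0, min(birth - 0.02, feca_age - 0.02))
        branches.append((float(birth), float(death), "S"))
    return FixtureSpec(feca_age=feca_age, leca_age=leca_age, branches=tuple(branches))


def symmetric_fixture() -> FixtureSpec:
    """Single donor branch born at the window's older bound, alive today.

    With the eukaryogenesis window (2.42–1.89 Ga) this is the configuration
    whose shift probability is exactly 1/4.
    """
    return FixtureSpec(feca_age=2.42, leca_age=1.89, branches=((2.42, 0.0, "S"),))


def make_fixture_space(spec: FixtureSpec) -> tuple[BranchSpace, AcceptorWindow]:
    """Materialize a fixture as a validated :class:`BranchSpace`.

    Every declared branch must individually satisfy the eligibility filters
    (strict overlap with the open window); a failing branch is an error, not
    a silent drop.
    """
    window = spec.window
    records = []
    for i, (birth, death, label) in enumerate(spec.branches):
        rec = BranchRecord(
            branch_id=f"fx{i:03d}",
            birth_age=float(birth),
            death_age=float(death),
            clade_label=str(label),
            in_domain=True,
        )
        if not (rec.birth_age > window.leca_age and rec.death_age < window.feca_age):
            raise InputError(
                f"fixture branch {i} ({birth}, {death}) fails the overlap filter "
                f"against window ({window.feca_age}, {window.leca_age})"
            )
        records.append(rec)
    return build_branch_space(records, window), window


def load_fixture(path: str) -> FixtureSpec:
    """Read a fixture spec from YAML or JSON.

    Schema: ``{window: {feca: float, leca: float},
    branches: [{birth: float, death: float, label: str}, ...]}``.
    """
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise InputError(f"cannot read fixture {path!r}: {exc}") from exc
    try:
        data = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
    except Exception as exc:
        raise InputError(f"cannot parse fixture {path!r}: {exc}") from exc
    try:
        return FixtureSpec(
            feca_age=float(data["window"]["feca"]),
            leca_age=float(data["window"]["leca"]),
            branches=tuple(
                (float(b["birth"]), float(b["death"]), str(b.get("label", "S")))
                for b in data["branches"]
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise InputError(f"malformed fixture {path!r}: {exc}") from exc


def shift_probability_oracle(
    fixture: FixtureSpec,
    branch_pair: tuple[int, int],
    p_ghost: float,
    n_draws: int,
    seed: int,
) -> tuple[float, float]:
    """Brute-force shift probability for one donor branch pair, with its SE.

    Straight-line re-implementation from the definitions, using the stdlib
    RNG and no simulator code: for each member, draw the ghost birth
    uniformly between max(branch death, window younger bound) and the
    branch birth; draw the transfer uniformly between the younger bound and
    min(ghost birth, older bound); let the observed age be the ghost birth
    with probability ``p_ghost``, else the transfer age; count strict order
    reversals. The branch pair is put in a canonical order before sampling,
    so the estimate is symmetric in its arguments under the same seed.

    Returns ``(p_hat, se)`` with the binomial standard error.
    """
    if n_draws < 1_000:
        raise InputError(f"n_draws={n_draws} too small for a meaningful oracle")
    if not 0.0 <= p_ghost <= 1.0:
        raise InputError(f"p_ghost must be in [0, 1], got {p_ghost}")
    feca, leca = fixture.feca_age, fixture.leca_age
    pair = sorted(fixture.branches[i][:2] for i in branch_pair)
    rng = _pyrandom.Random(seed)
    n_shift = 0
    for _ in range(n_draws):
        obs = [0.0, 0.0]
        tau = [0.0, 0.0]
        for m, (birth, death) in enumerate(pair):
            g = rng.uniform(max(death, leca), birth)
            tau[m] = rng.uniform(leca, min(g, feca))
            obs[m] = g if rng.random() < p_ghost else tau[m]
        if (tau[0] - tau[1]) * (obs[0] - obs[1]) < 0.0:
            n_shift += 1
    p_hat = n_shift / n_draws
    se = (p_hat * (1.0 - p_hat) / n_draws) ** 0.5
    return p_hat, se
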