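"""Ghost-lineage and transfer sampling.

Each simulated donor is a ghost lineage branching off a sister branch drawn
from the donor branch space. With ages in time before present, window
``(feca, leca)`` and a sister branch living over ``[death, birth]``:

* ghost birth   ``g ~ U( max(death, leca), birth ]``
* transfer age  ``t ~ U( leca, min(g, feca) ]``

This single rule reproduces all the enumerated sampling cases — a branch
spanning the whole window, a branch born before the window's older bound and
dying inside it (with the sub-case of a ghost born before that bound), and a
branch born inside the window — and extends consistently to a branch both
born and dying inside the window. The ghost's death time is a formalism
(any time after the transfer) and never enters the shift assessment, so it
is not sampled.

The *observed* age of a transfer is the age that would be inferred without
the donor lineage in the tree: the ghost's birth ``g`` (its divergence from
the sampled sister) when the donor is a ghost, or the true transfer age
``t`` when the donor is treated as sampled. ``g`` may exceed the window's
older bound — that is the mechanism behind observed transfer ages older
than FECA.

Uniform draws use the half-open convention ``(low, high]``, implemented as
``high - U[0, high-low)``; the endpoint choice is measure-zero but fixed for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .branch_space import AcceptorWindow, BranchSpace
from .errors import GhostShiftError
from .tree import BranchRecord

__all__ = ["GhostTransfer", "sample_ghost", "sample_pair", "sample_rounds", "round_rng"]


@dataclass(frozen=True)
class GhostTransfer:
    """One simulated ghost donor and its transfer to the acceptor."""

    branch_id: str
    clade_label: str
    ghost_birth_age: float
    transfer_age: float
    observed_age: float

    def as_sampled(self) -> "GhostTransfer":
        """The same transfer with the donor treated as sampled (not a ghost)."""
        return replace(self, observed_age=self.transfer_age)


def round_rng(master_seed: int, round_index: int) -> np.random.Generator:
    """Independent RNG substream for one simulation round.

    Derived from ``(master_seed, round_index)`` via numpy's SeedSequence
    spawn-key mechanism, so per-round results are order-independent and
    identical seeds give bit-identical simulations.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(round_index,))
    )


def _uniform_open_low(rng: np.random.Generator, low, high):
    """Draw from (low, high]; low/high may be arrays."""
    return high - rng.uniform(0.0, 1.0, size=np.shape(high)) * (high - low)


def sample_ghost(
    branch: BranchRecord, window: AcceptorWindow, rng: np.random.Generator
) -> GhostTransfer:
    """Sample one ghost lineage on *branch* and its transfer into *window*."""
    g_low = max(branch.death_age, window.leca_age)
    g_high = branch.birth_age
    if not g_high > g_low:
        raise GhostShiftError(
            f"branch {branch.branch_id} has an empty ghost-birth interval "
            f"({g_low:g}, {g_high:g}]; it does not belong to a valid branch space"
        )
    g = float(g_high - rng.uniform() * (g_high - g_low))
    t_high = min(g, window.feca_age)
    t = float(t_high - rng.uniform() * (t_high - window.leca_age))
    return GhostTransfer(
        branch_id=branch.branch_id,
        clade_label=branch.clade_label,
        ghost_birth_age=g,
        transfer_age=t,
        observed_age=g,
    )


def sample_pair(
    space: BranchSpace, window: AcceptorWindow, rng: np.random.Generator
) -> tuple[GhostTransfer, GhostTransfer]:
    """Sample a pair of ghost transfers with independent sister-branch choice.

    Branches are drawn uniformly over the space *with replacement*: the same
    branch may host both ghosts (same-clade donor pairs are meaningful and
    appear on the diagonal of the clade-pair matrix).
    """
    if len(space) == 0:
        raise GhostShiftError("cannot sample from an empty branch space")
    i, j = rng.integers(0, len(space), size=2)
    return (
        sample_ghost(space[int(i)], window, rng),
        sample_ghost(space[int(j)], window, rng),
    )


def sample_rounds(
    space: BranchSpace,
    window: AcceptorWindow,
    n_pairs: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorized draw of ``n_pairs`` ghost-transfer pairs.

    Returns arrays of shape ``(n_pairs, 2)``: ``branch_idx`` (indices into
    the space), ``g`` (ghost births), ``tau`` (transfer ages) and ``u``
    (iid U[0,1) auxiliaries used as common random numbers for Bernoulli
    ghost/sampled assignment at any ghost proportion). Draw order is fixed:
    indices, then ghost births, then transfer ages, then auxiliaries.
    """
    if len(space) == 0:
        raise GhostShiftError("cannot sample from an empty branch space")
    if n_pairs < 1:
        raise GhostShiftError(f"n_pairs must be >= 1, got {n_pairs}")
    idx = rng.integers(0, len(space), size=(n_pairs, 2))
    g_low = np.maximum(space.death_ages[idx], window.leca_age)
    g_high = space.birth_ages[idx]
    g = _uniform_open_low(rng, g_low, g_high)
    t_high = np.minimum(g, window.feca_age)
    tau = _uniform_open_low(rng, window.leca_age, t_high)
    u = rng.uniform(0.0, 1.0, size=(n_pairs, 2))
    return {"branch_idx": idx, "g": g, "tau": tau, "u": u}
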