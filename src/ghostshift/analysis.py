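"""Shift classification and Monte Carlo aggregation.

A *shift* is a pair of transfers whose early/late ordering by observed age
(what would be inferred from the sampled sisters) is strictly reversed
relative to their ordering by true transfer age. Among shifted pairs we also
flag those with an observed age older than the window's upper bound
("older than FECA"): such inferences are evidently artifactual for the
eukaryogenesis question and would be discarded, so the *confounding*
fraction — shifted pairs that would survive that filter — is

    confounding = shift_proportion * (1 - outside_given_shift).

Simulation rounds of ``n_pairs`` pairs are repeated ``n_rounds`` times with
independent RNG substreams, giving a distribution of per-round proportions;
pooled statistics are unweighted means across rounds (identical to pooling
pairs when every round has equal n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .branch_space import AcceptorWindow, BranchSpace
from .errors import GhostShiftError
from .simulate import GhostTransfer, round_rng, sample_rounds

__all__ = [
    "PairClassification",
    "RoundSummary",
    "ExperimentSummary",
    "CladePairMatrix",
    "classify_pair",
    "run_round",
    "run_experiment",
    "pair_matrix",
    "ghost_fraction_sweep",
]

QUANTILES = (0.025, 0.25, 0.50, 0.75, 0.975)


@dataclass(frozen=True)
class PairClassification:
    """Ordering comparison for one pair of transfers.

    ``true_early`` / ``observed_early`` are 1-based member indices of the
    older (earlier) event under each dating; ties resolve to member 1 and
    never count as a shift (strict reversal required).
    """

    true_early: int
    observed_early: int
    is_shift: bool
    outside_window: bool


def classify_pair(
    pair: tuple[GhostTransfer, GhostTransfer], window: AcceptorWindow
) -> PairClassification:
    """Classify one transfer pair as shifted or consistently ordered."""
    a, b = pair
    true_early = 1 if a.transfer_age >= b.transfer_age else 2
    observed_early = 1 if a.observed_age >= b.observed_age else 2
    is_shift = (
        (a.transfer_age - b.transfer_age) * (a.observed_age - b.observed_age) < 0.0
    )
    outside = is_shift and (
        a.observed_age > window.feca_age or b.observed_age > window.feca_age
    )
    return PairClassification(true_early, observed_early, is_shift, outside)


@dataclass(frozen=True)
class RoundSummary:
    """Proportions from one simulation round.

    ``outside_given_shift`` is the fraction of shifted pairs with an
    observed age beyond the window's older bound; it is ``None`` when the
    round produced no shifts (undefined, excluded from pooling rather than
    counted as zero).
    """

    n_pairs: int
    shift_proportion: float
    outside_given_shift: float | None
    confounding_proportion: float


def _classify_arrays(
    tau: np.ndarray, obs: np.ndarray, feca: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pair classification; returns (is_shift, outside_window)."""
    reversal = (tau[:, 0] - tau[:, 1]) * (obs[:, 0] - obs[:, 1])
    is_shift = reversal < 0.0
    outside = is_shift & (obs > feca).any(axis=1)
    return is_shift, outside


def _summarize(is_shift: np.ndarray, outside: np.ndarray) -> RoundSummary:
    n = is_shift.size
    n_shift = int(is_shift.sum())
    shift_p = n_shift / n
    if n_shift == 0:
        return RoundSummary(n, 0.0, None, 0.0)
    out_p = float(outside.sum()) / n_shift
    return RoundSummary(n, shift_p, out_p, shift_p * (1.0 - out_p))


def run_round(
    space: BranchSpace,
    window: AcceptorWindow,
    n_pairs: int,
    rng: np.random.Generator,
    p_ghost: float = 1.0,
) -> RoundSummary:
    """Simulate and classify ``n_pairs`` transfer pairs in one round.

    ``p_ghost`` is the probability that each pair member's donor is a ghost
    (Bernoulli, independent per member); a sampled donor's observed age is
    its true transfer age. The default 1.0 is the worst case where every
    donor is a ghost.
    """
    if not 0.0 <= p_ghost <= 1.0:
        raise GhostShiftError(f"p_ghost must be in [0, 1], got {p_ghost}")
    draws = sample_rounds(space, window, n_pairs, rng)
    obs = np.where(draws["u"] < p_ghost, draws["g"], draws["tau"])
    is_shift, outside = _classify_arrays(draws["tau"], obs, window.feca_age)
    return _summarize(is_shift, outside)


@dataclass
class ExperimentSummary:
    """Per-round summaries plus pooled statistics for a full experiment.

    ``rounds`` has one row per round (round, n_pairs, shift_prop,
    outside_prop, confounding_prop; outside_prop is NaN for shift-free
    rounds). ``pairs`` is the pair-level table used for clade stratification
    (round, label_1, label_2 with the unordered pair sorted, is_shift,
    outside). ``audit`` is the optional per-ghost log.
    """

    window: AcceptorWindow
    seed: int
    p_ghost: float
    rounds: pd.DataFrame
    pairs: pd.DataFrame
    audit: pd.DataFrame | None = None
    pooled: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    @property
    def shift_proportion(self) -> float:
        return float(self.rounds["shift_prop"].mean())

    @property
    def outside_given_shift(self) -> float:
        """Pooled over rounds that produced at least one shift (NaN if none did)."""
        return float(self.rounds["outside_prop"].mean())

    @property
    def confounding_proportion(self) -> float:
        return float(self.rounds["confounding_prop"].mean())

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    @property
    def n_pairs_total(self) -> int:
        return int(self.rounds["n_pairs"].sum())


def _pooled_table(rounds: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for col in ("shift_prop", "outside_prop", "confounding_prop"):
        vals = rounds[col].dropna().to_numpy()
        if vals.size == 0:
            rows[col] = {"mean": np.nan, **{f"q{100*q:g}": np.nan for q in QUANTILES}}
            continue
        rows[col] = {
            "mean": float(vals.mean()),
            **{f"q{100*q:g}": float(np.quantile(vals, q)) for q in QUANTILES},
        }
    return pd.DataFrame(rows).T


def run_experiment(
    space: BranchSpace,
    window: AcceptorWindow,
    n_rounds: int,
    n_pairs: int,
    seed: int,
    p_ghost: float = 1.0,
    audit: bool = False,
) -> ExperimentSummary:
    """Run ``n_rounds`` independent rounds of ``n_pairs`` pairs each.

    Fully deterministic given ``seed``: round *r* uses the RNG substream
    derived from ``(seed, r)``, so results are independent of execution
    order. Set ``audit=True`` to retain the per-ghost log (large: two rows
    per pair).
    """
    if n_rounds < 1:
        raise GhostShiftError(f"n_rounds must be >= 1, got {n_rounds}")
    if not 0.0 <= p_ghost <= 1.0:
        raise GhostShiftError(f"p_ghost must be in [0, 1], got {p_ghost}")
    labels = np.asarray(space.labels, dtype=object)
    branch_ids = np.asarray(space.branch_ids, dtype=object)

    round_rows = []
    pair_frames = []
    audit_frames = [] if audit else None
    for r in range(n_rounds):
        rng = round_rng(seed, r)
        draws = sample_rounds(space, window, n_pairs, rng)
        obs = np.where(draws["u"] < p_ghost, draws["g"], draws["tau"])
        is_shift, outside = _classify_arrays(draws["tau"], obs, window.feca_age)
        s = _summarize(is_shift, outside)
        round_rows.append(
            (r, s.n_pairs, s.shift_proportion,
             np.nan if s.outside_given_shift is None else s.outside_given_shift,
             s.confounding_proportion)
        )
        lab = labels[draws["branch_idx"]]
        lab_lo = np.minimum(lab[:, 0], lab[:, 1])
        lab_hi = np.maximum(lab[:, 0], lab[:, 1])
        pair_frames.append(
            pd.DataFrame(
                {
                    "round": r,
                    "label_1": pd.Categorical(lab_lo),
                    "label_2": pd.Categorical(lab_hi),
                    "is_shift": is_shift,
                    "outside": outside,
                }
            )
        )
        if audit:
            idx = draws["branch_idx"]
            audit_frames.append(
                pd.DataFrame(
                    {
                        "round": r,
                        "pair_index": np.repeat(np.arange(n_pairs), 2),
                        "member": np.tile([1, 2], n_pairs),
                        "branch_id": branch_ids[idx].ravel(),
                        "clade_label": lab.ravel(),
                        "ghost_birth": draws["g"].ravel(),
                        "transfer_age": draws["tau"].ravel(),
                        "observed_age": obs.ravel(),
                    }
                )
            )

    rounds = pd.DataFrame(
        round_rows,
        columns=["round", "n_pairs", "shift_prop", "outside_prop", "confounding_prop"],
    )
    summary = ExperimentSummary(
        window=window,
        seed=seed,
        p_ghost=p_ghost,
        rounds=rounds,
        pairs=pd.concat(pair_frames, ignore_index=True),
        audit=pd.concat(audit_frames, ignore_index=True) if audit else None,
    )
    summary.pooled = _pooled_table(rounds)
    return summary


class CladePairMatrix:
    """Shift proportions stratified by unordered donor clade-label pairs.

    ``long`` is a tidy table (clade_a <= clade_b lexicographically, n_pairs,
    shift_prop); :meth:`to_matrix` pivots it into a symmetric DataFrame in
    which label pairs never sampled are NaN (empty, not zero).
    """

    def __init__(self, long: pd.DataFrame):
        self.long = long

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.long["clade_a"]) | set(self.long["clade_b"]))

    def to_matrix(self) -> pd.DataFrame:
        labs = self.labels
        mat = pd.DataFrame(np.nan, index=labs, columns=labs)
        for row in self.long.itertuples(index=False):
            mat.loc[row.clade_a, row.clade_b] = row.shift_prop
            mat.loc[row.clade_b, row.clade_a] = row.shift_prop
        return mat

    def cell(self, clade_a: str, clade_b: str) -> tuple[float, int]:
        """(shift proportion, pair count) for one unordered label pair."""
        a, b = sorted((clade_a, clade_b))
        hit = self.long[(self.long["clade_a"] == a) & (self.long["clade_b"] == b)]
        if hit.empty:
            raise KeyError(f"no sampled pairs for clades ({clade_a}, {clade_b})")
        return float(hit["shift_prop"].iloc[0]), int(hit["n_pairs"].iloc[0])


def pair_matrix(pairs: pd.DataFrame) -> CladePairMatrix:
    """Aggregate a pair-level table into a clade-pair shift matrix.

    Pairs are pooled over all rounds; the diagonal collects same-clade donor
    pairs (both ghosts hosted by branches of one clade).
    """
    grouped = (
        pairs.groupby(["label_1", "label_2"], observed=True)
        .agg(n_pairs=("is_shift", "size"), shift_prop=("is_shift", "mean"))
        .reset_index()
        .rename(columns={"label_1": "clade_a", "label_2": "clade_b"})
        .sort_values(["clade_a", "clade_b"], ignore_index=True)
    )
    grouped["clade_a"] = grouped["clade_a"].astype(str)
    grouped["clade_b"] = grouped["clade_b"].astype(str)
    return CladePairMatrix(grouped)


def ghost_fraction_sweep(
    space: BranchSpace,
    window: AcceptorWindow,
    p_grid: list[float],
    n_pairs: int,
    seed: int,
) -> pd.DataFrame:
    """Shift proportion as a function of the ghost-lineage proportion.

    Each pair member's donor is a ghost with probability p (Bernoulli,
    independent per member); a sampled donor's observed age is the true
    transfer age, so p=0 yields exactly zero shifts. One set of draws is
    shared across the whole grid (common random numbers), which removes
    between-p Monte Carlo noise from the shape of the curve.
    """
    for p in p_grid:
        if not 0.0 <= p <= 1.0:
            raise GhostShiftError(f"ghost proportion {p} outside [0, 1]")
    rng = round_rng(seed, 0)
    draws = sample_rounds(space, window, n_pairs, rng)
    rows = []
    for p in p_grid:
        obs = np.where(draws["u"] < p, draws["g"], draws["tau"])
        is_shift, _ = _classify_arrays(draws["tau"], obs, window.feca_age)
        rows.append((p, n_pairs, float(is_shift.mean())))
    return pd.DataFrame(rows, columns=["p_ghost", "n_pairs", "shift_prop"])
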