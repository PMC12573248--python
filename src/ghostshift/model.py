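"""Model / Results front end over the simulation modules.

:class:`GhostShiftModel` is configured once from the data — a dated species
tree with its recipient, sister and donor-domain tip sets, or a declared
fixture space — and exposes the acceptor window and donor branch space it
derived. :meth:`GhostShiftModel.fit` runs the Monte Carlo experiment and
returns a :class:`GhostShiftResults` carrying the estimated proportions,
their Monte Carlo uncertainty (across-round quantiles and the standard
error of the pooled mean), the per-round table, and stratified views
(clade-pair matrix, ghost-proportion sweep, plots).

    >>> model = GhostShiftModel.from_fixture(symmetric_fixture())
    >>> res = model.fit(n_rounds=100, n_pairs=1000, seed=1)
    >>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis
from .branch_space import AcceptorWindow, BranchSpace, build_branch_space, locate_window
from .errors import InputError
from .synthetic import FixtureSpec, make_fixture_space
from .tree import CladeMap, DatedTree, branch_records, prune_tips, read_clade_map, read_dated_tree, read_tip_set

__all__ = ["GhostShiftModel", "GhostShiftResults"]


class GhostShiftModel:
    """Ghost-transfer shift simulation bound to one acceptor window and donor space."""

    def __init__(self, space: BranchSpace, window: AcceptorWindow, tree: DatedTree | None = None):
        if window is not space.window:
            # allow equal-by-value windows from separate construction paths
            if (window.feca_age, window.leca_age) != (
                space.window.feca_age,
                space.window.leca_age,
            ):
                raise InputError("branch space was built against a different window")
        self.space = space
        self.window = window
        self.tree = tree

    # -- constructors ---------------------------------------------------------

    @classmethod
    def from_tree(
        cls,
        tree: DatedTree,
        euk_tips: set[str],
        sister_tips: set[str],
        domain_tips: set[str],
        clade_map: CladeMap | None = None,
        prune: set[str] | None = None,
    ) -> "GhostShiftModel":
        """Place the window and build the donor space from a dated tree.

        ``euk_tips`` delimit the recipient clade (its MRCA is the window's
        younger bound), ``euk_tips | sister_tips`` its divergence from the
        sister group (older bound); ``domain_tips`` define the eligible
        donor domain; ``prune`` (e.g. organellar tips) are removed first.
        """
        if prune:
            tree = prune_tips(tree, prune)
        window = locate_window(tree, euk_tips, sister_tips)
        cm = clade_map or CladeMap()
        cm = CladeMap(cm.labels, set(cm.domain_tips) | set(domain_tips))
        records = branch_records(tree, cm)
        space = build_branch_space(records, window)
        return cls(space, window, tree=tree)

    @classmethod
    def from_files(
        cls,
        tree_path: str,
        euk_path: str,
        sister_path: str,
        domain_path: str,
        clade_map_path: str | None = None,
        prune_path: str | None = None,
        ultrametric_tol: float = 1e-6,
    ) -> "GhostShiftModel":
        """Build from a Newick file plus plain-text tip-set / clade-map files."""
        try:
            with open(tree_path) as fh:
                newick = fh.read()
        except OSError as exc:
            raise InputError(f"cannot read tree {tree_path!r}: {exc}") from exc
        tree = read_dated_tree(newick, ultrametric_tol=ultrametric_tol)
        clade_map = read_clade_map(clade_map_path) if clade_map_path else None
        prune = read_tip_set(prune_path) if prune_path else None
        return cls.from_tree(
            tree,
            euk_tips=read_tip_set(euk_path),
            sister_tips=read_tip_set(sister_path),
            domain_tips=read_tip_set(domain_path),
            clade_map=clade_map,
            prune=prune,
        )

    @classmethod
    def from_fixture(cls, fixture: FixtureSpec) -> "GhostShiftModel":
        space, window = make_fixture_space(fixture)
        return cls(space, window)

    # -- estimation -----------------------------------------------------------

    def fit(
        self,
        n_rounds: int,
        n_pairs: int,
        seed: int,
        ghost_proportion: float = 1.0,
        audit: bool = False,
    ) -> "GhostShiftResults":
        """Run the Monte Carlo experiment; seed is mandatory (no hidden state)."""
        summary = analysis.run_experiment(
            self.space,
            self.window,
            n_rounds=n_rounds,
            n_pairs=n_pairs,
            seed=seed,
            p_ghost=ghost_proportion,
            audit=audit,
        )
        return GhostShiftResults(self, summary)

    def sweep(self, p_grid: list[float], n_pairs: int, seed: int) -> pd.DataFrame:
        """Shift proportion across a grid of ghost proportions (common random numbers)."""
        return analysis.ghost_fraction_sweep(self.space, self.window, p_grid, n_pairs, seed)

    def __repr__(self) -> str:
        return (
            f"<GhostShiftModel window=({self.window.feca_age:g}, "
            f"{self.window.leca_age:g}) donors={len(self.space)}>"
        )


@dataclass
class GhostShiftResults:
    """Fitted shift proportions with Monte Carlo uncertainty and views."""

    model: GhostShiftModel
    experiment: analysis.ExperimentSummary

    # -- point estimates ------------------------------------------------------

    @property
    def shift_proportion(self) -> float:
        return self.experiment.shift_proportion

    @property
    def outside_given_shift(self) -> float:
        return self.experiment.outside_given_shift

    @property
    def confounding_proportion(self) -> float:
        return self.experiment.confounding_proportion

    @property
    def rounds(self) -> pd.DataFrame:
        return self.experiment.rounds

    @property
    def pooled(self) -> pd.DataFrame:
        return self.experiment.pooled

    def se(self, metric: str = "shift_prop") -> float:
        """Standard error of the pooled mean from the across-round spread."""
        vals = self.rounds[metric].dropna()
        if len(vals) < 2:
            return float("nan")
        return float(vals.std(ddof=1) / np.sqrt(len(vals)))

    # -- stratified views -----------------------------------------------------

    def pair_matrix(self) -> analysis.CladePairMatrix:
        """Shift proportions by unordered donor clade-label pair."""
        return analysis.pair_matrix(self.experiment.pairs)

    # -- presentation ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fitted experiment."""
        e = self.experiment
        w = self.model.window
        lines = [
            "          Ghost-transfer conclusion-shift simulation",
            "=" * 64,
            f"Acceptor window (older, younger): ({w.feca_age:g}, {w.leca_age:g})",
            f"Donor branch space:               {len(self.model.space)} branches",
            f"Rounds x pairs per round:         {e.n_rounds} x {int(e.rounds['n_pairs'].iloc[0])}",
            f"Ghost proportion:                 {e.p_ghost:g}",
            f"Seed:                             {e.seed}",
            "-" * 64,
            e.pooled.rename(
                index={
                    "shift_prop": "shift proportion",
                    "outside_prop": "outside window | shift",
                    "confounding_prop": "confounding proportion",
                }
            ).to_string(float_format=lambda v: f"{v:8.4f}"),
            "=" * 64,
        ]
        return "\n".join(lines)

    def plot_round_distribution(self, metric: str = "shift_prop", ax=None):
        """Histogram of the per-round proportions (Monte Carlo distribution)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vals = self.rounds[metric].dropna()
        ax.hist(vals, bins=30, color="steelblue", edgecolor="white")
        ax.axvline(vals.mean(), color="crimson", lw=1.5, label=f"mean = {vals.mean():.3f}")
        ax.set_xlabel(metric)
        ax.set_ylabel("rounds")
        ax.legend()
        return ax

    def plot_pair_matrix(self, ax=None):
        """Heatmap of the clade-pair shift-proportion matrix."""
        import matplotlib.pyplot as plt

        mat = self.pair_matrix().to_matrix()
        if ax is None:
            _, ax = plt.subplots(figsize=(0.5 * len(mat) + 2,) * 2)
        im = ax.imshow(mat.to_numpy(), cmap="viridis")
        ax.set_xticks(range(len(mat)), mat.columns, rotation=90)
        ax.set_yticks(range(len(mat)), mat.index)
        ax.figure.colorbar(im, ax=ax, label="shift proportion")
        return ax

    def __repr__(self) -> str:
        return (
            f"<GhostShiftResults shift={self.shift_proportion:.4f} "
            f"outside|shift={self.outside_given_shift:.4f} "
            f"confounding={self.confounding_proportion:.4f} "
            f"rounds={self.experiment.n_rounds}>"
        )
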