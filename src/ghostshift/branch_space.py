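"""Acceptor window placement and the donor branch space.

The acceptor is the stem lineage of the recipient clade: for eukaryogenesis,
the branch running from FECA (divergence of eukaryotes from their closest
sampled archaeal relatives, the Asgard archaea) down to LECA (the MRCA of
extant eukaryotes). Eligible ghost-sister branches are the branches of the
donor domain (Bacteria) that coexist in time with that window — the
"branch space" the simulation draws donors from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyBranchSpaceError, InputError
from .tree import BranchRecord, DatedTree

__all__ = ["AcceptorWindow", "BranchSpace", "locate_window", "build_branch_space"]


@dataclass(frozen=True)
class AcceptorWindow:
    """The acceptor time window, delimited by two ages (older first)."""

    feca_age: float
    leca_age: float

    def __post_init__(self) -> None:
        if not self.feca_age > self.leca_age >= 0.0:
            raise InputError(
                f"invalid acceptor window: require feca_age > leca_age >= 0, "
                f"got ({self.feca_age}, {self.leca_age})"
            )

    @property
    def duration(self) -> float:
        return self.feca_age - self.leca_age


class BranchSpace:
    """Ordered set of donor-eligible branches, with vectorized views.

    Construct via :func:`build_branch_space`; members are guaranteed to be
    in-domain and to strictly overlap the open window
    ``(leca_age, feca_age)``.
    """

    def __init__(self, members: Sequence[BranchRecord], window: AcceptorWindow):
        self.members = list(members)
        self.window = window
        self.birth_ages = np.array([m.birth_age for m in self.members], dtype=float)
        self.death_ages = np.array([m.death_age for m in self.members], dtype=float)
        self.labels = [m.clade_label for m in self.members]
        self.branch_ids = [m.branch_id for m in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i: int) -> BranchRecord:
        return self.members[i]

    def __repr__(self) -> str:
        w = self.window
        return (
            f"<BranchSpace n={len(self)} "
            f"window=({w.feca_age:g}, {w.leca_age:g})>"
        )


def locate_window(
    tree: DatedTree, euk_tips: Iterable[str], sister_tips: Iterable[str]
) -> AcceptorWindow:
    """Place the acceptor window on a dated tree from two tip sets.

    The younger bound is the age of MRCA(recipient tips); the older bound is
    the age of MRCA(recipient ∪ sister tips), i.e. the divergence of the
    recipient clade from its sister group. Errors if the two MRCAs coincide
    (the sister set is nested inside the recipient clade, leaving a
    zero-length acceptor branch).
    """
    euk = set(euk_tips)
    sis = set(sister_tips)
    if not euk or not sis:
        raise InputError("recipient and sister tip sets must be non-empty")
    if euk & sis:
        raise InputError(f"tip sets overlap: {sorted(euk & sis)[:5]}")
    leca = tree.mrca_age(euk)
    feca = tree.mrca_age(euk | sis)
    if feca <= leca:
        raise InputError(
            "MRCA(recipient ∪ sister) is not older than MRCA(recipient): "
            "sister set is nested inside the recipient clade "
            f"(ages {feca:g} vs {leca:g})"
        )
    return AcceptorWindow(feca_age=feca, leca_age=leca)


def build_branch_space(
    records: Iterable[BranchRecord], window: AcceptorWindow
) -> BranchSpace:
    """Filter branch records down to eligible donor-sister branches.

    A branch is kept iff it is in the donor domain and strictly overlaps the
    open window: ``birth_age > leca_age`` and ``death_age < feca_age``.
    Branches merely touching a window bound are excluded — their ghost-birth
    or transfer sampling interval would be empty. The result is ordered by
    branch id and must be non-empty.
    """
    kept = [
        r
        for r in records
        if r.in_domain
        and r.birth_age > window.leca_age
        and r.death_age < window.feca_age
    ]
    kept.sort(key=lambda r: r.branch_id)
    if not kept:
        raise EmptyBranchSpaceError(
            f"no in-domain branch coexists with the window "
            f"({window.feca_age:g}, {window.leca_age:g}); simulation impossible"
        )
    return BranchSpace(kept, window)


def write_branch_space_tsv(space: BranchSpace, path: str, header_lines: Sequence[str] = ()) -> None:
    """Audit export: branch_id, birth_age, death_age, clade_label."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("branch_id\tbirth_age\tdeath_age\tclade_label\n")
        for m in space:
            fh.write(f"{m.branch_id}\t{m.birth_age:.10g}\t{m.death_age:.10g}\t{m.clade_label}\n")
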