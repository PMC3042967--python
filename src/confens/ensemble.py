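"""Conformer-ensemble filtering and accuracy evaluation.

An ensemble is evaluated against an experimental ("bioactive") reference
conformation by two per-conformer metrics — symmetry-aware heavy-atom RMSD
and shape-optimised Shape-Tanimoto — and the ensemble score is the minimum
RMSD and maximum ST over its conformers (each may come from a different
conformer).  Two data-reduction operations precede evaluation, in this fixed
pipeline order: truncation at a maximum conformer count (default 100,000;
ensembles that hit it are flagged as truncated), then an energy window that
discards conformers more than ``ewindow`` kcal/mol above the global-minimum
conformer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .molgraph import (
    Conformer,
    FlexibilityDescriptor,
    PerceivedGraph,
    effective_rotor_count,
    round_half_up,
)
from .shape import build_shape, shape_tanimoto
from .superpose import min_rmsd

__all__ = [
    "MAX_CONFS_DEFAULT",
    "ConformerEnsemble",
    "EvaluationResult",
    "filter_energy_window",
    "truncate_ensemble",
    "evaluate_ensemble",
    "aggregate_by_bins",
]

MAX_CONFS_DEFAULT = 100_000


@dataclass
class ConformerEnsemble:
    """Ordered conformer collection sharing one perceived molecule."""

    molecule: PerceivedGraph
    conformers: list[Conformer]
    truncated_100k: bool = False
    #: conformer count the generator attempted before any cap (bookkeeping).
    n_attempted: int | None = None

    def __post_init__(self) -> None:
        n = len(self.molecule.base.atoms)
        for k, c in enumerate(self.conformers):
            if c.n_atoms != n:
                raise ValueError(
                    f"conformer {k} has {c.n_atoms} atoms, molecule has {n}"
                )

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def descriptor(self) -> FlexibilityDescriptor:
        return effective_rotor_count(self.molecule)


@dataclass
class EvaluationResult:
    """Per-ensemble accuracy: min RMSD (Å), max ST, their conformer ordinals."""

    name: str
    min_rmsd: float
    max_st: float
    argmin_rmsd: int
    argmax_st: int
    n_conformers: int
    truncated_100k: bool
    n_nha: int
    n_er: float

    @property
    def n_er_bin(self) -> int:
        return round_half_up(self.n_er)


def filter_energy_window(e: ConformerEnsemble, ewindow: float) -> ConformerEnsemble:
    """Keep conformers within ``ewindow`` kcal/mol of the global minimum (inclusive).

    Order is preserved; the global-minimum conformer always survives.  An
    infinite window is the identity.  Raises ``ValueError`` naming the first
    conformer without an energy.
    """
    if ewindow < 0:
        raise ValueError("ewindow must be >= 0")
    for k, c in enumerate(e.conformers):
        if c.energy is None:
            raise ValueError(f"conformer {k} has no energy; cannot apply energy window")
    if math.isinf(ewindow):
        return e
    e_min = min(c.energy for c in e.conformers)
    kept = [c for c in e.conformers if c.energy <= e_min + ewindow]
    return replace(e, conformers=kept)


def truncate_ensemble(e: ConformerEnsemble, max_confs: int = MAX_CONFS_DEFAULT) -> ConformerEnsemble:
    """Keep the first ``max_confs`` conformers; flag the ensemble if any were dropped."""
    if max_confs < 1:
        raise ValueError("max_confs must be >= 1")
    if len(e.conformers) <= max_confs:
        return e
    return replace(e, conformers=e.conformers[:max_confs], truncated_100k=True)


def evaluate_ensemble(
    e: ConformerEnsemble,
    ref: Conformer,
    optimize_shape: bool = True,
    compute_st: bool = True,
) -> EvaluationResult:
    """Score an ensemble against a reference conformation.

    ``min_rmsd`` is the minimum symmetry-aware RMSD over conformers and
    ``max_st`` the maximum (independently overlay-optimised) Shape-Tanimoto;
    the two optima may come from different conformers and both ordinals are
    reported.  ``compute_st=False`` skips the shape overlay (max_st = NaN)
    for RMSD-only workflows.
    """
    if len(e.conformers) == 0:
        raise ValueError("cannot evaluate an empty ensemble")
    p = e.molecule
    d = e.descriptor

    best_rmsd, arg_rmsd = np.inf, 0
    for k, conf in enumerate(e.conformers):
        r = min_rmsd(conf, ref, p).rmsd
        if r < best_rmsd:
            best_rmsd, arg_rmsd = r, k

    best_st, arg_st = math.nan, 0
    if compute_st:
        ref_shape = build_shape(ref, p)
        best_st = -np.inf
        for k, conf in enumerate(e.conformers):
            st = shape_tanimoto(ref_shape, build_shape(conf, p), optimize=optimize_shape).st
            if st > best_st:
                best_st, arg_st = st, k

    return EvaluationResult(
        name=p.base.name,
        min_rmsd=float(best_rmsd),
        max_st=float(best_st),
        argmin_rmsd=arg_rmsd,
        argmax_st=arg_st,
        n_conformers=len(e.conformers),
        truncated_100k=e.truncated_100k,
        n_nha=d.n_nha,
        n_er=d.n_er,
    )


def aggregate_by_bins(
    results: list[EvaluationResult] | pd.DataFrame,
    by: str = "nha",
    exclude_truncated: bool = False,
) -> pd.DataFrame:
    """Mean min-RMSD and max-ST binned by size (``nha``) or flexibility (``er``).

    Effective rotor counts are binned half-up to whole numbers.  Optionally
    excludes ensembles that hit the conformer cap (the "non-truncated"
    view).  Empty bins are omitted; every row carries its member count.
    """
    if by not in ("nha", "er"):
        raise ValueError("by must be 'nha' or 'er'")
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        if not results:
            raise ValueError("no results to aggregate")
        df = pd.DataFrame(
            {
                "min_rmsd": [r.min_rmsd for r in results],
                "max_st": [r.max_st for r in results],
                "n_nha": [r.n_nha for r in results],
                "n_er": [r.n_er for r in results],
                "truncated_100k": [r.truncated_100k for r in results],
            }
        )
    if exclude_truncated:
        df = df[~df["truncated_100k"]]
    if df.empty:
        raise ValueError("no results to aggregate after exclusion")
    key = "n_nha" if by == "nha" else df["n_er"].map(round_half_up)
    grouped = (
        df.groupby(key)
        .agg(mean_min_rmsd=("min_rmsd", "mean"), mean_max_st=("max_st", "mean"), count=("min_rmsd", "size"))
        .reset_index()
        .rename(columns={"n_nha": "bin", "n_er": "bin"})
    )
    grouped.columns = ["bin", "mean_min_rmsd", "mean_max_st", "count"]
    return grouped
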