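"""RMSD-separation leader sampling of conformer ensembles.

Data reduction keeps a diverse subset of an ensemble by enforcing a minimum
symmetry-aware RMSD separation between retained conformers: conformers are
scanned in order (energy-ascending by default, so low-energy representatives
become leaders) and one is kept iff its RMSD to every already-kept conformer
exceeds the threshold.  A threshold of zero disables duplicate detection
entirely and retains every conformer.  The threshold itself can come from
the accuracy model (:func:`confens.accuracy.sampling_threshold`), which
targets ~90% ensemble coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .accuracy import sampling_threshold
from .ensemble import ConformerEnsemble
from .superpose import min_rmsd

__all__ = ["SamplingPlan", "sample_by_rmsd", "sample_with_model"]


@dataclass
class SamplingPlan:
    """Result of leader sampling: kept ordinals plus a coverage witness.

    ``coverage_map`` maps each discarded ordinal to a kept ordinal whose
    symmetry-aware RMSD to it is <= threshold (the leader that blocked it).
    """

    threshold: float
    ordering: str
    keep_list: list[int]
    coverage_map: dict[int, int]

    @property
    def n_kept(self) -> int:
        return len(self.keep_list)


def sample_by_rmsd(
    e: ConformerEnsemble, threshold: float, ordering: str = "energy_ascending"
) -> SamplingPlan:
    """Leader sampling at a fixed RMSD-separation threshold (Å).

    ``ordering`` is ``"energy_ascending"`` (default; requires energies, ties
    broken by input order) or ``"input"``.  With ``threshold == 0`` duplicate
    detection is skipped and every conformer is kept.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n = len(e.conformers)
    if ordering == "energy_ascending":
        for k, c in enumerate(e.conformers):
            if c.energy is None:
                raise ValueError(
                    f"conformer {k} has no energy; use ordering='input' instead"
                )
        order = sorted(range(n), key=lambda k: (e.conformers[k].energy, k))
    elif ordering == "input":
        order = list(range(n))
    else:
        raise ValueError(f"unknown ordering {ordering!r}")

    if threshold == 0:  # duplicate detection skipped
        return SamplingPlan(
            threshold=0.0, ordering=ordering, keep_list=order, coverage_map={}
        )

    p = e.molecule
    kept: list[int] = []
    coverage: dict[int, int] = {}
    for k in order:
        blocker = None
        for j in kept:
            r = min_rmsd(e.conformers[k], e.conformers[j], p).rmsd
            if r <= threshold:
                blocker = j
                break
        if blocker is None:
            kept.append(k)
        else:
            coverage[k] = blocker
    return SamplingPlan(
        threshold=float(threshold), ordering=ordering, keep_list=kept, coverage_map=coverage
    )


def sample_with_model(
    e: ConformerEnsemble, scheme: str = "eq5", ordering: str = "energy_ascending"
) -> SamplingPlan:
    """Leader sampling at the accuracy-model threshold for this molecule.

    The threshold is the predicted ensemble RMSD plus one residual SD at the
    molecule's (N_NHA, N_ER) under the chosen published scheme.
    """
    d = e.descriptor
    threshold = sampling_threshold(d.n_nha, d.n_er, scheme=scheme)
    return sample_by_rmsd(e, threshold=threshold, ordering=ordering)
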