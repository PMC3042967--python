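"""Symmetry-aware minimum heavy-atom RMSD between conformers.

Chemically equivalent atoms (e.g. the two ortho carbons of a phenyl ring)
make the naive coordinate-paired RMSD overestimate geometric dissimilarity.
The metric here enumerates the automorphisms of the heavy-atom graph —
permutations preserving elements, formal charges and bonds — and reports the
minimum, over those permutations, of the least-squares superposed RMSD
(Kabsch, proper rotations only: mirror images are distinct molecules).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from networkx.algorithms import isomorphism
from scipy.spatial.transform import Rotation

from .molgraph import Conformer, MoleculeGraph, PerceivedGraph

__all__ = [
    "Automorphism",
    "SuperpositionResult",
    "enumerate_automorphisms",
    "kabsch_superpose",
    "min_rmsd",
]

DEFAULT_AUTOMORPHISM_CAP = 10_000


@dataclass(frozen=True)
class Automorphism:
    """A heavy-atom permutation preserving elements, charges and bonds."""

    permutation: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.permutation)


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition: RMSD (Å), proper rotation, translation, permutation."""

    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    permutation_used: Automorphism | None = None
    automorphism_count: int = 1
    truncated: bool = False


def enumerate_automorphisms(
    p: PerceivedGraph | MoleculeGraph, cap: int = DEFAULT_AUTOMORPHISM_CAP
) -> tuple[list[Automorphism], bool]:
    """Enumerate heavy-atom graph automorphisms, in lexicographic permutation order.

    Returns ``(automorphisms, truncated)``; at most ``cap`` permutations are
    produced and ``truncated`` is set when the cap was hit.  The identity is
    always present: if the capped search stopped before yielding it, it
    replaces the last collected permutation.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    mol = p.base if isinstance(p, PerceivedGraph) else p
    heavy = mol.heavy_subgraph()
    g = heavy.to_networkx()

    nm = isomorphism.categorical_node_match(["element", "charge"], [None, None])
    em = isomorphism.categorical_edge_match("order", None)
    matcher = isomorphism.GraphMatcher(g, g, node_match=nm, edge_match=em)

    perms: list[tuple[int, ...]] = []
    truncated = False
    for mapping in matcher.isomorphisms_iter():
        perms.append(tuple(mapping[i] for i in range(len(heavy.atoms))))
        if len(perms) >= cap:
            truncated = True
            break

    identity = tuple(range(len(heavy.atoms)))
    if identity not in perms:
        if truncated:
            perms[-1] = identity
        else:  # pragma: no cover - VF2 always yields the identity
            perms.append(identity)
    perms = sorted(set(perms))
    if truncated:
        warnings.warn(
            f"automorphism enumeration truncated at cap={cap} for {mol.name!r}",
            stacklevel=2,
        )
    return [Automorphism(p_) for p_ in perms], truncated


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Closed-form SVD (Kabsch) with reflection correction; the returned
    rotation is proper (det = +1).  Degenerate inputs (collinear or fewer
    than three points) return one of the minimisers.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 1:
        raise ValueError("coords_a and coords_b must be equal-shape (n, 3) arrays, n >= 1")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # degenerate point sets
        rot, rssd = Rotation.align_vectors(a - ca, b - cb)
    rmsd = float(rssd) / np.sqrt(a.shape[0])
    r = rot.as_matrix()
    translation = ca - r @ cb
    return SuperpositionResult(rmsd=rmsd, rotation=r, translation=translation)


def min_rmsd(
    conf: Conformer,
    ref: Conformer,
    p: PerceivedGraph,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> SuperpositionResult:
    """Symmetry-aware minimum heavy-atom RMSD of ``conf`` against ``ref``.

    Minimum over all graph automorphisms of the Kabsch-superposed RMSD.
    Ties between automorphisms are broken by lexicographic permutation order
    (the enumeration order), making the reported permutation deterministic.
    """
    mol = p.base
    a = ref.heavy_coords(mol)
    b = conf.heavy_coords(mol)
    autos, truncated = enumerate_automorphisms(p, cap=cap)

    best: SuperpositionResult | None = None
    for auto in autos:
        res = kabsch_superpose(a, b[list(auto.permutation)])
        if best is None or res.rmsd < best.rmsd - 1e-15:
            res.permutation_used = auto
            best = res
    assert best is not None
    best.automorphism_count = len(autos)
    best.truncated = truncated
    return best
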