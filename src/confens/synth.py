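"""Synthetic conformer ensembles and regression datasets.

Real conformer generators assemble fragment templates and drive torsions
with rule-based angle sets; this module emulates the *output* of that
process at desk scale so that every evaluation and data-reduction operation
in the package can be exercised with known ground truth.  Toy molecules
(heavy-atom alkane chains, saturated rings, decalin, phenyl-alkyl chains)
are built on ideal geometry, conformers are enumerated as the Cartesian
product of per-rotor torsion states (3 states per rotor by default:
anti/gauche+/gauche-), and each conformer gets a crude deterministic
pseudo-energy (per-gauche torsion penalty plus a short-contact steric term).
The pseudo-energies are NOT a force field: their only contract is a
deterministic total order for energy-window and sampling tests.

A "bioactive reference" is planted by perturbing a chosen conformer, so
evaluation can be checked against the known source ordinal, and regression
datasets with stated linear structure and noise emulate the inputs of the
accuracy model.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .molgraph import AROMATIC, Conformer, MoleculeGraph, perceive
from .ensemble import ConformerEnsemble, MAX_CONFS_DEFAULT

__all__ = [
    "TorsionEnsembleSpec",
    "RegressionDatasetSpec",
    "ReferenceConformer",
    "build_template",
    "generate_torsion_ensemble",
    "make_reference",
    "generate_regression_dataset",
]

CC_BOND = 1.54
CC_AROMATIC = 1.39
CC_RING_CHAIN = 1.50
TETRAHEDRAL = math.radians(109.47122)

GAUCHE_PENALTY = 0.9  # kcal/mol per gauche rotor state
ECLIPSED_PENALTY = 2.5  # kcal/mol for eclipsed-like states (4+ state grids)
STERIC_CUTOFF = 2.5  # Å
STERIC_FORCE = 10.0  # kcal/mol/Å^2


@dataclass(frozen=True)
class TorsionEnsembleSpec:
    """Recipe for a torsion-driven ensemble of a template molecule."""

    template: str
    states_per_rotor: int = 3
    noise_sd: float = 0.02
    seed: int = 0
    max_confs: int = MAX_CONFS_DEFAULT


@dataclass(frozen=True)
class RegressionDatasetSpec:
    """Recipe for a synthetic (n_nha, n_er, rmsd_actual) regression table."""

    n: int
    intercept: float = 0.029
    coef_nha: float = 0.0099
    coef_er: float = 0.040
    noise_sd: float = 0.19
    nha_range: tuple[int, int] = (2, 50)
    er_range: tuple[float, float] = (0.0, 16.0)
    noise: str = "normal"
    seed: int = 0


@dataclass
class ReferenceConformer:
    """A planted bioactive-reference conformation with its ground truth."""

    conformer: Conformer
    source_ordinal: int
    perturb_sd: float


# ---------------------------------------------------------------------------
# Template geometry
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates (radians)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.cos(dihedral) * math.sin(angle),
            bond * math.sin(dihedral) * math.sin(angle),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _chain_coords(n: int, bond: float = CC_BOND, angle: float = TETRAHEDRAL) -> np.ndarray:
    coords = np.zeros((n, 3))
    if n > 1:
        coords[1] = [bond, 0.0, 0.0]
    if n > 2:
        coords[2] = coords[1] + [
            -bond * math.cos(angle),
            bond * math.sin(angle),
            0.0,
        ]
    for k in range(3, n):
        coords[k] = _nerf(coords[k - 3], coords[k - 2], coords[k - 1], bond, angle, math.pi)
    return coords


def _chair_coords(bond: float = CC_BOND) -> np.ndarray:
    """Ideal cyclohexane chair: alternating-z hexagon with tetrahedral angles."""

    def angle_at(z0: float) -> float:
        r = math.sqrt(bond**2 - 4 * z0**2)
        pts = np.array(
            [
                [r * math.cos(k * math.pi / 3), r * math.sin(k * math.pi / 3), z0 * (-1) ** k]
                for k in range(6)
            ]
        )
        v1 = pts[0] - pts[1]
        v2 = pts[2] - pts[1]
        return math.acos(float(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))

    z0 = brentq(lambda z: angle_at(z) - TETRAHEDRAL, 1e-6, bond / 2 - 1e-6)
    r = math.sqrt(bond**2 - 4 * z0**2)
    return np.array(
        [
            [r * math.cos(k * math.pi / 3), r * math.sin(k * math.pi / 3), z0 * (-1) ** k]
            for k in range(6)
        ]
    )


def _polygon_coords(n: int, bond: float) -> np.ndarray:
    r = bond / (2 * math.sin(math.pi / n))
    return np.array(
        [[r * math.cos(2 * math.pi * k / n), r * math.sin(2 * math.pi * k / n), 0.0] for k in range(n)]
    )


def _ring_mol(n: int, name: str, order: int = 1) -> MoleculeGraph:
    atoms = tuple(("C", 0) for _ in range(n))
    bonds = tuple((k, (k + 1) % n, order) for k in range(n))
    return MoleculeGraph(atoms=atoms, bonds=bonds, name=name)


def build_template(template_id: str) -> tuple[MoleculeGraph, Conformer]:
    """Build a toy heavy-atom molecule with deterministic ideal coordinates.

    Known ids: ``alkane_chain(n)`` (n >= 2), ``ring(n)`` (n >= 3; chair for
    n = 6, planar otherwise), ``fused_decalin``, ``phenyl_chain(n)``
    (benzene for n = 0).
    """
    m = re.fullmatch(r"(alkane_chain|ring|phenyl_chain)\((\d+)\)", template_id.strip())
    if template_id.strip() == "fused_decalin":
        chair = _chair_coords()
        mid = (chair[0] + chair[1]) / 2
        extra = 2 * mid - chair[2:]  # inversion through the fusion-bond midpoint
        coords = np.vstack([chair, extra])
        atoms = tuple(("C", 0) for _ in range(10))
        bonds = [(k, k + 1, 1) for k in range(5)] + [(5, 0, 1)]
        # second ring: 1 - 0 - 6 - 7 - 8 - 9 - 1  (6..9 are inverted images of 2..5)
        bonds += [(0, 6, 1), (6, 7, 1), (7, 8, 1), (8, 9, 1), (9, 1, 1)]
        mol = MoleculeGraph(atoms=atoms, bonds=tuple(bonds), name="fused_decalin")
        return mol, Conformer(coords=coords, name="fused_decalin")
    if m is None:
        raise ValueError(f"unknown template id {template_id!r}")
    kind, n = m.group(1), int(m.group(2))

    if kind == "alkane_chain":
        if n < 2:
            raise ValueError("alkane_chain needs at least 2 heavy atoms")
        atoms = tuple(("C", 0) for _ in range(n))
        bonds = tuple((k, k + 1, 1) for k in range(n - 1))
        mol = MoleculeGraph(atoms=atoms, bonds=bonds, name=template_id)
        return mol, Conformer(coords=_chain_coords(n), name=template_id)

    if kind == "ring":
        if n < 3:
            raise ValueError("ring needs at least 3 atoms")
        mol = _ring_mol(n, template_id)
        coords = _chair_coords() if n == 6 else _polygon_coords(n, CC_BOND)
        return mol, Conformer(coords=coords, name=template_id)

    # phenyl_chain(n): benzene + n-carbon chain on ring atom 0
    ring = _polygon_coords(6, CC_AROMATIC)
    atoms = [("C", 0)] * (6 + n)
    bonds = [(k, (k + 1) % 6, AROMATIC) for k in range(6)]
    coords = [ring[k] for k in range(6)]
    if n > 0:
        # first chain atom: in-plane, radially outward from the ring centre
        direction = ring[0] / np.linalg.norm(ring[0])
        coords.append(ring[0] + CC_RING_CHAIN * direction)
        bonds.append((0, 6, 1))
        prev3 = [ring[1], ring[0], coords[6]]
        for k in range(1, n):
            nxt = _nerf(prev3[-3], prev3[-2], prev3[-1], CC_BOND, TETRAHEDRAL, math.pi)
            coords.append(nxt)
            bonds.append((6 + k - 1, 6 + k, 1))
            prev3 = [prev3[-2], prev3[-1], nxt]
    mol = MoleculeGraph(atoms=tuple(atoms), bonds=tuple(bonds), name=template_id)
    return mol, Conformer(coords=np.array(coords), name=template_id)


# ---------------------------------------------------------------------------
# Torsion-driven ensembles
# ---------------------------------------------------------------------------

def _torsion_penalty(offset_deg: float) -> float:
    off = offset_deg % 360.0
    if math.isclose(off, 0.0, abs_tol=1e-6):
        return 0.0
    if math.isclose(off, 120.0, abs_tol=1e-6) or math.isclose(off, 240.0, abs_tol=1e-6):
        return GAUCHE_PENALTY
    return ECLIPSED_PENALTY


def _moving_sets(mol: MoleculeGraph, rotors: list[tuple[int, int]]) -> list[list[int]]:
    g = mol.to_networkx()
    moving = []
    for i, j in rotors:
        h = g.copy()
        h.remove_edge(i, j)
        side = nx.node_connected_component(h, j)
        moving.append(sorted(side - {j}))
    return moving


def _nonbonded_pairs(mol: MoleculeGraph) -> np.ndarray:
    """Heavy-atom pairs separated by >= 3 bonds (1-2 and 1-3 excluded)."""
    g = mol.to_networkx()
    heavy = mol.heavy_indices
    pairs = []
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
    for a, b in itertools.combinations(heavy, 2):
        if b not in dist.get(a, {}):
            pairs.append((a, b))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def generate_torsion_ensemble(spec: TorsionEnsembleSpec) -> ConformerEnsemble:
    """Enumerate all torsion-state combinations of a template, with pseudo-energies.

    Conformers are the Cartesian product of per-rotor torsion offsets
    (``k * 360 / states_per_rotor`` degrees away from the template's anti
    geometry), enumerated in lexicographic state order and truncated at
    ``max_confs`` with the truncation flag set — the same semantics as the
    generator-side conformer cap.  Seeded Gaussian coordinate noise breaks
    exact degeneracies; the pseudo-energy is the summed per-rotor torsion
    penalty plus a quadratic short-contact steric term.
    """
    if spec.states_per_rotor < 1:
        raise ValueError("states_per_rotor must be >= 1")
    mol, base = build_template(spec.template)
    p = perceive(mol)
    rotors = sorted(p.rotatable_bonds)
    moving = _moving_sets(mol, rotors)
    nb_pairs = _nonbonded_pairs(mol)
    rng = np.random.default_rng(spec.seed)

    n_rotors = len(rotors)
    n_attempted = spec.states_per_rotor**n_rotors
    offsets = [k * 360.0 / spec.states_per_rotor for k in range(spec.states_per_rotor)]

    conformers: list[Conformer] = []
    for states in itertools.product(range(spec.states_per_rotor), repeat=n_rotors):
        if len(conformers) >= spec.max_confs:
            break
        coords = base.coords.copy()
        energy = 0.0
        for (i, j), move, s in zip(rotors, moving, states):
            off = offsets[s]
            energy += _torsion_penalty(off)
            if off != 0.0 and move:
                axis = coords[j] - coords[i]
                axis /= np.linalg.norm(axis)
                rot = Rotation.from_rotvec(math.radians(off) * axis)
                coords[move] = rot.apply(coords[move] - coords[j]) + coords[j]
        if spec.noise_sd > 0:
            coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
        if len(nb_pairs):
            d = np.linalg.norm(coords[nb_pairs[:, 0]] - coords[nb_pairs[:, 1]], axis=1)
            close = d < STERIC_CUTOFF
            energy += float(np.sum(STERIC_FORCE * (STERIC_CUTOFF - d[close]) ** 2))
        conformers.append(
            Conformer(coords=coords, energy=energy, name=f"{mol.name}:{len(conformers)}")
        )

    return ConformerEnsemble(
        molecule=p,
        conformers=conformers,
        truncated_100k=n_attempted > spec.max_confs,
        n_attempted=n_attempted,
    )


def make_reference(
    e: ConformerEnsemble, pick: int, perturb_sd: float = 0.0, seed: int = 0
) -> ReferenceConformer:
    """Plant a bioactive-reference conformation by perturbing conformer ``pick``.

    The returned object records the source ordinal so evaluation results
    (argmin of the ensemble RMSD) can be checked against ground truth.
    """
    if not (0 <= pick < len(e.conformers)):
        raise ValueError(f"ordinal {pick} out of range 0..{len(e.conformers) - 1}")
    rng = np.random.default_rng(seed)
    src = e.conformers[pick]
    coords = src.coords.copy()
    if perturb_sd > 0:
        coords = coords + rng.normal(0.0, perturb_sd, size=coords.shape)
    conf = Conformer(coords=coords, energy=None, name=f"{src.name}:ref")
    return ReferenceConformer(conformer=conf, source_ordinal=pick, perturb_sd=perturb_sd)


# ---------------------------------------------------------------------------
# Regression datasets
# ---------------------------------------------------------------------------

def generate_regression_dataset(spec: RegressionDatasetSpec) -> pd.DataFrame:
    """Synthetic (name, n_nha, n_er, rmsd_actual) table with known linear structure.

    Descriptors are sampled uniformly over their ranges (N_NHA as integers);
    ``rmsd_actual`` is the stated linear model plus noise, clipped at zero.
    ``noise="lognormal"`` produces right-skewed, zero-mean residuals scaled
    to ``noise_sd`` (emulating the skew of real accuracy residuals);
    ``"normal"`` is Gaussian.
    """
    if spec.n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    n_nha = rng.integers(spec.nha_range[0], spec.nha_range[1] + 1, size=spec.n)
    n_er = rng.uniform(spec.er_range[0], spec.er_range[1], size=spec.n)
    mean = spec.intercept + spec.coef_nha * n_nha + spec.coef_er * n_er
    if spec.noise == "normal":
        noise = rng.normal(0.0, spec.noise_sd, size=spec.n)
    elif spec.noise == "lognormal":
        shape = 1.0
        raw = rng.lognormal(mean=0.0, sigma=shape, size=spec.n)
        raw = (raw - math.exp(shape**2 / 2)) / math.sqrt(
            (math.exp(shape**2) - 1) * math.exp(shape**2)
        )
        noise = spec.noise_sd * raw
    else:
        raise ValueError(f"unknown noise family {spec.noise!r}")
    rmsd = np.clip(mean + noise, 0.0, None)
    return pd.DataFrame(
        {
            "name": [f"synthetic-{k}" for k in range(spec.n)],
            "n_nha": n_nha.astype(int),
            "n_er": n_er,
            "rmsd_actual": rmsd,
        }
    )
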