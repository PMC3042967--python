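"""Independent reference implementations used only to validate the package.

Everything here is deliberately written from first principles (plain
SVD/enumeration/grid integration) and shares no code path with the
implementation under test.
"""

import itertools

import numpy as np


def svd_superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares superposed RMSD via a direct SVD Kabsch, proper rotations only."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    diff = a - b @ r.T
    return float(np.sqrt((diff**2).sum() / a.shape[0]))


def brute_force_min_rmsd(coords_ref, coords_conf, atom_labels) -> float:
    """Minimum superposed RMSD over ALL label-consistent permutations (exhaustive)."""
    n = len(atom_labels)
    groups: dict = {}
    for i, lab in enumerate(atom_labels):
        groups.setdefault(lab, []).append(i)
    keys = list(groups)
    best = np.inf
    for parts in itertools.product(*[itertools.permutations(groups[k]) for k in keys]):
        perm = [0] * n
        for key, part in zip(keys, parts):
            for src, dst in zip(groups[key], part):
                perm[src] = dst
        best = min(best, svd_superposed_rmsd(np.asarray(coords_ref), np.asarray(coords_conf)[perm]))
    return float(best)


def brute_force_automorphisms(atoms, bonds):
    """All atom permutations preserving (element, charge) labels and the bond multiset."""
    n = len(atoms)
    bond_set = {(min(i, j), max(i, j), o) for i, j, o in bonds}
    out = []
    for perm in itertools.permutations(range(n)):
        if any(atoms[i] != atoms[perm[i]] for i in range(n)):
            continue
        mapped = {(min(perm[i], perm[j]), max(perm[i], perm[j]), o) for i, j, o in bonds}
        if mapped == bond_set:
            out.append(perm)
    return out


def grid_overlap_volume(centers_a, exps_a, centers_b, exps_b, amplitude, spacing=0.1, pad=3.0):
    """Numeric 3-D grid integration of rho_A(r) * rho_B(r) for sums of Gaussians."""
    centers = np.vstack([centers_a, centers_b])
    lo = centers.min(axis=0) - pad
    hi = centers.max(axis=0) + pad
    axes = [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def density(centers, exps):
        rho = np.zeros(pts.shape[0])
        for c, a in zip(centers, exps):
            d2 = np.sum((pts - c) ** 2, axis=1)
            rho += amplitude * np.exp(-a * d2)
        return rho

    return float(np.sum(density(centers_a, exps_a) * density(centers_b, exps_b)) * spacing**3)
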