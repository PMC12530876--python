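"""Relative conformational energies from a Lennard-Jones molecular-mechanics model.

The nanoscale optimization target is the set of relative conformational
energies (RCE) of n-octane: per-conformer single-molecule energies referenced
to a designated conformer.  Here each conformer energy is a fixed bonded-term
offset plus the intramolecular nonbonded Lennard-Jones sum, so the RCE vector
responds directly to the four (sigma, eps) parameters under optimization.

The fixture generator builds octane-like C8H18 chains with ideal bond lengths
and angles and seeded backbone dihedrals (trans / gauche+/-), and computes
target RCEs with a designated "true" parameter set, making parameter recovery
well-posed by construction.  It is a synthetic stand-in for quantum-chemical
reference energies, which are out of scope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ContractError
from .space import LJParamSet

# ideal alkane geometry
R_CC = 0.1530  # nm
R_CH = 0.1090  # nm
ANGLE_CCC = math.radians(112.0)
ANGLE_HCC = math.radians(109.47)
ANGLE_HCH = math.radians(107.8)

#: default "true" parameter set used to generate fixture targets (nm, kJ/mol).
#: Chosen on the synthetic oracle's 700 kg/m^3 level set (sigma_H = 0.15 nm
#: zeroes the rugged term; sigma_C puts the smooth term on target), so the
#: density and RCE objectives share an optimum and combined multiscale
#: optimization is well-posed.
DEFAULT_TRUE_PARAMS = LJParamSet(0.2234, 0.1500, 0.6500, 0.1100)

#: bonded-energy increment per gauche backbone dihedral, kJ/mol
GAUCHE_OFFSET = 2.9


def lj_pair_energy(r: float, sigma_ij: float, eps_ij: float) -> float:
    """12-6 Lennard-Jones pair energy ``4*eps*[(sigma/r)^12 - (sigma/r)^6]``.

    Zero at ``r = sigma``; minimum ``-eps`` at ``r = 2**(1/6) * sigma``.
    """
    if r <= 0:
        raise ContractError(f"pair distance must be > 0, got {r}")
    x = (sigma_ij / r) ** 6
    return 4.0 * eps_ij * (x * x - x)


@dataclass
class ConformerSet:
    """Conformers sharing one topology, plus target relative energies.

    ``coords``: (n_conf, n_atoms, 3) Cartesian coordinates in nm.
    ``elements``: per-atom element symbols ("C"/"H").
    ``bonds``: covalent bond list as index pairs.
    ``bonded_offsets``: fixed per-conformer bonded-term energies, kJ/mol.
    ``target_rce``: length n_conf vector, zero at ``reference_index``.
    """

    coords: np.ndarray
    elements: list[str]
    bonds: list[tuple[int, int]]
    bonded_offsets: np.ndarray
    reference_index: int = 0
    target_rce: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ContractError(f"coords must be (n_conf, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != len(self.elements):
            raise ContractError("elements length does not match atom count")
        self.bonded_offsets = np.asarray(self.bonded_offsets, dtype=float)
        if len(self.bonded_offsets) != self.n_conformers:
            raise ContractError("bonded_offsets length does not match conformer count")
        if not 0 <= self.reference_index < self.n_conformers:
            raise ContractError("reference index out of range")
        if self.target_rce is not None:
            self.target_rce = np.asarray(self.target_rce, dtype=float)
            if len(self.target_rce) != self.n_conformers:
                raise ContractError("target_rce length does not match conformer count")
            if abs(self.target_rce[self.reference_index]) > 1e-12:
                raise ContractError("target RCE of the reference conformer must be 0")

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _bond_path_weights(
    n_atoms: int, bonds: list[tuple[int, int]], scale14: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nonbonded pair lists with exclusion weights.

    Pairs separated by 1 or 2 bonds are excluded; 1-4 pairs carry ``scale14``
    (1.0 by default); all farther pairs are included at full weight.
    """
    adj = [[] for _ in range(n_atoms)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    # BFS bond-path distance, capped at 4 (anything >= 4 behaves the same)
    dist = np.full((n_atoms, n_atoms), 99, dtype=int)
    for start in range(n_atoms):
        dist[start, start] = 0
        frontier = [start]
        for d in range(1, 4):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[start, v] > d:
                        dist[start, v] = d
                        nxt.append(v)
            frontier = nxt
    ii, jj, ww = [], [], []
    for i in range(n_atoms):
        for j in range(i + 1, n_atoms):
            d = dist[i, j]
            if d <= 2:
                continue
            ii.append(i)
            jj.append(j)
            ww.append(scale14 if d == 3 else 1.0)
    return np.array(ii), np.array(jj), np.array(ww)


def _pair_parameters(
    elements: list[str],
    i_idx: np.ndarray,
    j_idx: np.ndarray,
    p: LJParamSet,
    combining: str,
) -> tuple[np.ndarray, np.ndarray]:
    sigma = np.array([p.sigma_C if e == "C" else p.sigma_H for e in elements])
    eps = np.array([p.eps_C if e == "C" else p.eps_H for e in elements])
    if combining == "lorentz_berthelot":
        sig_ij = 0.5 * (sigma[i_idx] + sigma[j_idx])
    elif combining == "geometric":
        sig_ij = np.sqrt(sigma[i_idx] * sigma[j_idx])
    else:
        raise ContractError(f"unknown combining rule {combining!r}")
    eps_ij = np.sqrt(eps[i_idx] * eps[j_idx])
    return sig_ij, eps_ij


def rce(
    p: LJParamSet,
    conf: ConformerSet,
    combining: str = "lorentz_berthelot",
    scale14: float = 1.0,
) -> np.ndarray:
    """Relative conformational energies under parameter set ``p``, kJ/mol.

    Per-conformer energy = bonded offset + sum of intramolecular Lennard-Jones
    pair energies (1-2/1-3 excluded, optional 1-4 scaling, Lorentz-Berthelot
    combination by default).  The returned vector is referenced to the
    designated conformer, whose entry is exactly 0.
    """
    i_idx, j_idx, w = _bond_path_weights(conf.n_atoms, conf.bonds, scale14)
    sig_ij, eps_ij = _pair_parameters(conf.elements, i_idx, j_idx, p, combining)
    diff = conf.coords[:, i_idx, :] - conf.coords[:, j_idx, :]
    r = np.linalg.norm(diff, axis=2)  # (n_conf, n_pairs)
    if np.any(r <= 0):
        raise ContractError("coincident atoms in a conformer")
    x6 = (sig_ij / r) ** 6
    energies = (w * 4.0 * eps_ij * (x6 * x6 - x6)).sum(axis=1) + conf.bonded_offsets
    out = energies - energies[conf.reference_index]
    out[conf.reference_index] = 0.0
    return out


# ---------------------------------------------------------------------------
# geometry construction


def _place_atom(a, b, c, r, theta, phi):
    """Position a fourth atom from three predecessors and internal coordinates.

    ``r``: bond length to ``c``; ``theta``: angle b-c-new; ``phi``: dihedral
    a-b-c-new (radians).  Standard natural-extension-of-reference-frame step.
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(phi), r * math.sin(theta) * math.sin(phi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _octane_topology() -> tuple[list[str], list[tuple[int, int]]]:
    """C8H18 atom ordering: carbons 0-7, then hydrogens carbon by carbon."""
    elements = ["C"] * 8
    bonds = [(i, i + 1) for i in range(7)]
    h_index = 8
    h_of: list[list[int]] = []
    for c in range(8):
        n_h = 3 if c in (0, 7) else 2
        mine = []
        for _ in range(n_h):
            elements.append("H")
            bonds.append((c, h_index))
            mine.append(h_index)
            h_index += 1
        h_of.append(mine)
    return elements, bonds


def _build_octane(dihedrals_deg: tuple[float, ...]) -> np.ndarray:
    """Cartesian coordinates (26, 3) of one octane conformer.

    ``dihedrals_deg``: the 5 backbone C-C-C-C dihedrals (C0..C3 ... C4..C7).
    """
    if len(dihedrals_deg) != 5:
        raise ContractError("octane needs exactly 5 backbone dihedrals")
    carbons = np.zeros((8, 3))
    carbons[1] = [R_CC, 0.0, 0.0]
    carbons[2] = carbons[1] + R_CC * np.array(
        [math.cos(math.pi - ANGLE_CCC), math.sin(math.pi - ANGLE_CCC), 0.0]
    )
    for i in range(3, 8):
        phi = math.radians(dihedrals_deg[i - 3])
        carbons[i] = _place_atom(
            carbons[i - 3], carbons[i - 2], carbons[i - 1], R_CC, ANGLE_CCC, phi
        )

    coords = [carbons[i] for i in range(8)]
    half = 0.5 * ANGLE_HCH
    for c in range(8):
        if c in (0, 7):
            # terminal methyl: three staggered hydrogens defined by a dihedral
            # relative to the second-nearest backbone carbon
            nb = 1 if c == 0 else 6
            ref = 2 if c == 0 else 5
            for phi_deg in (60.0, 180.0, 300.0):
                coords.append(
                    _place_atom(
                        carbons[ref], carbons[nb], carbons[c], R_CH, ANGLE_HCC,
                        math.radians(phi_deg),
                    )
                )
        else:
            # methylene: two hydrogens flanking the C-C-C bisector plane
            b1 = carbons[c - 1] - carbons[c]
            b2 = carbons[c + 1] - carbons[c]
            b1 /= np.linalg.norm(b1)
            b2 /= np.linalg.norm(b2)
            u = -(b1 + b2)
            u /= np.linalg.norm(u)
            w = np.cross(b1, b2)
            w /= np.linalg.norm(w)
            for sign in (+1.0, -1.0):
                coords.append(
                    carbons[c] + R_CH * (u * math.cos(half) + sign * w * math.sin(half))
                )
    return np.array(coords)


def make_conformer_fixture(
    n_conformers: int = 97,
    seed: int = 0,
    true_params: LJParamSet = DEFAULT_TRUE_PARAMS,
) -> ConformerSet:
    """Seeded octane conformer set with self-consistent target RCEs.

    The reference conformer is all-trans; the remaining conformers draw
    distinct backbone dihedral combinations from {trans, gauche+, gauche-}^5.
    Each conformer carries a fixed bonded-energy offset (a gauche increment
    plus small seeded variation); targets are the RCEs evaluated at
    ``true_params``, so that parameter set reproduces the targets exactly.
    The default of 97 conformers yields 96 nonreference relative energies.
    """
    if n_conformers < 1:
        raise ContractError(f"need at least 1 conformer, got {n_conformers}")

    def clash_free(combo: tuple[float, ...]) -> bool:
        # adjacent opposite-sign gauche dihedrals fold the chain onto itself
        # (syn-pentane clash); exclude them to keep energies physical
        return not any(
            a * b < 0 and abs(a) < 90.0 and abs(b) < 90.0
            for a, b in zip(combo, combo[1:])
        )

    choices = [c for c in itertools.product((180.0, 60.0, -60.0), repeat=5)
               if c != (180.0,) * 5 and clash_free(c)]
    if n_conformers - 1 > len(choices):
        raise ContractError(
            f"at most {len(choices) + 1} distinct octane conformers available"
        )
    rng = np.random.default_rng(seed)
    picked = [(180.0,) * 5]
    if n_conformers > 1:
        idx = rng.choice(len(choices), size=n_conformers - 1, replace=False)
        picked += [choices[i] for i in idx]

    elements, bonds = _octane_topology()
    coords = np.array([_build_octane(d) for d in picked])
    n_gauche = np.array([sum(1 for x in d if abs(x) < 90.0) for d in picked])
    offsets = GAUCHE_OFFSET * n_gauche + rng.normal(0.0, 0.3, size=n_conformers)

    conf = ConformerSet(
        coords=coords,
        elements=elements,
        bonds=bonds,
        bonded_offsets=offsets,
        reference_index=0,
    )
    conf.target_rce = rce(true_params, conf)
    return conf


def write_conformers(path: str | Path, conf: ConformerSet) -> None:
    """Serialize as concatenated XYZ blocks plus a sidecar target table."""
    path = Path(path)
    with open(path, "w") as fh:
        for k in range(conf.n_conformers):
            fh.write(f"{conf.n_atoms}\n")
            fh.write(f"conformer {k}\n")
            for e, (x, y, z) in zip(conf.elements, conf.coords[k]):
                fh.write(f"{e} {x:.9f} {y:.9f} {z:.9f}\n")
    side = path.with_suffix(".targets.csv")
    with open(side, "w") as fh:
        fh.write("conformer,bonded_offset,target_rce\n")
        targets = conf.target_rce if conf.target_rce is not None else np.zeros(conf.n_conformers)
        for k in range(conf.n_conformers):
            fh.write(f"{k},{conf.bonded_offsets[k]:.9f},{targets[k]:.9f}\n")
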