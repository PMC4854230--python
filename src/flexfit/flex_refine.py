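"""Refinement engine: stereochemical restraints, the combined
density + stereochemistry objective, capped-step simulated-annealing
optimization of rigid bodies and atoms, the hierarchical protocol, and
SMOC-ranked loop-ensemble refinement.

Energy model
------------
total = w_em * (1 - CCC(EM, simulated model density)) + stereochemistry

with harmonic stereochemical terms in the convention E = k * delta^2
(no 1/2 factor): bonds, angles and improper dihedrals anchored at the
values in the input structure with force constants from a packaged table
of typical covalent values; a flat-bottom Ramachandran basin penalty on
(phi, psi); and a one-sided (lower-bound) non-bonded term
E = k * max(0, bound - d)^2 with bound = scaled sum of van der Waals radii
and k = 400 kcal/mol/A^2.

The optimizer displaces rigid bodies (translation + rotation about the
body centroid) and free atoms down the objective gradient with per-DOF
sign-adaptive step sizes, Gaussian noise scaled by a 0K -> T_max -> 0K
temperature schedule, and a hard per-step per-axis displacement cap per
stage. Runs are deterministic for a fixed seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geometry import place_atom, rotvec_matrix
from .core_model import (ModelStructure, ResidueRange, ResidueSegment,
                         RigidBodyScheme, SSEAnnotation)
from .density_ops import (SIGMA_PER_RESOLUTION, DensityGrid,
                          accumulate_gaussians, _atom_weights, global_ccc,
                          simulate_density)
from .local_fit import SMOCProfile, segment_voxels, smoc_profile, smoc_segment
from .rigid_bodies import backbone_dihedrals, scheme_for_level

# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def load_covalent_params() -> dict:
    """The packaged table of typical covalent force constants and radii."""
    text = (resources.files("flexfit") / "data" / "covalent_params.json"
            ).read_text()
    return json.loads(text)


# Ramachandran basins, degrees: (phi_lo, phi_hi, psi_lo, psi_hi); psi
# intervals may extend past 180 (wrapped on the circle).
RAMA_BASINS = (
    (-160.0, -20.0, -120.0, 45.0),   # alpha-R (incl. 3-10)
    (-180.0, -45.0, 90.0, 210.0),    # beta / PPII (psi wraps through 180)
    (20.0, 100.0, -50.0, 100.0),     # alpha-L
)


def _interval_offset(angle: float, lo: float, hi: float) -> float:
    """Signed angular offset (deg) from the wrapped interval [lo, hi].

    0 inside; positive when the shortest exit is past ``hi``; negative when
    past ``lo``.
    """
    a = lo + (angle - lo) % 360.0
    if a <= hi:
        return 0.0
    over = a - hi
    under = lo + 360.0 - a
    return over if over <= under else -under


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

_BOND_MAX = 1.75   # Å, generic heavy-atom covalent bond detection
_BOND_MAX_S = 2.1  # Å, bonds involving sulfur/phosphorus
_BOND_MAX_H = 1.3


def _detect_bonds(structure: ModelStructure) -> list[tuple[int, int]]:
    """Covalent bonds: within-residue by distance, peptide C-N between
    consecutive residues of a chain."""
    bonds: list[tuple[int, int]] = []
    coords = structure.coords()
    for key in structure.residue_keys():
        idx = structure.residue_atom_indices(key)
        for ii, i in enumerate(idx):
            for j in idx[ii + 1:]:
                ei = structure.atoms[i].element
                ej = structure.atoms[j].element
                d = np.linalg.norm(coords[i] - coords[j])
                if "H" in (ei, ej):
                    limit = _BOND_MAX_H
                elif ei in ("S", "P") or ej in ("S", "P"):
                    limit = _BOND_MAX_S
                else:
                    limit = _BOND_MAX
                if d <= limit:
                    bonds.append((int(i), int(j)))
    # peptide bonds
    for chain in structure.chains():
        res = structure.chain_residues(chain)
        for a, b in zip(res, res[1:]):
            if b[1] != a[1] + 1:
                continue
            try:
                c = structure.atom(chain, a[1], "C", a[2])
                n = structure.atom(chain, b[1], "N", b[2])
            except KeyError:
                continue
            if np.linalg.norm(c.position - n.position) <= 2.0:
                bonds.append((structure.atoms.index(c),
                              structure.atoms.index(n)))
    # every heavy atom in a multi-atom residue must be bonded to something
    bonded = {i for b in bonds for i in b}
    for key in structure.residue_keys():
        idx = structure.residue_atom_indices(key)
        if len(idx) < 2:
            continue
        for i in idx:
            if int(i) not in bonded:
                a = structure.atoms[i]
                raise ValueError(
                    f"cannot build topology: atom {a.name} of "
                    f"{a.res_name} {a.chain_id}:{a.res_seq} has no covalent "
                    "neighbor")
    return bonds


def _graph_exclusions(n_atoms: int, bonds: list[tuple[int, int]],
                      max_sep: int = 4) -> set[int]:
    """Atom pairs within ``max_sep`` bonds, as packed i*n+j keys (i<j)."""
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    excluded: set[int] = set()
    for start in range(n_atoms):
        depth = {start: 0}
        frontier = [start]
        for d in range(1, max_sep + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in depth:
                        depth[v] = d
                        nxt.append(v)
            frontier = nxt
        for v, d in depth.items():
            if v > start:
                excluded.add(start * n_atoms + v)
    return excluded


# ---------------------------------------------------------------------------
# vectorized geometry kernels (value + gradient)
# ---------------------------------------------------------------------------


def _bond_values(coords, idx):
    v = coords[idx[:, 0]] - coords[idx[:, 1]]
    return np.linalg.norm(v, axis=1)


def _angle_values_grads(coords, idx, want_grad=True):
    p0, p1, p2 = (coords[idx[:, k]] for k in range(3))
    u = p0 - p1
    v = p2 - p1
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos = np.einsum("ij,ij->i", u, v) / (nu * nv)
    cos = np.clip(cos, -1.0, 1.0)
    theta = np.arccos(cos)
    if not want_grad:
        return theta, None
    sin = np.sqrt(np.clip(1.0 - cos * cos, 1e-12, None))
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    g0 = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
    g2 = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
    g1 = -(g0 + g2)
    return theta, (g0, g1, g2)


def _dihedral_values_grads(coords, idx, want_grad=True):
    """Dihedral angles (radians, signed) and per-point gradients."""
    p0, p1, p2, p3 = (coords[idx[:, k]] for k in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / nb2[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = np.arctan2(y, x)
    if not want_grad:
        return phi, None
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    n1sq = np.clip(n1sq, 1e-12, None)
    n2sq = np.clip(n2sq, 1e-12, None)
    g0 = (nb2 / n1sq)[:, None] * n1
    g3 = -(nb2 / n2sq)[:, None] * n2
    p = np.einsum("ij,ij->i", b1, b2) / (nb2 * nb2)
    q = np.einsum("ij,ij->i", b3, b2) / (nb2 * nb2)
    g1 = -(1.0 + p)[:, None] * g0 + q[:, None] * g3
    g2 = p[:, None] * g0 - (1.0 + q)[:, None] * g3
    return phi, (g0, g1, g2, g3)


def _wrap_rad(x):
    return (x + np.pi) % (2.0 * np.pi) - np.pi


# ---------------------------------------------------------------------------
# RestraintSet
# ---------------------------------------------------------------------------


@dataclass
class RestraintSet:
    """Harmonic stereochemical terms anchored at a reference conformation.

    All harmonic terms use E = k * delta^2. Angles and dihedrals are in
    radians internally; k_angle/k_improper/k_rama are per rad^2.
    """
    n_atoms: int
    bond_idx: np.ndarray     # (nb, 2)
    bond_mean: np.ndarray    # Å
    bond_k: np.ndarray
    angle_idx: np.ndarray    # (na, 3)
    angle_mean: np.ndarray   # rad
    angle_k: np.ndarray
    improper_idx: np.ndarray  # (ni, 4)
    improper_mean: np.ndarray  # rad
    improper_k: np.ndarray
    phi_idx: np.ndarray      # (nr, 4) quadruples for phi (may be empty)
    psi_idx: np.ndarray      # (nr, 4)
    rama_k: float
    nb_k: float
    nb_bound: np.ndarray     # per-atom scaled vdW radius (Å)
    nb_excluded: set[int]    # packed i*n+j keys
    nb_cutoff: float

    # -- evaluation -------------------------------------------------------

    def energy(self, coords: np.ndarray) -> tuple[float, dict[str, float]]:
        comps = {}
        d = _bond_values(coords, self.bond_idx) if len(self.bond_idx) else np.zeros(0)
        comps["bonds"] = float(np.sum(self.bond_k * (d - self.bond_mean) ** 2))
        if len(self.angle_idx):
            th, _ = _angle_values_grads(coords, self.angle_idx, want_grad=False)
            comps["angles"] = float(np.sum(self.angle_k
                                           * (th - self.angle_mean) ** 2))
        else:
            comps["angles"] = 0.0
        comps["impropers"] = self._dihedral_energy(
            coords, self.improper_idx, self.improper_mean, self.improper_k)
        comps["ramachandran"] = self._rama_energy(coords)
        comps["nonbonded"] = self._nonbonded(coords)[0]
        return sum(comps.values()), comps

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        grad = np.zeros_like(coords)
        if len(self.bond_idx):
            v = coords[self.bond_idx[:, 0]] - coords[self.bond_idx[:, 1]]
            d = np.linalg.norm(v, axis=1)
            f = (2.0 * self.bond_k * (d - self.bond_mean) / d)[:, None] * v
            np.add.at(grad, self.bond_idx[:, 0], f)
            np.add.at(grad, self.bond_idx[:, 1], -f)
        if len(self.angle_idx):
            th, gs = _angle_values_grads(coords, self.angle_idx)
            pref = 2.0 * self.angle_k * (th - self.angle_mean)
            for k in range(3):
                np.add.at(grad, self.angle_idx[:, k], pref[:, None] * gs[k])
        self._dihedral_grad(grad, coords, self.improper_idx,
                            self.improper_mean, self.improper_k)
        self._rama_grad(grad, coords)
        self._nonbonded(coords, grad=grad)
        return grad

    # -- term helpers -----------------------------------------------------

    def _dihedral_energy(self, coords, idx, mean, k) -> float:
        if not len(idx):
            return 0.0
        phi, _ = _dihedral_values_grads(coords, idx, want_grad=False)
        return float(np.sum(k * _wrap_rad(phi - mean) ** 2))

    def _dihedral_grad(self, grad, coords, idx, mean, k) -> None:
        if not len(idx):
            return
        phi, gs = _dihedral_values_grads(coords, idx)
        pref = 2.0 * k * _wrap_rad(phi - mean)
        for kk in range(4):
            np.add.at(grad, idx[:, kk], pref[:, None] * gs[kk])

    def _rama_offsets(self, coords, want_grad=True):
        if not len(self.phi_idx):
            return None
        phi, gphi = _dihedral_values_grads(coords, self.phi_idx, want_grad)
        psi, gpsi = _dihedral_values_grads(coords, self.psi_idx, want_grad)
        phi_d = np.degrees(phi)
        psi_d = np.degrees(psi)
        off_phi = np.zeros(len(phi))
        off_psi = np.zeros(len(psi))
        for i in range(len(phi)):
            best = None
            for plo, phi_hi, slo, shi in RAMA_BASINS:
                dp = _interval_offset(phi_d[i], plo, phi_hi)
                ds = _interval_offset(psi_d[i], slo, shi)
                dist2 = dp * dp + ds * ds
                if best is None or dist2 < best[0]:
                    best = (dist2, dp, ds)
            off_phi[i] = best[1]
            off_psi[i] = best[2]
        return np.radians(off_phi), np.radians(off_psi), gphi, gpsi

    def _rama_energy(self, coords) -> float:
        res = self._rama_offsets(coords, want_grad=False)
        if res is None:
            return 0.0
        off_phi, off_psi, _, _ = res
        return float(self.rama_k * np.sum(off_phi ** 2 + off_psi ** 2))

    def _rama_grad(self, grad, coords) -> None:
        res = self._rama_offsets(coords)
        if res is None:
            return
        off_phi, off_psi, gphi, gpsi = res
        pref_phi = 2.0 * self.rama_k * off_phi
        pref_psi = 2.0 * self.rama_k * off_psi
        for kk in range(4):
            np.add.at(grad, self.phi_idx[:, kk], pref_phi[:, None] * gphi[kk])
            np.add.at(grad, self.psi_idx[:, kk], pref_psi[:, None] * gpsi[kk])

    def _nonbonded(self, coords, grad=None) -> tuple[float, None]:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(r=self.nb_cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return 0.0, None
        n = self.n_atoms
        keys = pairs[:, 0] * n + pairs[:, 1]
        keep = np.array([k not in self.nb_excluded for k in keys])
        pairs = pairs[keep]
        if len(pairs) == 0:
            return 0.0, None
        v = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        d = np.linalg.norm(v, axis=1)
        bound = self.nb_bound[pairs[:, 0]] + self.nb_bound[pairs[:, 1]]
        gap = bound - d
        viol = gap > 0
        e = float(np.sum(self.nb_k * gap[viol] ** 2))
        if grad is not None and np.any(viol):
            pv = pairs[viol]
            f = (-2.0 * self.nb_k * gap[viol] / d[viol])[:, None] * v[viol]
            np.add.at(grad, pv[:, 0], f)
            np.add.at(grad, pv[:, 1], -f)
        return e, None


def _bond_k_for(params: dict, ea: str, eb: str) -> float:
    table = params["bond_k"]
    key = "-".join(sorted([ea, eb]))
    return float(table.get(key, table["default"]))


def build_restraints(structure: ModelStructure,
                     params: dict | None = None) -> RestraintSet:
    """Restraints anchored at the current conformation of ``structure``.

    Bond, angle and improper means are measured from the input, so the
    input structure has zero energy in those terms; the Ramachandran and
    non-bonded terms are absolute (basin membership / vdW lower bounds).
    """
    params = params or load_covalent_params()
    coords = structure.coords()
    n = len(structure)
    bonds = _detect_bonds(structure)
    bond_idx = np.array(bonds, dtype=int).reshape(-1, 2)
    bond_mean = _bond_values(coords, bond_idx) if len(bonds) else np.zeros(0)
    bond_k = np.array([
        _bond_k_for(params, structure.atoms[i].element,
                    structure.atoms[j].element) for i, j in bonds])
    # angles from shared-atom bond pairs
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    angle_triples = []
    for center in range(n):
        nbrs = sorted(adj[center])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                angle_triples.append((nbrs[a], center, nbrs[b]))
    angle_idx = np.array(angle_triples, dtype=int).reshape(-1, 3)
    angle_mean, _ = (_angle_values_grads(coords, angle_idx, want_grad=False)
                     if len(angle_triples) else (np.zeros(0), None))
    angle_k = np.full(len(angle_triples), float(params["angle_k"]["default"]))
    # impropers: peptide omega, carbonyl planarity, Calpha chirality
    impropers = []
    atom_of = {}
    for i, a in enumerate(structure.atoms):
        atom_of[(a.chain_id, a.res_seq, a.insertion_code, a.name)] = i
    for chain in structure.chains():
        res = structure.chain_residues(chain)
        for k_res, key in enumerate(res):
            c, r, ic = key

            def gi(name, rk=key):
                return atom_of.get((rk[0], rk[1], rk[2], name))

            n_i, ca_i, c_i, o_i, cb_i = (gi(x) for x in
                                         ("N", "CA", "C", "O", "CB"))
            nxt = res[k_res + 1] if (k_res + 1 < len(res)
                                     and res[k_res + 1][1] == r + 1) else None
            if nxt is not None:
                n_next = atom_of.get((nxt[0], nxt[1], nxt[2], "N"))
                ca_next = atom_of.get((nxt[0], nxt[1], nxt[2], "CA"))
                if None not in (ca_i, c_i, n_next, ca_next):
                    impropers.append((ca_i, c_i, n_next, ca_next))  # omega
                if None not in (n_next, ca_i, c_i, o_i):
                    impropers.append((n_next, ca_i, c_i, o_i))  # C=O plane
            if None not in (n_i, c_i, ca_i, cb_i):
                impropers.append((n_i, c_i, ca_i, cb_i))  # chirality
    improper_idx = np.array(impropers, dtype=int).reshape(-1, 4)
    improper_mean, _ = (_dihedral_values_grads(coords, improper_idx,
                                               want_grad=False)
                        if len(impropers) else (np.zeros(0), None))
    improper_k = np.full(len(impropers), float(params["improper_k"]["default"]))
    # Ramachandran quadruples
    phi_quads, psi_quads = [], []
    for chain in structure.chains():
        res = structure.chain_residues(chain)
        for k_res, key in enumerate(res):
            prv = res[k_res - 1] if (k_res > 0
                                     and res[k_res - 1][1] == key[1] - 1) else None
            nxt = res[k_res + 1] if (k_res + 1 < len(res)
                                     and res[k_res + 1][1] == key[1] + 1) else None
            if prv is None or nxt is None:
                continue
            names = {}
            for rk, nm, tag in ((prv, "C", "c_prev"), (key, "N", "n"),
                                (key, "CA", "ca"), (key, "C", "c"),
                                (nxt, "N", "n_next")):
                names[tag] = atom_of.get((rk[0], rk[1], rk[2], nm))
            if None in names.values():
                continue
            phi_quads.append((names["c_prev"], names["n"], names["ca"],
                              names["c"]))
            psi_quads.append((names["n"], names["ca"], names["c"],
                              names["n_next"]))
    phi_idx = np.array(phi_quads, dtype=int).reshape(-1, 4)
    psi_idx = np.array(psi_quads, dtype=int).reshape(-1, 4)
    # nonbonded
    radii = params["vdw_radii"]
    scale = float(params["vdw_scale"])
    nb_bound = np.array([scale * float(radii.get(a.element, radii["default"]))
                         for a in structure.atoms])
    excluded = _graph_exclusions(n, bonds)
    return RestraintSet(
        n_atoms=n,
        bond_idx=bond_idx, bond_mean=bond_mean, bond_k=bond_k,
        angle_idx=angle_idx, angle_mean=angle_mean, angle_k=angle_k,
        improper_idx=improper_idx, improper_mean=improper_mean,
        improper_k=improper_k,
        phi_idx=phi_idx, psi_idx=psi_idx,
        rama_k=float(params["ramachandran_k"]),
        nb_k=float(params["nonbonded_k"]),
        nb_bound=nb_bound,
        nb_excluded=excluded,
        nb_cutoff=float(2.0 * nb_bound.max()),
    )


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def _density_term(coords: np.ndarray, weights: np.ndarray, em: DensityGrid,
                  sigma: float, w_em: float, want_grad: bool = True
                  ) -> tuple[float, np.ndarray | None, float]:
    """w_em * (1 - CCC) and its analytic gradient w.r.t. atom positions.

    Returns (value, grad, ccc). The gradient flows through the Gaussian
    model density: dCCC/dp_v = e'_v / sqrt(See*Spp) - CCC * p'_v / Spp.
    """
    sim = em.copy_geometry()
    accumulate_gaussians(sim, coords, weights, sigma, warn_clipped=False)
    p = sim.values
    e = em.values
    ep = e - e.mean()
    pp = p - p.mean()
    see = float(np.sum(ep * ep))
    spp = float(np.sum(pp * pp))
    if see <= 0 or spp <= 0:
        raise ValueError("zero variance in density (model outside map?)")
    sep = float(np.sum(ep * pp))
    ccc = sep / np.sqrt(see * spp)
    value = w_em * (1.0 - ccc)
    if not want_grad:
        return value, None, ccc
    gfield = ep / np.sqrt(see * spp) - ccc * pp / spp
    grad = np.zeros_like(coords)
    nz, ny, nx = em.values.shape
    dims = np.array([nx, ny, nz])
    from .density_ops import TRUNCATION_SIGMAS
    half = TRUNCATION_SIGMAS * sigma
    inv_s2 = 1.0 / (sigma * sigma)
    axes_1d = [em.origin[d] + em.spacing[d] * np.arange(dims[d])
               for d in range(3)]
    for a, (pos, w) in enumerate(zip(coords, weights)):
        lo = np.maximum(np.ceil((pos - half - em.origin) / em.spacing
                                ).astype(int), 0)
        hi = np.minimum(np.floor((pos + half - em.origin) / em.spacing
                                 ).astype(int), dims - 1)
        if np.any(lo > hi):
            continue
        dx = axes_1d[0][lo[0]:hi[0] + 1] - pos[0]
        dy = axes_1d[1][lo[1]:hi[1] + 1] - pos[1]
        dz = axes_1d[2][lo[2]:hi[2] + 1] - pos[2]
        gx = np.exp(-0.5 * dx * dx * inv_s2)
        gy = np.exp(-0.5 * dy * dy * inv_s2)
        gz = np.exp(-0.5 * dz * dz * inv_s2)
        gauss = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        gf = gfield[lo[2]:hi[2] + 1, lo[1]:hi[1] + 1, lo[0]:hi[0] + 1]
        common = gf * gauss
        # dp_v/dx_a = w * gauss * (r_v - x_a) / sigma^2
        grad[a, 0] = np.sum(common * dx[None, None, :])
        grad[a, 1] = np.sum(common * dy[None, :, None])
        grad[a, 2] = np.sum(common * dz[:, None, None])
        grad[a] *= -w_em * w * inv_s2
    return value, grad, ccc


def objective(structure: ModelStructure | np.ndarray, em: DensityGrid,
              restraints: RestraintSet, w_em: float = 1.0,
              resolution: float | None = None,
              weights: np.ndarray | None = None
              ) -> tuple[float, dict[str, float]]:
    """Combined objective: w_em*(1 - CCC) + stereochemical energy.

    Accepts a ModelStructure or a raw coordinate array (with ``weights``).
    """
    if isinstance(structure, ModelStructure):
        coords = structure.coords()
        weights = _atom_weights(structure)
    else:
        coords = structure
        if weights is None:
            raise ValueError("weights required with raw coordinates")
    resolution = resolution or em.resolution_hint
    if resolution is None:
        raise ValueError("resolution not given and no resolution_hint on map")
    sigma = SIGMA_PER_RESOLUTION * resolution
    dens, _, ccc = _density_term(coords, weights, em, sigma, w_em,
                                 want_grad=False)
    stereo, comps = restraints.energy(coords)
    comps = {"density": dens, "ccc": ccc, **comps}
    return dens + stereo, comps


# ---------------------------------------------------------------------------
# annealing
# ---------------------------------------------------------------------------


@dataclass
class AnnealConfig:
    """Schedule and step-cap parameters for one annealing run.

    max_step is the hard per-step per-axis displacement cap in Å (0.39 for
    the large-rigid-body stage; the hierarchical protocol lowers it to 0.15
    at the SSE stage and 0.1 for all-atom refinement). The temperature ramps
    0K -> t_max -> 0K within each cycle and scales only the exploration
    noise; cycles stop early once the cycle-to-cycle CCC gain drops below
    ccc_tol.

    w_em rescales the dimensionless density term 1 - CCC onto the kcal/mol
    scale of the stereochemical restraints; the default 1e4 makes density
    forces comparable to moderate covalent-term gradients, so the fit
    improves without distorting anchored geometry.
    """
    t_max: float = 1000.0
    steps_per_leg: int = 200
    max_step: float = 0.39
    w_em: float = 1.0e4
    cycles: int = 5
    ccc_tol: float = 1e-4
    seed: int = 0
    noise_scale: float = 0.05
    stage_caps: dict = field(default_factory=lambda: {
        "ribfind_clusters": 0.39, "sse": 0.15, "all_atom": 0.1})

    def __post_init__(self):
        if self.max_step <= 0:
            raise ValueError("max_step must be > 0")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")
        if self.ccc_tol < 0:
            raise ValueError("ccc_tol must be >= 0")


@dataclass
class RefinementTrace:
    """Per-cycle CCC, per-stage SMOC profiles, per-step displacement log."""
    ccc_by_cycle: list = field(default_factory=list)  # (stage, cycle, ccc)
    smoc_profiles: list = field(default_factory=list)
    max_step_log: list = field(default_factory=list)  # (stage, max |dx|)

    def ccc_values(self, stage: str | None = None) -> list[float]:
        return [c for s, _, c in self.ccc_by_cycle
                if stage is None or s == stage]

    def max_steps(self, stage: str | None = None) -> list[float]:
        return [m for s, m in self.max_step_log
                if stage is None or s == stage]

    def extend(self, other: "RefinementTrace") -> None:
        self.ccc_by_cycle.extend(other.ccc_by_cycle)
        self.smoc_profiles.extend(other.smoc_profiles)
        self.max_step_log.extend(other.max_step_log)

    def to_json(self, path: str) -> None:
        doc = {
            "ccc_by_cycle": [
                {"stage": s, "cycle": c, "ccc": v}
                for s, c, v in self.ccc_by_cycle],
            "max_step_per_stage": {
                s: max(self.max_steps(s)) for s, _ in self.max_step_log},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


_RPROP_UP = 1.2
_RPROP_DOWN = 0.5
_RPROP_INIT = 0.1   # x cap
_RPROP_MIN = 1e-4   # x cap


class _RpropState:
    """Per-DOF sign-adaptive step sizes (iRprop- update rule)."""

    def __init__(self, n: int, cap: np.ndarray):
        self.cap = cap
        self.step = _RPROP_INIT * cap.copy()
        self.prev_sign = np.zeros(n)

    def delta(self, grad: np.ndarray) -> np.ndarray:
        sign = np.sign(grad)
        same = sign * self.prev_sign
        self.step = np.where(same > 0, np.minimum(self.step * _RPROP_UP,
                                                  self.cap), self.step)
        self.step = np.where(same < 0, np.maximum(self.step * _RPROP_DOWN,
                                                  _RPROP_MIN * self.cap),
                             self.step)
        move_sign = np.where(same < 0, 0.0, sign)  # skip after sign flip
        self.prev_sign = np.where(same < 0, 0.0, sign)
        return -move_sign * self.step


def anneal(structure: ModelStructure, em: DensityGrid,
           scheme: RigidBodyScheme, restraints: RestraintSet,
           config: AnnealConfig, resolution: float | None = None,
           stage_label: str | None = None
           ) -> tuple[ModelStructure, RefinementTrace]:
    """Capped-step simulated annealing of rigid bodies and free atoms.

    Rigid bodies move as units (translation + rotation about the body
    centroid); atoms outside every body move individually. Forces are the
    negative gradient of the combined objective; the per-step per-axis
    displacement of every atom is clipped to config.max_step. Bit-identical
    outputs for identical inputs and seed.
    """
    resolution = resolution or em.resolution_hint
    if resolution is None:
        raise ValueError("resolution not given and no resolution_hint on map")
    scheme.validate(structure)
    stage = stage_label or scheme.level
    coords = structure.coords().copy()
    weights = _atom_weights(structure)
    sigma = SIGMA_PER_RESOLUTION * resolution
    cap = config.max_step
    rng = np.random.default_rng(config.seed)
    trace = RefinementTrace()

    body_idx = scheme.body_atom_indices(structure)
    in_body = np.zeros(len(coords), dtype=bool)
    for idx in body_idx:
        in_body[idx] = True
    free_idx = np.where(~in_body)[0]

    n_body_dof = 6 * len(body_idx)
    body_radius = np.array([
        max(1.0, np.max(np.linalg.norm(
            coords[idx] - coords[idx].mean(axis=0), axis=1)))
        for idx in body_idx]) if body_idx else np.zeros(0)
    body_cap = np.concatenate([
        np.concatenate([np.full(3, cap), np.full(3, cap / r)])
        for r in body_radius]) if len(body_radius) else np.zeros(0)
    rp_body = _RpropState(n_body_dof, body_cap)
    free_cap = np.full(3 * len(free_idx), cap)
    rp_free = _RpropState(3 * len(free_idx), free_cap)

    half = config.steps_per_leg
    temps = np.concatenate([np.linspace(0.0, config.t_max, half,
                                        endpoint=False),
                            np.linspace(config.t_max, 0.0, half)])
    prev_ccc = None
    for cycle in range(config.cycles):
        for t in temps:
            _, dens_grad, _ = _density_term(coords, weights, em, sigma,
                                            config.w_em)
            grad = dens_grad + restraints.gradient(coords)
            if not np.all(np.isfinite(grad)):
                raise RuntimeError("non-finite force encountered")
            heat = t / config.t_max
            max_disp = 0.0
            # rigid bodies: 6 DOF each
            if body_idx:
                dof_grad = np.empty(n_body_dof)
                centroids = []
                for b, idx in enumerate(body_idx):
                    c = coords[idx].mean(axis=0)
                    centroids.append(c)
                    f = grad[idx].sum(axis=0)
                    torque = np.cross(coords[idx] - c, grad[idx]).sum(axis=0)
                    dof_grad[6 * b:6 * b + 3] = f
                    dof_grad[6 * b + 3:6 * b + 6] = torque
                delta = rp_body.delta(dof_grad)
                delta = delta + rng.normal(size=n_body_dof) * (
                    config.noise_scale * heat * rp_body.cap)
                for b, idx in enumerate(body_idx):
                    tvec = delta[6 * b:6 * b + 3]
                    rvec = delta[6 * b + 3:6 * b + 6]
                    c = centroids[b]
                    for _attempt in range(6):
                        rot = rotvec_matrix(rvec)
                        disp = (coords[idx] - c) @ rot.T + c + tvec - coords[idx]
                        m = float(np.abs(disp).max())
                        if m <= cap + 1e-12:
                            break
                        scale = cap / m
                        tvec = tvec * scale
                        rvec = rvec * scale
                    coords[idx] += disp
                    max_disp = max(max_disp, float(np.abs(disp).max()))
            # free atoms
            if len(free_idx):
                fg = grad[free_idx].ravel()
                delta = rp_free.delta(fg)
                delta = delta + rng.normal(size=len(delta)) * (
                    config.noise_scale * heat * cap)
                delta = np.clip(delta, -cap, cap)
                coords[free_idx] += delta.reshape(-1, 3)
                max_disp = max(max_disp, float(np.abs(delta).max()))
            trace.max_step_log.append((stage, max_disp))
        sim = em.copy_geometry()
        accumulate_gaussians(sim, coords, weights, sigma, warn_clipped=False)
        ccc = global_ccc(em, sim)
        trace.ccc_by_cycle.append((stage, cycle, ccc))
        if prev_ccc is not None and ccc - prev_ccc < config.ccc_tol:
            break
        prev_ccc = ccc
    return structure.with_coords(coords), trace


def freeze_interface(scheme: RigidBodyScheme,
                     segments: list[ResidueSegment]) -> RigidBodyScheme:
    """Add each segment as an extra rigid body (kept rigid even at the
    all-atom level), e.g. exposed interface loops whose atoms would
    otherwise over-fit into a neighboring component's density."""
    if not segments:
        return scheme
    bodies = [list(body) for body in scheme.bodies]
    for seg in segments:
        ranges = []
        run_start = seg.res_seqs[0]
        prev = run_start
        for r in seg.res_seqs[1:] + [None]:  # type: ignore[list-item]
            if r is not None and r == prev + 1:
                prev = r
                continue
            ranges.append(ResidueRange(seg.chain_id, run_start, prev))
            if r is not None:
                run_start = prev = r
        bodies.append(ranges)
    out = RigidBodyScheme(bodies, level=scheme.level)
    sets = out.body_residue_sets()
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            clash = sets[i] & sets[j]
            if clash:
                raise ValueError(
                    f"frozen segment overlaps rigid body on residues "
                    f"{sorted(clash)[:6]}")
    return out


def hierarchical_refine(structure: ModelStructure, em: DensityGrid,
                        sses: SSEAnnotation,
                        clusters: RigidBodyScheme | None,
                        config: AnnealConfig,
                        resolution: float | None = None,
                        frozen_segments: list[ResidueSegment] | None = None
                        ) -> tuple[ModelStructure, RefinementTrace]:
    """Three-stage protocol: cluster-level rigid bodies, then individual
    SSEs, then all atoms free, with stage displacement caps 0.39 / 0.15 /
    0.1 Å. When the model has no multi-SSE clusters the first stage is
    skipped and refinement starts at the SSE level. Restraints are
    re-anchored on the input of each stage; a SMOC profile is appended to
    the trace after every stage.
    """
    resolution = resolution or em.resolution_hint
    if resolution is None:
        raise ValueError("resolution not given and no resolution_hint on map")
    trace = RefinementTrace()
    if config.cycles <= 0:
        return structure, trace
    stages = []
    if clusters is not None and len(clusters.bodies) >= 2:
        stages.append("ribfind_clusters")
    stages += ["sse", "all_atom"]
    current = structure
    for k, level in enumerate(stages):
        scheme = scheme_for_level(sses, clusters, level)
        if frozen_segments:
            scheme = freeze_interface(scheme, frozen_segments)
        restraints = build_restraints(current)
        stage_cfg = AnnealConfig(
            t_max=config.t_max, steps_per_leg=config.steps_per_leg,
            max_step=config.stage_caps.get(level, config.max_step),
            w_em=config.w_em, cycles=config.cycles, ccc_tol=config.ccc_tol,
            seed=config.seed + k, noise_scale=config.noise_scale,
            stage_caps=config.stage_caps)
        current, stage_trace = anneal(current, em, scheme, restraints,
                                      stage_cfg, resolution,
                                      stage_label=level)
        trace.extend(stage_trace)
        trace.smoc_profiles.append(
            smoc_profile(em, current, sses, resolution, stage=level))
    return current, trace


# ---------------------------------------------------------------------------
# loop-ensemble refinement
# ---------------------------------------------------------------------------


def _loop_backbone_rebuild(structure: ModelStructure, loop: ResidueSegment,
                           phis: np.ndarray, psis: np.ndarray
                           ) -> tuple[np.ndarray, dict]:
    """Rebuild loop backbone (N, CA, C) with given torsions, ideal-ized from
    the current internal coordinates; returns coords for loop atoms plus
    rebuilt positions of the next residue's (N, CA, C) for closure checks."""
    chain = loop.chain_id
    lo, hi = loop.res_seqs[0], loop.res_seqs[-1]
    get = lambda r, n: structure.atom(chain, r, n).position

    # measured internal coordinates (lengths and angles kept from input)
    def length(p, q):
        return float(np.linalg.norm(p - q))

    prev = lo - 1
    nxt = hi + 1
    n_prev, ca_prev, c_prev = (get(prev, x) for x in ("N", "CA", "C"))
    out: dict[tuple[int, str], np.ndarray] = {}
    a, b, c = n_prev, ca_prev, c_prev
    res_list = list(range(lo, hi + 1)) + [nxt]
    for j, r in enumerate(res_list):
        is_anchor = r == nxt
        n_pos = place_atom(a, b, c, 1.329, 116.6,
                           psis[j - 1] if j > 0 else _psi_of(structure, chain,
                                                             prev))
        ca_pos = place_atom(b, c, n_pos, 1.458, 121.7, 180.0)
        phi = phis[j] if not is_anchor else _phi_target(structure, chain, nxt)
        c_pos = place_atom(c, n_pos, ca_pos, 1.525, 111.0, phi)
        out[(r, "N")] = n_pos
        out[(r, "CA")] = ca_pos
        out[(r, "C")] = c_pos
        a, b, c = n_pos, ca_pos, c_pos
    return out


def _psi_of(structure, chain, r):
    d = backbone_dihedrals(structure, chain)
    psi = d[r][1]
    return psi if psi is not None else 180.0


def _phi_target(structure, chain, r):
    d = backbone_dihedrals(structure, chain)
    phi = d[r][0]
    return phi if phi is not None else -120.0


def _ccd_close(out: dict, loop_res: list[int], targets: dict,
               chain_done: None = None, sweeps: int = 12) -> float:
    """Cyclic-coordinate-descent closure: rotate about loop phi/psi axes to
    bring the rebuilt next-residue (N, CA, C) onto their fixed targets.
    Returns the final anchor RMSD."""
    nxt = max(targets)[0]
    anchor_names = [(nxt, "N"), (nxt, "CA"), (nxt, "C")]

    def anchor_rmsd():
        return float(np.sqrt(np.mean([
            np.sum((out[k] - targets[k]) ** 2) for k in anchor_names])))

    moving_after: dict[tuple[int, str], list] = {}
    keys = sorted(out, key=lambda k: (k[0], ("N", "CA", "C").index(k[1])))
    for r in loop_res:
        for pivot in ("phi", "psi"):
            ax_from = (r, "N") if pivot == "phi" else (r, "CA")
            ax_to = (r, "CA") if pivot == "phi" else (r, "C")
            after = [k for k in keys if k > ax_to]
            moving_after[(r, pivot)] = (ax_from, ax_to, after)
    for _ in range(sweeps):
        for r in loop_res:
            for pivot in ("phi", "psi"):
                ax_from, ax_to, after = moving_after[(r, pivot)]
                o = out[ax_to]
                axis = out[ax_to] - out[ax_from]
                nrm = np.linalg.norm(axis)
                if nrm < 1e-9:
                    continue
                axis = axis / nrm
                num = 0.0
                den = 0.0
                for k in anchor_names:
                    m = out[k] - o
                    tvec = targets[k] - o
                    m_perp = m - np.dot(m, axis) * axis
                    t_perp = tvec - np.dot(tvec, axis) * axis
                    num += float(np.dot(np.cross(m_perp, t_perp), axis))
                    den += float(np.dot(m_perp, t_perp))
                theta = np.arctan2(num, den)
                if abs(theta) < 1e-10:
                    continue
                rot = rotvec_matrix(axis * theta)
                for k in after:
                    out[k] = (out[k] - o) @ rot.T + o
        if anchor_rmsd() < 1e-3:
            break
    return anchor_rmsd()


def sample_loop_conformation(structure: ModelStructure, loop: ResidueSegment,
                             amplitude: float, rng: np.random.Generator,
                             closure_tol: float = 0.5
                             ) -> np.ndarray | None:
    """One candidate loop conformation by seeded torsion perturbation with
    CCD endpoint closure; returns new coordinates for the whole structure,
    or None when closure fails."""
    chain = loop.chain_id
    lo, hi = loop.res_seqs[0], loop.res_seqs[-1]
    dih = backbone_dihedrals(structure, chain)
    res_list = list(range(lo, hi + 1))
    phis = np.array([dih[r][0] if dih[r][0] is not None else -120.0
                     for r in res_list] + [0.0])
    psis = np.array([dih[r][1] if dih[r][1] is not None else 130.0
                     for r in res_list])
    phis[:-1] += rng.normal(0.0, amplitude, size=len(res_list))
    psis += rng.normal(0.0, amplitude, size=len(res_list))
    out = _loop_backbone_rebuild(structure, loop, phis, psis)
    nxt = hi + 1
    targets = {(nxt, n): structure.atom(chain, nxt, n).position
               for n in ("N", "CA", "C")}
    final = _ccd_close(out, res_list, targets)
    if final > closure_tol:
        return None
    coords = structure.coords().copy()
    index = {(a.chain_id, a.res_seq, a.name): i
             for i, a in enumerate(structure.atoms)}
    for r in res_list:
        for nm in ("N", "CA", "C"):
            coords[index[(chain, r, nm)]] = out[(r, nm)]
    # rebuild O and CB from local backbone frames
    for r in res_list:
        n_pos, ca_pos, c_pos = (out[(r, x)] for x in ("N", "CA", "C"))
        n_next = out.get((r + 1, "N"),
                         structure.atom(chain, r + 1, "N").position
                         if structure.has_residue(chain, r + 1) else None)
        key_o = index.get((chain, r, "O"))
        if key_o is not None and n_next is not None:
            coords[key_o] = place_atom(n_next, ca_pos, c_pos, 1.231, 120.5,
                                       180.0)
        key_cb = index.get((chain, r, "CB"))
        if key_cb is not None:
            coords[key_cb] = place_atom(c_pos, n_pos, ca_pos, 1.521, 110.5,
                                        -121.0)
    return coords


def refine_loop_ensemble(structure: ModelStructure, em: DensityGrid,
                         loop: ResidueSegment, n: int = 200,
                         config: AnnealConfig | None = None,
                         resolution: float | None = None,
                         amplitude: float = 30.0,
                         candidates: list[np.ndarray] | None = None,
                         radius: float | None = None,
                         clash_distance: float = 1.8
                         ) -> tuple[ModelStructure, pd.DataFrame]:
    """Sample loop conformations, rank them by SMOC, keep the best.

    ``n`` conformations are generated by seeded backbone torsion
    perturbation (sigma = ``amplitude`` degrees) with CCD endpoint closure
    and steric rejection; the input conformation is always ranked alongside.
    Pre-built whole-structure coordinate arrays can be supplied via
    ``candidates`` instead. Returns the model with the top-scoring loop
    substituted, plus the ranked score table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or AnnealConfig()
    resolution = resolution or em.resolution_hint
    if resolution is None:
        raise ValueError("resolution not given and no resolution_hint on map")
    chain = loop.chain_id
    lo, hi = loop.res_seqs[0], loop.res_seqs[-1]
    if not (structure.has_residue(chain, lo - 1)
            and structure.has_residue(chain, hi + 1)):
        raise ValueError("loop must be interior to a chain (anchors needed)")
    rng = np.random.default_rng(config.seed)
    rows = []
    pool: list[tuple[str, np.ndarray]] = []
    if candidates is not None:
        pool = [(f"candidate_{i}", np.asarray(c, dtype=float))
                for i, c in enumerate(candidates)]
    elif amplitude == 0.0:
        pool = [("input", structure.coords())] * 0 + [("input",
                                                       structure.coords())]
        n = 1
    else:
        failures = 0
        for i in range(n):
            c = sample_loop_conformation(structure, loop, amplitude, rng)
            if c is None:
                failures += 1
                continue
            pool.append((f"sample_{i}", c))
        if not pool:
            raise RuntimeError(
                f"loop closure failed for all {n} samples; increase n or "
                "the perturbation amplitude")
        pool.append(("input", structure.coords()))
    loop_atom_idx = loop.atom_indices(structure)
    flank = np.concatenate([
        structure.residue_atom_indices((chain, r, ""))
        for r in (lo - 1, hi + 1)])
    other_idx = np.setdiff1d(np.arange(len(structure)),
                             np.concatenate([loop_atom_idx, flank]))
    weights = _atom_weights(structure)
    sigma_kw = {}
    best = None
    for label, coords in pool:
        # steric screen: loop vs the rest, excluding the flanking residues
        d = cKDTree(coords[other_idx]).query(coords[loop_atom_idx])[0]
        clash = bool((d < clash_distance).any()) and label != "input"
        cand = structure.with_coords(coords)
        vox = segment_voxels(em, cand, loop, radius)
        model_density = simulate_density(cand, resolution, grid=em,
                                         **sigma_kw)
        score = smoc_segment(em, model_density, vox)
        rows.append({"candidate": label, "smoc": score, "clash": clash})
        if not clash and (best is None or score > best[1]):
            best = (coords, score, label)
    table = pd.DataFrame(rows).sort_values(
        "smoc", ascending=False).reset_index(drop=True)
    if best is None:
        raise RuntimeError("all candidates rejected by the steric screen")
    return structure.with_coords(best[0]), table
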