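"""Synthetic ground-truth structures, perturbations and RMSD metrics.

The generators build poly-alanine backbones (N, CA, C, O, CB) with ideal
covalent geometry from internal coordinates, so every pipeline stage can be
exercised without external depositions. Perturbations emulate the
conformational difference between a starting model and the state captured
by a map: a hinge rotation between domains, a rigid displacement, or a
displaced surface loop.

Fixture kinds
-------------
helix             one ideal alpha-helix
helix_loop_helix  a packed helix-loop-helix hairpin
two_domain_hinge  two hairpin domains joined by an extended linker
four_helix_bundle four packed helices (optionally plus one helix displaced
                  far away), connected by geometrically approximate loops
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import kabsch, place_atom, rotation_matrix
from .core_model import (AtomRecord, ModelStructure, ResidueSegment,
                         SSEAnnotation, SSESegment)

# ideal backbone internal coordinates (Å, degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_CA_CB = 1.521
A_N_CA_C = 111.0
A_CA_C_N = 116.6
A_C_N_CA = 121.7
A_CA_C_O = 120.5
A_N_CA_CB = 110.5
OMEGA = 180.0

HELIX_PHI = -57.0
HELIX_PSI = -47.0
EXTENDED_PHI = -120.0
EXTENDED_PSI = 135.0

# loop torsions that fold the chain back into a packed two-helix hairpin
# (chosen once by construction; see docs/methods.md)
HAIRPIN_LOOP_TORSIONS = [
    (-52.5, 131.0),
    (-107.0, 24.6),
    (82.0, 43.7),
    (-83.7, -105.4),
    (-76.0, -90.0),
    (-126.4, 102.6),
]


@dataclass
class FixtureSpec:
    """Recipe for one synthetic ground-truth structure."""
    kind: str = "helix"
    helix_len: int = 12
    loop_len: int = 6
    linker_len: int = 6
    n_helices: int = 4
    outlier_helix: bool = False
    outlier_offset: float = 30.0
    chain_id: str = "A"
    seed: int = 0

    def __post_init__(self):
        valid = ("helix", "helix_loop_helix", "two_domain_hinge",
                 "four_helix_bundle")
        if self.kind not in valid:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.helix_len < 4:
            raise ValueError("helix_len must be >= 4")

    # residue bookkeeping for the standard kinds -------------------------

    def loop_range(self) -> tuple[int, int]:
        """Residue range of the (first) loop, for helix_loop_helix."""
        if self.kind not in ("helix_loop_helix", "two_domain_hinge"):
            raise ValueError(f"{self.kind} fixture has no canonical loop")
        return (self.helix_len + 1, self.helix_len + self.loop_len)

    def domain_len(self) -> int:
        return 2 * self.helix_len + self.loop_len

    def linker_range(self) -> tuple[int, int]:
        """Residue range of the inter-domain linker (two_domain_hinge)."""
        if self.kind != "two_domain_hinge":
            raise ValueError("linker_range applies to two_domain_hinge only")
        d = self.domain_len()
        return (d + 1, d + self.linker_len)

    def domain_ranges(self) -> list[tuple[int, int]]:
        if self.kind != "two_domain_hinge":
            raise ValueError("domain_ranges applies to two_domain_hinge only")
        d = self.domain_len()
        lk = self.linker_len
        return [(1, d), (d + lk + 1, 2 * d + lk)]


def _torsion_sequence(spec: FixtureSpec) -> list[tuple[float, float]]:
    helix = [(HELIX_PHI, HELIX_PSI)] * spec.helix_len
    loop = _loop_torsions(spec.loop_len)
    if spec.kind == "helix":
        return helix
    if spec.kind == "helix_loop_helix":
        return helix + loop + helix
    if spec.kind == "two_domain_hinge":
        # first linker residue eases the helix-to-extended transition so the
        # ground truth is free of van der Waals violations
        linker = [(-70.0, 150.0)] + [(EXTENDED_PHI, EXTENDED_PSI)
                                     ] * (spec.linker_len - 1)
        domain = helix + loop + helix
        return domain + linker + domain
    raise ValueError(spec.kind)


def _loop_torsions(n: int) -> list[tuple[float, float]]:
    base = HAIRPIN_LOOP_TORSIONS
    if n <= len(base):
        return list(base[:n])
    extra = [(-70.0, -35.0)] * (n - len(base))
    return list(base) + extra


def build_chain(torsions: list[tuple[float, float]], chain_id: str = "A",
                first_res: int = 1) -> ModelStructure:
    """Poly-Ala backbone from a (phi, psi) list, ideal covalent geometry."""
    n_res = len(torsions)
    # seed the first residue explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    c0 = place_atom(np.array([-1.0, 1.0, 0.0]), n0, ca0, B_CA_C, A_N_CA_C,
                    torsions[0][0] + 180.0)
    coords = {"N": [n0], "CA": [ca0], "C": [c0]}
    for i in range(1, n_res):
        psi_prev = torsions[i - 1][1]
        phi = torsions[i][0]
        n = place_atom(coords["N"][-1], coords["CA"][-1], coords["C"][-1],
                       B_C_N, A_CA_C_N, psi_prev)
        ca = place_atom(coords["CA"][-1], coords["C"][-1], n,
                        B_N_CA, A_C_N_CA, OMEGA)
        c = place_atom(coords["C"][-1], n, ca, B_CA_C, A_N_CA_C, phi)
        coords["N"].append(n)
        coords["CA"].append(ca)
        coords["C"].append(c)
    atoms: list[AtomRecord] = []
    serial = 0
    for i in range(n_res):
        n, ca, c = coords["N"][i], coords["CA"][i], coords["C"][i]
        if i + 1 < n_res:
            o = place_atom(coords["N"][i + 1], ca, c, B_C_O, A_CA_C_O, OMEGA)
        else:
            o = place_atom(n, ca, c, B_C_O, A_CA_C_O, torsions[i][1] + 180.0)
        cb = place_atom(c, n, ca, B_CA_CB, A_N_CA_CB, -121.0)
        for name, pos in (("N", n), ("CA", ca), ("C", c), ("O", o),
                          ("CB", cb)):
            serial += 1
            atoms.append(AtomRecord(serial, name, name[0], "", "ALA",
                                    chain_id, first_res + i, "", pos))
    return ModelStructure(atoms, title="synthetic poly-Ala fixture")


def _ideal_helix_coords(n_res: int) -> ModelStructure:
    return build_chain([(HELIX_PHI, HELIX_PSI)] * n_res)


def _build_bundle(spec: FixtureSpec) -> tuple[ModelStructure, SSEAnnotation]:
    """Ideal helices on a square lattice, alternating direction, joined by
    geometrically approximate loops (CA interpolation with a copied local
    residue frame) — adequate for contact/clustering and scoring tests, not
    for torsion analysis.
    """
    n_hel = spec.n_helices
    hlen = spec.helix_len
    llen = spec.loop_len
    template = _ideal_helix_coords(hlen)
    t_coords = template.coords()
    ca_idx = [i for i, a in enumerate(template.atoms) if a.name == "CA"]
    axis = t_coords[ca_idx[-1]] - t_coords[ca_idx[0]]
    axis /= np.linalg.norm(axis)
    # align the template axis to +z and center it on the origin
    r_axis, _ = kabsch(np.array([axis, -axis]),
                       np.array([[0, 0, 1.0], [0, 0, -1.0]]))
    base = (t_coords - t_coords.mean(axis=0)) @ r_axis.T
    flip_r = rotation_matrix(np.array([1.0, 0.0, 0.0]), 180.0)
    sep = 7.5
    lattice = [(0.0, 0.0), (sep, 0.0), (sep, sep), (0.0, sep),
               (2 * sep, 0.0), (2 * sep, sep)]
    n_total = n_hel + (1 if spec.outlier_helix else 0)
    placements: list[np.ndarray] = []
    for h in range(n_total):
        placed = base @ flip_r.T if h % 2 == 1 else base.copy()
        if h < n_hel:
            xy = lattice[h]
        else:
            xy = (lattice[0][0] - spec.outlier_offset, lattice[0][1])
        placements.append(placed + np.array([xy[0], xy[1], 0.0]))
    atoms: list[AtomRecord] = []
    serial = 0
    res = 0
    segments: list[SSESegment] = []
    for h, placed in enumerate(placements):
        start_res = res + 1
        for i, a in enumerate(template.atoms):
            serial += 1
            atoms.append(AtomRecord(serial, a.name, a.element, "", "ALA",
                                    spec.chain_id, res + 1 + (i // 5), "",
                                    placed[i]))
        res += hlen
        segments.append(SSESegment("helix", spec.chain_id, start_res, res))
        if h + 1 < len(placements):
            ca_end = placed[ca_idx[-1]]
            ca_next = placements[h + 1][ca_idx[0]]
            offsets = placed[-5:] - ca_end  # local residue frame
            # quadratic Bezier arc bulging axially outward so the CA spacing
            # stays near 3.8 Å and the loop clears the helix ends
            mid = 0.5 * (ca_end + ca_next)
            out_dir = np.array([0.0, 0.0, np.sign(ca_end[2]) or 1.0])
            chord = float(np.linalg.norm(ca_next - ca_end))
            want = 3.8 * (llen + 1)
            bulge = 0.75 * np.sqrt(max(want * want - chord * chord, 1.0))
            ctrl = mid + bulge * out_dir
            tt = np.linspace(0.0, 1.0, 200)
            curve = ((1 - tt[:, None]) ** 2 * ca_end
                     + 2 * tt[:, None] * (1 - tt[:, None]) * ctrl
                     + tt[:, None] ** 2 * ca_next)
            arc = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(curve, axis=0), axis=1))])
            for j in range(llen):
                s = arc[-1] * (j + 1) / (llen + 1)
                ca = curve[int(np.searchsorted(arc, s))]
                res += 1
                for name, off in zip(("N", "CA", "C", "O", "CB"), offsets):
                    serial += 1
                    atoms.append(AtomRecord(serial, name, name[0], "", "ALA",
                                            spec.chain_id, res, "",
                                            ca + off))
    st = ModelStructure(atoms, title="synthetic helix bundle")
    return st, SSEAnnotation(segments)


def make_fixture(spec: FixtureSpec) -> tuple[ModelStructure, SSEAnnotation]:
    """Ground-truth structure and matching SSE annotation for a spec."""
    if spec.kind == "four_helix_bundle":
        return _build_bundle(spec)
    torsions = _torsion_sequence(spec)
    structure = build_chain(torsions, chain_id=spec.chain_id)
    segments: list[SSESegment] = []
    c = spec.chain_id
    h = spec.helix_len
    if spec.kind == "helix":
        segments.append(SSESegment("helix", c, 1, h))
    elif spec.kind == "helix_loop_helix":
        segments.append(SSESegment("helix", c, 1, h))
        segments.append(SSESegment("helix", c, h + spec.loop_len + 1,
                                   2 * h + spec.loop_len))
    elif spec.kind == "two_domain_hinge":
        d = spec.domain_len()
        lk = spec.linker_len
        for base in (0, d + lk):
            segments.append(SSESegment("helix", c, base + 1, base + h))
            segments.append(SSESegment("helix", c,
                                       base + h + spec.loop_len + 1,
                                       base + 2 * h + spec.loop_len))
    return structure, SSEAnnotation(segments)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

MIN_NONBONDED_DISTANCE = 1.5  # Å; closer than this counts as steric collapse


def _steric_check(structure: ModelStructure) -> None:
    from scipy.spatial import cKDTree
    coords = structure.coords()
    res_of = np.empty(len(coords), dtype=int)
    for i, a in enumerate(structure.atoms):
        res_of[i] = a.res_seq
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=MIN_NONBONDED_DISTANCE, output_type="ndarray")
    for i, j in pairs:
        if abs(res_of[i] - res_of[j]) > 1:
            raise ValueError(
                f"perturbation causes steric collapse: atoms "
                f"{structure.atoms[i].res_seq}:{structure.atoms[i].name} and "
                f"{structure.atoms[j].res_seq}:{structure.atoms[j].name} at "
                f"< {MIN_NONBONDED_DISTANCE} Å")


def perturb(structure: ModelStructure, mode: str, magnitude: float,
            seed: int = 0,
            linker: tuple[int, int] | None = None,
            loop: tuple[int, int] | None = None,
            chain_id: str | None = None) -> ModelStructure:
    """Perturb a fixture away from its ground truth.

    hinge          rotate every residue after the linker midpoint by
                   ``magnitude`` degrees about the linker axis
    translate      rigid shift by ``magnitude`` Å along a seeded random
                   direction
    loop_displace  displace the atoms of ``loop`` by up to ``magnitude`` Å
                   along a seeded direction with a smooth taper to zero at
                   the loop endpoints (endpoint repair)
    """
    rng = np.random.default_rng(seed)
    chain = chain_id or structure.chains()[0]
    coords = structure.coords()
    if mode == "translate":
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        out = structure.with_coords(coords + magnitude * direction)
    elif mode == "hinge":
        if linker is None:
            raise ValueError("hinge mode needs linker=(start, end)")
        lo, hi = linker
        mid = (lo + hi) // 2
        ca_lo = structure.atom(chain, lo, "CA").position
        ca_hi = structure.atom(chain, hi, "CA").position
        pivot = structure.atom(chain, mid, "CA").position
        axis = ca_hi - ca_lo
        r = rotation_matrix(axis, magnitude)
        moving = np.array([a.res_seq > mid and a.chain_id == chain
                           for a in structure.atoms])
        new = coords.copy()
        new[moving] = (coords[moving] - pivot) @ r.T + pivot
        out = structure.with_coords(new)
    elif mode == "loop_displace":
        if loop is None:
            raise ValueError("loop_displace mode needs loop=(start, end)")
        lo, hi = loop
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        new = coords.copy()
        span = hi - lo
        for i, a in enumerate(structure.atoms):
            if a.chain_id == chain and lo <= a.res_seq <= hi:
                t = (a.res_seq - lo) / span if span else 0.5
                w = np.sin(np.pi * (0.15 + 0.7 * t))  # taper, max ~1
                new[i] = coords[i] + magnitude * w * direction
        out = structure.with_coords(new)
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    _steric_check(out)
    return out


# ---------------------------------------------------------------------------
# RMSD metrics
# ---------------------------------------------------------------------------

def rmsd(a: ModelStructure, b: ModelStructure,
         selection: str | ResidueSegment = "calpha",
         superpose: bool = False) -> float:
    """Root-mean-square deviation over matched atoms.

    By default the deviation is computed in the shared map frame (no
    superposition), the meaningful comparison for models fitted to the same
    density; ``superpose=True`` applies a least-squares superposition first.
    Selections: "calpha", "all_atom", or a ResidueSegment (all atoms of its
    residues).
    """
    keys_a = {(at.chain_id, at.res_seq, at.insertion_code, at.name): i
              for i, at in enumerate(a.atoms)}
    keys_b = {(at.chain_id, at.res_seq, at.insertion_code, at.name): i
              for i, at in enumerate(b.atoms)}

    def selected(key) -> bool:
        chain, res, _icode, name = key
        if isinstance(selection, ResidueSegment):
            return chain == selection.chain_id and res in selection.res_seqs
        if selection == "calpha":
            return name == "CA"
        if selection == "all_atom":
            return True
        raise ValueError(f"unknown selection {selection!r}")

    sel_a = {k for k in keys_a if selected(k)}
    sel_b = {k for k in keys_b if selected(k)}
    if sel_a != sel_b:
        missing = sorted(sel_a ^ sel_b)
        raise ValueError(f"atom sets differ under selection: {missing[:8]}")
    if not sel_a:
        raise ValueError("empty selection")
    order = sorted(sel_a)
    ca = np.array([a.atoms[keys_a[k]].position for k in order])
    cb = np.array([b.atoms[keys_b[k]].position for k in order])
    if superpose:
        r, t = kabsch(ca, cb)
        ca = ca @ r.T + t
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=-1))))
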