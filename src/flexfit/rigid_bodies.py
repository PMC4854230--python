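"""Rigid-body identification: geometric SSE assignment (fallback when no
annotation is supplied) and spatial clustering of SSEs into rigid bodies.

Clustering treats helices and strands as basic units: two SSEs are in
contact when at least ``min_pair_fraction`` of their inter-SSE residue
pairs have a Calpha-Calpha distance within ``cutoff``. Connected components
of the contact graph become rigid bodies; the loops connecting two SSEs of
the same cluster along the chain are absorbed into the body, loops that are
not enclosed within one cluster stay free, and SSEs outside any cluster
become singleton bodies.
"""
from __future__ import annotations

import warnings

import numpy as np

from ._geometry import dihedral
from .core_model import (ModelStructure, ResidueRange, RigidBodyScheme,
                         SSEAnnotation, SSESegment)

DEFAULT_CONTACT_CUTOFF = 6.5  # Å, Calpha-Calpha
DEFAULT_MIN_PAIR_FRACTION = 0.1

# generous dihedral windows (degrees)
_HELIX_PHI = (-120.0, -20.0)
_HELIX_PSI = (-90.0, 10.0)
_STRAND_PHI = (-180.0, -60.0)
_STRAND_PSI_LO = 90.0   # psi > 90 or psi < -150 counts as extended
_STRAND_PSI_HI = -150.0

MIN_HELIX_LEN = 4
MIN_STRAND_LEN = 3


def backbone_dihedrals(structure: ModelStructure, chain: str
                       ) -> dict[int, tuple[float | None, float | None]]:
    """(phi, psi) per residue; None where the neighbor residue is absent."""
    res = structure.chain_residues(chain)
    out: dict[int, tuple[float | None, float | None]] = {}

    def atom_pos(key, name):
        for a in structure.residue_atoms(key):
            if a.name == name:
                return a.position
        return None

    for i, key in enumerate(res):
        n = atom_pos(key, "N")
        ca = atom_pos(key, "CA")
        c = atom_pos(key, "C")
        phi = psi = None
        if n is None or ca is None or c is None:
            out[key[1]] = (None, None)
            continue
        if i > 0 and res[i - 1][1] == key[1] - 1:
            c_prev = atom_pos(res[i - 1], "C")
            if c_prev is not None:
                phi = dihedral(c_prev, n, ca, c)
        if i + 1 < len(res) and res[i + 1][1] == key[1] + 1:
            n_next = atom_pos(res[i + 1], "N")
            if n_next is not None:
                psi = dihedral(n, ca, c, n_next)
        out[key[1]] = (phi, psi)
    return out


def _is_helix(phi: float | None, psi: float | None) -> bool:
    checks = []
    if phi is not None:
        checks.append(_HELIX_PHI[0] <= phi <= _HELIX_PHI[1])
    if psi is not None:
        checks.append(_HELIX_PSI[0] <= psi <= _HELIX_PSI[1])
    return bool(checks) and all(checks)


def _is_strand(phi: float | None, psi: float | None) -> bool:
    checks = []
    if phi is not None:
        checks.append(_STRAND_PHI[0] <= phi <= _STRAND_PHI[1])
    if psi is not None:
        checks.append(psi >= _STRAND_PSI_LO or psi <= _STRAND_PSI_HI)
    return bool(checks) and all(checks)


def assign_sses(structure: ModelStructure) -> SSEAnnotation:
    """Assign helices and strands from backbone dihedral patterns.

    Minimum lengths: 4 residues for a helix, 3 for a strand. A TSV
    annotation or HELIX/SHEET records, when available, should be preferred
    over this geometric fallback.
    """
    segments: list[SSESegment] = []
    for chain in structure.chains():
        res_seqs = [k[1] for k in structure.chain_residues(chain)]
        if len(res_seqs) < MIN_HELIX_LEN:
            warnings.warn(f"chain {chain} has fewer than {MIN_HELIX_LEN} "
                          "residues; no SSEs assigned", stacklevel=2)
            continue
        dihedrals = backbone_dihedrals(structure, chain)
        state = {}
        for r in res_seqs:
            phi, psi = dihedrals[r]
            if _is_helix(phi, psi):
                state[r] = "helix"
            elif _is_strand(phi, psi):
                state[r] = "strand"
            else:
                state[r] = "coil"
        min_len = {"helix": MIN_HELIX_LEN, "strand": MIN_STRAND_LEN}
        run: list[int] = []
        kind = "coil"
        for r in res_seqs + [None]:  # type: ignore[list-item]
            s = state[r] if r is not None else "coil"
            if s == kind and run and r == run[-1] + 1:
                run.append(r)
                continue
            if kind in min_len and len(run) >= min_len[kind]:
                segments.append(SSESegment(kind, chain, run[0], run[-1]))
            run = [r] if r is not None else []
            kind = s
    return SSEAnnotation(segments)


def _ca_coords(structure: ModelStructure, seg: SSESegment) -> np.ndarray:
    out = []
    for r in range(seg.start, seg.end + 1):
        for a in structure.residue_atoms((seg.chain_id, r, "")):
            if a.name == "CA":
                out.append(a.position)
                break
    return np.array(out)


def contact_weight(structure: ModelStructure, a: SSESegment,
                   b: SSESegment, cutoff: float = DEFAULT_CONTACT_CUTOFF
                   ) -> float:
    """Fraction of inter-SSE residue pairs with Calpha distance <= cutoff."""
    ca = _ca_coords(structure, a)
    cb = _ca_coords(structure, b)
    if len(ca) == 0 or len(cb) == 0:
        return 0.0
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    return float((d <= cutoff).mean())


def contact_graph(structure: ModelStructure, sses: SSEAnnotation,
                  cutoff: float = DEFAULT_CONTACT_CUTOFF) -> np.ndarray:
    """Symmetric matrix of pairwise SSE contact weights (diagonal zero)."""
    n = len(sses.segments)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            w[i, j] = w[j, i] = contact_weight(structure, sses.segments[i],
                                               sses.segments[j], cutoff)
    return w


def _connected_components(adjacency: np.ndarray) -> list[list[int]]:
    n = len(adjacency)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if adjacency[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(comps.values(), key=lambda c: c[0])


def cluster_sses(structure: ModelStructure, sses: SSEAnnotation,
                 cutoff: float = DEFAULT_CONTACT_CUTOFF,
                 min_pair_fraction: float = DEFAULT_MIN_PAIR_FRACTION
                 ) -> RigidBodyScheme:
    """Cluster spatially proximal SSEs into rigid bodies.

    Each multi-SSE cluster becomes one body holding the cluster's SSE
    residues plus all loop residues lying strictly between two SSEs of the
    cluster along the chain; isolated SSEs become singleton bodies; loops
    not enclosed within a cluster remain free.
    """
    if not sses.segments:
        raise ValueError("no SSE segments to cluster")
    sses.validate(structure)
    w = contact_graph(structure, sses, cutoff)
    adj = w >= min_pair_fraction
    comps = _connected_components(adj)
    bodies: list[list[ResidueRange]] = []
    segs = sses.segments
    for comp in comps:
        members = sorted(comp, key=lambda i: (segs[i].chain_id, segs[i].start))
        ranges: list[ResidueRange] = []
        for a, b in zip(members, members[1:]):
            sa, sb = segs[a], segs[b]
            if (len(comp) > 1 and sa.chain_id == sb.chain_id
                    and _consecutive_along_chain(segs, sa, sb)):
                # absorb the connecting loop: both flanks in this cluster
                ranges.append(ResidueRange(sa.chain_id, sa.start, sb.end))
            else:
                ranges.append(ResidueRange(sa.chain_id, sa.start, sa.end))
        last = segs[members[-1]]
        ranges.append(ResidueRange(last.chain_id, last.start, last.end))
        bodies.append(_merge_ranges(ranges))
    return RigidBodyScheme(bodies, level="ribfind_clusters")


def _consecutive_along_chain(segs: list[SSESegment], a: SSESegment,
                             b: SSESegment) -> bool:
    """True when no other SSE lies between a and b on their chain."""
    return not any(s.chain_id == a.chain_id and a.end < s.start
                   and s.end < b.start for s in segs)


def _merge_ranges(ranges: list[ResidueRange]) -> list[ResidueRange]:
    out: list[ResidueRange] = []
    for r in sorted(ranges, key=lambda r: (r.chain_id, r.start)):
        if out and out[-1].chain_id == r.chain_id and r.start <= out[-1].end + 1:
            if r.end > out[-1].end:
                out[-1] = ResidueRange(r.chain_id, out[-1].start, r.end)
        else:
            out.append(r)
    return out


def scheme_for_level(sses: SSEAnnotation, clusters: RigidBodyScheme | None,
                     level: str) -> RigidBodyScheme:
    """Rigid-body scheme for one stage of the hierarchical protocol.

    ribfind_clusters -> the cluster scheme as given; sse -> one body per
    SSE segment with loops free; all_atom -> no bodies (every atom free).
    """
    if level == "ribfind_clusters":
        if clusters is None:
            raise ValueError("no cluster scheme supplied")
        return clusters
    if level == "sse":
        bodies = [[ResidueRange(s.chain_id, s.start, s.end)]
                  for s in sses.segments]
        return RigidBodyScheme(bodies, level="sse")
    if level == "all_atom":
        return RigidBodyScheme([], level="all_atom")
    raise ValueError(f"unknown level {level!r}")
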