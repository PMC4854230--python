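"""Domain types and file I/O for atomic models, SSE annotations and rigid bodies.

Coordinates are Å in the map frame throughout. Residue numbering follows the
input file (no renumbering); insertion codes are preserved. Alternate
locations are resolved at parse time by keeping the highest-occupancy
conformer (ties: first encountered) — the refinement engine is
single-conformer. Hydrogens are retained if present, never added.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

ResidueKey = tuple[str, int, str]  # (chain_id, res_seq, insertion_code)


class ParseError(ValueError):
    """Raised when a structure, annotation or rigid-body file is malformed."""


@dataclass
class AtomRecord:
    """One atom: identity, hierarchy placement, position (Å), occupancy, B."""
    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0,1]")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.insertion_code)


class ModelStructure:
    """An ordered atom list with a chain/residue index.

    The residue index maps (chain_id, res_seq, insertion_code) to the
    contiguous span of atom indices belonging to that residue; it partitions
    the atom list (every atom appears in exactly one residue span).
    """

    def __init__(self, atoms: list[AtomRecord], title: str = ""):
        if not atoms:
            raise ParseError("empty structure (no atoms)")
        self.atoms = list(atoms)
        self.title = title
        self._build_index()

    def _build_index(self) -> None:
        index: dict[ResidueKey, tuple[int, int]] = {}
        seen_atoms: set[tuple] = set()
        start = 0
        for i, atom in enumerate(self.atoms):
            uid = (atom.chain_id, atom.res_seq, atom.insertion_code,
                   atom.name, atom.alt_loc)
            if uid in seen_atoms:
                raise ParseError(f"duplicate atom {uid}")
            seen_atoms.add(uid)
            key = atom.residue_key
            if i > 0 and key != self.atoms[i - 1].residue_key:
                prev = self.atoms[i - 1].residue_key
                if key in index:
                    raise ParseError(f"residue {key} atoms are not contiguous")
                index[prev] = (start, i)
                start = i
        index[self.atoms[-1].residue_key] = (start, len(self.atoms))
        self.residue_index = index

    # -- accessors ---------------------------------------------------------

    def residue_keys(self) -> list[ResidueKey]:
        return list(self.residue_index)

    def chain_residues(self, chain_id: str) -> list[ResidueKey]:
        return [k for k in self.residue_index if k[0] == chain_id]

    def chains(self) -> list[str]:
        out: list[str] = []
        for key in self.residue_index:
            if key[0] not in out:
                out.append(key[0])
        return out

    def residue_atoms(self, key: ResidueKey) -> list[AtomRecord]:
        lo, hi = self.residue_index[key]
        return self.atoms[lo:hi]

    def residue_atom_indices(self, key: ResidueKey) -> np.ndarray:
        lo, hi = self.residue_index[key]
        return np.arange(lo, hi)

    def atom(self, chain_id: str, res_seq: int, name: str,
             insertion_code: str = "") -> AtomRecord:
        for a in self.residue_atoms((chain_id, res_seq, insertion_code)):
            if a.name == name:
                return a
        raise KeyError(f"atom {name} not in residue {chain_id}:{res_seq}")

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of positions, in atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "ModelStructure":
        """A copy of this structure with replaced positions."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, position=coords[i].copy())
                 for i, a in enumerate(self.atoms)]
        return ModelStructure(atoms, self.title if title is None else title)

    def copy(self) -> "ModelStructure":
        return self.with_coords(self.coords())

    def __len__(self) -> int:
        return len(self.atoms)

    def has_residue(self, chain_id: str, res_seq: int,
                    insertion_code: str = "") -> bool:
        return (chain_id, res_seq, insertion_code) in self.residue_index


@dataclass(frozen=True)
class SSESegment:
    kind: str  # "helix" | "strand"
    chain_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.kind not in ("helix", "strand"):
            raise ValueError(f"unknown SSE kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError(f"SSE start {self.start} > end {self.end}")


@dataclass
class SSEAnnotation:
    """Helix/strand segments; the basic units for rigid-body clustering."""
    segments: list[SSESegment] = field(default_factory=list)

    def __post_init__(self):
        by_chain: dict[str, list[SSESegment]] = {}
        for s in self.segments:
            by_chain.setdefault(s.chain_id, []).append(s)
        for chain, segs in by_chain.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping SSE segments in chain {chain}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}")

    def validate(self, structure: ModelStructure) -> None:
        for s in self.segments:
            for r in range(s.start, s.end + 1):
                if not structure.has_residue(s.chain_id, r):
                    raise ValueError(
                        f"SSE {s.kind} {s.chain_id}:{s.start}-{s.end} "
                        f"references missing residue {s.chain_id}:{r}")

    def sse_residues(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for s in self.segments:
            out.update((s.chain_id, r) for r in range(s.start, s.end + 1))
        return out

    def segment_of(self, chain_id: str, res_seq: int) -> SSESegment | None:
        for s in self.segments:
            if s.chain_id == chain_id and s.start <= res_seq <= s.end:
                return s
        return None


@dataclass(frozen=True)
class ResidueRange:
    chain_id: str
    start: int
    end: int

    def residues(self) -> list[tuple[str, int]]:
        return [(self.chain_id, r) for r in range(self.start, self.end + 1)]


@dataclass
class RigidBodyScheme:
    """Grouping of residues into rigid bodies for one refinement stage.

    ``bodies`` is a list of bodies, each a list of residue ranges. Residues
    not covered by any body are free (move as individual atoms). An empty
    body list means everything is free (the all-atom stage).
    """
    bodies: list[list[ResidueRange]]
    level: str = "ribfind_clusters"  # ribfind_clusters | sse | all_atom | custom

    def body_residue_sets(self) -> list[set[tuple[str, int]]]:
        out = []
        for body in self.bodies:
            s: set[tuple[str, int]] = set()
            for rng in body:
                s.update(rng.residues())
            out.append(s)
        return out

    def validate(self, structure: ModelStructure) -> None:
        sets = self.body_residue_sets()
        for i, s in enumerate(sets):
            for chain, res in sorted(s):
                if not structure.has_residue(chain, res):
                    raise ValueError(
                        f"rigid body {i + 1} references missing residue "
                        f"{chain}:{res}")
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                clash = sets[i] & sets[j]
                if clash:
                    shared = ", ".join(f"{c}:{r}" for c, r in sorted(clash))
                    raise ValueError(
                        f"rigid bodies {i + 1} and {j + 1} overlap on "
                        f"residues {shared}")

    def body_atom_indices(self, structure: ModelStructure) -> list[np.ndarray]:
        out = []
        for s in self.body_residue_sets():
            idx: list[np.ndarray] = []
            for chain, res in sorted(s):
                idx.append(structure.residue_atom_indices((chain, res, "")))
            out.append(np.concatenate(idx) if idx else np.array([], dtype=int))
        return out


@dataclass
class ResidueSegment:
    """A labelled, ordered run of residues in one chain (e.g. a loop)."""
    chain_id: str
    res_seqs: list[int]
    label: str = ""
    allow_breaks: bool = False

    def __post_init__(self):
        if not self.res_seqs:
            raise ValueError("empty residue segment")
        if not self.allow_breaks:
            diffs = np.diff(self.res_seqs)
            if len(diffs) and not np.all(diffs == 1):
                raise ValueError(
                    f"segment {self.label or self.res_seqs} is not contiguous "
                    "(pass allow_breaks=True to permit)")

    @classmethod
    def from_range(cls, chain_id: str, start: int, end: int,
                   label: str = "") -> "ResidueSegment":
        return cls(chain_id, list(range(start, end + 1)),
                   label or f"{chain_id}:{start}-{end}")

    def atom_indices(self, structure: ModelStructure) -> np.ndarray:
        idx = [structure.residue_atom_indices((self.chain_id, r, ""))
               for r in self.res_seqs]
        return np.concatenate(idx)


# ---------------------------------------------------------------------------
# structure I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _dialect_from_path(path: str) -> str:
    p = str(path).lower()
    if p.endswith((".cif", ".mmcif", ".cif.gz")):
        return "mmcif"
    return "pdb"


def read_structure(path: str, dialect: str | None = None) -> ModelStructure:
    """Read a PDB or mmCIF file into a ModelStructure.

    All ATOM/HETATM records of the first model are captured. Alternate
    locations are resolved by keeping the highest-occupancy conformer.
    """
    dialect = dialect or _dialect_from_path(path)
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(str(path))
        elif dialect == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ParseError(f"unknown dialect {dialect!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models in file")
    atoms: list[AtomRecord] = []
    serial = 0
    for chain in st[0]:
        for res in chain:
            # resolve altlocs: keep highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in res:
                if best.get(at.name) is not at:
                    continue
                serial += 1
                atoms.append(AtomRecord(
                    serial=serial,
                    name=at.name,
                    element=at.element.name or at.name[0],
                    alt_loc="",
                    res_name=res.name,
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    insertion_code=(res.seqid.icode or " ").strip(),
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    b_iso=at.b_iso,
                ))
    if not atoms:
        raise ParseError(f"{path}: structure contains no atoms")
    return ModelStructure(atoms, title=st.name or "")


def to_gemmi(structure: ModelStructure, name: str = "model") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.title or name
    model = gemmi.Model("1")
    chain = None
    residue = None
    prev_key = None
    for a in structure.atoms:
        if chain is None or a.chain_id != chain.name:
            chain = gemmi.Chain(a.chain_id)
            model.add_chain(chain)
            chain = model[-1]
            prev_key = None
        if a.residue_key != prev_key:
            residue = gemmi.Residue()
            residue.name = a.res_name
            residue.seqid = gemmi.SeqId(a.res_seq, a.insertion_code or " ")
            chain.add_residue(residue)
            residue = chain[-1]
            prev_key = a.residue_key
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        at.b_iso = a.b_iso
        residue.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: ModelStructure, path: str,
                    dialect: str | None = None) -> None:
    """Write a ModelStructure to PDB or mmCIF (dialect from file suffix)."""
    dialect = dialect or _dialect_from_path(path)
    st = to_gemmi(structure)
    if dialect == "pdb":
        st.write_pdb(str(path))
    elif dialect == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ParseError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# rigid-body and SSE annotation files
# ---------------------------------------------------------------------------

def read_rigid_body_file(path: str, structure: ModelStructure) -> RigidBodyScheme:
    """Read rigid-body definitions, one body per line.

    Plain-text dialect: each line holds one or more whitespace-separated
    triples ``start end chain``; blank lines and ``#`` comments are ignored.
    A JSON dialect is also accepted (suffix .json): ``{"level": ...,
    "bodies": [[[chain, start, end], ...], ...]}``.
    """
    text = open(path).read()
    if str(path).lower().endswith(".json"):
        doc = json.loads(text)
        bodies = [[ResidueRange(str(c), int(s), int(e)) for c, s, e in body]
                  for body in doc["bodies"]]
        scheme = RigidBodyScheme(bodies, level=doc.get("level", "custom"))
        scheme.validate(structure)
        return scheme
    bodies = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) % 3 != 0:
            raise ParseError(
                f"{path}:{ln}: expected 'start end chain' triples, got "
                f"{len(fields)} fields")
        ranges = []
        for i in range(0, len(fields), 3):
            try:
                start, end = int(fields[i]), int(fields[i + 1])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer residue number") from exc
            chain = fields[i + 2]
            if start > end:
                raise ParseError(f"{path}:{ln}: start {start} > end {end}")
            ranges.append(ResidueRange(chain, start, end))
        bodies.append(ranges)
    scheme = RigidBodyScheme(bodies, level="custom")
    scheme.validate(structure)
    return scheme


def write_rigid_body_file(scheme: RigidBodyScheme, path: str) -> None:
    with open(path, "w") as fh:
        for body in scheme.bodies:
            fh.write("   ".join(f"{r.start} {r.end} {r.chain_id}"
                                for r in body) + "\n")


def read_sse_tsv(path: str, structure: ModelStructure | None = None) -> SSEAnnotation:
    """Read SSE segments from a TSV with columns kind, chain, start, end."""
    segments = []
    for ln, line in enumerate(open(path), start=1):
        line = line.split("#", 1)[0].strip()
        if not line or line.lower().startswith("kind"):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ParseError(f"{path}:{ln}: expected 4 columns, got {len(fields)}")
        kind, chain, start, end = fields
        segments.append(SSESegment(kind, chain, int(start), int(end)))
    ann = SSEAnnotation(segments)
    if structure is not None:
        ann.validate(structure)
    return ann


def write_sse_tsv(annotation: SSEAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tchain\tstart\tend\n")
        for s in annotation.segments:
            fh.write(f"{s.kind}\t{s.chain_id}\t{s.start}\t{s.end}\n")


def sses_from_pdb_records(path: str) -> SSEAnnotation:
    """Take helix/strand segments from HELIX/SHEET records of a PDB file."""
    st = gemmi.read_pdb(str(path))
    segments = []
    for h in st.helices:
        segments.append(SSESegment("helix", h.start.chain_name,
                                   h.start.res_id.seqid.num,
                                   h.end.res_id.seqid.num))
    for sheet in st.sheets:
        for strand in sheet.strands:
            segments.append(SSESegment("strand", strand.start.chain_name,
                                       strand.start.res_id.seqid.num,
                                       strand.end.res_id.seqid.num))
    return SSEAnnotation(segments)
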