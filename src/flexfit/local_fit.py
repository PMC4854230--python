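"""Local goodness-of-fit assessment with the segment-based Manders' overlap
coefficient (SMOC).

SMOC for a residue segment is

    SMOC = sum_i(rho_i^EM * rho_i^P) /
           sqrt(sum_i(rho_i^EM)^2 * sum_i(rho_i^P)^2)

over the voxels i occupied by the segment's atoms, where rho^EM is the
target map and rho^P the model-derived map. Unlike the mean-subtracted CCC
it is insensitive to scaling of either map but sensitive to additive
offsets, which makes it usable when the target map contains density beyond
the fitted component.

Per-residue profiles assign each SSE residue its segment's SMOC and score
loop residues over overlapping nine-residue windows. Z-scores over the
profile flag poorly fitting segments.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import ModelStructure, ResidueSegment, SSEAnnotation
from .density_ops import (DensityGrid, GridIndexSet, simulate_density)

DEFAULT_WINDOW = 9


def default_mask_radius(grid: DensityGrid) -> float:
    """Voxel-occupancy radius: max(2.5 Å, 1.5 x largest voxel spacing)."""
    return max(2.5, 1.5 * float(np.max(grid.spacing)))


def segment_voxels(grid: DensityGrid, structure: ModelStructure,
                   segment: ResidueSegment,
                   radius: float | None = None) -> GridIndexSet:
    """Voxels whose centers lie within ``radius`` of any atom of the segment."""
    if radius is None:
        radius = default_mask_radius(grid)
    if radius <= 0:
        raise ValueError(f"non-positive radius {radius}")
    coords = structure.coords()[segment.atom_indices(structure)]
    return voxels_near_atoms(grid, coords, radius)


def voxels_near_atoms(grid: DensityGrid, coords: np.ndarray,
                      radius: float) -> GridIndexSet:
    nz, ny, nx = grid.values.shape
    dims = np.array([nx, ny, nz])
    hit: set[tuple[int, int, int]] = set()
    r2 = radius * radius
    for pos in np.atleast_2d(coords):
        lo = np.maximum(np.ceil((pos - radius - grid.origin)
                                / grid.spacing).astype(int), 0)
        hi = np.minimum(np.floor((pos + radius - grid.origin)
                                 / grid.spacing).astype(int), dims - 1)
        if np.any(lo > hi):
            continue
        ii = np.arange(lo[0], hi[0] + 1)
        jj = np.arange(lo[1], hi[1] + 1)
        kk = np.arange(lo[2], hi[2] + 1)
        dx = grid.origin[0] + ii * grid.spacing[0] - pos[0]
        dy = grid.origin[1] + jj * grid.spacing[1] - pos[1]
        dz = grid.origin[2] + kk * grid.spacing[2] - pos[2]
        d2 = (dz[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dx[None, None, :] ** 2)
        sel = np.argwhere(d2 <= r2)
        for a, b, c in sel:
            hit.add((int(kk[a]), int(jj[b]), int(ii[c])))
    if not hit:
        raise ValueError("segment occupies no voxels (outside the grid?)")
    return GridIndexSet(np.array(sorted(hit), dtype=int))


def smoc_segment(em: DensityGrid, model_density: DensityGrid,
                 vox: GridIndexSet,
                 mean_subtract: bool = False) -> float:
    """SMOC over a voxel set; ``mean_subtract=True`` gives the SCCC variant
    (local mean-subtracted cross-correlation) instead."""
    if not em.same_geometry(model_density):
        raise ValueError("EM and model grids have different geometry")
    if len(vox) == 0:
        raise ValueError("empty voxel set")
    vox.validate(em)
    a = vox.take(em)
    b = vox.take(model_density)
    if mean_subtract:
        a = a - a.mean()
        b = b - b.mean()
    denom = float(a @ a) * float(b @ b)
    if denom <= 0:
        raise ValueError("flat density over the segment mask")
    return float((a @ b) / np.sqrt(denom))


@dataclass
class SMOCProfile:
    """Per-residue SMOC scores with segment provenance."""
    per_residue: dict[tuple[str, int], float]
    segments: list[tuple[ResidueSegment, float]] = field(default_factory=list)
    stage: str = ""

    def residues(self) -> list[tuple[str, int]]:
        return list(self.per_residue)

    def scores(self) -> np.ndarray:
        return np.array(list(self.per_residue.values()), dtype=float)

    def to_frame(self) -> pd.DataFrame:
        labels = {}
        for seg, _ in self.segments:
            for r in seg.res_seqs:
                labels[(seg.chain_id, r)] = seg.label
        rows = [(c, r, labels.get((c, r), ""), s)
                for (c, r), s in self.per_residue.items()]
        return pd.DataFrame(rows, columns=["chain", "res_seq",
                                           "segment_label", "smoc"])

    def to_tsv(self, path: str, zscores: "ZScoreProfile | None" = None) -> None:
        df = self.to_frame()
        if zscores is not None:
            df["z"] = [zscores.per_residue[key] for key in self.per_residue]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "SMOCProfile":
        df = pd.read_csv(path, sep="\t")
        per_res = {(str(r.chain), int(r.res_seq)): float(r.smoc)
                   for r in df.itertuples()}
        return cls(per_res, stage=str(path))


@dataclass
class ZScoreProfile:
    """Z = (s_r - mu) / sigma over all residues (population sigma)."""
    per_residue: dict[tuple[str, int], float]
    mu: float
    sigma: float


def smoc_profile(em: DensityGrid, structure: ModelStructure,
                 sses: SSEAnnotation, resolution: float,
                 window: int = DEFAULT_WINDOW,
                 radius: float | None = None,
                 stage: str = "",
                 model_density: DensityGrid | None = None,
                 sigma_factor: float | None = None) -> SMOCProfile:
    """Per-residue SMOC profile.

    Residues inside an SSE segment get that segment's SMOC; every loop
    residue gets the SMOC of the ``window``-residue stretch centered on it.
    Windows are kept inside the loop run when the run is long enough
    (shifted inward at SSE boundaries and chain termini), and otherwise
    extended over flanking residues, shrinking only at chain ends, so the
    profile is total: every residue receives exactly one score.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    sses.validate(structure)
    for key in structure.residue_keys():
        if not any(a.element != "H" for a in structure.residue_atoms(key)):
            raise ValueError(f"residue {key} has no heavy atoms")
    sim_kwargs = {}
    if sigma_factor is not None:
        sim_kwargs["sigma_factor"] = sigma_factor
    if model_density is None:
        model_density = simulate_density(structure, resolution, grid=em,
                                         **sim_kwargs)
    per_res: dict[tuple[str, int], float] = {}
    segments: list[tuple[ResidueSegment, float]] = []
    for chain in structure.chains():
        res_seqs = [k[1] for k in structure.chain_residues(chain)]
        in_sse = {r: sses.segment_of(chain, r) is not None for r in res_seqs}
        # SSE segments first
        n_sse = 0
        for seg in sses.segments:
            if seg.chain_id != chain:
                continue
            n_sse += 1
            label = ("H" if seg.kind == "helix" else "S") + str(n_sse)
            members = [r for r in res_seqs if seg.start <= r <= seg.end]
            rseg = ResidueSegment(chain, members, label=label)
            vox = segment_voxels(em, structure, rseg, radius)
            score = smoc_segment(em, model_density, vox)
            segments.append((rseg, score))
            for r in members:
                per_res[(chain, r)] = score
        # loop runs
        pos = {r: i for i, r in enumerate(res_seqs)}
        runs = _loop_runs(res_seqs, in_sse)
        for run in runs:
            label = f"loop {run[0]}-{run[-1]}"
            for r in run:
                widx = _window_indices(pos[r], pos[run[0]], pos[run[-1]],
                                       len(res_seqs), window)
                wres = [res_seqs[i] for i in widx]
                wseg = ResidueSegment(chain, wres, label=label,
                                      allow_breaks=True)
                vox = segment_voxels(em, structure, wseg, radius)
                per_res[(chain, r)] = smoc_segment(em, model_density, vox)
            segments.append((ResidueSegment(chain, run, label=label,
                                            allow_breaks=True),
                             float(np.mean([per_res[(chain, r)]
                                            for r in run]))))
    return SMOCProfile(per_res, segments, stage=stage)


def _loop_runs(res_seqs: list[int], in_sse: dict[int, bool]) -> list[list[int]]:
    runs: list[list[int]] = []
    current: list[int] = []
    for r in res_seqs:
        if in_sse[r]:
            if current:
                runs.append(current)
                current = []
        else:
            current.append(r)
    if current:
        runs.append(current)
    return runs


def _window_indices(center: int, run_lo: int, run_hi: int, chain_len: int,
                    window: int) -> list[int]:
    """Chain positions covered by a loop window centered at ``center``.

    Prefers a window of full width inside [run_lo, run_hi]; when the run is
    shorter than ``window`` the window extends over flanking residues,
    clipped (shrunk) only at the chain termini.
    """
    half = window // 2
    run_len = run_hi - run_lo + 1
    if run_len >= window:
        lo = min(max(center - half, run_lo), run_hi - window + 1)
        return list(range(lo, lo + window))
    lo = center - half
    hi = center + half
    if lo < 0:
        hi = min(hi - lo, chain_len - 1)
        lo = 0
    if hi > chain_len - 1:
        lo = max(0, lo - (hi - (chain_len - 1)))
        hi = chain_len - 1
    return list(range(lo, hi + 1))


def smoc_zscores(profile: SMOCProfile) -> ZScoreProfile:
    """Z-scores of the per-residue SMOC profile (population sigma)."""
    scores = profile.scores()
    if len(scores) < 2:
        raise ValueError("need at least two residues for Z-scores")
    mu = float(scores.mean())
    sigma = float(scores.std())  # population SD
    if sigma == 0:
        warnings.warn("constant SMOC profile; all Z-scores set to 0",
                      stacklevel=2)
        z = {key: 0.0 for key in profile.per_residue}
        return ZScoreProfile(z, mu, 0.0)
    z = {key: (s - mu) / sigma for key, s in profile.per_residue.items()}
    return ZScoreProfile(z, mu, sigma)


def flag_poor_segments(z: ZScoreProfile, sses: SSEAnnotation,
                       threshold: float = -1.0,
                       min_run: int = 3) -> list[ResidueSegment]:
    """Maximal runs of consecutive residues with Z below ``threshold``.

    Runs shorter than ``min_run`` are dropped. Each run is labelled with its
    containing SSE when it lies inside one, else as a loop.
    """
    if threshold >= 0:
        raise ValueError("threshold must be negative (Z-units below mean)")
    chains: dict[str, list[int]] = {}
    for c, r in z.per_residue:
        chains.setdefault(c, []).append(r)
    out: list[ResidueSegment] = []
    for chain, res_seqs in chains.items():
        run: list[int] = []
        for r in res_seqs + [None]:  # type: ignore[list-item]
            below = r is not None and z.per_residue[(chain, r)] < threshold
            if below and (not run or r == run[-1] + 1):
                run.append(r)
                continue
            if len(run) >= min_run:
                seg = sses.segment_of(chain, run[0])
                if seg is not None and seg.start <= run[-1] <= seg.end:
                    label = f"{seg.kind} {run[0]}-{run[-1]}"
                else:
                    label = f"loop {run[0]}-{run[-1]}"
                out.append(ResidueSegment(chain, run, label=label))
            run = [r] if below else []
    return out


def compare_profiles(a: SMOCProfile, b: SMOCProfile) -> tuple[pd.DataFrame, dict]:
    """Per-residue SMOC change from stage a to stage b.

    Returns (table, summary) where table has columns chain, res_seq,
    smoc_a, smoc_b, delta and summary reports the fraction of residues
    strictly improved and the mean delta.
    """
    ka, kb = set(a.per_residue), set(b.per_residue)
    if ka != kb:
        only_a = sorted(ka - kb)
        only_b = sorted(kb - ka)
        raise ValueError(f"residue sets differ (only in a: {only_a[:5]}, "
                         f"only in b: {only_b[:5]})")
    rows = [(c, r, a.per_residue[(c, r)], b.per_residue[(c, r)],
             b.per_residue[(c, r)] - a.per_residue[(c, r)])
            for (c, r) in a.per_residue]
    df = pd.DataFrame(rows, columns=["chain", "res_seq", "smoc_a", "smoc_b",
                                     "delta"])
    summary = {
        "fraction_improved": float((df["delta"] > 0).mean()),
        "mean_delta": float(df["delta"].mean()),
    }
    return df, summary
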