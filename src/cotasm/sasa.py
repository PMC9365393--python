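"""Solvent-accessible surface area by the Shrake–Rupley sphere-point method.

Each atom is expanded by the probe radius (default 1.4 Å) and sampled with a
deterministic golden-section (Fibonacci) point lattice; a sample point is
accessible when it lies outside every neighbouring expanded sphere. Per-atom
ASA is the accessible fraction of the expanded sphere's area, and per-residue
ASA is the sum over member atoms. The lattice is fixed, so results are exactly
reproducible for a given ``n_points``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chemdata import MAX_ASA
from .structio import Chain, ComplexStructure

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
SURFACE_RASA_THRESHOLD = 0.25


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    k = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_sasa(
    centers: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom accessible surface area (Å²).

    ``centers`` is (n, 3); ``radii`` length n. Exactly coincident atoms of
    equal radius are tolerated: the later one is treated as fully occluded
    rather than double-counting the shared surface.
    """
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if centers.ndim != 2 or centers.shape[0] == 0:
        raise ValueError("empty atom list")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    n_atoms = centers.shape[0]
    expanded = radii + probe
    lattice = _sphere_points(n_points)

    tree = cKDTree(centers)
    max_reach = 2.0 * expanded.max()
    out = np.empty(n_atoms)
    eps = 1e-9
    for i in range(n_atoms):
        pts = centers[i] + expanded[i] * lattice
        neighbours = [j for j in tree.query_ball_point(centers[i], max_reach)
                      if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - centers[j], pts - centers[j])
            dc = np.dot(centers[i] - centers[j], centers[i] - centers[j])
            if dc < eps and expanded[j] >= expanded[i] - eps:
                if j < i:
                    accessible[:] = False  # duplicate atom: first one wins
                    break
                continue
            accessible &= d2 > (expanded[j] - eps) ** 2
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return out


@dataclass
class SasaResult:
    """Residue-level ASA for one chain in a given context."""
    chain_id: str
    context: str                      # "isolated" or "in_complex"
    residue_asa: dict[int, float]     # seq_pos -> Å²
    probe_radius: float = DEFAULT_PROBE
    n_points: int = DEFAULT_N_POINTS


def _gather(chains: list[Chain]):
    centers, radii, owner = [], [], []
    for ci, chain in enumerate(chains):
        for res in chain.residues:
            for atom in res.atoms:
                centers.append(atom.coords())
                radii.append(atom.radius)
                owner.append((ci, res.seq_pos))
    return np.array(centers), np.array(radii), owner


def chain_sasa(
    target: Chain,
    context_chains: list[Chain] | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Residue ASA of ``target``, optionally in the presence of other chains."""
    others = context_chains or []
    chains = [target] + [c for c in others if c is not target]
    centers, radii, owner = _gather(chains)
    per_atom = atom_sasa(centers, radii, probe=probe, n_points=n_points)
    residue_asa: dict[int, float] = {r.seq_pos: 0.0 for r in target.residues}
    for asa, (ci, seq_pos) in zip(per_atom, owner):
        if ci == 0:
            residue_asa[seq_pos] += asa
    return SasaResult(
        chain_id=target.chain_id,
        context="isolated" if not others else "in_complex",
        residue_asa=residue_asa,
        probe_radius=probe,
        n_points=n_points,
    )


def complex_sasa(
    cx: ComplexStructure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[str, SasaResult]:
    """Residue ASA of every chain in the context of the full complex."""
    centers, radii, owner = _gather(cx.chains)
    per_atom = atom_sasa(centers, radii, probe=probe, n_points=n_points)
    results = {
        c.chain_id: SasaResult(c.chain_id, "in_complex",
                               {r.seq_pos: 0.0 for r in c.residues},
                               probe, n_points)
        for c in cx.chains
    }
    for asa, (ci, seq_pos) in zip(per_atom, owner):
        results[cx.chains[ci].chain_id].residue_asa[seq_pos] += asa
    return results


@dataclass
class RelativeAsa:
    seq_pos: int
    aa: str
    rasa: float
    surface: bool


def relative_asa(
    res_asa: float,
    aa: str,
    max_table: dict[str, float] | None = None,
    threshold: float = SURFACE_RASA_THRESHOLD,
    seq_pos: int = 0,
) -> RelativeAsa | None:
    """rASA = ASA / max reference ASA; surface when strictly above threshold.

    Returns None (with the caller expected to warn) for residues absent from
    the reference table, e.g. unmapped nonstandard residues.
    """
    table = max_table if max_table is not None else MAX_ASA
    if aa not in table:
        return None
    rasa = res_asa / table[aa]
    return RelativeAsa(seq_pos=seq_pos, aa=aa, rasa=rasa, surface=rasa > threshold)


def chain_relative_asa(
    chain: Chain,
    result: SasaResult,
    max_table: dict[str, float] | None = None,
    threshold: float = SURFACE_RASA_THRESHOLD,
) -> list[RelativeAsa]:
    """Per-residue rASA entries for a chain, skipping unknown residues."""
    out: list[RelativeAsa] = []
    for res in chain.residues:
        entry = relative_asa(
            result.residue_asa[res.seq_pos], res.aa, max_table, threshold,
            seq_pos=res.seq_pos,
        )
        if entry is not None:
            out.append(entry)
    return out
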