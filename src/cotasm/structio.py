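"""Structure and metadata I/O, chain selection and data-set filtering.

Structures are multi-chain biological assemblies in Brookhaven PDB format.
Residue positions are 1-based indices into the full-length translated
sequence, so gaps in the observed structure retain native numbering; the
full length ``L`` either comes from a sequence-length table or falls back
to the maximum observed position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import pandas as pd

from .chemdata import (
    DEFAULT_RADIUS,
    NONSTANDARD_MAP,
    ONE_TO_THREE,
    THREE_TO_ONE,
    VDW_RADII,
)


@dataclass
class Atom:
    element: str
    x: float
    y: float
    z: float
    radius: float

    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Residue:
    seq_pos: int          # 1-based position in the full-length sequence
    aa: str               # one-letter code; "X" when no mapping exists
    atoms: list[Atom] = field(default_factory=list)
    nonstandard: bool = False


@dataclass
class Chain:
    chain_id: str
    protein_id: str
    residues: list[Residue] = field(default_factory=list)
    full_length: int | None = None   # L; None until resolved
    length_source: str = "observed"  # "table" or "observed"

    @property
    def observed_count(self) -> int:
        return len(self.residues)

    @property
    def L(self) -> int:
        if self.full_length is not None:
            return self.full_length
        return max(r.seq_pos for r in self.residues)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class ComplexStructure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    assembly_label: str = "1"

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in complex {self.id!r}")

    @property
    def n_subunits(self) -> int:
        return len(self.chains)

    def validate(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in complex {self.id!r}")
        for c in self.chains:
            pos = [r.seq_pos for r in c.residues]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError(
                    f"residue positions not strictly increasing in {self.id}/{c.chain_id}"
                )


@dataclass(frozen=True)
class ChainCandidate:
    """One observed chain for a protein, ranked when picking a representative."""
    protein_id: str
    chain_ref: str           # "<complex_id>/<chain_id>"
    seq_identity: float
    n_unique_subunits: int
    n_atoms: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.seq_identity <= 1.0:
            raise ValueError("seq_identity must be a fraction in [0, 1]")


@dataclass
class FilterConfig:
    min_completeness: float = 0.70
    large_iface: float = 800.0   # Å², multi-interface inclusion rule
    max_subunits: int = 10       # exclusion at >= this count
    min_chain_len: int = 51      # chains must exceed 50 residues

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class FilterReport:
    complex_id: str
    chain_id: str | None
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (not self.reasons):
            raise ValueError("passed must mirror an empty reason list")


class StructureError(ValueError):
    pass


def _map_residue_name(name: str) -> tuple[str, bool]:
    name = name.strip().upper()
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name], False
    if name in NONSTANDARD_MAP:
        return NONSTANDARD_MAP[name], True
    return "X", True


def read_structure(
    path: str | Path,
    complex_id: str | None = None,
    bead_radius: float | None = None,
) -> ComplexStructure:
    """Read a PDB file into a :class:`ComplexStructure`.

    Only model 1 is used, the first altloc of each atom is kept, and
    heteroatoms (waters, ligands) are excluded. Nonstandard residues are
    mapped to canonical equivalents where a mapping exists, otherwise kept
    for geometry but flagged. ``bead_radius`` overrides the element-based
    van der Waals radius, for coarse-grained bead models.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path} contains no models")
    st.setup_entities()
    model = st[0]

    cx = ComplexStructure(id=complex_id or path.stem)
    for gchain in model:
        chain = Chain(chain_id=gchain.name, protein_id=gchain.name)
        for gres in gchain:
            if gres.het_flag == "H" and gres.name not in NONSTANDARD_MAP:
                continue  # true heteroatoms; mapped modified residues stay
            aa, nonstd = _map_residue_name(gres.name)
            res = Residue(seq_pos=gres.seqid.num, aa=aa, nonstandard=nonstd)
            seen_names: set[str] = set()
            for atom in gres:
                if atom.element.is_hydrogen:
                    continue
                if atom.name in seen_names:
                    continue  # keep first altloc only
                seen_names.add(atom.name)
                elem = atom.element.name.upper()
                radius = bead_radius if bead_radius is not None else VDW_RADII.get(
                    elem, DEFAULT_RADIUS
                )
                res.atoms.append(
                    Atom(elem, atom.pos.x, atom.pos.y, atom.pos.z, radius)
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chain.residues.sort(key=lambda r: r.seq_pos)
            cx.chains.append(chain)
        else:
            raise StructureError(f"chain {gchain.name!r} in {path} has no residues")
    if not cx.chains:
        raise StructureError(f"{path} has no polymer chains")
    cx.validate()
    return cx


def write_structure(cx: ComplexStructure, path: str | Path) -> None:
    """Write a complex as minimal ATOM/TER/END PDB records."""
    lines: list[str] = []
    serial = 1
    for chain in cx.chains:
        for res in chain.residues:
            res3 = ONE_TO_THREE.get(res.aa, "UNK")
            for atom in res.atoms:
                name = "CA" if atom.element == "C" else atom.element.rjust(2)
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s} {res3:>3s} {chain.chain_id[:1]}"
                    f"{res.seq_pos:4d}    {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {ONE_TO_THREE.get(chain.residues[-1].aa, 'UNK'):>3s} "
                     f"{chain.chain_id[:1]}{chain.residues[-1].seq_pos:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def select_representative_chain(
    candidates: Sequence[ChainCandidate],
) -> ChainCandidate:
    """Pick one chain per protein by lexicographic ranking.

    Ordering keys, all descending: sequence identity, number of unique
    subunits in the parent complex, number of atoms in the chain. Remaining
    ties break deterministically by chain reference ascending.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    return max(
        candidates,
        key=lambda c: (c.seq_identity, c.n_unique_subunits, c.n_atoms,
                       _neg_str(c.chain_ref)),
    )


class _neg_str(str):
    """String with reversed ordering, for ascending tie-break inside max()."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def filter_complex(
    cx: ComplexStructure,
    interfaces: Iterable,
    cfg: FilterConfig | None = None,
    chain_id: str | None = None,
) -> FilterReport:
    """Apply the data-set inclusion rules to a complex (and one chain).

    Complex-level: heteromeric complexes with >= ``max_subunits`` subunits
    are excluded from multi-interface analyses. Chain-level (when
    ``chain_id`` is given): the chain must be at least 70% complete,
    longer than 50 observed residues, and must form pairwise interfaces
    above ``large_iface`` Å² with at least two different subunits.
    """
    cfg = cfg or FilterConfig()
    reasons: list[str] = []
    if cx.n_subunits >= cfg.max_subunits:
        reasons.append("too_many_subunits")
    if chain_id is not None:
        chain = cx.chain(chain_id)
        if chain.observed_count / chain.L < cfg.min_completeness:
            reasons.append("chain_incomplete")
        if chain.observed_count < cfg.min_chain_len:
            reasons.append("short_chain")
        partners = set()
        for iface in interfaces:
            a, b = iface.chain_pair
            if iface.bsa_total > cfg.large_iface:
                if a == chain_id:
                    partners.add(b)
                elif b == chain_id:
                    partners.add(a)
        if len(partners) < 2:
            reasons.append("too_few_large_interfaces")
    return FilterReport(cx.id, chain_id, passed=not reasons, reasons=reasons)


METADATA_COLUMNS = [
    "protein_id", "chain_id", "symmetry", "cotranslational",
    "onset", "age_class", "operon", "localisation",
]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-protein metadata TSV (header per METADATA_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return df


def apply_length_table(cx: ComplexStructure, lengths: dict[str, int]) -> None:
    """Attach full-length L per chain from a protein_id -> length table."""
    for chain in cx.chains:
        if chain.protein_id in lengths:
            chain.full_length = int(lengths[chain.protein_id])
            chain.length_source = "table"
        else:
            chain.full_length = max(r.seq_pos for r in chain.residues)
            chain.length_source = "observed"
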