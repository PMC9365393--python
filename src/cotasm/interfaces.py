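"""Pairwise buried interfaces and every per-interface / per-subunit metric.

The buried surface area (BSA) of a subunit pair is the per-residue loss of
solvent-accessible area of each subunit between isolation and the presence
of the partner. From the residue-level build-up during N-to-C synthesis the
module derives interface midpoints, first/last translated interfaces of
multi-interface subunits, and the relative location / translational distance
/ size-difference metrics, plus contact- and surface-composition properties
used by the contact-based affinity model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chemdata import APOLAR_AA, CHARGED_AA, NEGATIVE_AA, POSITIVE_AA, residue_class
from .sasa import (
    DEFAULT_N_POINTS,
    DEFAULT_PROBE,
    SURFACE_RASA_THRESHOLD,
    chain_relative_asa,
    chain_sasa,
    complex_sasa,
)
from .structio import Chain, ComplexStructure

#: Minimum area for a biologically significant interface (Å²).
MIN_INTERFACE_AREA = 400.0
#: Area above which an interface counts towards multi-interface inclusion (Å²).
LARGE_INTERFACE_AREA = 800.0
#: Per-residue BSA below this is numerical noise, not an interface residue (Å²).
RESIDUE_BSA_TOL = 1e-6


@dataclass
class Interface:
    """One subunit:subunit buried interface, with both residue-level sides."""
    complex_id: str
    chain_pair: tuple[str, str]
    per_residue_bsa: dict[str, dict[int, float]]  # chain_id -> seq_pos -> Å²
    aa_by_pos: dict[str, dict[int, str]]
    homomeric: bool

    @property
    def interface_id(self) -> str:
        return f"{self.complex_id}:{self.chain_pair[0]}-{self.chain_pair[1]}"

    def side(self, chain_id: str) -> dict[int, float]:
        return self.per_residue_bsa[chain_id]

    def bsa_side(self, chain_id: str) -> float:
        return float(sum(self.side(chain_id).values()))

    @property
    def bsa_total(self) -> float:
        """Mean of the two buried sides (the pair's interface size)."""
        a, b = self.chain_pair
        return 0.5 * (self.bsa_side(a) + self.bsa_side(b))

    def apolar_side(self, chain_id: str) -> float:
        aa = self.aa_by_pos[chain_id]
        return float(
            sum(v for pos, v in self.side(chain_id).items()
                if aa.get(pos) in APOLAR_AA)
        )

    def residues(self, chain_id: str) -> list[int]:
        return sorted(p for p, v in self.side(chain_id).items()
                      if v > RESIDUE_BSA_TOL)

    def first_res(self, chain_id: str) -> int:
        return self.residues(chain_id)[0]

    def last_res(self, chain_id: str) -> int:
        return self.residues(chain_id)[-1]

    def midpoint(self, chain_id: str) -> int:
        return interface_midpoint(self.side(chain_id))


def pairwise_interfaces(
    cx: ComplexStructure,
    probe: float = DEFAULT_PROBE,
    min_area: float | None = MIN_INTERFACE_AREA,
    n_points: int = DEFAULT_N_POINTS,
    pairwise_context: bool = True,
) -> list[Interface]:
    """Buried interfaces between all subunit pairs of a complex.

    With ``pairwise_context`` (default) a side's in-complex ASA is computed
    in the presence of the partner chain only, matching the additivity
    assumption of assembly-order prediction; set it False to bury against
    the full complex instead. Interfaces whose size is <= ``min_area``
    (default 400 Å²) are dropped; pass ``min_area=None`` to keep all
    non-empty contacts.
    """
    if cx.n_subunits < 2:
        return []
    iso = {
        c.chain_id: chain_sasa(c, probe=probe, n_points=n_points)
        for c in cx.chains
    }
    full = None if pairwise_context else complex_sasa(cx, probe, n_points)

    out: list[Interface] = []
    chains = cx.chains
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            a, b = chains[i], chains[j]
            per_res: dict[str, dict[int, float]] = {}
            for target, partner in ((a, b), (b, a)):
                if pairwise_context:
                    in_ctx = chain_sasa(target, [partner], probe, n_points)
                else:
                    in_ctx = full[target.chain_id]
                iso_res = iso[target.chain_id].residue_asa
                buried = {
                    pos: max(0.0, iso_res[pos] - ctx_asa)
                    for pos, ctx_asa in in_ctx.residue_asa.items()
                }
                per_res[target.chain_id] = {
                    pos: v for pos, v in buried.items() if v > RESIDUE_BSA_TOL
                }
            iface = Interface(
                complex_id=cx.id,
                chain_pair=(a.chain_id, b.chain_id),
                per_residue_bsa=per_res,
                aa_by_pos={
                    c.chain_id: {r.seq_pos: r.aa for r in c.residues}
                    for c in (a, b)
                },
                homomeric=(a.protein_id == b.protein_id),
            )
            if not per_res[a.chain_id] and not per_res[b.chain_id]:
                continue
            if min_area is not None and iface.bsa_total <= min_area:
                continue
            out.append(iface)
    return out


def apolar_area(iface: Interface, chain_id: str | None = None) -> float:
    """Apolar buried area: BSA summed over A,F,G,I,L,V,M,P,Y residues."""
    if chain_id is not None:
        return iface.apolar_side(chain_id)
    a, b = iface.chain_pair
    return 0.5 * (iface.apolar_side(a) + iface.apolar_side(b))


def interface_midpoint(per_residue_bsa: dict[int, float]) -> int:
    """Residue at which half the interface's buried area is reached.

    Smallest sequence position whose N-to-C cumulative per-residue BSA
    reaches half of the side's total, so a single-residue interface is its
    own midpoint.
    """
    if not per_residue_bsa:
        raise ValueError("empty interface side")
    total = sum(per_residue_bsa.values())
    half = total / 2.0
    cum = 0.0
    for pos in sorted(per_residue_bsa):
        cum += per_residue_bsa[pos]
        if cum >= half - 1e-12:
            return pos
    return max(per_residue_bsa)  # pragma: no cover - unreachable


def relative_interface_location(i: int, L: int) -> float:
    """(i - 1) / (L - 1): 0 at the N terminus, 1 at the C terminus."""
    if L < 2:
        raise ValueError("sequence length must be at least 2")
    if not 1 <= i <= L:
        raise ValueError(f"midpoint {i} outside sequence 1..{L}")
    return (i - 1) / (L - 1)


def is_n_terminal(i: int, L: int) -> bool:
    """N-terminal-half interface: relative location <= 0.5 (boundary to N)."""
    return relative_interface_location(i, L) <= 0.5


@dataclass
class SubunitProfile:
    """Ordered interface view of one chain: translational build-up metrics."""
    protein_id: str
    chain_id: str
    complex_id: str
    L: int
    interfaces: list[Interface] = field(default_factory=list)

    def retained(self, min_area: float = MIN_INTERFACE_AREA) -> list[Interface]:
        return [i for i in self.interfaces if i.bsa_total > min_area]

    def heteromeric(self, min_area: float = MIN_INTERFACE_AREA) -> list[Interface]:
        return [i for i in self.retained(min_area) if not i.homomeric]

    def cumulative_buildup(self, iface: Interface) -> dict[int, float]:
        side = iface.side(self.chain_id)
        cum, out = 0.0, {}
        for pos in sorted(side):
            cum += side[pos]
            out[pos] = cum
        return out


class NestedInterfacesError(ValueError):
    """First and last interface coincide: the interface set fully nests."""


def first_last_interfaces(
    profile: SubunitProfile,
    min_area: float = MIN_INTERFACE_AREA,
) -> tuple[Interface, Interface]:
    """First and last translated interfaces of a multi-interface subunit.

    The first interface exposes the most N-terminal interface residue; the
    last, symmetrically, exposes the most C-terminal one. Ties on the
    extreme residue go to the larger interface. A subunit whose interfaces
    fully nest (first == last) is excluded from first/last analyses.
    """
    cid = profile.chain_id
    retained = profile.retained(min_area)
    if len(retained) < 2:
        raise ValueError(
            f"{profile.complex_id}/{cid}: not a multi-interface subunit"
        )
    first = min(retained, key=lambda i: (i.first_res(cid), -i.bsa_total))
    last = max(retained, key=lambda i: (i.last_res(cid), i.bsa_total))
    if first is last:
        raise NestedInterfacesError(
            f"{profile.complex_id}/{cid}: interfaces fully nested"
        )
    return first, last


def relative_translational_distance(f_first: int, f_last: int, L: int) -> float:
    """(f_last - f_first) / L for the first residues of the two interfaces."""
    if not (1 <= f_first <= f_last <= L):
        raise ValueError("require 1 <= f_first <= f_last <= L")
    return (f_last - f_first) / L


def relative_size_difference(bsa_first: float, bsa_last: float) -> float:
    """(BSA_first - BSA_last) / (BSA_first + BSA_last), in [-1, 1]."""
    total = bsa_first + bsa_last
    if total <= 0:
        raise ValueError("both interface areas are zero")
    return (bsa_first - bsa_last) / total


@dataclass
class ContactSet:
    """Residue-residue contacts of one chain pair within a distance cutoff."""
    chain_pair: tuple[str, str]
    cutoff: float
    pairs: list[tuple[int, int, float]]           # (res_a, res_b, min dist Å)
    class_counts: dict[str, int]

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)


CONTACT_CLASSES = [
    "charged-charged", "charged-polar", "charged-apolar",
    "polar-polar", "polar-apolar", "apolar-apolar",
]


def _class_pair(a: str, b: str) -> str:
    order = {"charged": 0, "polar": 1, "apolar": 2}
    ca, cb = residue_class(a), residue_class(b)
    if order[ca] > order[cb]:
        ca, cb = cb, ca
    return f"{ca}-{cb}"


def residue_contacts(
    cx: ComplexStructure,
    pair: tuple[str, str],
    cutoff: float = 5.5,
) -> ContactSet:
    """Residue pairs of two chains with min heavy-atom distance <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a, b = cx.chain(pair[0]), cx.chain(pair[1])

    def flat(chain: Chain):
        coords, pos, aa = [], [], {}
        for res in chain.residues:
            aa[res.seq_pos] = res.aa
            for atom in res.atoms:
                coords.append(atom.coords())
                pos.append(res.seq_pos)
        return np.array(coords), np.array(pos), aa

    ca, pa, aa_a = flat(a)
    cb, pb, aa_b = flat(b)
    tree_b = cKDTree(cb)
    best: dict[tuple[int, int], float] = {}
    hits = tree_b.query_ball_point(ca, cutoff)
    for ia, js in enumerate(hits):
        for jb in js:
            d = float(np.linalg.norm(ca[ia] - cb[jb]))
            key = (int(pa[ia]), int(pb[jb]))
            if d < best.get(key, math.inf):
                best[key] = d
    pairs = [(ra, rb, d) for (ra, rb), d in sorted(best.items())]
    counts = {c: 0 for c in CONTACT_CLASSES}
    for ra, rb, _ in pairs:
        counts[_class_pair(aa_a[ra], aa_b[rb])] += 1
    return ContactSet(pair, cutoff, pairs, counts)


@dataclass
class SurfaceComposition:
    nis_a: float      # % apolar surface residues
    nis_c: float      # % charged surface residues
    frac_pos: float   # fraction of R+K in the full sequence
    frac_neg: float   # fraction of D+E
    pi: float | None = None


def nis_parameters(
    chain: Chain,
    in_complex_asa,
    threshold: float = SURFACE_RASA_THRESHOLD,
) -> tuple[float, float]:
    """Non-interacting-surface apolar and charged percentages of a subunit.

    Surface residues are those with rASA > ``threshold`` in the complexed
    chain context; the percentages are over surface residues only.
    """
    entries = chain_relative_asa(chain, in_complex_asa, threshold=threshold)
    surface = [e for e in entries if e.surface]
    if not surface:
        raise ValueError(f"chain {chain.chain_id}: no surface residues")
    n = len(surface)
    nis_a = 100.0 * sum(e.aa in APOLAR_AA for e in surface) / n
    nis_c = 100.0 * sum(e.aa in CHARGED_AA for e in surface) / n
    return nis_a, nis_c


def charged_fractions(sequence: str) -> tuple[float, float]:
    """Fractions of positively (R+K) and negatively (D+E) charged residues."""
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    pos = sum(aa in POSITIVE_AA for aa in sequence) / n
    neg = sum(aa in NEGATIVE_AA for aa in sequence) / n
    return pos, neg


def interpolate_pi(curve: list[tuple[float, float]]) -> float:
    """Isoelectric point: linear interpolation of a pH ~ net-charge curve
    at charge = 0. The curve must be pH-ascending and bracket zero."""
    if len(curve) < 2:
        raise ValueError("titration curve needs at least two points")
    phs = [p for p, _ in curve]
    if any(b <= a for a, b in zip(phs, phs[1:])):
        raise ValueError("pH values must be strictly ascending")
    for (ph1, q1), (ph2, q2) in zip(curve, curve[1:]):
        if q1 == 0.0:
            return ph1
        if q1 > 0.0 >= q2 or q1 < 0.0 <= q2:
            return ph1 + (0.0 - q1) * (ph2 - ph1) / (q2 - q1)
    if curve[-1][1] == 0.0:
        return curve[-1][0]
    sign = "positive" if curve[-1][1] > 0 else "negative"
    raise ValueError(f"no zero crossing: charge stays {sign} over the curve")


def mean_fragment_pi(fragment_pis: list[float]) -> float:
    """Protein pI for fragmented models: arithmetic mean of fragment pIs."""
    if not fragment_pis:
        raise ValueError("no fragment pI values")
    return float(np.mean(fragment_pis))


#: Coefficient keys required by the contact-based affinity model.
AFFINITY_COEFFICIENT_KEYS = ["intercept", *CONTACT_CLASSES, "nis_a", "nis_c"]


def predict_affinity(
    contacts: ContactSet,
    nis: tuple[float, float],
    coefficients: dict[str, float],
) -> float:
    """Linear contact-based binding-affinity model (ΔG, kcal/mol).

    ΔG = intercept + Σ w_class · count_class + w_a · NIS_a + w_c · NIS_c.
    All coefficients must be supplied; none are baked in.
    """
    missing = [k for k in AFFINITY_COEFFICIENT_KEYS if k not in coefficients]
    if missing:
        raise KeyError(f"missing affinity coefficients: {missing}")
    dg = coefficients["intercept"]
    for cls in CONTACT_CLASSES:
        dg += coefficients[cls] * contacts.class_counts.get(cls, 0)
    dg += coefficients["nis_a"] * nis[0] + coefficients["nis_c"] * nis[1]
    return float(dg)


def build_profiles(
    cx: ComplexStructure,
    interfaces: list[Interface],
) -> dict[str, SubunitProfile]:
    """Group a complex's interfaces into per-chain subunit profiles."""
    profiles = {
        c.chain_id: SubunitProfile(
            protein_id=c.protein_id, chain_id=c.chain_id,
            complex_id=cx.id, L=c.L,
        )
        for c in cx.chains
    }
    for iface in interfaces:
        for cid in iface.chain_pair:
            if iface.side(cid):
                profiles[cid].interfaces.append(iface)
    return profiles
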