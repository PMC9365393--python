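"""Synthetic structures, cohorts, onsets and titration curves.

The generators emulate the statistical structure the analysis assumes so
the whole pipeline is testable without downloads:

* :func:`generate_complex` builds coarse-grained bead complexes (one
  3.0 Å sphere per residue) in which exactly the planned sequence windows
  of paired chains are in contact, so buried areas, midpoints and contacts
  have controllable ground truth.
* :func:`generate_cohort` draws per-subunit first/last interface areas
  from a paired log-normal model - a shared subunit-level size factor plus
  interface-level residual - with the first translated interface inflated
  by a factor delta on average, plus cotranslational flags, age/operon
  labels, and assembly-onset positions placed at designated interface
  midpoints (shifted by the ribosome tunnel, with Gaussian noise).
* :func:`generate_titration_curve` produces Henderson-Hasselbalch pH ~ net
  charge curves from sequence, for the isoelectric-point interpolation.

Every generator takes an explicit seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemdata import ACIDIC_AA, BASIC_AA, PKA_CTERM, PKA_NTERM, PKA_SIDECHAIN
from .interfaces import Interface, SubunitProfile
from .structio import Atom, Chain, ComplexStructure, Residue

BEAD_RADIUS = 3.0       # Å, one sphere per residue
_ROW_SPACING = 4.0      # Å between consecutive beads within a contact row
_ROW_GAP = 6.0          # Å between the two rows of a contact block
_BLOCK_SPACING = 150.0  # Å between interface blocks
_FREE_SPACING = 12.0    # Å grid for non-interface beads (no mutual occlusion)


@dataclass
class InterfacePlan:
    chain_a: str
    chain_b: str
    window_a: tuple[int, int]   # inclusive 1-based residue range on chain_a
    window_b: tuple[int, int]
    size_rank: int = 0          # 1 = planned largest


@dataclass
class ComplexSpec:
    complex_id: str
    chain_lengths: dict[str, int]            # chain id -> residue count
    plan: list[InterfacePlan] = field(default_factory=list)
    protein_ids: dict[str, str] | None = None  # same id => homomeric pair
    bead_radius: float = BEAD_RADIUS
    seed: int = 0

    @property
    def n_chains(self) -> int:
        return len(self.chain_lengths)


class InfeasiblePlanError(ValueError):
    pass


def _check_plan(spec: ComplexSpec) -> None:
    used: dict[str, set[int]] = {c: set() for c in spec.chain_lengths}
    for p in spec.plan:
        for cid, (lo, hi) in ((p.chain_a, p.window_a), (p.chain_b, p.window_b)):
            if cid not in spec.chain_lengths:
                raise InfeasiblePlanError(f"unknown chain {cid!r} in plan")
            L = spec.chain_lengths[cid]
            if not (1 <= lo <= hi <= L):
                raise InfeasiblePlanError(
                    f"window {lo}-{hi} outside chain {cid} (L={L})")
            window = set(range(lo, hi + 1))
            if used[cid] & window:
                raise InfeasiblePlanError(
                    f"overlapping interface windows on chain {cid}: a residue "
                    "cannot sit in two planned contact blocks")
            used[cid] |= window


def generate_complex(spec: ComplexSpec) -> ComplexStructure:
    """Bead-model complex realising a planned set of pairwise interfaces.

    Each planned interface becomes an isolated contact block: the two
    windows' beads form parallel rows 6 Å apart (well within occlusion
    reach of 3.0 Å beads and a 1.4 Å probe), and blocks sit 150 Å apart so
    interfaces are independent. Residues outside every window live on a
    sparse per-chain grid far from all blocks, keeping them fully solvent
    exposed. Realised buried area grows with window length, so the plan's
    size ranks are realised by choosing window lengths.
    """
    _check_plan(spec)
    rng = np.random.default_rng(spec.seed)
    protein_ids = spec.protein_ids or {c: f"P_{c}" for c in spec.chain_lengths}

    coords: dict[str, dict[int, np.ndarray]] = {
        c: {} for c in spec.chain_lengths
    }
    for k, p in enumerate(spec.plan):
        cx0 = k * _BLOCK_SPACING
        for row, (cid, (lo, hi)) in enumerate(
            ((p.chain_a, p.window_a), (p.chain_b, p.window_b))
        ):
            n = hi - lo + 1
            for idx, pos in enumerate(range(lo, hi + 1)):
                y = (idx - (n - 1) / 2.0) * _ROW_SPACING
                coords[cid][pos] = np.array([cx0, y, row * _ROW_GAP])
    # free (non-interface) residues: distant sparse grid, one zone per chain
    for ci, (cid, L) in enumerate(sorted(spec.chain_lengths.items())):
        free = [p for p in range(1, L + 1) if p not in coords[cid]]
        for idx, pos in enumerate(free):
            gx = -400.0 - ci * 200.0
            coords[cid][pos] = np.array([
                gx, (idx % 25) * _FREE_SPACING, (idx // 25) * _FREE_SPACING,
            ])

    aa_cycle = "ALDKVESRGF"  # mixed chemistry for classification tests
    chains = []
    for cid, L in sorted(spec.chain_lengths.items()):
        chain = Chain(chain_id=cid, protein_id=protein_ids[cid],
                      full_length=L, length_source="table")
        for pos in range(1, L + 1):
            x, y, z = coords[cid][pos] + rng.normal(0.0, 0.0, 3)
            chain.residues.append(
                Residue(seq_pos=pos, aa=aa_cycle[pos % len(aa_cycle)],
                        atoms=[Atom("C", float(x), float(y), float(z),
                                    spec.bead_radius)])
            )
        chains.append(chain)
    cx = ComplexStructure(id=spec.complex_id, chains=chains)
    cx.validate()
    return cx


@dataclass
class CohortSpec:
    """Study conditions for a synthetic multi-interface subunit cohort."""
    n_subunits: int = 150
    delta: float = 1.15            # mean first/last area ratio
    subunit_log_mean: float = np.log(1000.0)  # ~1000 Å² median interface
    subunit_log_sd: float = 0.7    # between-subunit size spread
    residual_log_sd: float = 0.25  # within-subunit interface spread
    n_extra_interfaces: int = 1    # interfaces between first and last
    cotrans_slope: float = 1.5     # logistic link of flag on log area
    cotrans_base_rate: float = 0.35
    age_mix: dict[str, float] = field(
        default_factory=lambda: {"ancient": 0.6, "more_recent": 0.4})
    operon_fraction: float = 0.4
    delta_by_operon: dict[bool, float] | None = None
    delta_by_age: dict[str, float] | None = None
    onset_noise: float = 5.0       # residues, sd of Gaussian onset noise
    tunnel_offset: int = 30
    homomeric_decoy_fraction: float = 0.0
    min_L: int = 300
    max_L: int = 600
    window_len: int = 21
    seed: int = 0


def _uniform_window_interface(
    complex_id: str, chain_id: str, partner: str,
    lo: int, hi: int, area: float, homomeric: bool,
) -> Interface:
    """Abstract interface: uniform per-residue area over a sequence window."""
    n = hi - lo + 1
    per_res = {pos: area / n for pos in range(lo, hi + 1)}
    return Interface(
        complex_id=complex_id,
        chain_pair=(chain_id, partner),
        per_residue_bsa={chain_id: per_res, partner: dict(per_res)},
        aa_by_pos={chain_id: {p: "L" for p in per_res},
                   partner: {p: "L" for p in per_res}},
        homomeric=homomeric,
    )


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, SubunitProfile]]:
    """Synthetic cohort of multi-interface heteromeric subunits.

    Returns ``(cohort, onsets, profiles)``: the per-protein cohort table
    joining areas with labels, the raw onset table (protein_id, onset),
    and abstract subunit profiles whose interfaces occupy disjoint
    sequence windows (first interface most N-terminal), usable directly by
    the onset-mapping and assembly stages. Onsets are placed at the
    midpoint of the designated (first) interface, shifted C-terminally by
    the tunnel offset, with Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    ages = list(spec.age_mix)
    age_p = np.array([spec.age_mix[a] for a in ages], dtype=float)
    age_p = age_p / age_p.sum()

    rows, onset_rows = [], []
    profiles: dict[str, SubunitProfile] = {}
    for i in range(spec.n_subunits):
        pid = f"SYN{i:04d}"
        L = int(rng.integers(spec.min_L, spec.max_L + 1))
        age = str(rng.choice(ages, p=age_p))
        operon = bool(rng.random() < spec.operon_fraction)
        delta = spec.delta
        if spec.delta_by_operon is not None:
            delta = spec.delta_by_operon[operon]
        elif spec.delta_by_age is not None:
            delta = spec.delta_by_age[age]

        mu = rng.normal(spec.subunit_log_mean, spec.subunit_log_sd)
        bsa_first = float(np.exp(
            mu + np.log(delta) + rng.normal(0.0, spec.residual_log_sd)))
        bsa_last = float(np.exp(mu + rng.normal(0.0, spec.residual_log_sd)))
        k = 2 + spec.n_extra_interfaces
        extras = [float(np.exp(mu + rng.normal(0.0, spec.residual_log_sd)))
                  for _ in range(spec.n_extra_interfaces)]

        # disjoint windows, one per interface, evenly spread over the chain
        block = L // k
        windows = []
        for j in range(k):
            centre = j * block + block // 2
            lo = max(1, centre - spec.window_len // 2)
            hi = min(L, lo + spec.window_len - 1)
            windows.append((lo, hi))
        areas = [bsa_first, *extras, bsa_last]
        profile = SubunitProfile(protein_id=pid, chain_id="A",
                                 complex_id=pid, L=L)
        for j, ((lo, hi), area) in enumerate(zip(windows, areas)):
            profile.interfaces.append(
                _uniform_window_interface(pid, "A", f"B{j}", lo, hi, area,
                                          homomeric=False)
            )
        designated = profile.interfaces[0]
        if rng.random() < spec.homomeric_decoy_fraction:
            # the onset-bearing interface is homomeric: its midpoint is the
            # nearest one, so the mapping must discard this record
            designated.homomeric = True
        profiles[pid] = profile

        midpoint = designated.midpoint("A")
        raw_onset = int(np.clip(round(
            midpoint + spec.tunnel_offset + rng.normal(0.0, spec.onset_noise)
        ), 1, L + spec.tunnel_offset))
        p_cotrans = 1.0 / (1.0 + np.exp(-(
            np.log(spec.cotrans_base_rate / (1 - spec.cotrans_base_rate))
            + spec.cotrans_slope * (np.log(bsa_first) - spec.subunit_log_mean)
        )))
        cotrans = bool(rng.random() < p_cotrans)

        f_first, f_last = windows[0][0], windows[-1][0]
        rows.append({
            "protein_id": pid, "chain_id": "A", "symmetry": "C1",
            "cotranslational": cotrans, "onset": raw_onset,
            "age_class": age, "operon": operon, "localisation": "cytoplasm",
            "L": L, "bsa_first": bsa_first, "bsa_last": bsa_last,
            "f_first": f_first, "f_last": f_last,
            "designated_interface": designated.interface_id,
            "midpoint_first": midpoint,
        })
        onset_rows.append({"protein_id": pid, "onset": raw_onset})
    cohort = pd.DataFrame(rows)
    onsets = pd.DataFrame(onset_rows)
    return cohort, onsets, profiles


def random_complex_spec(
    seed: int,
    min_chains: int = 2,
    max_chains: int = 4,
    chain_len: tuple[int, int] = (40, 80),
    window_len: tuple[int, int] = (8, 24),
) -> ComplexSpec:
    """Random feasible bead-complex spec (non-overlapping contact windows).

    Draws a random spanning set of chain pairs plus optional extra pairs,
    then allocates disjoint windows along each chain for its interfaces.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(min_chains, max_chains + 1))
    ids = [chr(65 + i) for i in range(n)]
    lengths = {c: int(rng.integers(*chain_len)) for c in ids}
    pairs = [(ids[i], ids[i + 1]) for i in range(n - 1)]      # spanning chain
    for i in range(n):
        for j in range(i + 2, n):
            if rng.random() < 0.3:
                pairs.append((ids[i], ids[j]))
    cursor = {c: 1 for c in ids}
    plan = []
    for a, b in pairs:
        w = int(rng.integers(*window_len))
        if (cursor[a] + w - 1 > lengths[a]) or (cursor[b] + w - 1 > lengths[b]):
            continue  # no room left on a chain: drop this pair
        plan.append(InterfacePlan(a, b, (cursor[a], cursor[a] + w - 1),
                                  (cursor[b], cursor[b] + w - 1)))
        cursor[a] += w + 2
        cursor[b] += w + 2
    return ComplexSpec(f"rnd{seed}", lengths, plan=plan, seed=seed)


def generate_titration_curve(
    sequence: str,
    pka_table: dict[str, float] | None = None,
    ph_min: float = 0.0,
    ph_max: float = 14.0,
    step: float = 0.1,
) -> list[tuple[float, float]]:
    """Henderson-Hasselbalch net charge of a sequence on a pH grid.

    Includes the free termini; the net charge is monotone non-increasing
    in pH, so the curve crosses zero exactly once for any sequence with at
    least one ionisable group of each sign.
    """
    if not sequence:
        raise ValueError("empty sequence")
    table = pka_table or PKA_SIDECHAIN
    ph = np.arange(ph_min, ph_max + step / 2, step)
    charge = np.zeros_like(ph)
    basic = [PKA_NTERM] + [table[aa] for aa in sequence
                           if aa in BASIC_AA and aa in table]
    acidic = [PKA_CTERM] + [table[aa] for aa in sequence
                            if aa in ACIDIC_AA and aa in table]
    for pka in basic:
        charge += 1.0 / (1.0 + 10.0 ** (ph - pka))
    for pka in acidic:
        charge -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return [(float(p), float(c)) for p, c in zip(ph, charge)]
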