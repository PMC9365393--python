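"""Mapping cotranslational assembly-onset positions to interfaces.

An assembly-onset is the sequence position being decoded by the ribosome
when cotranslational binding is detected. Because the nascent chain is
buried in the ribosome exit tunnel, 30 residues are subtracted from the
raw onset before mapping. The adjusted onset is assigned to the nearest
interface midpoint in the linear sequence - midpoint compression avoids
biasing the mapping towards large interfaces with many residues - and
onsets whose nearest midpoint belongs to a homomeric interface are
discarded (the homomeric interface is assumed to assemble in cis).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .interfaces import MIN_INTERFACE_AREA, Interface, SubunitProfile

TUNNEL_OFFSET = 30


@dataclass
class OnsetRecord:
    protein_id: str
    raw_onset: int
    adjusted_onset: int
    mapped_interface: str | None
    discard_reason: str | None = None   # homomeric | no_interface | beyond_length


def adjust_onset(raw: int, tunnel_offset: int = TUNNEL_OFFSET) -> int:
    """Shift a raw onset by the ribosome-tunnel length, clamped to 1."""
    if raw < 1:
        raise ValueError("onset positions are 1-based")
    return max(1, raw - tunnel_offset)


def map_onset_to_interface(
    pos: int,
    profile: SubunitProfile,
    min_area: float = MIN_INTERFACE_AREA,
) -> tuple[Interface | None, str | None]:
    """Nearest-midpoint interface for an adjusted onset position.

    Returns ``(interface, None)`` on success, or ``(None, reason)`` when
    the subunit has no retained interface or the nearest midpoint is
    homomeric. Equidistant midpoints resolve to the more N-terminal
    (earlier-translated) interface.
    """
    retained = profile.retained(min_area)
    if not retained:
        return None, "no_interface"
    cid = profile.chain_id
    nearest = min(retained, key=lambda i: (abs(pos - i.midpoint(cid)),
                                           i.midpoint(cid)))
    if nearest.homomeric:
        return None, "homomeric"
    return nearest, None


def map_onsets(
    profiles: dict[str, SubunitProfile],
    onsets: pd.DataFrame,
    tunnel_offset: int = TUNNEL_OFFSET,
    min_area: float = MIN_INTERFACE_AREA,
) -> list[OnsetRecord]:
    """Map a table of raw onsets (protein_id, onset) onto subunit profiles.

    Onsets for proteins absent from the profiles, or beyond the protein's
    full length, are logged in the record and skipped from mapping.
    """
    by_protein = {p.protein_id: p for p in profiles.values()}
    records: list[OnsetRecord] = []
    for row in onsets.itertuples(index=False):
        raw = int(row.onset)
        adjusted = adjust_onset(raw, tunnel_offset)
        profile = by_protein.get(row.protein_id)
        if profile is None:
            continue  # unjoinable: logged by caller via missing record
        if adjusted > profile.L:
            records.append(OnsetRecord(row.protein_id, raw, adjusted,
                                       None, "beyond_length"))
            continue
        iface, reason = map_onset_to_interface(adjusted, profile, min_area)
        records.append(
            OnsetRecord(
                row.protein_id, raw, adjusted,
                iface.interface_id if iface else None, reason,
            )
        )
    return records


def recovery_rate(
    profiles: dict[str, SubunitProfile],
    onsets: pd.DataFrame,
    designated: dict[str, str],
    tunnel_offset: int = TUNNEL_OFFSET,
    min_area: float = MIN_INTERFACE_AREA,
) -> tuple[float, int]:
    """Fraction of mappable onsets that recover their designated interface.

    An onset is mappable when the subunit's designated interface passes the
    area cutoff, so the rate measures the nearest-midpoint mapping itself
    rather than cutoff censoring. Returns ``(rate, n_mappable)``.
    """
    records = map_onsets(profiles, onsets, tunnel_offset, min_area)
    hits = total = 0
    for rec in records:
        profile = next(p for p in profiles.values()
                       if p.protein_id == rec.protein_id)
        target = designated[rec.protein_id]
        if not any(i.interface_id == target
                   for i in profile.retained(min_area)):
            continue
        total += 1
        hits += rec.mapped_interface == target
    if total == 0:
        raise ValueError("no mappable onsets")
    return hits / total, total


def annotate_cohort(
    profiles: dict[str, SubunitProfile],
    onsets: pd.DataFrame,
    tunnel_offset: int = TUNNEL_OFFSET,
    min_area: float = MIN_INTERFACE_AREA,
) -> pd.DataFrame:
    """Per-subunit cotranslational annotations for the paired comparisons.

    For every multi-interface heteromeric subunit with a mapped onset the
    row carries the mapped (cotranslationally forming) interface, its
    buried area on this subunit, and the mean area of the subunit's other
    heteromeric interfaces - the paired-comparison basis. Subunits with a
    single heteromeric interface or a discarded mapping carry NA columns.
    """
    records = {r.protein_id: r for r in map_onsets(
        profiles, onsets, tunnel_offset, min_area)}
    rows = []
    for profile in profiles.values():
        rec = records.get(profile.protein_id)
        het = profile.heteromeric(min_area)
        row = {
            "protein_id": profile.protein_id,
            "complex_id": profile.complex_id,
            "chain_id": profile.chain_id,
            "n_heteromeric_interfaces": len(het),
            "cotranslational_interface": None,
            "cotranslational_bsa": float("nan"),
            "other_mean_bsa": float("nan"),
            "discard_reason": rec.discard_reason if rec else "no_onset",
        }
        if rec is not None and rec.mapped_interface is not None:
            mapped = next(
                (i for i in het if i.interface_id == rec.mapped_interface), None
            )
            if mapped is not None and len(het) >= 2:
                others = [i for i in het if i is not mapped]
                cid = profile.chain_id
                row.update(
                    cotranslational_interface=mapped.interface_id,
                    cotranslational_bsa=mapped.bsa_side(cid),
                    other_mean_bsa=sum(i.bsa_side(cid) for i in others)
                    / len(others),
                    discard_reason=None,
                )
        rows.append(row)
    return pd.DataFrame(rows)
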