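"""Assembly-pathway prediction by interface-size additivity.

The predicted pathway is a greedy agglomeration over subunits: starting
from monomers, each step merges the two current components whose union
gains the largest summed pairwise buried area, under the assumption that
pairwise interfaces are additive. The step at which an interface's two
chains first share a component is its formation step; normalising the step
index to a 0-to-1 scale gives the interface's assembly order, with steps
at or below 0.5 classed as early.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .interfaces import MIN_INTERFACE_AREA, Interface


@dataclass
class AssemblyStep:
    merged: tuple[frozenset[str], frozenset[str]]
    gained_interfaces: list[str]
    gained_bsa: float


@dataclass
class AssemblyPathway:
    complex_id: str
    steps: list[AssemblyStep] = field(default_factory=list)

    @property
    def S(self) -> int:
        return len(self.steps)

    def step_of(self, interface_id: str) -> int:
        """1-based index of the step at which an interface forms."""
        for s, step in enumerate(self.steps, start=1):
            if interface_id in step.gained_interfaces:
                return s
        raise KeyError(f"interface {interface_id} not in pathway")


@dataclass
class InterfaceOrder:
    interface_id: str
    step_index: int
    normalized_order: float
    label: str  # "early" | "late"


def _pair_gain(
    c1: frozenset[str], c2: frozenset[str],
    interfaces: list[Interface],
) -> tuple[float, list[Interface]]:
    gained = [
        i for i in interfaces
        if (i.chain_pair[0] in c1 and i.chain_pair[1] in c2)
        or (i.chain_pair[0] in c2 and i.chain_pair[1] in c1)
    ]
    return sum(i.bsa_total for i in gained), gained


def predict_assembly_pathway(
    cx_id: str,
    interfaces: list[Interface],
) -> AssemblyPathway:
    """Greedy largest-gain agglomeration of a complex's subunits.

    Ties on gained area break deterministically by the lexicographically
    smallest (min chain id of one component, min chain id of the other)
    pair. Disconnected interface graphs are agglomerated per connected
    component; merging stops when no remaining pair gains area.
    """
    if not interfaces:
        raise ValueError("cannot predict a pathway without interfaces")
    chains: set[str] = set()
    for i in interfaces:
        chains.update(i.chain_pair)
    components = [frozenset([c]) for c in sorted(chains)]
    pathway = AssemblyPathway(complex_id=cx_id)

    while len(components) > 1:
        best = None
        for c1, c2 in combinations(components, 2):
            gain, gained = _pair_gain(c1, c2, interfaces)
            if gain <= 0:
                continue
            key = (-gain, tuple(sorted((min(c1), min(c2)))))
            if best is None or key < best[0]:
                best = (key, c1, c2, gain, gained)
        if best is None:
            break  # disconnected: remaining components never bind
        _, c1, c2, gain, gained = best
        pathway.steps.append(
            AssemblyStep(
                merged=(c1, c2),
                gained_interfaces=[i.interface_id for i in gained],
                gained_bsa=gain,
            )
        )
        components = [c for c in components if c is not c1 and c is not c2]
        components.append(c1 | c2)
    return pathway


def normalized_order(step_index: int, S: int) -> float:
    """(s - 1) / (S - 1) on a 0-to-1 scale; 0 for a single-step pathway."""
    if not 1 <= step_index <= S:
        raise ValueError("step index outside pathway")
    if S == 1:
        return 0.0
    return (step_index - 1) / (S - 1)


def classify_step(order: float) -> str:
    """Early when normalised order <= 0.5, late otherwise."""
    if not 0.0 <= order <= 1.0:
        raise ValueError("normalised order must lie in [0, 1]")
    return "early" if order <= 0.5 else "late"


def interface_orders(
    pathway: AssemblyPathway,
    interfaces: list[Interface],
    min_area: float | None = MIN_INTERFACE_AREA,
) -> list[InterfaceOrder]:
    """Normalised assembly order per interface.

    Sub-threshold interfaces contribute gained area inside the pathway but
    are not emitted as ordered interfaces unless ``min_area`` is None.
    """
    out = []
    for iface in interfaces:
        if min_area is not None and iface.bsa_total <= min_area:
            continue
        s = pathway.step_of(iface.interface_id)
        order = normalized_order(s, pathway.S)
        out.append(
            InterfaceOrder(iface.interface_id, s, order, classify_step(order))
        )
    return out
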