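"""Buried interface areas between residue selections, compared across states.

The buried surface area between two selections A and B is

    buried = ASA(A alone) + ASA(B alone) − ASA(A ∪ B)

i.e. the surface each partner loses on forming the contact; following the
PISA convention, the *interface area* is half the buried area.  Interface
area acts as a proxy for binding energy: a larger contact buries more
surface and generally indicates a more favourable interaction, with
interfaces above ~2000 Å² conventionally classed as strong-affinity.

Comparing the same interfaces in a resting and a transport state of an
assembly therefore gives a simple energetic reading of a conformational
switch: interfaces that grow on activation suggest the activated state sits
at a lower energy.

By default each interface is evaluated on the isolated A ∪ B subcomplex
(as when submitting the two contacting domains alone to PISA); the rest of
the assembly can optionally be included as occluding context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, sasa
from .structure_io import ConformerPair, DomainMap, ResidueKey, StructureModel, resolve_selection

logger = logging.getLogger(__name__)

__all__ = [
    "InterfaceArea",
    "InterfaceReport",
    "interface",
    "assembly_interface_report",
    "DEFAULT_AFFINITY_THRESHOLD",
]

DEFAULT_AFFINITY_THRESHOLD = 2000.0  # Å², strict greater-than => strong
_BURIED_TOL = 1e-6


@dataclass
class InterfaceArea:
    """Buried area between two selections in one state."""

    selection_a: str
    selection_b: str
    asa_a_isolated: float
    asa_b_isolated: float
    asa_complex: float
    state: str = ""

    def __post_init__(self) -> None:
        if self.buried < -_BURIED_TOL:
            raise ValueError(
                f"negative buried area ({self.buried:.3g} Å²) — inconsistent SASA inputs"
            )

    @property
    def buried(self) -> float:
        return self.asa_a_isolated + self.asa_b_isolated - self.asa_complex

    @property
    def interface_area(self) -> float:
        """Half the buried area (PISA convention)."""
        return self.buried / 2.0


@dataclass
class InterfaceReport:
    """Per-state interface areas for named selection pairs, with deltas.

    ``deltas`` holds interface_area(transport) − interface_area(resting) per
    pair name; ``affinity`` classes each per-state interface as strong iff
    its interface area exceeds the threshold (strict >).  Pairs resolvable
    in one state only are kept with a gap flag rather than dropped.
    """

    entries: list[InterfaceArea]
    deltas: dict[str, float]
    affinity_threshold: float = DEFAULT_AFFINITY_THRESHOLD
    gaps: list[str] = field(default_factory=list)

    def affinity_class(self, entry: InterfaceArea) -> str:
        return "strong" if entry.interface_area > self.affinity_threshold else "weak"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "state": e.state,
                "selection_a": e.selection_a,
                "selection_b": e.selection_b,
                "asa_a": e.asa_a_isolated,
                "asa_b": e.asa_b_isolated,
                "asa_complex": e.asa_complex,
                "buried": e.buried,
                "interface_area": e.interface_area,
                "affinity": self.affinity_class(e),
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows)

    def delta_frame(self) -> pd.DataFrame:
        rows = [{"pair": name, "delta_interface_area": d} for name, d in self.deltas.items()]
        return pd.DataFrame(rows)

    def total_delta(self) -> float:
        return float(sum(self.deltas.values()))


def interface(
    model: StructureModel,
    selection_a: list[ResidueKey],
    selection_b: list[ResidueKey],
    name_a: str = "A",
    name_b: str = "B",
    state: str = "",
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    context: list[ResidueKey] | None = None,
) -> InterfaceArea:
    """Buried area between two disjoint residue selections of one model.

    Three SASA evaluations are performed (A alone, B alone, A ∪ B); atoms
    outside the two selections are excluded throughout unless ``context``
    residues are supplied, in which case those atoms occlude (but do not
    contribute area to) all three evaluations.
    """
    if not selection_a or not selection_b:
        raise ValueError("selections must be non-empty")
    set_a, set_b = set(selection_a), set(selection_b)
    if set_a & set_b:
        raise ValueError("selections overlap")

    ctx = set(context) - set_a - set_b if context else set()

    def _asa_of(wanted: set[ResidueKey]) -> float:
        keys = wanted | ctx
        coords, radii, atoms = model.atom_records(keys)
        if coords.shape[0] == 0:
            raise ValueError("selection contains no atoms")
        result = sasa(coords, radii, probe=probe, n_points=n_points,
                      keys=[a.key for a in atoms])
        if not ctx:
            return result.total
        return float(sum(area for k, area in result.per_residue.items() if k in wanted))

    return InterfaceArea(
        selection_a=name_a,
        selection_b=name_b,
        asa_a_isolated=_asa_of(set_a),
        asa_b_isolated=_asa_of(set_b),
        asa_complex=_asa_of(set_a | set_b),
        state=state,
    )


def assembly_interface_report(
    pair: ConformerPair,
    domain_map: DomainMap,
    interface_spec: list[tuple[str, str]],
    affinity_threshold: float = DEFAULT_AFFINITY_THRESHOLD,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    include_context: bool = False,
) -> InterfaceReport:
    """Interface areas for named block pairs in both states, with deltas.

    ``interface_spec`` lists (block_a, block_b) names from ``domain_map`` —
    e.g. all adjacent subunit pairs of a ring, per-domain decompositions, or
    tip-to-tip contacts.  Block residue ranges are expressed in state-A
    numbering; the pair's chain map carries them onto state B.  The delta for
    each pair is interface_area(state B) − interface_area(state A), i.e.
    transport minus resting under this package's state convention.
    """
    b_key_of = dict(pair.common_residues)
    entries: list[InterfaceArea] = []
    deltas: dict[str, float] = {}
    gaps: list[str] = []
    for name_a, name_b in interface_spec:
        pair_label = f"{name_a}|{name_b}"
        sel_a_state_a = resolve_selection(pair.state_a, domain_map, name_a)
        sel_b_state_a = resolve_selection(pair.state_a, domain_map, name_b)
        sel_a_state_b = [b_key_of[k] for k in sel_a_state_a if k in b_key_of]
        sel_b_state_b = [b_key_of[k] for k in sel_b_state_a if k in b_key_of]
        per_state: dict[str, float] = {}
        for state_label, model, sa, sb in (
            ("A", pair.state_a, sel_a_state_a, sel_b_state_a),
            ("B", pair.state_b, sel_a_state_b, sel_b_state_b),
        ):
            if not sa or not sb:
                logger.warning("interface %s unresolvable in state %s", pair_label, state_label)
                gaps.append(f"{pair_label}:{state_label}")
                continue
            ctx = None
            if include_context:
                ctx = [r.key for r in model.residues]
            entry = interface(model, sa, sb, name_a=name_a, name_b=name_b,
                              state=state_label, probe=probe, n_points=n_points,
                              context=ctx)
            entries.append(entry)
            per_state[state_label] = entry.interface_area
        if {"A", "B"} <= per_state.keys():
            deltas[pair_label] = per_state["B"] - per_state["A"]
    return InterfaceReport(entries=entries, deltas=deltas,
                           affinity_threshold=affinity_threshold, gaps=gaps)
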