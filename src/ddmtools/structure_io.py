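"""Reading coordinate files and resolving residue-level frames and selections.

The difference-distance and interface analyses in this package compare two
conformational states of the same multimeric assembly.  Everything downstream
works on three light in-memory objects built here:

``StructureModel``
    An ordered residue list (with one representative alpha-carbon coordinate
    per residue) plus the full heavy-atom list with van der Waals radii.
``ChainMap`` / ``DomainMap``
    Explicit user-supplied correspondence between chains of the two states,
    and named blocks (domains) given as chain + inclusive author-numbered
    residue ranges, e.g. the outer-membrane-protein periplasmic helices
    H3/H4 (residues 126–206) and H7/H8 (348–427).
``ConformerPair``
    The two states plus the ordered list of residues present, with an
    alpha-carbon, in both.

Parsing is delegated to :mod:`gemmi`; this module decides the residue- and
atom-level policies (waters and hydrogens out, altloc by occupancy, author
numbering throughout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import yaml

from .radii import RADII_SET_NAME, vdw_radius

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueKey",
    "Residue",
    "Atom",
    "StructureModel",
    "ChainMap",
    "DomainMap",
    "ConformerPair",
    "load_structure",
    "write_pdb",
    "build_pair",
    "resolve_selection",
]


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue: chain, author residue number, insertion code."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chain_id}{self.residue_number}{self.insertion_code}"


@dataclass(frozen=True)
class Residue:
    key: ResidueKey
    name: str
    ca: tuple[float, float, float]


@dataclass(frozen=True)
class Atom:
    key: ResidueKey
    name: str
    element: str
    coord: tuple[float, float, float]
    radius: float


@dataclass
class StructureModel:
    """One conformational state: ordered residues plus heavy atoms."""

    identifier: str
    residues: list[Residue]
    atoms: list[Atom]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"{self.identifier}: duplicate residue keys")
        self._index = {k: i for i, k in enumerate(keys)}

    @property
    def residue_keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.key.chain_id, None)
        return list(seen)

    def has_residue(self, key: ResidueKey) -> bool:
        return key in self._index

    def residue(self, key: ResidueKey) -> Residue:
        return self.residues[self._index[key]]

    def ca_coords(self, keys: Sequence[ResidueKey] | None = None) -> np.ndarray:
        """(N, 3) array of representative-atom coordinates in Å."""
        residues = self.residues if keys is None else [self.residue(k) for k in keys]
        return np.asarray([r.ca for r in residues], dtype=float)

    def atom_records(
        self, keys: Iterable[ResidueKey] | None = None
    ) -> tuple[np.ndarray, np.ndarray, list[Atom]]:
        """Coordinates (M, 3), radii (M,) and atoms, optionally restricted to keys."""
        if keys is None:
            atoms = self.atoms
        else:
            keyset = set(keys)
            atoms = [a for a in self.atoms if a.key in keyset]
        coords = np.asarray([a.coord for a in atoms], dtype=float)
        radii = np.asarray([a.radius for a in atoms], dtype=float)
        return coords, radii, atoms


@dataclass
class ChainMap:
    """Explicit chain correspondence between state A and state B.

    ``pairs`` maps chain ids of state A to chain ids of state B.  An optional
    per-chain-pair residue-number offset shifts A's author numbering onto B's
    (B number = A number + offset).  The map must be injective both ways:
    protomer relabelling between depositions is common and automatic matching
    would silently misassign subunits.
    """

    pairs: list[tuple[str, str]]
    offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("ChainMap must be injective in both directions")

    @classmethod
    def identity(cls, chain_ids: Iterable[str]) -> "ChainMap":
        return cls(pairs=[(c, c) for c in chain_ids])

    def inverted(self) -> "ChainMap":
        return ChainMap(
            pairs=[(b, a) for a, b in self.pairs],
            offsets={b: -off for (a, b), off in
                     ((p, self.offsets.get(p[0], 0)) for p in self.pairs) if off},
        )

    def offset_for(self, chain_a: str) -> int:
        return self.offsets.get(chain_a, 0)

    @classmethod
    def from_config(cls, path: str | Path) -> "ChainMap":
        """Load from YAML/JSON: {pairs: [[A, a], ...], offsets: {A: 2}}."""
        data = yaml.safe_load(Path(path).read_text())
        pairs = [(str(a), str(b)) for a, b in data["pairs"]]
        offsets = {str(k): int(v) for k, v in (data.get("offsets") or {}).items()}
        return cls(pairs=pairs, offsets=offsets)


@dataclass
class DomainMap:
    """Named blocks, each a list of (chain, start, end) inclusive segments."""

    blocks: dict[str, list[tuple[str, int, int]]]
    order: list[str] | None = None

    def __post_init__(self) -> None:
        for name, segments in self.blocks.items():
            if not segments:
                raise ValueError(f"block {name!r} has no segments")
            for chain, start, end in segments:
                if start > end:
                    raise ValueError(
                        f"block {name!r}: segment {chain}:{start}-{end} has start > end"
                    )

    @property
    def block_names(self) -> list[str]:
        return list(self.order) if self.order else list(self.blocks)

    def chains_of(self, block: str) -> set[str]:
        return {chain for chain, _, _ in self.blocks[block]}

    def block_of(self, residue_number: int, chain_id: str | None = None) -> str | None:
        """Name of the first block whose segments contain the residue."""
        for name in self.block_names:
            for chain, start, end in self.blocks[name]:
                if chain_id is not None and chain != chain_id:
                    continue
                if start <= residue_number <= end:
                    return name
        return None

    @classmethod
    def from_config(cls, path: str | Path) -> "DomainMap":
        """Load from YAML/JSON.

        Schema::

            blocks:
              H3H4: [[A, 126, 206]]
              H7H8: [[A, 348, 427]]
            order: [H3H4, H7H8]   # optional display order
        """
        data = yaml.safe_load(Path(path).read_text())
        blocks = {
            str(name): [(str(c), int(s), int(e)) for c, s, e in segments]
            for name, segments in data["blocks"].items()
        }
        order = [str(n) for n in data["order"]] if data.get("order") else None
        return cls(blocks=blocks, order=order)


@dataclass
class ConformerPair:
    """Two states of the same assembly and their common residues."""

    state_a: StructureModel
    state_b: StructureModel
    chain_map: ChainMap
    common_residues: list[tuple[ResidueKey, ResidueKey]]

    @property
    def n_common(self) -> int:
        return len(self.common_residues)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Representative-atom coordinates of the common residues, per state."""
        keys_a = [a for a, _ in self.common_residues]
        keys_b = [b for _, b in self.common_residues]
        return self.state_a.ca_coords(keys_a), self.state_b.ca_coords(keys_b)


# ---------------------------------------------------------------------------
# loading


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _pick_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name, ties by altloc letter."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
        elif (atom.occ, _neg_ord(atom.altloc)) > (prev.occ, _neg_ord(prev.altloc)):
            chosen[atom.name] = atom
    return list(chosen.values())


def _neg_ord(altloc: str) -> int:
    # earlier altloc letters win ties -> larger score for smaller letter
    return -ord(altloc) if altloc else 0


def load_structure(
    path: str | Path,
    format: str = "auto",
    model_index: int = 1,
    include_hetero: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        Coordinate file.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (by extension/content).
    model_index:
        1-based model number for multi-model (NMR-style) files.
    include_hetero:
        If true, keep non-water heteroatom residues (ligands, ions).

    Waters and hydrogens are always excluded.  The representative atom is the
    alpha-carbon; residues without one are kept in the atom list (they still
    occlude surface) but dropped from the residue frame used for distance
    matrices.  Van der Waals radii come from a single element-level set
    recorded in ``metadata["radii_set"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    if not (1 <= model_index <= len(st)):
        raise IndexError(
            f"model_index {model_index} out of range (file has {len(st)} model(s))"
        )
    model = st[model_index - 1]

    residues: list[Residue] = []
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            is_het = res.het_flag == "H"
            if is_het and not include_hetero:
                continue
            key = ResidueKey(
                chain_id=chain.name,
                residue_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
            )
            ca = None
            kept = [a for a in _pick_altlocs(res) if not a.is_hydrogen()]
            if not kept:
                continue
            for atom in kept:
                el = atom.element.name or "C"
                atoms.append(
                    Atom(
                        key=key,
                        name=atom.name,
                        element=el,
                        coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                        radius=vdw_radius(el),
                    )
                )
                if atom.name == "CA" and atom.element.name != "Ca":
                    ca = (atom.pos.x, atom.pos.y, atom.pos.z)
            if ca is not None:
                residues.append(Residue(key=key, name=res.name, ca=ca))
            else:
                logger.debug("%s: residue %s has no alpha-carbon", path.name, key)
    if not atoms:
        raise ValueError(f"{path}: model {model_index} contains no usable atoms")
    return StructureModel(
        identifier=st.name or path.stem,
        residues=residues,
        atoms=atoms,
        metadata={
            "source": str(path),
            "model_index": model_index,
            "radii_set": RADII_SET_NAME,
        },
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model back out as a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.identifier
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    res_names = {r.key: r.name for r in model.residues}
    current: dict[ResidueKey, gemmi.Residue] = {}
    for atom in model.atoms:
        chain = chains.get(atom.key.chain_id)
        if chain is None:
            chain = gemmi.Chain(atom.key.chain_id)
            chains[atom.key.chain_id] = chain
        res = current.get(atom.key)
        if res is None:
            res = gemmi.Residue()
            res.name = res_names.get(atom.key, "GLY")
            res.seqid = gemmi.SeqId(atom.key.residue_number, atom.key.insertion_code or " ")
            current[atom.key] = res
        ga = gemmi.Atom()
        ga.name = atom.name
        ga.element = gemmi.Element(atom.element)
        ga.pos = gemmi.Position(*atom.coord)
        ga.occ = 1.0
        res.add_atom(ga)
    # preserve residue order per chain as encountered in the atom list
    added: set[int] = set()
    for atom in model.atoms:
        res = current[atom.key]
        if id(res) not in added:
            chains[atom.key.chain_id].add_residue(res)
            added.add(id(res))
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# pairing and selections


def build_pair(
    state_a: StructureModel,
    state_b: StructureModel,
    chain_map: ChainMap | None = None,
) -> ConformerPair:
    """Intersect two states into a :class:`ConformerPair`.

    Residues are matched by (mapped chain, residue number + offset, insertion
    code); residues lacking a representative atom in either state are dropped
    and logged.  The common-residue order is deterministic: chain order of the
    map, then residue number, then insertion code.
    """
    if chain_map is None:
        chain_map = ChainMap.identity(state_a.chain_ids)
    chains_a = set(state_a.chain_ids)
    chains_b = set(state_b.chain_ids)
    for ca_id, cb_id in chain_map.pairs:
        if ca_id not in chains_a:
            raise ValueError(f"chain {ca_id!r} not present in state A ({state_a.identifier})")
        if cb_id not in chains_b:
            raise ValueError(f"chain {cb_id!r} not present in state B ({state_b.identifier})")

    b_keys = {r.key for r in state_b.residues}
    common: list[tuple[ResidueKey, ResidueKey]] = []
    n_dropped = 0
    for ca_id, cb_id in chain_map.pairs:
        offset = chain_map.offset_for(ca_id)
        chain_res = sorted(
            (r.key for r in state_a.residues if r.key.chain_id == ca_id),
            key=lambda k: (k.residue_number, k.insertion_code),
        )
        for key_a in chain_res:
            key_b = ResidueKey(cb_id, key_a.residue_number + offset, key_a.insertion_code)
            if key_b in b_keys:
                common.append((key_a, key_b))
            else:
                n_dropped += 1
    if n_dropped:
        logger.info(
            "build_pair(%s, %s): dropped %d residue(s) absent or without "
            "alpha-carbon in the other state",
            state_a.identifier, state_b.identifier, n_dropped,
        )
    if not common:
        raise ValueError("no common residues between the two states under this chain map")
    return ConformerPair(state_a=state_a, state_b=state_b,
                         chain_map=chain_map, common_residues=common)


def resolve_selection(
    model: StructureModel,
    domain_map: DomainMap,
    block_names: Sequence[str] | str,
) -> list[ResidueKey]:
    """Residues of the named blocks, deduplicated, in model order.

    Residues named in the map but absent from the model are logged, not fatal;
    an unknown block name raises with the available names listed.
    """
    if isinstance(block_names, str):
        block_names = [block_names]
    unknown = [n for n in block_names if n not in domain_map.blocks]
    if unknown:
        raise KeyError(
            f"unknown block(s) {unknown}; available: {sorted(domain_map.blocks)}"
        )
    wanted: set[tuple[str, int]] = set()
    n_requested = 0
    for name in block_names:
        for chain, start, end in domain_map.blocks[name]:
            for num in range(start, end + 1):
                if (chain, num) not in wanted:
                    wanted.add((chain, num))
                    n_requested += 1
    selected = [
        r.key for r in model.residues
        if (r.key.chain_id, r.key.residue_number) in wanted
    ]
    found = {(k.chain_id, k.residue_number) for k in selected}
    n_absent = len(wanted - found)
    if n_absent:
        logger.info(
            "resolve_selection(%s): %d residue(s) named in blocks %s absent "
            "from the model", model.identifier, n_absent, list(block_names),
        )
    return selected
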