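"""Synthetic two-state assemblies with planted motions and EC fixtures.

Real two-state comparisons of efflux-pump components hinge on downloaded
cryo-EM models and web-server coupling runs; this module builds miniature
stand-ins with *known* answers so every pipeline stage can be exercised and
checked quantitatively offline.

``make_ring_assembly`` builds a Cn-symmetric ring of idealized helical
protomers (rise 1.5 Å and 100° twist per residue — canonical α-helix
geometry), one Cα plus one dummy side-chain atom per residue.  It emulates
the ring architectures of the membrane-fusion-protein hexamer and the
outer-membrane-protein trimer.

``apply_motions`` produces state B by applying named rigid-body transforms
(rotations/translations) to whole blocks — emulating the outward helix
movements, ring contraction and twisting motions seen on pump activation —
plus optional Gaussian coordinate noise emulating limited map resolution.
The returned ground truth contains per-residue displacements and expected
block-DDM means computed by an independent brute-force double loop, so the
main pipeline can be validated against it.

``make_ec_fixture`` plants coupling records at true spatial contacts plus
decoys elsewhere, with labels, so the EC filtering and classification rules
can be scored against known composition.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .ec import ECRecord, ECTable
from .structure_io import (
    Atom,
    DomainMap,
    Residue,
    ResidueKey,
    StructureModel,
)
from .radii import vdw_radius

__all__ = [
    "MotionSpec",
    "GroundTruth",
    "make_ring_assembly",
    "apply_motions",
    "make_ec_fixture",
    "brute_force_block_means",
    "brute_force_sasa",
    "brute_force_buried_area",
]

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST_DEG = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å, Cα distance from helix axis
_MIN_CLEARANCE = 2.0  # Å between atoms of different protomers


@dataclass
class MotionSpec:
    """A rigid-body motion applied to one named block in state B.

    ``rotation`` is (axis, angle in degrees, centre point); the axis is
    normalized on construction.  Rotation (if any) is applied first, then
    ``translation``.
    """

    block: str
    translation: tuple[float, float, float] | None = None
    rotation: tuple[tuple[float, float, float], float, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.rotation is not None:
            axis, angle, center = self.rotation
            norm = float(np.linalg.norm(axis))
            if norm == 0:
                raise ValueError("rotation axis must be non-zero")
            self.rotation = (tuple(np.asarray(axis, float) / norm), float(angle),
                             tuple(float(c) for c in center))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        out = np.asarray(coords, dtype=float)
        if self.rotation is not None:
            axis, angle, center = self.rotation
            rot = Rotation.from_rotvec(np.deg2rad(angle) * np.asarray(axis))
            out = rot.apply(out - center) + center
        if self.translation is not None:
            out = out + np.asarray(self.translation, dtype=float)
        return out


@dataclass
class GroundTruth:
    """What was planted, and what the pipeline should recover."""

    motions: list[MotionSpec]
    seed: int
    noise_sigma: float
    residue_displacements: dict[str, float]  # str(ResidueKey) -> Å
    expected_block_means: dict[str, float]  # "blockP|blockQ" -> Å (brute force)
    expected_buried_deltas: dict[str, float] = field(default_factory=dict)

    def block_mean(self, p: str, q: str) -> float:
        return self.expected_block_means[f"{p}|{q}"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "motions": [
                {"block": m.block, "translation": m.translation, "rotation": m.rotation}
                for m in self.motions
            ],
            "residue_displacements": self.residue_displacements,
            "expected_block_means": self.expected_block_means,
            "expected_buried_deltas": self.expected_buried_deltas,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# generators


def _helix_protomer(n_residues: int) -> np.ndarray:
    """(n, 2, 3) local coordinates: [CA, dummy side-chain] per residue.

    Idealized α-helix along +z, centred at the origin.
    """
    i = np.arange(n_residues, dtype=float)
    phi = np.deg2rad(HELIX_TWIST_DEG) * i
    z = HELIX_RISE * i
    z -= z.mean()
    ca = np.column_stack([HELIX_RADIUS * np.cos(phi), HELIX_RADIUS * np.sin(phi), z])
    # dummy side-chain atom 1.5 Å further out from the helix axis
    out_dir = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
    cb = ca + 1.5 * out_dir
    return np.stack([ca, cb], axis=1)


def _chain_label(k: int) -> str:
    return chr(ord("A") + k)


def make_ring_assembly(
    n_protomers: int,
    residues_per_protomer: int,
    ring_radius: float,
    seed: int = 0,
    n_domains_per_protomer: int = 1,
) -> tuple[StructureModel, DomainMap]:
    """Cn-symmetric ring of idealized helical protomers.

    Chains are labelled A, B, …; residues are numbered 1..n per chain, each
    with a Cα and a dummy side-chain atom.  The domain map carries one block
    per protomer (``prot_A`` …), or ``n_domains_per_protomer`` equal splits
    per protomer (``A_d1`` …) for finer block analyses.  Construction is
    deterministic given (parameters, seed); the seed only drives the small
    jitter used to resolve accidental steric overlap (error after 5 tries).
    """
    if n_protomers < 2:
        raise ValueError("need at least 2 protomers")
    if residues_per_protomer < 6:
        raise ValueError("need at least 6 residues per protomer")
    local = _helix_protomer(residues_per_protomer)
    rng = np.random.default_rng(seed)
    for attempt in range(5):
        chains: list[np.ndarray] = []
        jitter = np.zeros(3) if attempt == 0 else rng.normal(0.0, 0.5, size=3)
        base = local + jitter
        for k in range(n_protomers):
            angle = 2.0 * np.pi * k / n_protomers
            rot = Rotation.from_rotvec([0.0, 0.0, angle])
            center = ring_radius * np.array([np.cos(angle), np.sin(angle), 0.0])
            chains.append(rot.apply(base.reshape(-1, 3)).reshape(base.shape) + center)
        flat = [c.reshape(-1, 3) for c in chains]
        clear = True
        for a in range(n_protomers):
            for b in range(a + 1, n_protomers):
                d = np.linalg.norm(flat[a][:, None, :] - flat[b][None, :, :], axis=2)
                if d.min() < _MIN_CLEARANCE:
                    clear = False
        if clear:
            break
    else:
        raise RuntimeError("could not build a clash-free ring in 5 attempts")

    residues: list[Residue] = []
    atoms: list[Atom] = []
    for k, coords in enumerate(chains):
        chain_id = _chain_label(k)
        for r in range(residues_per_protomer):
            key = ResidueKey(chain_id, r + 1)
            ca = tuple(float(x) for x in coords[r, 0])
            cb = tuple(float(x) for x in coords[r, 1])
            residues.append(Residue(key=key, name="ALA", ca=ca))
            atoms.append(Atom(key=key, name="CA", element="C", coord=ca,
                              radius=vdw_radius("C")))
            atoms.append(Atom(key=key, name="CB", element="C", coord=cb,
                              radius=vdw_radius("C")))
    model = StructureModel(
        identifier=f"ring{n_protomers}x{residues_per_protomer}",
        residues=residues,
        atoms=atoms,
        metadata={"generator": "make_ring_assembly", "seed": seed,
                  "ring_radius": ring_radius},
    )

    blocks: dict[str, list[tuple[str, int, int]]] = {}
    if n_domains_per_protomer <= 1:
        for k in range(n_protomers):
            c = _chain_label(k)
            blocks[f"prot_{c}"] = [(c, 1, residues_per_protomer)]
    else:
        bounds = np.linspace(1, residues_per_protomer + 1,
                             n_domains_per_protomer + 1).astype(int)
        for k in range(n_protomers):
            c = _chain_label(k)
            for d in range(n_domains_per_protomer):
                blocks[f"{c}_d{d + 1}"] = [(c, int(bounds[d]), int(bounds[d + 1] - 1))]
    return model, DomainMap(blocks=blocks)


def _block_residue_indices(model: StructureModel, domain_map: DomainMap) -> dict[str, list[int]]:
    member: dict[str, list[int]] = {name: [] for name in domain_map.block_names}
    for idx, res in enumerate(model.residues):
        for name in domain_map.block_names:
            for chain, start, end in domain_map.blocks[name]:
                if res.key.chain_id == chain and start <= res.key.residue_number <= end:
                    member[name].append(idx)
                    break
            else:
                continue
            break
    return member


def brute_force_block_means(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    block_indices: dict[str, list[int]],
) -> dict[str, float]:
    """Expected block-DDM means by a plain double loop (oracle code path).

    Intentionally naive: per residue pair, two explicit Euclidean norms and a
    running sum — no distance-matrix code shared with the main pipeline.
    """
    names = list(block_indices)
    out: dict[str, float] = {}
    for p_i, p in enumerate(names):
        for q in names[p_i:]:
            total = 0.0
            n = 0
            for i in block_indices[p]:
                for j in block_indices[q]:
                    if i == j:
                        continue
                    da = float(np.sqrt(((coords_a[i] - coords_a[j]) ** 2).sum()))
                    db = float(np.sqrt(((coords_b[i] - coords_b[j]) ** 2).sum()))
                    total += db - da
                    n += 1
            if n:
                out[f"{p}|{q}"] = total / n
    return out


def apply_motions(
    model: StructureModel,
    domain_map: DomainMap,
    motions: list[MotionSpec],
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> tuple[StructureModel, GroundTruth]:
    """Build state B by rigid-body block motions (+ optional noise).

    Every atom of a block moves with the block's transform; residues outside
    all moved blocks stay put.  ``noise_sigma`` adds isotropic Gaussian noise
    (Å, per coordinate) to state B, emulating coordinate uncertainty of
    low-resolution models.  The ground truth records per-residue Cα
    displacements and brute-forced expected block-DDM means (computed on the
    noisy coordinates, so they remain exact expectations for the pipeline).
    """
    known = set(domain_map.blocks)
    for m in motions:
        if m.block not in known:
            raise KeyError(f"motion references unknown block {m.block!r}; have {sorted(known)}")

    def transform_for(key: ResidueKey) -> MotionSpec | None:
        for m in motions:
            for chain, start, end in domain_map.blocks[m.block]:
                if key.chain_id == chain and start <= key.residue_number <= end:
                    return m
        return None

    rng = np.random.default_rng(seed)
    new_residues: list[Residue] = []
    new_atoms: list[Atom] = []
    moved_ca: dict[ResidueKey, np.ndarray] = {}
    for res in model.residues:
        m = transform_for(res.key)
        ca = np.asarray(res.ca, dtype=float)
        if m is not None:
            ca = m.apply(ca[None, :])[0]
        moved_ca[res.key] = ca
    for atom in model.atoms:
        m = transform_for(atom.key)
        xyz = np.asarray(atom.coord, dtype=float)
        if m is not None:
            xyz = m.apply(xyz[None, :])[0]
        if noise_sigma > 0:
            xyz = xyz + rng.normal(0.0, noise_sigma, size=3)
        new_atoms.append(Atom(key=atom.key, name=atom.name, element=atom.element,
                              coord=tuple(float(x) for x in xyz), radius=atom.radius))
        if atom.name == "CA":
            moved_ca[atom.key] = xyz
    for res in model.residues:
        new_residues.append(Residue(key=res.key, name=res.name,
                                    ca=tuple(float(x) for x in moved_ca[res.key])))

    state_b = StructureModel(
        identifier=model.identifier + "_stateB",
        residues=new_residues,
        atoms=new_atoms,
        metadata={**model.metadata, "motions": [m.block for m in motions],
                  "noise_sigma": noise_sigma, "seed": seed},
    )

    coords_a = model.ca_coords()
    coords_b = state_b.ca_coords()
    displacements = {
        str(res.key): float(np.linalg.norm(coords_b[i] - coords_a[i]))
        for i, res in enumerate(model.residues)
    }
    block_idx = _block_residue_indices(model, domain_map)
    expected = brute_force_block_means(coords_a, coords_b, block_idx)
    truth = GroundTruth(
        motions=list(motions),
        seed=seed,
        noise_sigma=noise_sigma,
        residue_displacements=displacements,
        expected_block_means=expected,
    )
    return state_b, truth


# ---------------------------------------------------------------------------
# EC fixtures


def make_ec_fixture(
    model: StructureModel,
    contact_cutoff: float = 8.0,
    n_true: int = 20,
    n_decoys: int = 20,
    cn_true_range: tuple[float, float] = (1.0, 3.0),
    cn_decoy_range: tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
    chain: str | None = None,
    min_sequence_separation: int = 5,
) -> tuple[ECTable, "np.recarray"]:
    """Plant EC records at true contacts plus spatially random decoys.

    True records are sampled (without replacement) from intra-protomer
    residue pairs with Cα distance below ``contact_cutoff``; decoys from the
    complement.  Both honour ``min_sequence_separation`` so the standard
    near-diagonal filter does not remove them.  cn values are drawn uniformly
    in the given ranges.  Returns the table plus a labels record array with
    fields (i, j, cn, is_contact, distance).
    """
    chain_id = chain if chain is not None else model.chain_ids[0]
    chain_res = [r for r in model.residues if r.key.chain_id == chain_id]
    nums = np.asarray([r.key.residue_number for r in chain_res])
    coords = np.asarray([r.ca for r in chain_res])
    n = len(chain_res)
    contacts: list[tuple[int, int, float]] = []
    noncontacts: list[tuple[int, int, float]] = []
    for a in range(n):
        for b in range(a + 1, n):
            if abs(int(nums[b]) - int(nums[a])) < min_sequence_separation:
                continue
            d = float(np.linalg.norm(coords[a] - coords[b]))
            rec = (int(nums[a]), int(nums[b]), d)
            (contacts if d < contact_cutoff else noncontacts).append(rec)
    if len(contacts) < n_true:
        raise ValueError(
            f"only {len(contacts)} contact pair(s) below {contact_cutoff} Å "
            f"available, need {n_true}"
        )
    if len(noncontacts) < n_decoys:
        raise ValueError(
            f"only {len(noncontacts)} non-contact pair(s) available, need {n_decoys}"
        )
    rng = np.random.default_rng(seed)
    chosen_true = [contacts[i] for i in rng.choice(len(contacts), n_true, replace=False)]
    chosen_decoy = [noncontacts[i] for i in rng.choice(len(noncontacts), n_decoys, replace=False)]
    rows: list[tuple[int, int, float, bool, float]] = []
    for (i, j, d), is_contact in (
        [(c, True) for c in chosen_true] + [(c, False) for c in chosen_decoy]
    ):
        lo, hi = cn_true_range if is_contact else cn_decoy_range
        cn = float(rng.uniform(lo, hi))
        rows.append((i, j, cn, is_contact, d))
    rows.sort()
    records = [ECRecord(i, j, cn) for i, j, cn, _, _ in rows]
    labels = np.rec.fromrecords(
        rows, names=["i", "j", "cn", "is_contact", "distance"]
    )
    table = ECTable(records=records, provenance={
        "generator": "make_ec_fixture", "seed": seed,
        "contact_cutoff": contact_cutoff,
    })
    return table, labels


# ---------------------------------------------------------------------------
# independent SASA oracle (separate code path from ddmtools.sasa)


def brute_force_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Total SASA by an all-pairs double loop over a latitude point grid.

    Oracle path: no k-d tree, and a different (random-free, latitude-band)
    point construction than the golden-spiral quadrature used by the main
    implementation.  Quadratic in atom count — intended for ≤ ~100 atoms.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    m = len(coords)
    # latitude-band point set (Deserno-style equal-area placement)
    pts: list[list[float]] = []
    a = 4.0 * np.pi / n_points
    d = np.sqrt(a)
    m_theta = int(round(np.pi / d))
    d_theta = np.pi / m_theta
    d_phi = a / d_theta
    for t in range(m_theta):
        theta = np.pi * (t + 0.5) / m_theta
        m_phi = int(round(2.0 * np.pi * np.sin(theta) / d_phi))
        for p in range(max(m_phi, 1)):
            phi = 2.0 * np.pi * p / max(m_phi, 1)
            pts.append([np.sin(theta) * np.cos(phi),
                        np.sin(theta) * np.sin(phi),
                        np.cos(theta)])
    unit = np.asarray(pts)
    total = 0.0
    for i in range(m):
        r_i = radii[i] + probe
        surface = coords[i] + r_i * unit
        accessible = np.ones(len(unit), dtype=bool)
        for j in range(m):
            if j == i:
                continue
            r_j = radii[j] + probe
            accessible &= np.sum((surface - coords[j]) ** 2, axis=1) >= r_j**2
        total += accessible.mean() * 4.0 * np.pi * r_i**2
    return float(total)


def brute_force_buried_area(
    model: StructureModel,
    selection_a: list[ResidueKey],
    selection_b: list[ResidueKey],
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Buried area ASA(A) + ASA(B) − ASA(A∪B) via the brute-force SASA oracle."""
    parts = []
    for keys in (set(selection_a), set(selection_b), set(selection_a) | set(selection_b)):
        coords, radii, _ = model.atom_records(keys)
        parts.append(brute_force_sasa(coords, radii, probe=probe, n_points=n_points))
    return parts[0] + parts[1] - parts[2]
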