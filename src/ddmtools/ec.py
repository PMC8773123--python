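"""Evolutionary-couplings tables: parsing, filtering, spatial classification.

Evolutionary couplings (ECs) are covariation scores between two positions of
a protein sequence, inferred from a deep multiple sequence alignment
(e.g. by plmDCA on an EVcouplings-server run).  Each record carries a
coupling number (cn); higher cn means stronger coupling.  Strong couplings
usually reflect physical contact that maintains the tertiary fold; strongly
coupled pairs that are *distant* in the structure are candidates for
allosteric communication.

This module consumes precomputed EC tables (coupling inference itself is out
of scope), applies the standard filters — a cn floor (inclusive by default),
removal of pairs within the same named segment (e.g. the same helix), a
minimum sequence separation — classifies each pair as spatially close or
distant against one or both conformers (default: close iff Cα–Cα distance is
strictly below 10 Å), and annotates pairs with the local difference-distance
value so couplings can be read against conformational change.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ddm import DDMatrix
from .structure_io import DomainMap, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "ECRecord",
    "ECTable",
    "OverlayRecord",
    "load_ec_table",
    "filter_ecs",
    "classify_spatial",
    "overlay_on_ddm",
]

DEFAULT_CN_MIN = 1.0
DEFAULT_CLOSE_CUTOFF = 10.0  # Å, strict less-than
DEFAULT_MIN_SEPARATION = 5


@dataclass(frozen=True)
class ECRecord:
    """One coupled residue pair, canonicalized so residue_i < residue_j."""

    residue_i: int
    residue_j: int
    cn: float
    segment_i: str | None = None
    segment_j: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.cn):
            raise ValueError("coupling number must be finite")
        if self.residue_i >= self.residue_j:
            raise ValueError("records must be canonicalized with residue_i < residue_j")


@dataclass
class ECTable:
    records: list[ECRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [(r.residue_i, r.residue_j) for r in self.records]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate residue pairs in EC table")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"i": r.residue_i, "j": r.residue_j, "cn": r.cn,
                 "segment_i": r.segment_i, "segment_j": r.segment_j}
                for r in self.records
            ]
        )


@dataclass
class OverlayRecord:
    """An EC record placed onto structure(s) and, optionally, onto a DDM."""

    record: ECRecord
    distances: dict[str, float]  # e.g. {"intra": 8.1, "inter": 12.3}
    spatial_class: str  # "close" | "distant"
    same_segment: bool
    ddm_value: float | None = None  # None when masked or outside the DDM
    ddm_class: str | None = None  # "contracting" | "expanding" | "masked"


# ---------------------------------------------------------------------------
# parsing

_I_NAMES = {"i", "res_i", "residue_i", "pos_i", "first"}
_J_NAMES = {"j", "res_j", "residue_j", "pos_j", "second"}
_CN_NAMES = {"cn", "coupling", "coupling_number", "score"}
_SEG_I_NAMES = {"segment_i", "seg_i"}
_SEG_J_NAMES = {"segment_j", "seg_j"}


def _find_column(columns: list[str], wanted: set[str]) -> str | None:
    for c in columns:
        if c.strip().lower() in wanted:
            return c
    return None


def load_ec_table(path: str | Path, numbering_offset: int = 0) -> ECTable:
    """Read a delimited EC file (EVcouplings-server CSV layout accepted).

    The delimiter (comma/tab/whitespace) is sniffed; columns are located by
    header name with ``i``/``j``/``cn`` fallbacks.  ``numbering_offset`` is
    added to both residue indices to map sequence numbering onto structure
    author numbering (e.g. −21 to strip a signal peptide).  Duplicate pairs —
    including (j, i) mirrors — collapse to one record keeping the highest cn.
    Non-numeric rows are skipped with a logged count.
    """
    path = Path(path)
    text = path.read_text()
    first_line = text.splitlines()[0] if text.strip() else ""
    sep = "," if "," in first_line else (r"\t" if "\t" in first_line else r"\s+")
    df = pd.read_csv(io.StringIO(text), sep=sep, engine="python")
    cols = list(df.columns)
    col_i = _find_column(cols, _I_NAMES)
    col_j = _find_column(cols, _J_NAMES)
    col_cn = _find_column(cols, _CN_NAMES)
    if col_i is None or col_j is None:
        # headerless fallback: first two columns are i, j
        if len(cols) >= 3:
            df = pd.read_csv(io.StringIO(text), sep=sep, engine="python", header=None)
            col_i, col_j = df.columns[0], df.columns[1]
            col_cn = df.columns[-1]
        else:
            raise ValueError(f"{path}: cannot identify residue index columns")
    if col_cn is None:
        raise ValueError(f"{path}: no coupling-number (cn) column found")
    col_si = _find_column(cols, _SEG_I_NAMES)
    col_sj = _find_column(cols, _SEG_J_NAMES)

    n_bad = 0
    best: dict[tuple[int, int], ECRecord] = {}
    for _, row in df.iterrows():
        try:
            i = int(row[col_i]) + numbering_offset
            j = int(row[col_j]) + numbering_offset
            cn = float(row[col_cn])
        except (TypeError, ValueError):
            n_bad += 1
            continue
        if not np.isfinite(cn) or i == j:
            n_bad += 1
            continue
        si = str(row[col_si]) if col_si is not None and pd.notna(row[col_si]) else None
        sj = str(row[col_sj]) if col_sj is not None and pd.notna(row[col_sj]) else None
        if i > j:
            i, j, si, sj = j, i, sj, si
        prev = best.get((i, j))
        if prev is None or cn > prev.cn:
            if prev is not None:
                logger.warning("duplicate EC pair (%d, %d): keeping higher cn", i, j)
            best[(i, j)] = ECRecord(i, j, cn, si, sj)
    if n_bad:
        logger.info("%s: skipped %d non-numeric/degenerate row(s)", path.name, n_bad)
    records = [best[k] for k in sorted(best)]
    return ECTable(records=records,
                   provenance={"source": str(path), "numbering_offset": numbering_offset})


# ---------------------------------------------------------------------------
# filtering


def _segment_of(residue: int, segments: DomainMap | None) -> str | None:
    if segments is None:
        return None
    return segments.block_of(residue)


def filter_ecs(
    table: ECTable,
    cn_min: float = DEFAULT_CN_MIN,
    exclude_same_segment: bool = False,
    min_sequence_separation: int = 0,
    segments: DomainMap | None = None,
    strict_cn: bool = False,
) -> ECTable:
    """Apply the cn floor, sequence-separation and same-segment filters.

    The cn floor is inclusive (keep cn ≥ cn_min) by default; ``strict_cn``
    switches to a strict ``>`` rule.  ``exclude_same_segment`` drops pairs
    whose two residues fall in the same named segment of ``segments`` (the
    generalization of removing same-helix pairs, which reflect the tertiary
    fold rather than allosteric communication); segment labels carried by the
    records themselves are used when no DomainMap is given.  An empty result
    is allowed and logged.
    """
    kept: list[ECRecord] = []
    for rec in table.records:
        ok_cn = rec.cn > cn_min if strict_cn else rec.cn >= cn_min
        if not ok_cn:
            continue
        if abs(rec.residue_j - rec.residue_i) < min_sequence_separation:
            continue
        if exclude_same_segment:
            if segments is not None:
                si = _segment_of(rec.residue_i, segments)
                sj = _segment_of(rec.residue_j, segments)
            else:
                si, sj = rec.segment_i, rec.segment_j
            if si is not None and si == sj:
                continue
        kept.append(rec)
    if not kept:
        logger.info("filter_ecs: no records survive (cn_min=%s)", cn_min)
    return ECTable(records=kept, provenance=dict(table.provenance))


# ---------------------------------------------------------------------------
# spatial classification and DDM overlay


def _chain_coord_maps(model: StructureModel) -> dict[str, dict[int, np.ndarray]]:
    out: dict[str, dict[int, np.ndarray]] = {}
    for res in model.residues:
        out.setdefault(res.key.chain_id, {})[res.key.residue_number] = np.asarray(res.ca)
    return out


def classify_spatial(
    table: ECTable,
    model: StructureModel,
    chain_scope: str = "intra",
    close_cutoff: float = DEFAULT_CLOSE_CUTOFF,
    chain: str | None = None,
) -> list[OverlayRecord]:
    """Classify each EC pair as spatially close or distant on a conformer.

    Distances are representative-atom (Cα) distances.  Scope:

    - ``intra``: distance within one protomer (``chain``, default the first);
    - ``inter``: minimum distance over all ordered pairs of distinct chains;
    - ``both``: both are computed; the intra distance decides the class.

    A pair is ``close`` iff its deciding distance is strictly below
    ``close_cutoff`` (default 10 Å).  Pairs unresolvable in the model are
    logged and dropped; if nothing resolves, an error is raised.
    """
    if chain_scope not in {"intra", "inter", "both"}:
        raise ValueError(f"unknown chain_scope {chain_scope!r}")
    coords = _chain_coord_maps(model)
    chain_ids = list(coords)
    ref_chain = chain if chain is not None else chain_ids[0]
    if ref_chain not in coords:
        raise ValueError(f"chain {ref_chain!r} not in model")

    out: list[OverlayRecord] = []
    n_dropped = 0
    for rec in table.records:
        distances: dict[str, float] = {}
        if chain_scope in {"intra", "both"}:
            cmap = coords[ref_chain]
            if rec.residue_i in cmap and rec.residue_j in cmap:
                distances["intra"] = float(
                    np.linalg.norm(cmap[rec.residue_i] - cmap[rec.residue_j])
                )
        if chain_scope in {"inter", "both"}:
            best = np.inf
            for c1 in chain_ids:
                for c2 in chain_ids:
                    if c1 == c2:
                        continue
                    m1, m2 = coords[c1], coords[c2]
                    if rec.residue_i in m1 and rec.residue_j in m2:
                        best = min(best, float(
                            np.linalg.norm(m1[rec.residue_i] - m2[rec.residue_j])
                        ))
            if np.isfinite(best):
                distances["inter"] = best
        deciding = distances.get("intra") if chain_scope != "inter" else distances.get("inter")
        if deciding is None:
            n_dropped += 1
            continue
        same_seg = (rec.segment_i is not None and rec.segment_i == rec.segment_j)
        out.append(OverlayRecord(
            record=rec,
            distances=distances,
            spatial_class="close" if deciding < close_cutoff else "distant",
            same_segment=same_seg,
        ))
    if n_dropped:
        logger.info("classify_spatial: dropped %d unresolvable pair(s)", n_dropped)
    if table.records and not out:
        raise ValueError("no EC pair resolvable against the model")
    return out


def overlay_on_ddm(
    overlay: list[OverlayRecord],
    ddmatrix: DDMatrix,
    chain: str | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Annotate overlay records with the DDM value at (i, j).

    Looks up each pair on ``chain`` (default: chain of the first DDM key).
    Records in masked DDM cells get no value and class ``masked``; otherwise
    the class is ``contracting`` (Δd ≤ −threshold) or ``expanding``
    (Δd ≥ +threshold).  Returns the combined long table and summary counts
    (``contracting`` / ``expanding`` / ``masked`` / ``outside``).
    """
    ref_chain = chain if chain is not None else (
        ddmatrix.keys[0].chain_id if ddmatrix.keys else None
    )
    lookup = {
        (k.chain_id, k.residue_number): idx for idx, k in enumerate(ddmatrix.keys)
    }
    counts = {"contracting": 0, "expanding": 0, "masked": 0, "outside": 0}
    rows: list[dict] = []
    for ov in overlay:
        rec = ov.record
        ii = lookup.get((ref_chain, rec.residue_i))
        jj = lookup.get((ref_chain, rec.residue_j))
        if ii is None or jj is None:
            ov.ddm_value, ov.ddm_class = None, None
            counts["outside"] += 1
        elif ddmatrix.mask[ii, jj]:
            ov.ddm_value, ov.ddm_class = None, "masked"
            counts["masked"] += 1
        else:
            val = float(ddmatrix.values[ii, jj])
            ov.ddm_value = val
            ov.ddm_class = "contracting" if val < 0 else "expanding"
            counts[ov.ddm_class] += 1
        rows.append({
            "i": rec.residue_i,
            "j": rec.residue_j,
            "cn": rec.cn,
            **{f"dist_{k}": v for k, v in ov.distances.items()},
            "spatial_class": ov.spatial_class,
            "same_segment": ov.same_segment,
            "ddm_value": ov.ddm_value,
            "ddm_class": ov.ddm_class,
        })
    columns = ["i", "j", "cn", "dist_intra", "dist_inter",
               "spatial_class", "same_segment", "ddm_value", "ddm_class"]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.reindex(columns=[c for c in columns if c in df.columns or c in
                                 {"i", "j", "cn", "spatial_class", "same_segment",
                                  "ddm_value", "ddm_class"}])
    return df, counts
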