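"""Fixed-position design masks from ligand proximity and MSA conservation.

The design space for function-preserving sequence redesign is chosen by
*fixing* (excluding from redesign) two classes of residues: the ligand
first shell — every residue with a heavy atom within a cutoff distance
(default 7 Å) of any heavy ligand atom — and the most conserved positions
of a family alignment. The resulting mask partitions each design chain
into fixed and free positions and is emitted in the fixed-position JSON
dialect consumed by inverse-folding backends.

Conservation here is the parent-identity column frequency: the fraction
of alignment rows carrying the parent's residue at that column, with gaps
counting in the denominator (a mostly-deleted column is not conserved).
Alternative metrics can be plugged in via ``ConservationProfile.metric_name``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structio import Msa, Residue, Structure

VALID_LABELS = ("shell", "conserved", "catalytic", "manual")

#: Hetero-group names never offered as ligands (solvent).
_MONOATOMIC_MAX = 1


@dataclass(frozen=True)
class ResidueSelection:
    """A labelled set of (chain_id, seq_index) positions."""

    positions: frozenset[tuple[str, int]]
    label: str

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        object.__setattr__(self, "positions", frozenset(self.positions))

    def __len__(self) -> int:
        return len(self.positions)

    def __contains__(self, pos: tuple[str, int]) -> bool:
        return pos in self.positions

    def validate(self, structure: Structure) -> None:
        for chain_id, idx in self.positions:
            structure.residue_at(chain_id, idx)  # raises KeyError if absent


@dataclass
class ConservationProfile:
    """Per-parent-position conservation scores in [0, 1]."""

    scores: np.ndarray          # one score per ungapped parent position
    n_effective: int            # rows counted per column (denominator)
    metric_name: str = "parent_identity_frequency"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be 1-D")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("conservation scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class DesignMask:
    """Partition of design-chain positions into fixed and free sets."""

    fixed: frozenset[tuple[str, int]]
    free: frozenset[tuple[str, int]]
    sources: dict[tuple[str, int], tuple[str, ...]]
    design_chains: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.fixed & self.free:
            raise ValueError("fixed and free position sets overlap")

    @property
    def all_positions(self) -> frozenset[tuple[str, int]]:
        return self.fixed | self.free

    @property
    def n_fixed(self) -> int:
        return len(self.fixed)

    @property
    def fraction_fixed(self) -> float:
        total = len(self.fixed) + len(self.free)
        return len(self.fixed) / total if total else 0.0


# ---------------------------------------------------------------------------
# ligand shell
# ---------------------------------------------------------------------------

def resolve_ligand(
    structure: Structure,
    ligand: str,
    include_waters: bool = False,
    include_monoatomic: bool = False,
) -> list[Residue]:
    """Resolve a ligand selector to hetero groups or a whole chain.

    ``ligand`` is either a hetero-group residue name (het code, e.g. HEM)
    or a chain id (a peptide-substrate chain). Waters and monoatomic
    groups (ions) are excluded by default.
    """
    groups = [
        g for g in structure.hetero_groups
        if g.res_name == ligand
        and (include_waters or not g.is_water)
        and (include_monoatomic or len(g.heavy_coords()) > _MONOATOMIC_MAX)
    ]
    if groups:
        return groups
    if ligand in structure.chain_ids():
        return list(structure.get_chain(ligand).residues)
    available = sorted({
        g.res_name for g in structure.hetero_groups
        if not g.is_water and len(g.heavy_coords()) > _MONOATOMIC_MAX
    })
    raise KeyError(
        f"ligand {ligand!r} not found; available hetero groups: "
        f"{', '.join(available) or '(none)'}; chains: {', '.join(structure.chain_ids())}"
    )


def ligand_shell(
    structure: Structure,
    ligand: str,
    cutoff: float = 7.0,
    include_waters: bool = False,
    exclude_chains: tuple[str, ...] = (),
) -> ResidueSelection:
    """First-shell residues: any heavy atom within ``cutoff`` Å of any heavy
    ligand atom.

    Hydrogens are ignored on both sides. When the ligand is itself a
    polymer chain (a peptide substrate), that chain is excluded from the
    returned selection.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    groups = resolve_ligand(structure, ligand, include_waters=include_waters)
    lig_pts = np.vstack([g.heavy_coords() for g in groups])
    if lig_pts.size == 0:
        raise ValueError(f"ligand {ligand!r} has no heavy atoms")
    lig_is_chain = ligand in structure.chain_ids() and not any(
        g.res_name == ligand for g in structure.hetero_groups
    )
    skip = set(exclude_chains)
    if lig_is_chain:
        skip.add(ligand)
    hits: set[tuple[str, int]] = set()
    for chain in structure.chains:
        if chain.id in skip:
            continue
        for res in chain:
            pts = res.heavy_coords()
            if pts.size and cdist(pts, lig_pts).min() <= cutoff:
                hits.add((chain.id, res.seq_index))
    return ResidueSelection(positions=frozenset(hits), label="shell")


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def conservation_scores(msa: Msa, metric: str = "parent_identity_frequency") -> ConservationProfile:
    """Score each ungapped parent position by conservation.

    Default metric: fraction of rows whose residue equals the parent's at
    that column. Gaps count in the denominator, not the numerator, so a
    column where homologs are mostly deleted scores low.
    """
    if msa.n_rows < 2:
        raise ValueError("conservation requires an alignment with at least 2 rows")
    if metric != "parent_identity_frequency":
        raise ValueError(f"unknown conservation metric {metric!r}")
    parent = msa.rows[msa.parent_row]
    cols = msa.parent_columns()
    n = msa.n_rows
    scores = np.empty(len(cols))
    for i, j in enumerate(cols):
        target = parent[j]
        scores[i] = sum(1 for row in msa.rows if row[j] == target) / n
    return ConservationProfile(scores=scores, n_effective=n, metric_name=metric)


def top_conserved(profile: ConservationProfile, percent: float, chain: str) -> ResidueSelection:
    """Select the ceil(percent/100 × n) most conserved parent positions.

    Ties are broken by ascending position index, which makes selections at
    increasing percentages nested. Positions are reported as
    ``(chain, seq_index)`` with 1-based indices along the parent sequence.
    """
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    n = len(profile)
    k = math.ceil(percent / 100.0 * n)
    order = sorted(range(n), key=lambda i: (-profile.scores[i], i))
    chosen = frozenset((chain, i + 1) for i in order[:k])
    return ResidueSelection(positions=chosen, label="conserved")


# ---------------------------------------------------------------------------
# mask assembly and emission
# ---------------------------------------------------------------------------

def build_mask(
    structure: Structure,
    selections: list[ResidueSelection],
    design_chains: tuple[str, ...] | list[str],
) -> DesignMask:
    """Union the selections into a fixed set; the complement over the
    design chains is free. Provenance labels are merged per position."""
    design_chains = tuple(design_chains)
    for cid in design_chains:
        structure.get_chain(cid)
    universe = frozenset(
        (cid, res.seq_index)
        for cid in design_chains
        for res in structure.get_chain(cid)
    )
    sources: dict[tuple[str, int], tuple[str, ...]] = {}
    for sel in selections:
        sel.validate(structure)
        for pos in sel.positions:
            if pos[0] not in design_chains:
                raise ValueError(
                    f"selection {sel.label!r} references chain {pos[0]!r} "
                    f"outside design chains {design_chains}"
                )
            labels = sources.get(pos, ())
            if sel.label not in labels:
                sources[pos] = labels + (sel.label,)
    fixed = frozenset(sources)
    return DesignMask(
        fixed=fixed,
        free=universe - fixed,
        sources=sources,
        design_chains=design_chains,
    )


def emit_fixed_positions(mask: DesignMask, name: str) -> str:
    """Serialize the mask in the fixed-position JSON dialect.

    Shape: ``{name: {chain_id: [ascending seq_index ...]}}``. Every design
    chain appears, with an empty list when nothing is fixed on it. Keys and
    lists are sorted so identical masks emit byte-identical files.
    """
    per_chain: dict[str, list[int]] = {cid: [] for cid in mask.design_chains}
    for cid, idx in mask.fixed:
        per_chain[cid].append(idx)
    payload = {name: {cid: sorted(v) for cid, v in per_chain.items()}}
    return json.dumps(payload, sort_keys=True, separators=(", ", ": "))


def mask_report(mask: DesignMask, structure: Structure) -> pd.DataFrame:
    """Per-position table: chain, seq_index, auth_seq_id, residue name,
    fixed/free status and provenance. Summary counts in ``df.attrs``."""
    rows = []
    for cid in mask.design_chains:
        for res in structure.get_chain(cid):
            pos = (cid, res.seq_index)
            fixed = pos in mask.fixed
            rows.append({
                "chain": cid,
                "seq_index": res.seq_index,
                "auth_seq_id": f"{res.auth_seq_id}{res.icode}",
                "res_name": res.res_name,
                "status": "fixed" if fixed else "free",
                "provenance": ",".join(mask.sources.get(pos, ())),
            })
    df = pd.DataFrame(rows, columns=["chain", "seq_index", "auth_seq_id",
                                     "res_name", "status", "provenance"])
    n_fixed = mask.n_fixed
    n_total = len(df)
    df.attrs["n_fixed"] = n_fixed
    df.attrs["n_free"] = n_total - n_fixed
    df.attrs["fraction_fixed"] = n_fixed / n_total if n_total else 0.0
    return df
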