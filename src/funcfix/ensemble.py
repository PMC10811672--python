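"""Conformational-ensemble rigidity and catalytic-dyad geometry.

Operates on coordinate ensembles — MD trajectory snapshots or ensembles
of predicted models written as multi-model PDB — and computes the
summary statistics used to relate variant dynamics to activity:

* per-residue Cα RMSF after rigid superposition of every frame onto the
  first (rigidification shows up as lowered RMSF, typically in loops);
* mean RMSF over named residue spans (region rigidity);
* per-frame internal distances between a chosen atom pair, e.g. the
  catalytic Cys SG – His NE2 dyad distance of a cysteine protease; and
* the fraction of frames with that distance at or below a cutoff — the
  population of catalytically competent conformations. The competence
  cutoff defaults to 4.0 Å but is a judgment call the caller must own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structio import Structure, read_models
from .triage import DesignCandidate, kabsch_superpose

DEFAULT_DYAD_CUTOFF = 4.0  # Å, Cys SG – His N; user-confirmable


@dataclass
class Ensemble:
    """Same-topology coordinate frames with shared atom labels.

    ``coords`` is (n_frames, n_atoms, 3) in Å. ``atom_keys`` maps each
    atom column to ``(chain_id, auth_seq_id, atom_name)``; ``ca_index``
    lists the columns holding Cα atoms, and ``residue_keys`` their
    ``(chain_id, auth_seq_id)`` labels in order.
    """

    coords: np.ndarray
    atom_keys: list[tuple[str, int, str]]
    source: str = "trajectory"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atom_keys):
            raise ValueError("atom_keys length must match the atom dimension")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def ca_index(self) -> np.ndarray:
        return np.array([i for i, (_, _, name) in enumerate(self.atom_keys) if name == "CA"],
                        dtype=int)

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        return [(c, r) for c, r, name in self.atom_keys if name == "CA"]

    def atom_column(self, chain_id: str, auth_seq_id: int, atom_name: str) -> int:
        key = (chain_id, auth_seq_id, atom_name)
        try:
            return self.atom_keys.index(key)
        except ValueError:
            raise KeyError(f"atom {chain_id}:{auth_seq_id}:{atom_name} not in ensemble") from None

    @classmethod
    def from_structures(cls, frames: list[Structure], source: str = "trajectory") -> "Ensemble":
        if len(frames) < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        keys = _atom_keys(frames[0])
        coords = np.empty((len(frames), len(keys), 3))
        for fi, st in enumerate(frames):
            k = _atom_keys(st)
            if k != keys:
                raise ValueError(f"frame {fi} atom topology differs from frame 0")
            coords[fi] = _atom_coords(st)
        return cls(coords=coords, atom_keys=keys, source=source)


def _atom_keys(st: Structure) -> list[tuple[str, int, str]]:
    keys = [(c.id, r.auth_seq_id, a.name) for c in st.chains for r in c for a in r.atoms]
    keys += [(r.chain_id, r.auth_seq_id, a.name) for r in st.hetero_groups for a in r.atoms]
    return keys


def _atom_coords(st: Structure) -> np.ndarray:
    pts = [a.coords for c in st.chains for r in c for a in r.atoms]
    pts += [a.coords for r in st.hetero_groups for a in r.atoms]
    return np.array(pts, dtype=float)


def read_ensemble(path: str | Path) -> Ensemble:
    """Read a multi-model PDB as an ensemble of same-topology frames."""
    return Ensemble.from_structures(read_models(path))


def write_ensemble(ensemble: Ensemble, path: str | Path,
                   template: Structure | None = None) -> None:
    """Write an ensemble as a multi-model PDB file.

    Residue names are taken from ``template`` where its
    (chain, auth_seq_id) labels match; unmatched residues are written as
    UNK. Elements are guessed from the first letter of the atom name.
    """
    import gemmi

    names: dict[tuple[str, int], str] = {}
    if template is not None:
        for c in template.chains:
            for r in c:
                names[(c.id, r.auth_seq_id)] = r.res_name
        for r in template.hetero_groups:
            names[(r.chain_id, r.auth_seq_id)] = r.res_name

    # group atom columns by chain, then residue, preserving first-seen order
    layout: dict[str, dict[tuple[int, str], list[tuple[int, str]]]] = {}
    for ai, (cid, num, aname) in enumerate(ensemble.atom_keys):
        layout.setdefault(cid, {}).setdefault((num, names.get((cid, num), "UNK")), []).append(
            (ai, aname)
        )

    st = gemmi.Structure()
    st.name = "ensemble"
    for fi in range(ensemble.n_frames):
        model = gemmi.Model(str(fi + 1))
        for cid, res_map in layout.items():
            gchain = gemmi.Chain(cid)
            for (num, rname), atoms in res_map.items():
                gres = gemmi.Residue()
                gres.name = rname
                gres.seqid = gemmi.SeqId(num, " ")
                gres.het_flag = "A"
                for ai, aname in atoms:
                    gat = gemmi.Atom()
                    gat.name = aname
                    gat.element = gemmi.Element(aname[:1])
                    gat.pos = gemmi.Position(*ensemble.coords[fi, ai])
                    gres.add_atom(gat)
                gchain.add_residue(gres)
            model.add_chain(gchain)
        st.add_model(model)
    st.write_pdb(str(path))


@dataclass
class EnsembleStats:
    """Per-residue fluctuation plus dyad-distance populations."""

    rmsf: np.ndarray                       # per-residue Å
    residue_keys: list[tuple[str, int]]
    region_means: dict[str, float] = field(default_factory=dict)
    dyad_distances: np.ndarray | None = None
    competent_fraction: float | None = None

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF values must be nonnegative")
        if self.competent_fraction is not None and not 0 <= self.competent_fraction <= 1:
            raise ValueError("competent_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def superpose_frames(ensemble: Ensemble, selection: np.ndarray | list[int] | None = None) -> Ensemble:
    """Rigid-fit every frame onto the first over a column selection.

    ``selection`` defaults to the Cα columns. Returns a new ensemble;
    the input is not modified.
    """
    if ensemble.n_frames < 2:
        raise ValueError("superposition needs at least 2 frames")
    sel = ensemble.ca_index if selection is None else np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty fit selection")
    ref = ensemble.coords[0, sel]
    out = np.empty_like(ensemble.coords)
    out[0] = ensemble.coords[0]
    for fi in range(1, ensemble.n_frames):
        rot, trans, _ = kabsch_superpose(ref, ensemble.coords[fi, sel])
        out[fi] = ensemble.coords[fi] @ rot.T + trans
    return Ensemble(coords=out, atom_keys=list(ensemble.atom_keys), source=ensemble.source)


def per_residue_rmsf(ensemble: Ensemble, superposed: bool = True) -> EnsembleStats:
    """Cα root-mean-square fluctuation about the per-residue mean position.

    Frames are superposed onto the first over Cα unless ``superposed``
    says they already are. RMSF_i = sqrt(mean_t |x_i(t) − ⟨x_i⟩|²).
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    ens = ensemble if superposed else superpose_frames(ensemble)
    ca = ens.coords[:, ens.ca_index]                  # (frames, residues, 3)
    mean = ca.mean(axis=0)
    rmsf = np.sqrt(((ca - mean) ** 2).sum(axis=2).mean(axis=0))
    return EnsembleStats(rmsf=rmsf, residue_keys=ens.residue_keys)


def region_rigidity(stats: EnsembleStats, start: int, end: int, chain: str | None = None) -> float:
    """Mean RMSF (Å) over author residue numbers ``start``..``end`` inclusive."""
    vals = [
        stats.rmsf[i]
        for i, (cid, num) in enumerate(stats.residue_keys)
        if start <= num <= end and (chain is None or cid == chain)
    ]
    if not vals:
        raise ValueError(f"no residues in span {start}-{end}"
                         + (f" on chain {chain}" if chain else ""))
    return float(np.mean(vals))


def dyad_distance_series(
    ensemble: Ensemble,
    atom_a: tuple[str, int, str],
    atom_b: tuple[str, int, str],
) -> np.ndarray:
    """Per-frame Euclidean distance between two atoms (an internal
    coordinate — no superposition involved)."""
    ia = ensemble.atom_column(*atom_a)
    ib = ensemble.atom_column(*atom_b)
    diff = ensemble.coords[:, ia] - ensemble.coords[:, ib]
    return np.sqrt((diff ** 2).sum(axis=1))


def competent_fraction(distances: np.ndarray, cutoff: float = DEFAULT_DYAD_CUTOFF) -> float:
    """Fraction of frames with dyad distance ≤ cutoff (Å)."""
    distances = np.asarray(distances, dtype=float).ravel()
    if distances.size == 0:
        raise ValueError("empty distance series")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return float(np.mean(distances <= cutoff))


def ensemble_plddt_profile(models: list[DesignCandidate]) -> pd.DataFrame:
    """Per-position mean and population-SD of pLDDT across models."""
    if not models:
        raise ValueError("no models given")
    n = len(models[0].plddt)
    for m in models:
        if len(m.plddt) != n:
            raise ValueError(f"model {m.id} has {len(m.plddt)} residues, expected {n}")
    mat = np.vstack([m.plddt for m in models])
    return pd.DataFrame({
        "position": np.arange(1, n + 1),
        "mean_plddt": mat.mean(axis=0),
        "sd_plddt": mat.std(axis=0, ddof=0),
    })


def rmsf_report(stats: EnsembleStats) -> pd.DataFrame:
    """TSV-ready per-residue RMSF profile."""
    return pd.DataFrame({
        "chain": [c for c, _ in stats.residue_keys],
        "auth_seq_id": [n for _, n in stats.residue_keys],
        "rmsf": stats.rmsf,
    })
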