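"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator builds a toy version of one input class — structures with
a pseudo-ligand at controlled distances, alignments with exact per-column
conservation, rate tables from known Michaelis–Menten parameters, melt
curves with a known midpoint, coordinate ensembles with known per-residue
variance and dyad-mode occupancies — and returns the planted truth
alongside the data. Analysis-of-generated-data round trips are the
backbone of the test suite: noise-free fixtures must be recovered
exactly, noisy ones within stated statistical tolerance.

All randomness flows through an explicit integer seed
(`numpy.random.default_rng`); the same seed and parameters reproduce the
same bytes on any platform. Toy chains use ideal α-helix Cα geometry
(2.3 Å radius, 1.5 Å rise, 100° twist per residue) so the emitted PDB
files are also valid input for external tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design_space import ResidueSelection
from .ensemble import Ensemble
from .kinetics import MeltCurve, RateTable, michaelis_menten
from .structio import Atom, Chain, Msa, Residue, Structure
from .triage import DesignCandidate

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA3_BY_1 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# ideal alpha-helix Calpha parameters
_HELIX_RADIUS = 2.3   # Å
_HELIX_RISE = 1.5     # Å per residue
_HELIX_TWIST = 100.0  # degrees per residue


def helix_ca_coords(n_res: int) -> np.ndarray:
    """Ideal α-helix Cα trace, axis along z."""
    i = np.arange(n_res)
    theta = np.deg2rad(_HELIX_TWIST) * i
    return np.column_stack([
        _HELIX_RADIUS * np.cos(theta),
        _HELIX_RADIUS * np.sin(theta),
        _HELIX_RISE * i,
    ])


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

@dataclass
class ToyStructure:
    """A helical toy chain, its pseudo-ligand, and the exact shell truth."""

    structure: Structure
    min_distances: np.ndarray   # per-residue min heavy-atom distance to the ligand, Å
    chain_id: str = "A"

    def true_shell(self, cutoff: float) -> ResidueSelection:
        """The analytically known first shell at any cutoff."""
        hits = frozenset(
            (self.chain_id, i + 1)
            for i, d in enumerate(self.min_distances)
            if d <= cutoff
        )
        return ResidueSelection(positions=hits, label="shell")


def make_toy_structure(
    n_res: int,
    ligand_offsets: list[float] | np.ndarray,
    seed: int,
    ligand_name: str = "LIG",
) -> ToyStructure:
    """Helical chain plus a pseudo-ligand at controlled distances.

    ``ligand_offsets[j]`` places one ligand atom radially outward from
    residue j+1's Cα at that distance; the returned truth records the
    actual per-residue minimum distance to any ligand atom, so the shell
    at any cutoff is known exactly by construction.
    """
    if n_res < 3:
        raise ValueError("n_res must be at least 3")
    rng = np.random.default_rng(seed)
    ca = helix_ca_coords(n_res)
    residues = []
    for i in range(n_res):
        one = rng.choice(list(_AA20))
        residues.append(Residue(
            chain_id="A", auth_seq_id=i + 1, res_name=_AA3_BY_1[one],
            atoms=[Atom(name="CA", element="C", coords=ca[i])],
            seq_index=i + 1,
        ))
    lig_atoms = []
    for j, off in enumerate(ligand_offsets):
        if j >= n_res:
            raise ValueError("more ligand offsets than residues")
        radial = ca[j].copy()
        radial[2] = 0.0
        u = radial / np.linalg.norm(radial)
        pos = ca[j] + float(off) * u
        lig_atoms.append(Atom(name=f"L{j + 1}", element="C", coords=pos))
    hetero = []
    if lig_atoms:
        hetero.append(Residue(chain_id="L", auth_seq_id=1, res_name=ligand_name,
                              atoms=lig_atoms, is_hetero=True))
        lig_pts = np.array([a.coords for a in lig_atoms])
        dmat = np.sqrt(((ca[:, None, :] - lig_pts[None, :, :]) ** 2).sum(axis=2))
        min_d = dmat.min(axis=1)
    else:
        min_d = np.full(n_res, np.inf)
    st = Structure(id="toy", chains=[Chain(id="A", residues=residues)], hetero_groups=hetero)
    return ToyStructure(structure=st, min_distances=min_d)


# ---------------------------------------------------------------------------
# toy MSAs
# ---------------------------------------------------------------------------

def make_toy_msa(
    parent: str,
    n_rows: int,
    conservation: list[float] | np.ndarray,
    seed: int,
    gap_fraction_of_mismatches: float = 0.3,
) -> tuple[Msa, np.ndarray]:
    """MSA whose per-column parent-identity frequency is exact by design.

    ``conservation[j]`` must equal k/n_rows for an integer k ≥ 1 (the
    parent row always matches itself). Mismatching rows get a different
    residue, or a gap with probability ``gap_fraction_of_mismatches``
    (gaps count against conservation exactly like substitutions).
    Returns the alignment and the planted per-column profile.
    """
    conservation = np.asarray(conservation, dtype=float)
    if len(conservation) != len(parent):
        raise ValueError("one conservation target per parent position required")
    rng = np.random.default_rng(seed)
    counts = []
    for j, f in enumerate(conservation):
        k = f * n_rows
        k_int = round(k)
        if abs(k - k_int) > 1e-9 or not 1 <= k_int <= n_rows:
            raise ValueError(
                f"column {j}: target {f} unattainable with {n_rows} rows "
                f"(needs an integer count in 1..{n_rows})"
            )
        counts.append(k_int)
    cols = []
    for j, k in enumerate(counts):
        p = parent[j]
        col = [p] * n_rows
        others = rng.permutation(np.arange(1, n_rows))  # row 0 stays parent
        for r in others[: n_rows - k]:
            if rng.random() < gap_fraction_of_mismatches:
                col[r] = "-"
            else:
                choices = [a for a in _AA20 if a != p]
                col[r] = choices[rng.integers(len(choices))]
        cols.append(col)
    rows = ["".join(cols[j][r] for j in range(len(parent))) for r in range(n_rows)]
    ids = ["parent"] + [f"homolog_{r}" for r in range(1, n_rows)]
    msa = Msa(rows=rows, ids=ids, parent_row=0)
    return msa, np.array(counts, dtype=float) / n_rows


# ---------------------------------------------------------------------------
# candidate designs
# ---------------------------------------------------------------------------

def make_candidates(
    reference: Structure,
    plddts: list[float],
    noise_sigmas: list[float],
    seed: int,
    chain: str | None = None,
    n_mutations: int = 0,
) -> list[DesignCandidate]:
    """Mock designs: parent backbone plus per-atom Gaussian noise and a
    random rigid motion, each with a flat planted pLDDT profile.

    ``noise_sigmas[i] = 0`` gives a model congruent with the reference
    (Cα RMSD exactly 0 after superposition). ``n_mutations`` positions of
    the sequence are substituted to lower identity to the parent.
    """
    if len(plddts) != len(noise_sigmas):
        raise ValueError("plddts and noise_sigmas must have equal length")
    rng = np.random.default_rng(seed)
    cid = chain or reference.chains[0].id
    ref_ca = reference.get_chain(cid).ca_coords()
    parent_seq = "".join(r.one_letter for r in reference.get_chain(cid))
    out = []
    for i, (plddt, sigma) in enumerate(zip(plddts, noise_sigmas)):
        coords = ref_ca + rng.normal(0.0, sigma, size=ref_ca.shape)
        coords = _random_rigid_motion(coords, rng)
        seq = list(parent_seq)
        for pos in rng.choice(len(seq), size=min(n_mutations, len(seq)), replace=False):
            choices = [a for a in _AA20 if a != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
        out.append(DesignCandidate(
            id=f"design_{i:03d}",
            sequence="".join(seq),
            model_ca=coords,
            plddt=np.full(len(seq), float(plddt)),
        ))
    return out


def _random_rigid_motion(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a uniformly random proper rotation and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.uniform(-20.0, 20.0, size=3)
    return coords @ rot.T + trans


# ---------------------------------------------------------------------------
# kinetic and melt data
# ---------------------------------------------------------------------------

def make_rate_table(
    kcat: float,
    km: float,
    enzyme_conc: float,
    substrate_levels: list[float] | np.ndarray,
    noise_rel: float,
    seed: int,
) -> RateTable:
    """Rate table v = kcat·E·S/(Km+S) · (1 + ε), ε ~ N(0, noise_rel²)."""
    if km <= 0:
        raise ValueError("Km must be positive")
    rng = np.random.default_rng(seed)
    s = np.asarray(substrate_levels, dtype=float)
    v = michaelis_menten(s, kcat, km, enzyme_conc)
    if noise_rel > 0:
        v = v * (1.0 + rng.normal(0.0, noise_rel, size=s.shape))
    return RateTable(substrate_conc=s, rate=v, enzyme_conc=enzyme_conc)


def make_melt_curve(
    tm: float,
    width: float = 2.5,
    baselines: tuple[float, float] = (1.0, 0.0),
    noise: float = 0.0,
    seed: int = 0,
    temp_range: tuple[float, float] = (20.0, 95.0),
    n_points: int = 76,
) -> MeltCurve:
    """Two-state melt with midpoint ``tm`` and flat pre/post baselines.

    ``baselines`` are the folded and unfolded signal levels. ``noise`` is
    the Gaussian noise SD relative to the baseline separation; when the
    baselines coincide the curve is flat (the no-transition case).
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(*temp_range, n_points)
    folded, unfolded = baselines
    frac_unfolded = 1.0 / (1.0 + np.exp(-(t - tm) / width))
    y = folded + (unfolded - folded) * frac_unfolded
    if noise > 0:
        scale = abs(unfolded - folded) or max(abs(folded), 1.0)
        y = y + rng.normal(0.0, noise * scale, size=t.shape)
    return MeltCurve(temperature=t, signal=y)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleTruth:
    """Planted parameters of a generated ensemble."""

    per_residue_sigma: np.ndarray
    dyad_distances: np.ndarray | None
    dyad_mode_fractions: np.ndarray | None
    dyad_atoms: tuple[tuple[str, int, str], tuple[str, int, str]] | None

    def competent_fraction(self, cutoff: float) -> float:
        if self.dyad_distances is None:
            raise ValueError("fixture has no dyad pair")
        return float(np.mean(self.dyad_distances <= cutoff))


def make_ensemble(
    base: Structure,
    per_residue_sigma: list[float] | np.ndarray,
    n_frames: int,
    seed: int,
    dyad_modes: tuple[list[float], list[float]] | None = None,
    rigid_motion: bool = False,
) -> tuple[Ensemble, EnsembleTruth]:
    """Ensemble of frames = base + isotropic per-residue Gaussian noise.

    Every atom of residue i is displaced by an independent N(0, σ_i² I)
    vector per frame. When ``dyad_modes = (distances, fractions)`` is
    given, a Cys SG / His NE2 atom pair is appended to the first and last
    residues and placed at exactly the sampled mode distance each frame
    (exact allocation: round(f·n_frames) frames per mode, order shuffled
    by the seed). ``rigid_motion`` additionally applies a random rigid
    motion per frame, to be removed by superposition.
    """
    sigma = np.asarray(per_residue_sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma values must be nonnegative")
    chain = base.chains[0]
    if len(sigma) != len(chain):
        raise ValueError("one sigma per residue of the first chain required")
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    rng = np.random.default_rng(seed)

    keys: list[tuple[str, int, str]] = []
    base_pts: list[np.ndarray] = []
    res_of_atom: list[int] = []
    for ri, res in enumerate(chain):
        for at in res.atoms:
            keys.append((chain.id, res.auth_seq_id, at.name))
            base_pts.append(at.coords)
            res_of_atom.append(ri)
    base_arr = np.array(base_pts)

    dyad_truth = None
    fractions = None
    dyad_atoms = None
    if dyad_modes is not None:
        modes, fracs = np.asarray(dyad_modes[0], float), np.asarray(dyad_modes[1], float)
        if not math.isclose(fracs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("dyad mode fractions must sum to 1")
        counts = np.round(fracs * n_frames).astype(int)
        counts[-1] = n_frames - counts[:-1].sum()
        if np.any(counts < 0):
            raise ValueError("dyad mode fractions incompatible with n_frames")
        assignment = np.repeat(np.arange(len(modes)), counts)
        rng.shuffle(assignment)
        dyad_truth = modes[assignment]
        fractions = fracs
        first, last = chain.residues[0], chain.residues[-1]
        dyad_atoms = ((chain.id, first.auth_seq_id, "SG"),
                      (chain.id, last.auth_seq_id, "NE2"))
        keys.append(dyad_atoms[0])
        keys.append(dyad_atoms[1])

    n_atoms = len(keys)
    coords = np.empty((n_frames, n_atoms, 3))
    n_res_atoms = len(base_arr)
    anchor = base_arr.mean(axis=0) + np.array([8.0, 0.0, 0.0])  # SG site, off to the side
    for f in range(n_frames):
        disp = rng.normal(size=(n_res_atoms, 3)) * sigma[res_of_atom][:, None]
        frame = base_arr + disp
        if dyad_modes is not None:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            sg = anchor
            ne2 = anchor + dyad_truth[f] * u
            frame = np.vstack([frame, sg, ne2])
        if rigid_motion:
            frame = _random_rigid_motion(frame, rng)
        coords[f] = frame

    ens = Ensemble(coords=coords, atom_keys=keys, source="synthetic")
    truth = EnsembleTruth(
        per_residue_sigma=sigma,
        dyad_distances=dyad_truth,
        dyad_mode_fractions=fractions,
        dyad_atoms=dyad_atoms,
    )
    return ens, truth
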