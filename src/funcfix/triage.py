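"""Candidate-design triage: prediction confidence, backbone RMSD, identity.

Sequence designs for a fixed backbone are screened before experimental
testing by (i) the mean per-residue confidence (pLDDT, 0–100) of a
structure prediction of the designed sequence and (ii) the Cα RMSD of
that predicted model to the input backbone after optimal rigid
superposition. The default thresholds — pLDDT strictly above 85.0 and
RMSD strictly below 1.0 Å — mirror common single-sequence-prediction
filtering practice for native-backbone redesign.

Superposition is the Kabsch algorithm (SVD of the covariance matrix with
reflection correction). Superposition and RMSD are always computed over
the same residue selection, so region-wise numbers are self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structio import Structure, read_structure, extract_sequence
from .design_space import ResidueSelection


@dataclass
class DesignCandidate:
    """A designed sequence with its predicted model Cα trace and confidence."""

    id: str
    sequence: str
    model_ca: np.ndarray        # (n, 3) Å
    plddt: np.ndarray           # per-residue, 0–100

    def __post_init__(self) -> None:
        self.model_ca = np.asarray(self.model_ca, dtype=float).reshape(-1, 3)
        self.plddt = np.asarray(self.plddt, dtype=float).ravel()
        n = len(self.sequence)
        if self.model_ca.shape[0] != n or self.plddt.shape[0] != n:
            raise ValueError(
                f"candidate {self.id}: sequence ({n}), model ({self.model_ca.shape[0]}) "
                f"and plddt ({self.plddt.shape[0]}) lengths differ"
            )
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ValueError(f"candidate {self.id}: pLDDT values outside [0, 100]")

    @property
    def mean_plddt(self) -> float:
        return float(self.plddt.mean())


@dataclass
class TriageResult:
    id: str
    mean_plddt: float
    ca_rmsd: float
    identity_to_parent: float | None
    passed: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed flag inconsistent with failure reasons")


def load_candidate(path: str | Path, chain: str | None = None) -> DesignCandidate:
    """Load a predicted-model PDB (pLDDT in the B-factor column) as a candidate."""
    st = read_structure(path)
    cid = chain or st.chains[0].id
    ch = st.get_chain(cid)
    seq = extract_sequence(st, cid)
    ca = ch.ca_coords()
    plddt = np.array([r.atom("CA").bfactor for r in ch])
    return DesignCandidate(id=Path(path).stem, sequence=seq, model_ca=ca, plddt=plddt)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``q`` onto ``p``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``q @ rotation.T + translation`` best fits ``p``. The rotation is
    proper (det = +1): if the optimal orthogonal transform is a
    reflection, the singular direction with the smallest singular value
    is flipped.

    Raises for fewer than 3 points (under-determined). Collinear or
    coincident point sets are degenerate but still yield the minimal RMSD.
    """
    p = np.asarray(p, dtype=float).reshape(-1, 3)
    q = np.asarray(q, dtype=float).reshape(-1, 3)
    if p.shape != q.shape:
        raise ValueError(f"point sets differ in shape: {p.shape} vs {q.shape}")
    n = p.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs at least 3 points, got {n}")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    h = q0.T @ p0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = pc - qc @ rot.T
    diff = q0 @ rot.T - p0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return rot, trans, rmsd


def ca_rmsd(
    candidate: DesignCandidate,
    reference: Structure,
    selection: ResidueSelection | None = None,
    chain: str | None = None,
) -> float:
    """Cα RMSD (Å) of the candidate model to the reference design chain.

    Superposition and measurement use the same residue subset: all
    positions by default, or the ``selection`` (e.g. a remodeled loop).
    Candidate and reference must have equal length — designs here are
    fixed-length sequence redesigns, so a mismatch is an input error, not
    something to truncate silently.
    """
    cid = chain or reference.chains[0].id
    ref_ca = reference.get_chain(cid).ca_coords()
    if ref_ca.shape[0] != candidate.model_ca.shape[0]:
        raise ValueError(
            f"candidate {candidate.id} has {candidate.model_ca.shape[0]} residues but "
            f"reference chain {cid} has {ref_ca.shape[0]}; fixed-length designs required"
        )
    if selection is not None:
        idx = sorted(i for c, i in selection.positions if c == cid)
        if not idx:
            raise ValueError(f"selection contains no positions on chain {cid}")
        rows = [i - 1 for i in idx]
        ref_ca = ref_ca[rows]
        mob = candidate.model_ca[rows]
    else:
        mob = candidate.model_ca
    _, _, rmsd = kabsch_superpose(ref_ca, mob)
    return rmsd


def percent_identity(a: str, b: str) -> float:
    """Positional sequence identity in percent; sequences must align 1:1."""
    if len(a) != len(b):
        raise ValueError(
            f"sequences differ in length ({len(a)} vs {len(b)}); positional identity "
            "is defined for equal-length sequences — align them externally first"
        )
    if not a:
        raise ValueError("empty sequences")
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_candidates(
    candidates: list[DesignCandidate],
    reference: Structure,
    plddt_min: float = 85.0,
    rmsd_max: float = 1.0,
    chain: str | None = None,
    parent_sequence: str | None = None,
) -> list[TriageResult]:
    """Apply the confidence/RMSD filter to each candidate.

    A candidate passes iff ``mean_plddt > plddt_min`` and
    ``ca_rmsd < rmsd_max`` — strict inequalities, so a candidate exactly
    at a threshold fails. Input order is preserved.
    """
    if not np.isfinite(plddt_min) or not np.isfinite(rmsd_max):
        raise ValueError("thresholds must be finite")
    if parent_sequence is None:
        cid = chain or reference.chains[0].id
        parent_sequence = extract_sequence(reference, cid)
    results = []
    for cand in candidates:
        rmsd = ca_rmsd(cand, reference, chain=chain)
        ident = (percent_identity(cand.sequence, parent_sequence)
                 if len(cand.sequence) == len(parent_sequence) else None)
        reasons = []
        if not cand.mean_plddt > plddt_min:
            reasons.append(f"mean_plddt {cand.mean_plddt:.2f} <= {plddt_min}")
        if not rmsd < rmsd_max:
            reasons.append(f"ca_rmsd {rmsd:.3f} >= {rmsd_max}")
        results.append(TriageResult(
            id=cand.id,
            mean_plddt=cand.mean_plddt,
            ca_rmsd=rmsd,
            identity_to_parent=ident,
            passed=not reasons,
            reasons=tuple(reasons),
        ))
    return results


def triage_report(results: list[TriageResult]) -> pd.DataFrame:
    """TSV-ready table sorted by (pass desc, mean pLDDT desc)."""
    rows = [{
        "id": r.id,
        "mean_plddt": round(r.mean_plddt, 3),
        "ca_rmsd": round(r.ca_rmsd, 4),
        "identity_to_parent": None if r.identity_to_parent is None else round(r.identity_to_parent, 2),
        "pass": r.passed,
        "reasons": ";".join(r.reasons),
    } for r in results]
    df = pd.DataFrame(rows, columns=["id", "mean_plddt", "ca_rmsd",
                                     "identity_to_parent", "pass", "reasons"])
    if len(df):
        df = df.sort_values(["pass", "mean_plddt"], ascending=[False, False],
                            kind="mergesort").reset_index(drop=True)
    df.attrs["n_pass"] = int(sum(r.passed for r in results))
    df.attrs["n_total"] = len(results)
    return df
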