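"""Groove-geometry descriptors measured on peptide-MHC coordinate files.

Four descriptors capture how the C1/C2 dimorphism at heavy-chain
position 77 displaces the peptide's penultimate residue (pΩ-1):

* ``d77_pomega1`` — distance from the Cβ of heavy-chain residue 77 to
  the Cα of the peptide's penultimate residue.  The C1 groove holds
  pΩ-1 lower (shorter distance) than the C2 groove.
* ``d_tyr171_nterm`` — distance from the Tyr171 side-chain hydroxyl
  oxygen to the peptide p1 backbone nitrogen: a conserved A-pocket
  contact used as an internal control (same in C1 and C2).
* ``d_val76_side`` — minimum heavy-atom distance between the pΩ-1 side
  chain and the residue-76 side chain; within van der Waals range
  (3.3-4.0 A) only when pΩ-1 sits low in the groove.
* ``omega_term`` — the ω torsion of the terminal peptide bond,
  Cα(pΩ-1)-C(pΩ-1)-N(pΩ)-Cα(pΩ), which orients the pΩ-1 side chain
  either toward the α1 helix or out of the groove.  The auxiliary
  ψ(pΩ-1) dihedral is reported alongside.

Structures are read with gemmi (PDB or mmCIF); the first model is
used, and among alternate conformers the highest-occupancy one (ties
broken toward altloc "A").
"""

from __future__ import annotations

import logging
import math
import urllib.request
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .allotypes import Group
from .stats import welch_t_pvalue

log = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
PEPTIDE_MIN, PEPTIDE_MAX = 8, 11
HEAVY_MIN = 180  # MHC-I heavy chains in deposited constructs are ~270-280 aa


class ChainDetectionError(ValueError):
    """Peptide or heavy chain could not be identified unambiguously."""


class MissingAtomError(ValueError):
    """A required atom or residue is absent from the structure."""


class NoSideChainError(ValueError):
    """Glycine at a position where a side-chain descriptor is requested."""


@dataclass
class StructureModel:
    """A parsed peptide-MHC structure with designated chains.

    ``numbering_offset`` is added to the canonical heavy-chain residue
    numbers (76, 77, 171) before lookup, for files whose author
    numbering does not start at 1.
    """

    structure_id: str
    structure: gemmi.Structure
    heavy_chain: str
    peptide_chain: str
    group: Group | None = None
    numbering_offset: int = 0

    # -- residue / atom access ------------------------------------------------

    def _model(self) -> gemmi.Model:
        return self.structure[0]

    def peptide_residues(self) -> list[gemmi.Residue]:
        chain = self._model()[self.peptide_chain]
        return [r for r in chain if _is_amino_acid(r)]

    def heavy_residue(self, number: int) -> gemmi.Residue:
        chain = self._model()[self.heavy_chain]
        num = number + self.numbering_offset
        for res in chain:
            if res.seqid.num == num:
                return res
        raise MissingAtomError(
            f"{self.structure_id}: heavy chain {self.heavy_chain} has no residue {num}"
        )


def _is_amino_acid(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    return any(a.name == "CA" and not a.element.is_hydrogen for a in res)


def _pick_atom(res: gemmi.Residue, name: str, structure_id: str = "") -> gemmi.Atom:
    """Atom by name; among altlocs take highest occupancy, ties -> 'A'."""
    candidates = [a for a in res if a.name == name]
    if not candidates:
        raise MissingAtomError(
            f"{structure_id}: residue {res.name} {res.seqid.num} has no atom {name}"
        )
    return min(candidates, key=lambda a: (-a.occ, a.altloc or "A"))


def _pos(atom: gemmi.Atom) -> np.ndarray:
    return np.array([atom.pos.x, atom.pos.y, atom.pos.z])


def _side_chain_atoms(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Heavy atoms beyond the backbone (Cβ and outward), best altloc only."""
    names = {a.name for a in res if not a.element.is_hydrogen} - BACKBONE_ATOMS
    return [_pick_atom(res, n) for n in sorted(names)]


# -- loading -------------------------------------------------------------------


def load_structure(
    path: str | Path,
    heavy_chain: str | None = None,
    peptide_chain: str | None = None,
    group: Group | str | None = None,
    structure_id: str | None = None,
    numbering_offset: int = 0,
) -> StructureModel:
    """Read a PDB/mmCIF file and designate the heavy and peptide chains.

    When chain ids are not supplied, the peptide chain is auto-detected
    as the shortest polypeptide chain of 8-11 residues (an exact length
    tie between candidates is an error demanding explicit ids) and the
    heavy chain as a long chain containing residues 76, 77 and 171.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if structure_id is None:
        structure_id = st.name or path.stem
    if isinstance(group, str):
        group = Group(group)
    model = st[0]

    chain_lengths = {
        ch.name: sum(1 for r in ch if _is_amino_acid(r)) for ch in model
    }

    if peptide_chain is None:
        candidates = {
            name: n for name, n in chain_lengths.items() if PEPTIDE_MIN <= n <= PEPTIDE_MAX
        }
        if not candidates:
            raise ChainDetectionError(
                f"{structure_id}: no polypeptide chain of {PEPTIDE_MIN}-{PEPTIDE_MAX} residues"
            )
        shortest = min(candidates.values())
        tied = [name for name, n in candidates.items() if n == shortest]
        if len(tied) > 1:
            raise ChainDetectionError(
                f"{structure_id}: ambiguous peptide chain ({tied}); pass peptide_chain explicitly"
            )
        peptide_chain = tied[0]
        log.info("%s: auto-detected peptide chain %s (%d residues)", structure_id, peptide_chain, shortest)

    if heavy_chain is None:
        offset = numbering_offset
        found = []
        for ch in model:
            if ch.name == peptide_chain or chain_lengths[ch.name] < HEAVY_MIN:
                continue
            nums = {r.seqid.num for r in ch}
            if {76 + offset, 77 + offset, 171 + offset} <= nums:
                found.append(ch.name)
        if not found:
            raise ChainDetectionError(
                f"{structure_id}: no chain with residues 76/77/171 and >= {HEAVY_MIN} residues"
            )
        heavy_chain = found[0]
        log.info("%s: auto-detected heavy chain %s", structure_id, heavy_chain)

    names = {ch.name for ch in model}
    for required in (heavy_chain, peptide_chain):
        if required not in names:
            raise ChainDetectionError(f"{structure_id}: no chain named {required!r}")

    return StructureModel(
        structure_id=structure_id,
        structure=st,
        heavy_chain=heavy_chain,
        peptide_chain=peptide_chain,
        group=group,
        numbering_offset=numbering_offset,
    )


def fetch_pdb(accession: str, dest_dir: str | Path) -> Path:
    """Download a PDB entry from RCSB (explicit opt-in; needs network)."""
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / f"{accession.lower()}.cif"
    if not dest.exists():
        url = f"https://files.rcsb.org/download/{accession.upper()}.cif"
        log.info("fetching %s", url)
        urllib.request.urlretrieve(url, dest)
    return dest


# -- descriptors ---------------------------------------------------------------


def d77_pomega1(model: StructureModel) -> float:
    """Distance (A) from heavy-chain residue 77 Cβ to the peptide pΩ-1 Cα."""
    pep = model.peptide_residues()
    if len(pep) < 2:
        raise MissingAtomError(f"{model.structure_id}: peptide has fewer than 2 residues")
    cb = _pick_atom(model.heavy_residue(77), "CB", model.structure_id)
    ca = _pick_atom(pep[-2], "CA", model.structure_id)
    return float(np.linalg.norm(_pos(cb) - _pos(ca)))


def d_tyr171_nterm(model: StructureModel) -> float:
    """Distance (A) from Tyr171's hydroxyl oxygen to the peptide p1 backbone N.

    The tyrosine side-chain oxygen carries the standard atom name OH
    (the η-hydroxyl).
    """
    res171 = model.heavy_residue(171)
    if res171.name != "TYR":
        raise MissingAtomError(
            f"{model.structure_id}: heavy-chain residue 171 is {res171.name}, expected TYR"
        )
    oh = _pick_atom(res171, "OH", model.structure_id)
    pep = model.peptide_residues()
    n1 = _pick_atom(pep[0], "N", model.structure_id)
    return float(np.linalg.norm(_pos(oh) - _pos(n1)))


def mindist_side_chains(
    model: StructureModel, pep_index: int | None = None, heavy_number: int = 76
) -> float:
    """Minimum side-chain heavy-atom distance, peptide residue vs heavy residue.

    Defaults compare the peptide's penultimate residue (pΩ-1) with
    heavy-chain residue 76.  Backbone atoms (N, Cα, C, O, OXT) and
    hydrogens are excluded on both sides; glycine at either position
    raises :class:`NoSideChainError`.
    """
    pep = model.peptide_residues()
    res_p = pep[pep_index if pep_index is not None else len(pep) - 2]
    res_h = model.heavy_residue(heavy_number)
    for res in (res_p, res_h):
        if res.name == "GLY":
            raise NoSideChainError(
                f"{model.structure_id}: residue {res.name} {res.seqid.num} has no side chain"
            )
    atoms_p = _side_chain_atoms(res_p)
    atoms_h = _side_chain_atoms(res_h)
    if not atoms_p or not atoms_h:
        raise NoSideChainError(
            f"{model.structure_id}: no side-chain heavy atoms on "
            f"{res_p.name}{res_p.seqid.num} or {res_h.name}{res_h.seqid.num}"
        )
    pa = np.array([_pos(a) for a in atoms_p])
    ha = np.array([_pos(a) for a in atoms_h])
    d = np.linalg.norm(pa[:, None, :] - ha[None, :, :], axis=2)
    return float(d.min())


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking down the p2->p3 bond, a clockwise
    rotation from p1 to p4 is positive.
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = -math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def terminal_torsion(model: StructureModel) -> tuple[float, float]:
    """(ω of the pΩ-1 -> pΩ peptide bond, ψ of pΩ-1), both in degrees.

    ω = Cα(pΩ-1)-C(pΩ-1)-N(pΩ)-Cα(pΩ): ~180° trans, ~0° cis.
    ψ(pΩ-1) = N(pΩ-1)-Cα(pΩ-1)-C(pΩ-1)-N(pΩ) is reported as an
    auxiliary descriptor of the same linkage.
    """
    pep = model.peptide_residues()
    if len(pep) < 2:
        raise MissingAtomError(f"{model.structure_id}: peptide has fewer than 2 residues")
    r_prev, r_last = pep[-2], pep[-1]
    sid = model.structure_id
    n_prev = _pos(_pick_atom(r_prev, "N", sid))
    ca_prev = _pos(_pick_atom(r_prev, "CA", sid))
    c_prev = _pos(_pick_atom(r_prev, "C", sid))
    n_last = _pos(_pick_atom(r_last, "N", sid))
    ca_last = _pos(_pick_atom(r_last, "CA", sid))
    omega = dihedral(ca_prev, c_prev, n_last, ca_last)
    psi = dihedral(n_prev, ca_prev, c_prev, n_last)
    return omega, psi


@dataclass(frozen=True)
class GeometryRecord:
    """The four groove descriptors for one structure (NaN = undefined)."""

    structure_id: str
    d77_pomega1: float
    d_tyr171_nterm: float
    d_val76_side: float
    omega_term: float
    psi_pomega1: float
    group: Group | None = None

    def as_dict(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "group": self.group.value if self.group else "",
            "d77_pomega1": self.d77_pomega1,
            "d_tyr171_nterm": self.d_tyr171_nterm,
            "d_val76_side": self.d_val76_side,
            "omega_term": self.omega_term,
            "psi_pomega1": self.psi_pomega1,
        }


def measure_structure(model: StructureModel) -> GeometryRecord:
    """Compute all four descriptors for one structure.

    A glycine at pΩ-1 leaves the side-chain contact descriptor
    undefined (NaN, logged) rather than failing the whole record.
    """
    try:
        d_side = mindist_side_chains(model)
    except NoSideChainError as exc:
        log.warning("%s: side-chain contact undefined: %s", model.structure_id, exc)
        d_side = float("nan")
    omega, psi = terminal_torsion(model)
    return GeometryRecord(
        structure_id=model.structure_id,
        d77_pomega1=d77_pomega1(model),
        d_tyr171_nterm=d_tyr171_nterm(model),
        d_val76_side=d_side,
        omega_term=omega,
        psi_pomega1=psi,
        group=model.group,
    )


DESCRIPTORS = ("d77_pomega1", "d_tyr171_nterm", "d_val76_side", "omega_term", "psi_pomega1")


def group_geometry_stats(records: list[GeometryRecord]) -> pd.DataFrame:
    """Per-descriptor C1-vs-C2 means, sample SDs and Welch t p-values.

    Structures with an undefined (NaN) descriptor are excluded from
    that descriptor only, with a logged count; each group must retain
    at least two records overall.
    """
    df = pd.DataFrame([r.as_dict() for r in records])
    for g in ("C1", "C2"):
        if (df["group"] == g).sum() < 2:
            raise ValueError(f"need at least 2 {g} structures, got {(df['group'] == g).sum()}")
    rows = []
    for desc in DESCRIPTORS:
        sub = df[np.isfinite(df[desc])]
        dropped = len(df) - len(sub)
        if dropped:
            log.info("%s: excluded %d structure(s) with undefined values", desc, dropped)
        x1 = sub.loc[sub["group"] == "C1", desc].to_numpy()
        x2 = sub.loc[sub["group"] == "C2", desc].to_numpy()
        p = welch_t_pvalue(x1, x2) if len(x1) >= 2 and len(x2) >= 2 else float("nan")
        rows.append(
            {
                "descriptor": desc,
                "n_c1": len(x1),
                "n_c2": len(x2),
                "mean_c1": x1.mean() if len(x1) else float("nan"),
                "sd_c1": x1.std(ddof=1) if len(x1) > 1 else float("nan"),
                "mean_c2": x2.mean() if len(x2) else float("nan"),
                "sd_c2": x2.std(ddof=1) if len(x2) > 1 else float("nan"),
                "p_welch": p,
            }
        )
    return pd.DataFrame(rows)
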