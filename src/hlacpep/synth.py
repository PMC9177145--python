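"""Synthetic peptide panels and toy peptide-MHC structures.

The peptide generator draws allotype-specific peptide sets from
position frequency models with group-level effects at the two
C-terminal positions, mirroring the statistical structure of real
HLA-C elution data:

* a group-specific pΩ-Ala rate (C1 allotypes admit the short Ala
  anchor, C2 allotypes essentially do not);
* a pΩ-1 size-preference coefficient linking the log-frequency shift
  of each amino acid to its standardized side-chain volume, with
  opposite sign in the two groups (C1 favors small, C2 large);
* optional pΩ-conditional sharpening of the pΩ-1 size preference for
  peptides carrying the short pΩ-Ala anchor;
* between-allotype variability via a Dirichlet perturbation of the
  group-level model, so that group comparisons see realistic
  allotype-to-allotype scatter rather than pure multinomial noise.

Positions are otherwise sampled independently — a deliberate
simplification; real immunopeptidomes carry positional couplings this
generator does not emulate.

The toy-structure builder writes standards-conformant PDB files whose
four groove descriptors equal caller-specified targets exactly at zero
placement noise, by direct coordinate construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA
from .allotypes import AllotypeRecord, Group
from .contaminants import ContaminantMotif
from .peptides import PeptideSet
from .pfm import PositionFrequencyMatrix
from .volumes import ZAMYATNIN_1972

# Approximate proteome background amino-acid frequencies (percent scale).
_BACKGROUND = {
    "A": 8.3, "R": 5.5, "N": 4.1, "D": 5.5, "C": 1.4, "Q": 3.9, "E": 6.7,
    "G": 7.1, "H": 2.3, "I": 5.9, "L": 9.7, "K": 5.8, "M": 2.4, "F": 3.9,
    "P": 4.7, "S": 6.6, "T": 5.4, "W": 1.1, "Y": 2.9, "V": 6.9,
}

# HLA-C-like C-terminal anchor usage: hydrophobic pΩ dominated by Leu.
_POMEGA_ANCHOR = {"L": 0.55, "V": 0.12, "I": 0.09, "F": 0.09, "M": 0.05}
# B-pocket (p2) anchor preference.
_P2_ANCHOR = {"A": 0.45, "P": 0.10, "S": 0.05}


def _vector(weights: dict[str, float]) -> np.ndarray:
    v = np.array([weights.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    return v / v.sum()


def baseline_pfm(length: int = 9) -> np.ndarray:
    """Default (L, 20) per-position model: p2 and pΩ anchors over background."""
    bg = _vector(_BACKGROUND)
    pfm = np.tile(bg, (length, 1))
    p2 = _vector(_P2_ANCHOR)
    pfm[1] = 0.6 * p2 + 0.4 * bg
    anchor = _vector(_POMEGA_ANCHOR)
    pfm[length - 1] = 0.9 * anchor + 0.1 * bg
    return pfm


_VOLS = np.array([ZAMYATNIN_1972[aa] for aa in AMINO_ACIDS])
_VOL_Z = (_VOLS - _VOLS.mean()) / _VOLS.std()


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for a synthetic C1/C2 peptide panel.

    Defaults emulate the real 21-allotype panel: 14 C1 and 7 C2
    allotypes, ~1200 unique 9mers each, pΩ-Ala at 1.45% (C1) vs 0.27%
    (C2), and an opposite-signed size preference at pΩ-1.
    """

    n_c1: int = 14
    n_c2: int = 7
    peptides_per_allotype: int = 1200
    length: int = 9
    baseline: np.ndarray | None = None
    pomega_ala_c1: float = 0.0145
    pomega_ala_c2: float = 0.0027
    size_coef: float = 0.25
    conditional_size_coef: float = 0.0
    allotype_concentration: float = 500.0
    contaminant_fraction: float = 0.0
    planted_c2: dict[tuple[int, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pomega_ala_c1", "pomega_ala_c2", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.length < 8:
            raise ValueError("peptide length must be >= 8")
        if self.n_c1 < 1 or self.n_c2 < 1 or self.peptides_per_allotype < 1:
            raise ValueError("panel dimensions must be positive")


def _set_rate(row: np.ndarray, aa: str, rate: float) -> np.ndarray:
    """Pin one amino acid's frequency and rescale the rest."""
    out = row.copy()
    j = AA_INDEX[aa]
    rest = 1.0 - out[j]
    if rest <= 0:
        raise ValueError(f"cannot pin {aa} rate: no residual mass")
    out *= (1.0 - rate) / rest
    out[j] = rate
    return out


def _size_shift(row: np.ndarray, coef: float) -> np.ndarray:
    out = row * np.exp(coef * _VOL_Z)
    return out / out.sum()


def group_model(spec: GeneratorSpec, group: Group) -> np.ndarray:
    """The effective (L, 20) per-position model for one group."""
    pfm = (baseline_pfm(spec.length) if spec.baseline is None else spec.baseline).copy()
    if pfm.shape != (spec.length, N_AA):
        raise ValueError(f"baseline must have shape ({spec.length}, {N_AA})")
    last = spec.length - 1
    rate = spec.pomega_ala_c1 if group is Group.C1 else spec.pomega_ala_c2
    pfm[last] = _set_rate(pfm[last], "A", rate)
    sign = -1.0 if group is Group.C1 else 1.0
    pfm[last - 1] = _size_shift(pfm[last - 1], sign * spec.size_coef)
    if group is Group.C2:
        for (pos, aa), fold in spec.planted_c2.items():
            j = AA_INDEX[aa.upper()]
            new = pfm[pos - 1, j] * fold
            if new >= 1.0:
                raise ValueError(
                    f"unrealizable planted effect: {aa}@p{pos} x{fold} gives frequency {new:.3f}"
                )
            pfm[pos - 1] = _set_rate(pfm[pos - 1], aa.upper(), new)
    return pfm


def _conditional_pomega1(row: np.ndarray, spec: GeneratorSpec, group: Group) -> np.ndarray:
    sign = -1.0 if group is Group.C1 else 1.0
    return _size_shift(row, sign * spec.conditional_size_coef)


@dataclass(frozen=True)
class PanelSample:
    """A sampled panel plus its generating ground truth."""

    records: list[tuple[AllotypeRecord, PeptideSet]]
    truth: dict[str, np.ndarray]          # per-allotype effective (L, 20) model
    group_models: dict[str, np.ndarray]   # group-level (L, 20) models
    contaminant: ContaminantMotif | None
    spec: GeneratorSpec

    def panel_pfms(self) -> list[tuple[AllotypeRecord, PositionFrequencyMatrix]]:
        """Empirical PFMs for each allotype, ready for group enrichment."""
        from .pfm import position_frequency_matrix

        return [
            (rec, position_frequency_matrix(ps, self.spec.length))
            for rec, ps in self.records
        ]


def _sample_unique(
    rng: np.random.Generator,
    pfm: np.ndarray,
    n: int,
    spec: GeneratorSpec,
    group: Group,
) -> set[str]:
    """Draw n unique sequences from the per-position model (with top-up)."""
    length = pfm.shape[0]
    last = length - 1
    cond = spec.conditional_size_coef != 0.0
    cond_row = _conditional_pomega1(pfm[last - 1], spec, group) if cond else None
    ala = AA_INDEX["A"]
    out: set[str] = set()
    letters = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    for _ in range(200):
        need = n - len(out)
        if need <= 0:
            break
        batch = max(need, 16)
        idx = np.empty((batch, length), dtype=np.int64)
        for pos in range(length):
            idx[:, pos] = rng.choice(N_AA, size=batch, p=pfm[pos])
        if cond:
            mask = idx[:, last] == ala
            k = int(mask.sum())
            if k:
                idx[mask, last - 1] = rng.choice(N_AA, size=k, p=cond_row)
        for row in letters[idx]:
            out.add("".join(row))
            if len(out) == n:
                break
    if len(out) < n:
        raise RuntimeError("could not draw enough unique peptides; lower n or flatten the model")
    return out


def _contaminant_model(length: int) -> np.ndarray:
    """A B*35-like background motif: Pro at p2, Tyr at pΩ."""
    bg = _vector(_BACKGROUND)
    pfm = np.tile(bg, (length, 1))
    pfm[1] = _set_rate(bg, "P", 0.6)
    pfm[length - 1] = _set_rate(bg, "Y", 0.6)
    return pfm


def sample_peptide_panel(spec: GeneratorSpec) -> PanelSample:
    """Sample per-allotype peptide sets with known ground truth.

    Each allotype's effective model is a Dirichlet perturbation of its
    group model (concentration ``allotype_concentration`` x frequency),
    and its peptides are independent per-position draws from that
    model, deduplicated to exactly ``peptides_per_allotype`` unique
    sequences.  Identical spec and seed give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    models = {Group.C1: group_model(spec, Group.C1), Group.C2: group_model(spec, Group.C2)}
    contam_pfm = _contaminant_model(spec.length) if spec.contaminant_fraction > 0 else None

    records: list[tuple[AllotypeRecord, PeptideSet]] = []
    truth: dict[str, np.ndarray] = {}
    n = spec.peptides_per_allotype
    n_contam = int(round(spec.contaminant_fraction * n))
    for group, count, residues in (
        (Group.C1, spec.n_c1, ("S", "N")),
        (Group.C2, spec.n_c2, ("N", "K")),
    ):
        for i in range(count):
            name = f"SYN-{group.value}-{i + 1:02d}"
            rec = AllotypeRecord.from_residues(name, *residues)
            allo_pfm = np.vstack(
                [rng.dirichlet(spec.allotype_concentration * row) for row in models[group]]
            )
            seqs = _sample_unique(rng, allo_pfm, n - n_contam, spec, group)
            if n_contam:
                seqs |= _sample_unique(rng, contam_pfm, n_contam, spec, group)
            records.append(
                (rec, PeptideSet(rec, frozenset(seqs), {p: ("synthetic",) for p in seqs}))
            )
            truth[name] = _marginal_model(allo_pfm, spec, group)

    contaminant = None
    if contam_pfm is not None:
        counts = np.rint(contam_pfm * 10**6).astype(np.int64)
        counts[:, 0] += 10**6 - counts.sum(axis=1)  # exact row sums
        contaminant = ContaminantMotif(
            allotype_name="SYN-B35-BG",
            pfms={spec.length: PositionFrequencyMatrix(spec.length, counts, 10**6)},
            threshold=-3.4,
        )
    return PanelSample(records, truth, {g.value: m for g, m in models.items()}, contaminant, spec)


def _marginal_model(allo_pfm: np.ndarray, spec: GeneratorSpec, group: Group) -> np.ndarray:
    """Marginal per-position model, folding in any pΩ-conditional effect."""
    if spec.conditional_size_coef == 0.0:
        return allo_pfm
    out = allo_pfm.copy()
    last = allo_pfm.shape[0] - 1
    p_ala = allo_pfm[last, AA_INDEX["A"]]
    cond = _conditional_pomega1(allo_pfm[last - 1], spec, group)
    out[last - 1] = p_ala * cond + (1.0 - p_ala) * allo_pfm[last - 1]
    return out


# ----------------------------------------------------------------------------
# Toy structures


@dataclass(frozen=True)
class ToyStructureSpec:
    """Target descriptor values for a constructed peptide-MHC fixture.

    At ``noise_sd`` 0 the written structure reproduces each target
    exactly; positive noise adds isotropic Gaussian jitter (A) to every
    atom after exact placement.
    """

    d77: float = 5.0
    d_nterm: float = 2.8
    d_val76: float = 3.5
    omega: float = 180.0
    peptide_length: int = 9
    heavy_length: int = 278
    noise_sd: float = 0.0
    seed: int = 0
    structure_id: str = "TOY"
    group: Group | None = None

    def __post_init__(self) -> None:
        for name in ("d77", "d_nterm", "d_val76"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -180.0 < self.omega <= 180.0:
            raise ValueError("omega must lie in (-180, 180]")
        if not 8 <= self.peptide_length <= 11:
            raise ValueError("peptide length must be 8-11")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """Place atom d with |cd|=bond, angle(b,c,d)=angle, dihedral(a,b,c,d)=torsion."""
    from .geometry import dihedral

    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d2 = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor), bond * math.sin(ang) * math.sin(tor)]
    )
    d = c + d2[0] * bc + d2[1] * m + d2[2] * n
    # resolve the handedness of the local frame against the measured dihedral
    got = dihedral(a, b, c, d)
    if abs(_angdiff(got, torsion)) > 1e-6:
        d = c + d2[0] * bc + d2[1] * m - d2[2] * n
    return d


def _angdiff(x: float, y: float) -> float:
    return (x - y + 180.0) % 360.0 - 180.0


def build_toy_structure(spec: ToyStructureSpec, path: str | Path) -> Path:
    """Write a coordinate fixture whose descriptors hit the requested targets.

    The heavy chain is a geometric stub: full residues only at
    positions 76 (Val), 77 (Ser) and 171 (Tyr), the rest glycine
    backbones on a distant lattice.  Only the atoms the descriptors
    touch are placed meaningfully.
    """
    L = spec.peptide_length
    atoms: dict[str, list[tuple[int, str, str, np.ndarray]]] = {"pep": [], "heavy": []}

    def add(chain: str, resnum: int, resname: str, name: str, xyz) -> None:
        atoms[chain].append((resnum, resname, name, np.asarray(xyz, dtype=float)))

    # peptide residues 1..L-2 (Ala) on a straight stub; the terminal
    # region sits at the origin where serialized coordinates carry the
    # most absolute precision (the torsion is first-order sensitive)
    for i in range(1, L - 1):
        ca = np.array([(i - (L - 1)) * 4.0, 0.0, 0.0])
        add("pep", i, "ALA", "N", ca + [-1.2, 0.9, 0.0])
        add("pep", i, "ALA", "CA", ca)
        add("pep", i, "ALA", "C", ca + [1.2, 0.9, 0.0])
        add("pep", i, "ALA", "O", ca + [1.2, 2.1, 0.0])
        add("pep", i, "ALA", "CB", ca + [0.0, -1.0, 1.1])

    # pΩ-1: Ser with exact backbone for the terminal torsion
    A = np.array([0.0, 0.0, 0.0])  # CA(pΩ-1)
    n_prev = A + [-1.45, 0.6, 0.0]
    c_prev = A + [1.52, 0.0, 0.0]
    add("pep", L - 1, "SER", "N", n_prev)
    add("pep", L - 1, "SER", "CA", A)
    add("pep", L - 1, "SER", "C", c_prev)
    add("pep", L - 1, "SER", "O", c_prev + [0.3, 1.2, 0.0])
    cb_pep = A + [0.0, 0.0, 1.5]
    og_pep = cb_pep + [0.0, 0.7, 1.2]
    add("pep", L - 1, "SER", "CB", cb_pep)
    add("pep", L - 1, "SER", "OG", og_pep)

    # pΩ: Ala; N at 116° from CA(pΩ-1), CA by torsion placement (ω target)
    ang64 = math.radians(64.0)
    n_last = c_prev + 1.33 * np.array([math.cos(ang64), math.sin(ang64), 0.0])
    ca_last = _place_atom(A, c_prev, n_last, 1.46, 122.0, spec.omega)
    c_dir = np.array([1.0, 0.8, 0.4])
    c_last = ca_last + 1.52 * c_dir / np.linalg.norm(c_dir)
    add("pep", L, "ALA", "N", n_last)
    add("pep", L, "ALA", "CA", ca_last)
    add("pep", L, "ALA", "C", c_last)
    add("pep", L, "ALA", "O", c_last + [0.0, 1.2, 0.3])
    add("pep", L, "ALA", "OXT", c_last + [1.0, -0.7, 0.3])
    add("pep", L, "ALA", "CB", ca_last + [0.0, -1.0, 1.1])

    # heavy 77 (Ser): Cβ at d77 from CA(pΩ-1)
    cb77 = A + [0.0, -spec.d77, 0.0]
    ca77 = cb77 + [0.0, -1.53, 0.0]
    add("heavy", 77, "SER", "CB", cb77)
    add("heavy", 77, "SER", "OG", cb77 + [1.1, 0.0, 0.9])
    add("heavy", 77, "SER", "CA", ca77)
    add("heavy", 77, "SER", "N", ca77 + [-1.2, -0.9, 0.0])
    add("heavy", 77, "SER", "C", ca77 + [1.2, -0.9, 0.0])
    add("heavy", 77, "SER", "O", ca77 + [1.2, -2.1, 0.0])

    # heavy 76 (Val): CG1 is the closest side-chain atom to the pΩ-1 side chain
    cg1 = cb_pep + [0.0, -spec.d_val76, 0.0]
    cb76 = cg1 + [0.0, -1.53, 0.0]
    ca76 = cb76 + [-1.0, -1.0, -0.5]
    add("heavy", 76, "VAL", "CG1", cg1)
    add("heavy", 76, "VAL", "CB", cb76)
    add("heavy", 76, "VAL", "CG2", cb76 + [1.2, -0.8, 0.5])
    add("heavy", 76, "VAL", "CA", ca76)
    add("heavy", 76, "VAL", "N", ca76 + [-1.3, 0.4, 0.0])
    add("heavy", 76, "VAL", "C", ca76 + [1.0, -1.0, 0.0])
    add("heavy", 76, "VAL", "O", ca76 + [1.0, -2.2, 0.0])

    # heavy 171 (Tyr): OH at d_nterm from peptide p1 N
    n1 = np.array([(2 - L) * 4.0 - 1.2, 0.9, 0.0])
    oh = n1 + [0.0, 0.0, -spec.d_nterm]
    cz = oh + [0.0, 0.0, -1.38]
    ring = {
        "CE1": cz + [1.2, 0.0, -0.7], "CE2": cz + [-1.2, 0.0, -0.7],
        "CD1": cz + [1.2, 0.0, -2.1], "CD2": cz + [-1.2, 0.0, -2.1],
        "CG": cz + [0.0, 0.0, -2.8],
    }
    cb171 = ring["CG"] + [0.0, 0.8, -1.2]
    ca171 = cb171 + [0.0, 0.9, -1.2]
    add("heavy", 171, "TYR", "OH", oh)
    add("heavy", 171, "TYR", "CZ", cz)
    for name, xyz in ring.items():
        add("heavy", 171, "TYR", name, xyz)
    add("heavy", 171, "TYR", "CB", cb171)
    add("heavy", 171, "TYR", "CA", ca171)
    add("heavy", 171, "TYR", "N", ca171 + [-1.3, 0.5, 0.0])
    add("heavy", 171, "TYR", "C", ca171 + [1.2, 0.6, 0.0])
    add("heavy", 171, "TYR", "O", ca171 + [1.2, 0.6, -1.2])

    # remaining heavy residues: glycine backbones on a distant lattice
    for j in range(1, spec.heavy_length + 1):
        if j in (76, 77, 171):
            continue
        row, col = divmod(j - 1, 26)
        base = np.array([4.0 * col, -14.0 - 4.0 * row, -14.0])
        add("heavy", j, "GLY", "N", base + [-1.2, 0.6, 0.0])
        add("heavy", j, "GLY", "CA", base)
        add("heavy", j, "GLY", "C", base + [1.2, 0.6, 0.0])
        add("heavy", j, "GLY", "O", base + [1.2, 0.6, -1.2])

    rng = np.random.default_rng(spec.seed)
    st = gemmi.Structure()
    st.name = spec.structure_id
    model = gemmi.Model("1")
    for chain_name, key in (("A", "heavy"), ("C", "pep")):
        chain = gemmi.Chain(chain_name)
        by_residue: dict[int, list[tuple[str, str, np.ndarray]]] = {}
        for resnum, resname, atom_name, xyz in atoms[key]:
            by_residue.setdefault(resnum, []).append((resname, atom_name, xyz))
        # gemmi's add_residue/add_chain copy, so each residue is fully
        # populated before insertion
        for resnum in sorted(by_residue):
            res = gemmi.Residue()
            res.name = by_residue[resnum][0][0]
            res.seqid = gemmi.SeqId(resnum, " ")
            for _, atom_name, xyz in sorted(by_residue[resnum], key=lambda t: t[1]):
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(atom_name[0])
                if spec.noise_sd > 0:
                    xyz = xyz + rng.normal(0.0, spec.noise_sd, 3)
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                atom.b_iso = 20.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    # mmCIF keeps full coordinate precision; PDB truncates to 3 decimals
    if path.suffix.lower() == ".pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


def build_toy_panel(
    out_dir: str | Path,
    targets: list[tuple[str, Group, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    **spec_kwargs,
) -> list[Path]:
    """Write a small panel of toy structures, one per (id, group, d77) target."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if targets is None:
        targets = [(f"C1-{i}", Group.C1, 4.6) for i in range(5)] + [
            (f"C2-{i}", Group.C2, 5.7) for i in range(7)
        ]
    paths = []
    for k, (sid, group, d77) in enumerate(targets):
        spec = ToyStructureSpec(
            d77=d77, structure_id=sid, group=group, noise_sd=noise_sd, seed=seed + k, **spec_kwargs
        )
        paths.append(build_toy_structure(spec, out_dir / f"{sid}.cif"))
    return paths
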