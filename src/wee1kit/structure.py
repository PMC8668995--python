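"""Protein structures: PDB I/O, rigid-body superposition, pocket geometry.

Structures are parsed from PDB text with gemmi and reduced to a flat atom
table (first model, ATOM records only, one location per atom: the
highest-occupancy altloc, ties to 'A'). Superposition is least-squares Kabsch
on alignment-paired C-alpha atoms, and "pocket access" between two residues —
the geometric proxy for how much room a substrate has at the catalytic-pocket
entrance — is measured as the minimum distance between their heavy side-chain
atoms (glycine falls back to its C-alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .pairwise import PairwiseAlignment
from .seqio import GAP


class StructureError(ValueError):
    pass


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    resname: str
    chain: str
    resnum: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""
    element: str = ""

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def residue_key(self) -> tuple:
        return (self.chain, self.resnum, self.icode)


@dataclass(frozen=True)
class Structure:
    name: str
    atoms: tuple

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise StructureError(f"non-finite coordinates on atom {a.serial}")
            key = (a.chain, a.resnum, a.icode, a.name)
            if key in seen:
                raise StructureError(f"duplicate atom {key}")
            seen.add(key)

    def chains(self) -> list[str]:
        out = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def residues(self, chain: Optional[str] = None) -> list[tuple]:
        """Ordered residue keys (chain, resnum, icode)."""
        out: list[tuple] = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if not out or out[-1] != a.residue_key:
                if a.residue_key in out:  # non-contiguous atom records
                    continue
                out.append(a.residue_key)
        return out

    def residue_atoms(self, key: tuple) -> list[Atom]:
        return [a for a in self.atoms if a.residue_key == key]

    def sequence(self, chain: Optional[str] = None) -> str:
        letters = []
        for key in self.residues(chain):
            resname = next(a.resname for a in self.atoms if a.residue_key == key)
            letters.append(THREE_TO_ONE.get(resname, "X"))
        return "".join(letters)

    def ca(self, key: tuple) -> Optional[Atom]:
        for a in self.atoms:
            if a.residue_key == key and a.name == "CA":
                return a
        return None


def read_pdb(path_or_text: str | Path, name: Optional[str] = None,
             keep_hetatm: bool = False) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Only the first MODEL is read; HETATM records are skipped unless
    ``keep_hetatm``; alternate locations are resolved to the
    highest-occupancy altloc (ties prefer 'A'). An unparseable ATOM line is
    reported with its line number.
    """
    p = Path(path_or_text) if isinstance(path_or_text, (str, Path)) else None
    if p is not None and p.exists():
        text = p.read_text()
        label = name or p.stem
    else:
        text = str(path_or_text)
        label = name or "structure"

    # cheap syntactic pre-check so errors carry a line number
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise StructureError(
                    f"unparseable coordinates on line {lineno}: {line!r}"
                ) from None
        elif line.startswith(("ATOM  ", "HETATM")):
            raise StructureError(f"truncated ATOM record on line {lineno}")

    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"PDB parse failed: {exc}") from exc
    if len(st) == 0:
        raise StructureError("no models in PDB input")
    model = st[0]

    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            if res.het_flag == "H" and not keep_hetatm:
                continue
            # resolve altlocs per atom name
            groups: dict[str, list] = {}
            for at in res:
                groups.setdefault(at.name, []).append(at)
            for atom_name, alts in groups.items():
                best = sorted(
                    alts,
                    key=lambda a: (-a.occ, a.altloc if a.altloc else "A"),
                )[0]
                atoms.append(
                    Atom(
                        serial=best.serial,
                        name=atom_name,
                        resname=res.name,
                        chain=chain.name,
                        resnum=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        x=best.pos.x, y=best.pos.y, z=best.pos.z,
                        occupancy=best.occ,
                        altloc=best.altloc.strip(),
                        element=best.element.name,
                    )
                )
    if not atoms:
        raise StructureError("no ATOM records found")
    return Structure(name=label, atoms=tuple(atoms))


def write_pdb(struct: Structure, dest: str | Path) -> None:
    """Write ATOM/TER/END records (fixed-width PDB format)."""
    lines = []
    last_chain = None
    for a in struct.atoms:
        if last_chain is not None and a.chain != last_chain:
            lines.append("TER")
        last_chain = a.chain
        nm = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:5d} {nm}{'':1s}{a.resname:>3s} {a.chain:1s}"
            f"{a.resnum:4d}{a.icode or ' ':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(dest).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform mapping the first point set onto the second.

    ``rotation @ a + translation`` approximates ``b``; ``rmsd`` is the root
    mean square of the residual pair distances, minimal over all proper rigid
    transforms.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int


def kabsch_superpose(coords_a, coords_b) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch, SVD with reflection fix).

    Needs at least 3 non-collinear point pairs; the returned rotation is
    always proper (det = +1) even when the best unconstrained orthogonal map
    would be a reflection.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise StructureError("paired coordinate arrays must both be (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise StructureError(f"need >= 3 point pairs, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    for M, side in ((Ac, "first"), (Bc, "second")):
        sv = np.linalg.svd(M, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise StructureError(f"{side} point set is (near-)collinear")
    H = Ac.T @ Bc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    resid = (A @ R.T + t) - B
    rmsd = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def pair_residues(struct_a: Structure, struct_b: Structure,
                  alignment: PairwiseAlignment,
                  chain_a: Optional[str] = None, chain_b: Optional[str] = None,
                  max_mismatch: float = 0.05) -> list[tuple]:
    """Homologous residue pairs from an alignment of the two chain sequences.

    Returns (residue_key_a, residue_key_b) for every co-aligned non-gap
    column where both residues have a C-alpha atom. The alignment's ungapped
    rows must match the structures' chain sequences; more than
    ``max_mismatch`` disagreement is an error.
    """
    res_a = struct_a.residues(chain_a)
    res_b = struct_b.residues(chain_b)
    seq_a = struct_a.sequence(chain_a)
    seq_b = struct_b.sequence(chain_b)
    row_a = alignment.a.residues
    row_b = alignment.b.residues
    ug_a = row_a.replace(GAP, "")
    ug_b = row_b.replace(GAP, "")
    for ug, seq, label in ((ug_a, seq_a, struct_a.name), (ug_b, seq_b, struct_b.name)):
        if len(ug) != len(seq):
            raise StructureError(
                f"{label}: alignment row has {len(ug)} residues, structure "
                f"chain has {len(seq)}"
            )
        mism = sum(x != y for x, y in zip(ug, seq)) / len(seq)
        if mism > max_mismatch:
            raise StructureError(
                f"{label}: {mism:.1%} sequence/structure mismatch exceeds "
                f"{max_mismatch:.0%}"
            )
    pairs = []
    ia = ib = 0
    for ca_, cb_ in zip(row_a, row_b):
        if ca_ != GAP and cb_ != GAP:
            ka, kb = res_a[ia], res_b[ib]
            if struct_a.ca(ka) is not None and struct_b.ca(kb) is not None:
                pairs.append((ka, kb))
        if ca_ != GAP:
            ia += 1
        if cb_ != GAP:
            ib += 1
    return pairs


def superpose_structures(struct_a: Structure, struct_b: Structure,
                         alignment: PairwiseAlignment,
                         **kwargs) -> SuperpositionResult:
    """Kabsch on the C-alpha atoms of alignment-paired residues."""
    pairs = pair_residues(struct_a, struct_b, alignment, **kwargs)
    A = np.array([struct_a.ca(ka).xyz for ka, _ in pairs])
    B = np.array([struct_b.ca(kb).xyz for _, kb in pairs])
    return kabsch_superpose(A, B)


# ---------------------------------------------------------------------------
# pocket-access measurement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateMeasurement:
    """Closest-approach distance between two gate residues, in Angstrom."""

    structure: str
    residue_a: tuple
    residue_b: tuple
    atom_a: str
    atom_b: str
    distance: float
    mode: str


def parse_selector(sel: str) -> tuple:
    """'A:309' or 'A:309B' -> (chain, resnum, icode)."""
    try:
        chain, rest = sel.split(":")
        icode = ""
        if rest and rest[-1].isalpha():
            icode = rest[-1]
            rest = rest[:-1]
        return (chain, int(rest), icode)
    except (ValueError, AttributeError):
        raise StructureError(f"bad residue selector {sel!r} (expected CHAIN:NUM)")


def _select_atoms(struct: Structure, key: tuple, mode: str,
                  atom_name: Optional[str]) -> list[Atom]:
    atoms = struct.residue_atoms(key)
    if not atoms:
        raise StructureError(f"no residue {key} in {struct.name}")
    if mode == "atom-pair":
        chosen = [a for a in atoms if a.name == atom_name]
        if not chosen:
            raise StructureError(f"residue {key}: no atom named {atom_name!r}")
        return chosen
    heavy = [a for a in atoms if a.element != "H"]
    if mode == "min-heavy":
        return heavy
    if mode == "min-side-chain-heavy":
        side = [a for a in heavy if a.name not in BACKBONE]
        if side:
            return side
        resname = atoms[0].resname
        if resname == "GLY":
            ca_atoms = [a for a in atoms if a.name == "CA"]
            if ca_atoms:
                return ca_atoms
        raise StructureError(
            f"residue {key} ({resname}) has no side-chain heavy atoms"
        )
    raise StructureError(f"unknown distance mode {mode!r}")


def residue_distance(struct: Structure, sel_a: str | tuple, sel_b: str | tuple,
                     mode: str = "min-side-chain-heavy",
                     atom_names: Optional[tuple] = None) -> GateMeasurement:
    """Minimum distance between the selected atom sets of two residues.

    Default mode measures the closest approach of heavy side-chain atoms
    (glycine falls back to C-alpha); ``min-heavy`` uses all heavy atoms;
    ``atom-pair`` pins each side to a named atom via ``atom_names``.
    """
    key_a = parse_selector(sel_a) if isinstance(sel_a, str) else tuple(sel_a)
    key_b = parse_selector(sel_b) if isinstance(sel_b, str) else tuple(sel_b)
    name_a, name_b = atom_names if atom_names else (None, None)
    set_a = _select_atoms(struct, key_a, mode, name_a)
    set_b = _select_atoms(struct, key_b, mode, name_b)
    best = None
    for a in set_a:
        for b in set_b:
            d = float(np.linalg.norm(a.xyz - b.xyz))
            if best is None or d < best[0]:
                best = (d, a, b)
    d, a, b = best
    return GateMeasurement(structure=struct.name, residue_a=key_a,
                           residue_b=key_b, atom_a=a.name, atom_b=b.name,
                           distance=d, mode=mode)


def gate_access_report(structures: Iterable[tuple],
                       gates: dict | Sequence,
                       mode: str = "min-side-chain-heavy") -> list[GateMeasurement]:
    """One gate measurement per labeled structure.

    ``structures`` is an iterable of (label, Structure); ``gates`` maps each
    label to its (selector_a, selector_b) pair, or is a single pair applied
    to every structure.
    """
    rows = []
    for label, struct in structures:
        if isinstance(gates, dict):
            sel_a, sel_b = gates[label]
        else:
            sel_a, sel_b = gates
        m = residue_distance(struct, sel_a, sel_b, mode=mode)
        rows.append(GateMeasurement(structure=label, residue_a=m.residue_a,
                                    residue_b=m.residue_b, atom_a=m.atom_a,
                                    atom_b=m.atom_b, distance=m.distance,
                                    mode=m.mode))
    return rows


def gate_table_tsv(rows: Sequence[GateMeasurement]) -> str:
    header = "structure\tresidue_a\tresidue_b\tatom_a\tatom_b\tdistance_A\tmode"
    lines = [header]
    for r in rows:
        ra = f"{r.residue_a[0]}:{r.residue_a[1]}{r.residue_a[2]}"
        rb = f"{r.residue_b[0]}:{r.residue_b[1]}{r.residue_b[2]}"
        lines.append(
            f"{r.structure}\t{ra}\t{rb}\t{r.atom_a}\t{r.atom_b}"
            f"\t{r.distance:.3f}\t{r.mode}"
        )
    return "\n".join(lines) + "\n"
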