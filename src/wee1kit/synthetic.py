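"""Synthetic kinase families and structures with known ground truth.

Every pipeline stage is testable offline against data generated here:

* :func:`simulate_family` evolves a reference protein down a tree with
  per-site substitutions, optional indels, and *planted* substitutions at
  cataloged functional sites, while keeping the exact residue-level homology
  map as truth. Substitutions are uniform over the 19 alternative residues —
  bookkeeping and detectability matter for a truth-bearing generator, residism
  of the substitution process does not.
* :func:`simulate_structure_pair` emits two structures related by a known
  rigid transform plus Gaussian coordinate noise.
* :func:`simulate_gate` builds a structure whose two gate residues have an
  exactly known minimum side-chain heavy-atom distance.
* :func:`synthetic_reference_wee1` and :func:`synthetic_wee1_study_family`
  are SYNTHETIC surrogates for the human WEE1A protein and the cross-species
  comparison set: deterministic sequences carrying the documented functional
  residues (E309, N376, D426 in IVHxDLKPxNIx, DLG 463-465, EGD 477-479,
  R481, R518...) at the same coordinates as the real proteins, with plant
  surrogates offset so the G-loop gate falls at the documented per-species
  positions. They are generated sequences, not database entries.

All generators are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import phylo
from .seqio import AMINO_ACIDS, SequenceRecord
from .structure import Atom, Structure


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# sequence families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEvent:
    taxon: str
    ref_pos: int  # 1-based position in the reference
    new_residue: str


@dataclass
class FamilySpec:
    """Parameters of one simulated family; ``seed`` is mandatory."""

    reference: SequenceRecord
    n_taxa: int
    seed: int
    subst_prob: float = 0.02       # per site per branch
    indel_rate: float = 0.0        # per branch probability of one indel
    max_indel_len: int = 3
    planted: tuple = ()            # PlantedEvent list, applied on terminal branches
    # ref positions shielded from stochastic change: no background substitution
    # at the position itself, no indel within +-2 of it. Planted positions are
    # always shielded, so planted events are the only changes at tested sites.
    protected_positions: tuple = ()
    include_reference: bool = True

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise SimulationError("need at least 2 taxa")
        if not 0.0 <= self.subst_prob <= 1.0 or not 0.0 <= self.indel_rate <= 1.0:
            raise SimulationError("probabilities must be in [0, 1]")
        self.planted = tuple(
            e if isinstance(e, PlantedEvent) else PlantedEvent(*e)
            for e in self.planted
        )
        L = len(self.reference)
        for ev in self.planted:
            if not 1 <= ev.ref_pos <= L:
                raise SimulationError(f"planted position {ev.ref_pos} outside reference")
            if ev.new_residue == self.reference.residues[ev.ref_pos - 1]:
                raise SimulationError(
                    f"planted residue at {ev.ref_pos} equals the reference "
                    f"residue ({ev.new_residue}); not an event"
                )


@dataclass(frozen=True)
class FamilyTruth:
    """Ground truth of a simulated family."""

    tree: phylo.PhyloTree
    homology: dict          # taxon -> {own 1-based pos: ref 1-based pos or None}
    planted: tuple          # realized PlantedEvent list


def _random_topology(taxa: Sequence[str], rng: np.random.Generator) -> phylo.PhyloTree:
    nodes = [phylo.Node(label=t) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        p = phylo.Node()
        p.add(a, 1.0)
        p.add(b, 1.0)
        nodes.append(p)
    return phylo.PhyloTree(root=nodes[0], rooted=True)


def _protected_window(spec: FamilySpec) -> set[int]:
    prot = set()
    for p in list(spec.protected_positions) + [e.ref_pos for e in spec.planted]:
        prot.update(range(p - 2, p + 3))
    return prot


def simulate_family(spec: FamilySpec) -> tuple[list[SequenceRecord], FamilyTruth]:
    """Evolve the reference down a random tree and return taxa plus truth.

    Sites mutate independently with probability ``subst_prob`` per branch
    (uniform over the 19 alternative residues); protected and planted
    positions never mutate stochastically, so planted events are the only
    changes at tested sites and their truth set is exact. Indels (insertions
    of random residues or deletions) happen at most once per branch, never
    inside the +-2 window around protected or planted positions, so the
    homology of the tested sites is never ambiguous. Planted events are
    applied on the terminal branch of their taxon after stochastic evolution,
    hence are guaranteed in the output.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = [f"t{i + 1:02d}" for i in range(spec.n_taxa)]
    tree = _random_topology(taxa, rng)
    protected = _protected_window(spec)
    frozen = set(spec.protected_positions) | {e.ref_pos for e in spec.planted}
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

    # a sequence is a list of (ref_pos or None, residue) tokens
    root_tokens = [(i + 1, r) for i, r in enumerate(spec.reference.residues)]
    planted_by_taxon: dict[str, list[PlantedEvent]] = {}
    for ev in spec.planted:
        if ev.taxon not in taxa:
            raise SimulationError(f"planted event names unknown taxon {ev.taxon!r}")
        planted_by_taxon.setdefault(ev.taxon, []).append(ev)

    results: dict[str, list] = {}

    def evolve(tokens: list, node: phylo.Node):
        for child in node.children:
            t = [list(tok) for tok in tokens]
            # substitutions
            hits = np.nonzero(rng.random(len(t)) < spec.subst_prob)[0]
            for h in hits:
                if t[h][0] in frozen:
                    continue
                cur = t[h][1]
                alts = [x for x in aa if x != cur]
                t[h][1] = str(rng.choice(alts))
            # at most one indel per branch
            if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
                t = _apply_indel(t, spec, protected, rng)
            if child.is_leaf:
                for ev in planted_by_taxon.get(child.label, []):
                    for tok in t:
                        if tok[0] == ev.ref_pos:
                            tok[1] = ev.new_residue
                            break
                    else:
                        raise SimulationError(
                            f"planted site {ev.ref_pos} lost on the way to "
                            f"{child.label}"  # pragma: no cover (protected)
                        )
                results[child.label] = t
            else:
                evolve(t, child)

    evolve(root_tokens, tree.root)

    records = []
    homology: dict[str, dict] = {}
    if spec.include_reference:
        records.append(spec.reference)
        homology[spec.reference.id] = {
            i + 1: i + 1 for i in range(len(spec.reference))
        }
    for taxon in taxa:
        toks = results[taxon]
        residues = "".join(tok[1] for tok in toks)
        records.append(SequenceRecord(
            id=taxon, residues=residues, species=f"synthetic taxon {taxon}",
            description=f"{taxon} simulated from {spec.reference.id} "
                        f"(seed {spec.seed})",
        ))
        homology[taxon] = {k + 1: toks[k][0] for k in range(len(toks))}
    truth = FamilyTruth(tree=tree, homology=homology, planted=spec.planted)
    return records, truth


def _apply_indel(tokens: list, spec: FamilySpec, protected: set[int],
                 rng: np.random.Generator) -> list:
    length = int(rng.integers(1, spec.max_indel_len + 1))
    is_insert = bool(rng.random() < 0.5)
    n = len(tokens)

    def pos_ok(idx: int) -> bool:
        rp = tokens[idx][0]
        return rp is None or rp not in protected

    if is_insert:
        candidates = [i for i in range(n + 1)
                      if (i == 0 or pos_ok(i - 1)) and (i == n or pos_ok(i))]
        if not candidates:
            return tokens
        at = int(rng.choice(candidates))
        novel = [[None, str(rng.choice(list(AMINO_ACIDS)))] for _ in range(length)]
        return tokens[:at] + novel + tokens[at:]
    candidates = [i for i in range(n - length + 1)
                  if all(pos_ok(j) for j in range(i, i + length))]
    if not candidates:
        return tokens
    at = int(rng.choice(candidates))
    if len(tokens) - length < 10:  # never shred the sequence away
        return tokens
    return tokens[:at] + tokens[at + length:]


# ---------------------------------------------------------------------------
# structure pairs and gate fixtures
# ---------------------------------------------------------------------------

def rotation_from_axis_angle(axis, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise SimulationError("rotation axis must be non-zero")
    x, y, z = axis / nrm
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
            or not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise SimulationError("rotation must be a proper orthonormal 3x3 matrix")
    return R


def _helix_backbone(n: int, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Smooth helix-like C-alpha curve, spread in all three dimensions.

    A wide solenoid rather than a stereochemically realistic alpha helix:
    the point cloud must constrain rotations about every axis for
    superposition tests, and backbone realism is a non-goal.
    """
    t = np.arange(n) * 0.25
    xyz = np.stack([15.0 * np.cos(t), 15.0 * np.sin(t), 1.2 * np.arange(n)],
                   axis=1)
    if rng is not None:
        xyz = xyz + rng.normal(0.0, 0.05, size=xyz.shape)
    return xyz


def _build_structure(name: str, ca: np.ndarray, resname: str = "ALA",
                     chain: str = "A", first_resnum: int = 1,
                     with_cb: bool = True) -> Structure:
    atoms = []
    serial = 1
    for i, pos in enumerate(ca):
        resnum = first_resnum + i
        atoms.append(Atom(serial=serial, name="CA", resname=resname, chain=chain,
                          resnum=resnum, icode="", x=pos[0], y=pos[1], z=pos[2],
                          element="C"))
        serial += 1
        if with_cb:
            cb = pos + np.array([0.9, 0.9, 0.9])
            atoms.append(Atom(serial=serial, name="CB", resname=resname,
                              chain=chain, resnum=resnum, icode="",
                              x=cb[0], y=cb[1], z=cb[2], element="C"))
            serial += 1
    return Structure(name=name, atoms=tuple(atoms))


def simulate_structure_pair(n_residues: int, rotation, translation,
                            noise_sd: float, seed: int):
    """A helix-like structure and its rigidly moved, noisy copy.

    ``rotation`` is a proper 3x3 matrix or an ``(axis, angle_deg)`` pair.
    Returns ``(structure_a, structure_b, truth)`` with
    ``truth = {"rotation": R, "translation": t}`` such that B's coordinates
    are ``R @ a + t + N(0, noise_sd)``.
    """
    if n_residues < 3:
        raise SimulationError("need at least 3 residues")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    if isinstance(rotation, (tuple, list)) and len(rotation) == 2 \
            and np.shape(rotation[0]) == (3,):
        R = rotation_from_axis_angle(rotation[0], rotation[1])
    else:
        R = _check_rotation(rotation)
    t = np.asarray(translation, dtype=float).reshape(3)
    rng = np.random.default_rng(seed)
    ca = _helix_backbone(n_residues, rng)
    moved = ca @ R.T + t
    if noise_sd > 0:
        moved = moved + rng.normal(0.0, noise_sd, size=moved.shape)
    a = _build_structure("synthetic-A", ca)
    b = _build_structure("synthetic-B", moved)
    return a, b, {"rotation": R, "translation": t}


def simulate_gate(target_distance: float, seed: int,
                  resnum_a: int = 309, resnum_b: int = 518,
                  resname_a: str = "GLU", resname_b: str = "ARG",
                  n_decoy_residues: int = 20, name: str = "synthetic-gate"
                  ) -> Structure:
    """A structure whose two gate residues sit exactly ``target_distance`` apart.

    The minimum heavy side-chain atom distance between residues
    ``A:resnum_a`` and ``A:resnum_b`` equals ``target_distance`` to 1e-6;
    every other side-chain atom pair between the two residues is farther, and
    decoy residues are placed well away. The whole structure is randomly
    re-oriented per seed (distances are unaffected).
    """
    if target_distance <= 0:
        raise SimulationError("target distance must be positive")
    rng = np.random.default_rng(seed)
    D = float(target_distance)

    ca_a = np.array([0.0, 0.0, 0.0])
    ca_b = np.array([D + 3.0, 0.0, 0.0])
    tip_a = np.array([1.5, 0.0, 0.0])            # side-chain tip of residue A
    tip_b = np.array([1.5 + D, 0.0, 0.0])        # exactly D from tip_a
    cb_a = np.array([0.5, 1.2, 0.0])
    cb_b = np.array([D + 2.5, 1.2, 0.0])

    atoms: list[Atom] = []
    serial = 1

    def add(name_, resname, resnum, pos, element):
        nonlocal serial
        atoms.append(Atom(serial=serial, name=name_, resname=resname, chain="A",
                          resnum=resnum, icode="", x=pos[0], y=pos[1], z=pos[2],
                          element=element))
        serial += 1

    for nm, pos, el in (("N", ca_a + [-1.2, -0.8, 0.3], "N"),
                        ("CA", ca_a, "C"), ("C", ca_a + [1.0, -1.0, 0.2], "C"),
                        ("O", ca_a + [1.1, -2.1, 0.2], "O"),
                        ("CB", cb_a, "C"), ("OE1", tip_a, "O")):
        add(nm, resname_a, resnum_a, np.asarray(pos, dtype=float), el)
    for nm, pos, el in (("N", ca_b + [1.2, -0.8, 0.3], "N"),
                        ("CA", ca_b, "C"), ("C", ca_b + [-1.0, -1.0, 0.2], "C"),
                        ("O", ca_b + [-1.1, -2.1, 0.2], "O"),
                        ("CB", cb_b, "C"), ("NH1", tip_b, "N")):
        add(nm, resname_b, resnum_b, np.asarray(pos, dtype=float), el)

    # decoy residues on a helix displaced well off the gate axis
    helix = _helix_backbone(n_decoy_residues, rng) + np.array(
        [D / 2.0, 12.0 + D, 8.0]
    )
    decoy_start = max(resnum_a, resnum_b) + 10
    for i, pos in enumerate(helix):
        add("CA", "ALA", decoy_start + i, pos, "C")
        add("CB", "ALA", decoy_start + i, pos + np.array([0.9, 0.9, 0.9]), "C")

    # random global re-orientation: rigid, so all distances are preserved
    axis = rng.normal(size=3)
    R = rotation_from_axis_angle(axis, float(rng.uniform(0, 360)))
    shift = rng.uniform(-5, 5, size=3)
    moved = [
        Atom(serial=a.serial, name=a.name, resname=a.resname, chain=a.chain,
             resnum=a.resnum, icode=a.icode,
             **dict(zip("xyz", (R @ a.xyz + shift).tolist())),
             occupancy=a.occupancy, altloc=a.altloc, element=a.element)
        for a in atoms
    ]
    return Structure(name=name, atoms=tuple(moved))


# ---------------------------------------------------------------------------
# synthetic WEE1 study surrogates
# ---------------------------------------------------------------------------

#: human-numbering coordinates of the planted functional machinery
_REF_LENGTH = 646
_MOTIF_LAYOUT = {
    # start position -> residues written there (human WEE1A coordinates)
    304: "GSGGFEVWKAR",      # G-loop region; E at 309
    328: "K",                # ATP-contact lysine
    376: "NYSC",             # gatekeeper N376 ... hinge ... C379
    422: "IVHRDLKPENIL",     # catalytic segment = IVHxDLKPxNIx; D at 426
    463: "DLG",              # activation-segment start (human carries DLG)
    477: "EGDAR",            # EGD motif, D479, R481
    518: "R",                # second docking arginine
}
_FORBIDDEN_MOTIFS = ("DLG", "DFG", "EGD", "IVH")


def synthetic_reference_wee1(seed: int = 20211213) -> SequenceRecord:
    """SYNTHETIC surrogate of the human WEE1A protein (generated, not NCBI).

    A deterministic 646-residue sequence carrying the documented human WEE1A
    functional residues at their documented coordinates: E309 (G-loop gate),
    K328, gatekeeper N376, C379, the catalytic segment IVHRDLKPENIL at
    422-433 (catalytic D426, K428, N431), DLG at 463-465, EGD at 477-479
    (D479), R481 and R518. The random background is scrubbed of spurious
    copies of the diagnostic motifs so that motif-anchored scans are
    unambiguous.
    """
    rng = np.random.default_rng(seed)
    seq = [str(rng.choice(list(AMINO_ACIDS))) for _ in range(_REF_LENGTH)]
    planted_cols: set[int] = set()
    for start, text in _MOTIF_LAYOUT.items():
        for k, aa in enumerate(text):
            seq[start - 1 + k] = aa
            planted_cols.add(start - 1 + k)
    _scrub_spurious(seq, planted_cols, rng)
    residues = "".join(seq)
    for start, text in _MOTIF_LAYOUT.items():
        assert residues[start - 1 : start - 1 + len(text)] == text
    return SequenceRecord(
        id="HsWEE1_syn",
        residues=residues,
        species="Homo sapiens (synthetic surrogate)",
        accession="",
        description="HsWEE1_syn [species=Homo sapiens (synthetic surrogate)] "
                    "synthetic stand-in with the documented functional-site "
                    "layout of human WEE1A",
    )


def _scrub_spurious(seq: list, planted_cols: set[int],
                    rng: np.random.Generator) -> None:
    """Remove chance occurrences of diagnostic motifs outside planted windows."""
    safe = "QSTA"
    changed = True
    while changed:
        changed = False
        text = "".join(seq)
        for motif in _FORBIDDEN_MOTIFS:
            start = 0
            while True:
                idx = text.find(motif, start)
                if idx < 0:
                    break
                cols = set(range(idx, idx + len(motif)))
                if not cols & planted_cols:
                    mid = idx + len(motif) // 2
                    cur = seq[mid]
                    repl = next(s for s in safe if s != cur)
                    seq[mid] = repl
                    changed = True
                    text = "".join(seq)
                start = idx + 1


#: per-surrogate N-terminal truncation and planted substitutions, chosen so
#: the G-loop gate homologous to human E309 lands at the documented
#: per-species own-positions (259, 248, 256) and the documented variant
#: residues appear: plant H/Y/N at the gate, gatekeeper N->M, R518->E, and
#: the degenerate legume duplicate lacking both aspartates.
_STUDY_LAYOUT = (
    # id, species tag, truncation, {ref_pos: residue}
    ("AtWEE1_syn", "Arabidopsis thaliana (synthetic surrogate)", 50,
     {309: "H", 376: "M", 518: "E"}),
    ("MtWEE1_syn", "Medicago truncatula (synthetic surrogate)", 61,
     {309: "Y", 376: "M", 518: "E"}),
    ("PsWEE1_syn", "Pisum sativum (synthetic surrogate)", 53,
     {309: "N", 376: "M", 518: "E"}),
    ("VuChr61_syn", "Vigna unguiculata Chr6.1 (synthetic surrogate)", 55,
     {309: "H", 376: "M", 426: "N", 463: "G", 477: "A", 481: "G", 518: "E"}),
    ("SbWEE1_syn", "Sorghum bicolor (synthetic surrogate)", 47,
     {309: "H", 376: "M", 477: "D", 518: "E"}),
)


def synthetic_wee1_study_family(seed: int = 20211213,
                                background_subst: float = 0.03
                                ) -> tuple[SequenceRecord, list[SequenceRecord]]:
    """SYNTHETIC cross-species WEE1 comparison set (generated, not NCBI).

    Returns ``(reference, plants)``: the synthetic human surrogate plus five
    plant-like surrogates built from it by N-terminal truncation (so the
    G-loop gate falls at own-positions 259/248/256 for the
    Arabidopsis/Medicago/Pisum surrogates), the documented functional-site
    substitutions (gate E->H/Y/N, gatekeeper N->M, R518->E, the EGD E->D
    monocot variant, and a degenerate legume duplicate lacking catalytic and
    DFG aspartates), and sparse random background substitutions away from
    catalog sites.
    """
    ref = synthetic_reference_wee1(seed)
    rng = np.random.default_rng(seed + 1)
    protected = set()
    for start, text in _MOTIF_LAYOUT.items():
        protected.update(range(start - 3, start + len(text) + 3))
    plants = []
    for pid, species, trunc, subs in _STUDY_LAYOUT:
        seq = list(ref.residues)
        for pos, aa in subs.items():
            seq[pos - 1] = aa
        n_bg = rng.binomial(len(seq), background_subst)
        sites = rng.choice(len(seq), size=n_bg, replace=False)
        for s in sites:
            if (s + 1) in protected:
                continue
            cur = seq[s]
            alts = [x for x in AMINO_ACIDS if x != cur]
            seq[s] = str(rng.choice(alts))
        residues = "".join(seq[trunc:])
        plants.append(SequenceRecord(
            id=pid, residues=residues, species=species,
            description=f"{pid} [species={species}] synthetic surrogate derived "
                        f"from {ref.id} (truncation {trunc}, seed {seed})",
        ))
    return ref, plants
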