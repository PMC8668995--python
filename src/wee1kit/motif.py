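"""Functional-site conservation calls for WEE1-family kinases.

The catalog encodes the residues that make a WEE1 kinase work, in human WEE1A
numbering: the G-loop glutamate E309 implicated in tyrosine specificity, the
ATP-contact residues (K328, C379, K428, N431, D463), the gatekeeper N376, the
catalytic aspartate D426 inside the kinase consensus segment IVHxDLKPxNIx,
the activation-segment DFG/DLG motif (463-465; human carries DLG, plants
DFG), the WEE1-signatory EGD motif (477-479), and the substrate-docking
arginines R481 and R518 with D479.

Every sequence in an anchored alignment gets one call per site: conserved
(expected residue), conservative (same physicochemical class), class-change,
or missing (gap). Functionality flags are then derived from the calls alone —
e.g. a kinase lacking the catalytic aspartate is flagged catalytic-dead.

Physicochemical classes follow the standard coloring of kinase alignment
figures: hydrophobic AILMFVW, acidic DE, basic RK, polar QSNT, aromatic YH,
with C, P and G each their own class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .msa import MultipleAlignment
from .refanchor import ColumnMap, Observation, residue_at
from .seqio import ALPHABET, AMINO_ACIDS, GAP, SequenceRecord

HYDROPHOBIC = frozenset("AILMFVW")

_CLASSES = {
    "hydrophobic": HYDROPHOBIC,
    "acidic": frozenset("DE"),
    "basic": frozenset("RK"),
    "polar": frozenset("QSNT"),
    "aromatic": frozenset("YH"),
    "cysteine": frozenset("C"),
    "proline": frozenset("P"),
    "glycine": frozenset("G"),
}
_CLASS_OF = {aa: name for name, members in _CLASSES.items() for aa in members}


class MotifError(ValueError):
    pass


def classify_residue(aa: str) -> str:
    """Physicochemical class of one residue letter; ``X`` classifies as unknown."""
    if aa == "X":
        return "unknown"
    try:
        return _CLASS_OF[aa]
    except KeyError:
        raise MotifError(f"invalid residue {aa!r}") from None


# ---------------------------------------------------------------------------
# consensus pattern scanning
# ---------------------------------------------------------------------------

def scan_consensus(seq: SequenceRecord | str, pattern: str,
                   relaxed_hydrophobic: bool = False) -> list[tuple[int, str]]:
    """All 1-based start positions where ``pattern`` matches the sequence.

    ``x`` in the pattern matches any residue. In relaxed mode a hydrophobic
    pattern letter (AILMFVW) additionally accepts any hydrophobic residue,
    the tolerance kinase consensus sequences allow at hydrophobic positions.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not pattern:
        raise MotifError("empty pattern")
    for ch in pattern:
        if ch != "x" and ch not in ALPHABET:
            raise MotifError(f"invalid pattern character {ch!r}")
    hits = []
    k = len(pattern)
    for start in range(len(residues) - k + 1):
        window = residues[start : start + k]
        ok = True
        for p, aa in zip(pattern, window):
            if p == "x":
                continue
            if aa == p:
                continue
            if relaxed_hydrophobic and p in HYDROPHOBIC and aa in HYDROPHOBIC:
                continue
            ok = False
            break
        if ok:
            hits.append((start + 1, window))
    return hits


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Site:
    """One catalog entry: contiguous reference positions with expected residues.

    ``expected`` holds one allowed-residue set per position, so a
    single-residue site is a length-1 tuple and a motif like D-[LF]-G spans
    three.
    """

    name: str
    ref_start: int
    expected: tuple
    category: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "expected", tuple(frozenset(e) for e in self.expected)
        )
        for alt in self.expected:
            for aa in alt:
                if aa not in ALPHABET:
                    raise MotifError(f"site {self.name}: bad residue {aa!r}")

    @property
    def positions(self) -> range:
        return range(self.ref_start, self.ref_start + len(self.expected))


@dataclass(frozen=True)
class ConsensusPattern:
    name: str
    pattern: str
    anchor_start: int  # reference position where the pattern is expected

    @property
    def anchor_range(self) -> range:
        return range(self.anchor_start, self.anchor_start + len(self.pattern))


@dataclass(frozen=True)
class ReferenceSiteCatalog:
    ref_name: str
    sites: tuple
    consensus_patterns: tuple = ()
    segments: tuple = ()  # (name, ref_start, ref_end) display regions

    def __post_init__(self) -> None:
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise MotifError("duplicate site names in catalog")

    def site(self, name: str) -> Site:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)

    def max_position(self) -> int:
        return max(s.positions[-1] for s in self.sites)

    # -- JSON (de)serialization so other kinase families can be annotated --

    def to_json(self) -> str:
        return json.dumps(
            {
                "ref_name": self.ref_name,
                "sites": [
                    {
                        "name": s.name,
                        "ref_start": s.ref_start,
                        "expected": ["".join(sorted(e)) for e in s.expected],
                        "category": s.category,
                    }
                    for s in self.sites
                ],
                "consensus_patterns": [
                    {"name": p.name, "pattern": p.pattern,
                     "anchor_start": p.anchor_start}
                    for p in self.consensus_patterns
                ],
                "segments": [list(seg) for seg in self.segments],
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "ReferenceSiteCatalog":
        data = json.loads(text)
        return ReferenceSiteCatalog(
            ref_name=data["ref_name"],
            sites=tuple(
                Site(name=s["name"], ref_start=s["ref_start"],
                     expected=tuple(s["expected"]), category=s["category"])
                for s in data["sites"]
            ),
            consensus_patterns=tuple(
                ConsensusPattern(**p) for p in data.get("consensus_patterns", [])
            ),
            segments=tuple(tuple(seg) for seg in data.get("segments", [])),
        )

    @staticmethod
    def load(path: str | Path) -> "ReferenceSiteCatalog":
        return ReferenceSiteCatalog.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


#: Kinase consensus over the catalytic segment; the aspartate (5th symbol)
#: is the catalytic residue.
CATALYTIC_CONSENSUS = "IVHxDLKPxNIx"


def builtin_wee1_catalog() -> ReferenceSiteCatalog:
    """The WEE1 functional-site catalog in human WEE1A numbering."""
    sites = (
        Site("G-loop-E309", 309, ("E",), "g-loop-gate"),
        Site("K328", 328, ("K",), "atp-contact"),
        Site("gatekeeper", 376, ("N",), "gatekeeper"),
        Site("C379", 379, ("C",), "atp-contact"),
        Site("catalytic-D", 426, ("D",), "catalytic"),
        Site("K428", 428, ("K",), "atp-contact"),
        Site("N431", 431, ("N",), "atp-contact"),
        Site("DFG", 463, ("D", "LF", "G"), "activation-dfg"),
        Site("EGD", 477, ("E", "G", "D"), "activation-egd"),
        Site("D479", 479, ("D",), "docking"),
        Site("R481", 481, ("R",), "docking"),
        Site("R518", 518, ("R",), "docking"),
    )
    patterns = (
        ConsensusPattern("catalytic-segment", CATALYTIC_CONSENSUS,
                         anchor_start=422),
    )
    segments = (
        ("G-loop", 304, 314),
        ("ATP-binding", 372, 383),
        ("Catalytic", 420, 435),
        ("Activation", 460, 485),
    )
    return ReferenceSiteCatalog(ref_name="human-WEE1A", sites=sites,
                                consensus_patterns=patterns, segments=segments)


# ---------------------------------------------------------------------------
# conservation calls
# ---------------------------------------------------------------------------

STATUSES = ("conserved", "conservative", "class-change", "missing")


@dataclass(frozen=True)
class SiteCall:
    seq_id: str
    site: str
    observed: str  # observed residues over the site span; may contain '-'
    own_position: Optional[int]  # query's own 1-based position of first residue
    status: str


def _call_one(site: Site, observations: list[Observation]) -> SiteCall:
    observed = "".join(o.residue for o in observations)
    own = observations[0].own_position
    seq_id = observations[0].seq_id
    if any(o.residue == GAP or not o.in_alignment for o in observations):
        status = "missing"
    else:
        per_pos = []
        for o, allowed in zip(observations, site.expected):
            if o.residue in allowed:
                per_pos.append("conserved")
            elif classify_residue(o.residue) in {classify_residue(a) for a in allowed}:
                per_pos.append("conservative")
            else:
                per_pos.append("class-change")
        if all(s == "conserved" for s in per_pos):
            status = "conserved"
        elif "class-change" in per_pos:
            status = "class-change"
        else:
            status = "conservative"
    return SiteCall(seq_id=seq_id, site=site.name, observed=observed,
                    own_position=own, status=status)


@dataclass(frozen=True)
class ConservationTable:
    """SiteCalls for every (sequence, site) pair plus per-site summaries."""

    seq_ids: tuple
    site_names: tuple
    calls: dict  # (seq_id, site_name) -> SiteCall

    def call(self, seq_id: str, site: str) -> SiteCall:
        return self.calls[(seq_id, site)]

    def per_site_summary(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for site in self.site_names:
            counts = {s: 0 for s in STATUSES}
            for sid in self.seq_ids:
                counts[self.calls[(sid, site)].status] += 1
            out[site] = counts
        return out

    def non_conserved(self) -> list[SiteCall]:
        return [c for c in self.calls.values() if c.status != "conserved"]

    def to_tsv(self) -> str:
        lines = ["seq_id\t" + "\t".join(self.site_names)]
        for sid in self.seq_ids:
            cells = []
            for site in self.site_names:
                c = self.calls[(sid, site)]
                cells.append(f"{c.observed}/{c.status}")
            lines.append(sid + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def call_sites(msa: MultipleAlignment, cmap: ColumnMap,
               catalog: ReferenceSiteCatalog) -> ConservationTable:
    """Evaluate every catalog site on every sequence of an anchored alignment."""
    calls: dict = {}
    seq_ids = tuple(msa.ids)
    for sid in seq_ids:
        for site in catalog.sites:
            obs = [residue_at(msa, cmap, sid, p) for p in site.positions]
            calls[(sid, site.name)] = _call_one(site, obs)
    return ConservationTable(seq_ids=seq_ids,
                             site_names=tuple(s.name for s in catalog.sites),
                             calls=calls)


# ---------------------------------------------------------------------------
# functionality flags
# ---------------------------------------------------------------------------

FLAG_RULES = (
    # flag name, site, rule: flagged when the named position is not conserved
    ("catalytic-dead", "catalytic-D"),
    ("ATP-binding-compromised", "DFG"),  # judged on the D only, see below
    ("EGD-variant", "EGD"),
    ("docking-R481-variant", "R481"),
    ("gatekeeper-variant", "gatekeeper"),
    ("R518-variant", "R518"),
)


@dataclass(frozen=True)
class FunctionalFlags:
    seq_id: str
    flags: frozenset


def assess_function(table: ConservationTable) -> list[FunctionalFlags]:
    """Derive per-sequence functionality flags from the conservation calls.

    catalytic-dead: the catalytic aspartate (human D426) is not D.
    ATP-binding-compromised: the DFG/DLG aspartate (human D463) is not D —
    only the aspartate is function-critical; L/F exchange at the second
    position never flags. Remaining flags mark variants at the EGD motif, the
    docking arginines R481/R518 and the gatekeeper.
    """
    out = []
    for sid in table.seq_ids:
        flags = set()
        for flag, site in FLAG_RULES:
            call = table.call(sid, site)
            if site == "DFG":
                # judge the aspartate only (first motif position)
                if not call.observed or call.observed[0] != "D":
                    flags.add(flag)
            elif call.status != "conserved":
                flags.add(flag)
        out.append(FunctionalFlags(seq_id=sid, flags=frozenset(flags)))
    return out


# ---------------------------------------------------------------------------
# motif-anchored localization on a single sequence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPositions:
    """1-based positions of the core catalytic machinery found by scanning."""

    catalytic_segment_start: int
    catalytic_asp: int      # the D of the ...HxD... consensus
    dfg_start: int          # start of the D-[LF]-G motif
    dfg_asp: int
    egd_start: int


def locate_functional_motifs(seq: SequenceRecord,
                             relaxed_hydrophobic: bool = False) -> MotifPositions:
    """Locate the catalytic segment, DFG/DLG and EGD motifs by consensus scan.

    The catalytic segment is found with the kinase consensus IVHxDLKPxNIx
    (its aspartate is the 5th position); the activation-segment D-[LF]-G is
    the first such triplet downstream of the catalytic segment, and EGD the
    first occurrence downstream of D-[LF]-G — the canonical ordering of
    kinase-domain elements.
    """
    hits = scan_consensus(seq, CATALYTIC_CONSENSUS,
                          relaxed_hydrophobic=relaxed_hydrophobic)
    if not hits:
        raise MotifError(
            f"{seq.id}: catalytic-segment consensus {CATALYTIC_CONSENSUS} not found"
        )
    seg_start = hits[0][0]
    cat_asp = seg_start + 4
    seg_end = seg_start + len(CATALYTIC_CONSENSUS) - 1

    dfg_hits = sorted(
        h for pat in ("DLG", "DFG") for h in scan_consensus(seq, pat)
        if h[0] > seg_end
    )
    if not dfg_hits:
        raise MotifError(f"{seq.id}: no D-[LF]-G motif downstream of the "
                         "catalytic segment")
    dfg_start = dfg_hits[0][0]

    egd_hits = [h for h in scan_consensus(seq, "EGD") if h[0] > dfg_start + 2]
    if not egd_hits:
        raise MotifError(f"{seq.id}: no EGD motif downstream of D-[LF]-G")
    return MotifPositions(
        catalytic_segment_start=seg_start,
        catalytic_asp=cat_asp,
        dfg_start=dfg_start,
        dfg_asp=dfg_start,
        egd_start=egd_hits[0][0],
    )
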