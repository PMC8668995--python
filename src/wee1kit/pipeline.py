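"""End-to-end conservation analysis: one config in, one report bundle out.

``run_report`` ties the stages together the way the published analysis was
assembled: align the family, anchor the columns on the reference, evaluate
the functional-site catalog, derive functionality flags, build the
midpoint-rooted distance tree, and (when structures are supplied) measure the
catalytic-pocket access distances. Outputs are deterministic and
self-describing: every table carries a header comment naming the parameters
that produced it, and a JSON manifest records versions, parameters, seed and
input checksums.
"""

from __future__ import annotations

import hashlib
import json
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__, msa as msa_mod, phylo, refanchor, seqio, structure
from .motif import ReferenceSiteCatalog, assess_function, builtin_wee1_catalog, call_sites
from .pairwise import ScoringScheme, blosum62


class PipelineError(RuntimeError):
    """Stage-named failure of the report pipeline."""


@dataclass
class RunConfig:
    fasta: list
    ref_id: str
    outdir: str
    alignment: Optional[str] = None      # pre-computed alignment (aligned FASTA)
    catalog: str = "builtin-wee1"        # or a catalog JSON path
    trim_occupancy: Optional[float] = 0.5
    gap_open: float = 10.0
    gap_extend: float = 0.5
    poisson_correction: bool = False
    structures: list = field(default_factory=list)   # [(label, pdb path)]
    gates: dict = field(default_factory=dict)        # label -> (selA, selB)
    distance_mode: str = "min-side-chain-heavy"
    seed: int = 0

    @staticmethod
    def from_json(path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return RunConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _param_header(**params) -> str:
    parts = ", ".join(f"{k}={v}" for k, v in params.items())
    return f"# wee1kit {__version__}; {parts}\n"


def run_report(config: RunConfig) -> dict:
    """Run the whole analysis; returns a dict of artifact paths and objects.

    Any stage error aborts with a message naming the stage, and artifacts
    written so far are removed so a failed run leaves no partial bundle.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> Path:
        p = outdir / name
        p.write_text(text)
        written.append(p)
        return p

    try:
        return _run(config, outdir, emit, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, outdir: Path, emit, written) -> dict:
    # --- validation up front: fail before any computation -----------------
    for p in list(config.fasta) + [s[1] for s in config.structures]:
        if not Path(p).exists():
            raise PipelineError(f"stage 'config' failed: missing input {p}")
    if config.alignment and not Path(config.alignment).exists():
        raise PipelineError(
            f"stage 'config' failed: missing alignment {config.alignment}"
        )

    records = []
    for p in config.fasta:
        records.extend(seqio.read_fasta(p))
    ids = [r.id for r in records]
    if config.ref_id not in ids:
        raise PipelineError(
            f"stage 'config' failed: reference id {config.ref_id!r} not among "
            f"inputs {ids}"
        )

    scheme = blosum62(config.gap_open, config.gap_extend)
    if config.catalog == "builtin-wee1":
        catalog = builtin_wee1_catalog()
    else:
        catalog = ReferenceSiteCatalog.load(config.catalog)

    # --- alignment --------------------------------------------------------
    aln = _align_stage(config, records, scheme)
    ref_start = 1
    if config.trim_occupancy is not None:
        lo, hi = msa_mod.trim_bounds(aln, config.trim_occupancy)
        ref_row = aln.row(config.ref_id)
        ref_start = 1 + sum(
            1 for ch in ref_row.residues[:lo] if ch != seqio.GAP
        )
        aln = msa_mod.trim_ends(aln, config.trim_occupancy)
    emit("alignment.afa", seqio.fasta_str(aln.records))

    # --- anchoring, segments, conservation, flags -------------------------
    cmap = _anchor_stage(aln, config.ref_id, ref_start)
    seg_params = dict(reference=config.ref_id,
                      trim_occupancy=config.trim_occupancy,
                      scheme=scheme.name, gap_open=scheme.gap_open,
                      gap_extend=scheme.gap_extend)
    for name, lo_pos, hi_pos in catalog.segments:
        try:
            seg = refanchor.extract_segment(aln, cmap, lo_pos, hi_pos)
        except refanchor.AnchorError:
            continue  # segment trimmed away entirely
        rows = [f"{r.id}\t{r.residues}" for r in seg.records]
        emit(f"segment_{name.replace(' ', '_')}.tsv",
             _param_header(segment=f"{name} {lo_pos}-{hi_pos}", **seg_params)
             + "seq_id\tresidues\n" + "\n".join(rows) + "\n")

    table = _sites_stage(aln, cmap, catalog)
    emit("conservation.tsv", _param_header(**seg_params) + table.to_tsv())
    flags = assess_function(table)
    emit("flags.json", json.dumps(
        {f.seq_id: sorted(f.flags) for f in flags}, indent=2) + "\n")

    # --- tree --------------------------------------------------------------
    tree_path = None
    if len(records) >= 3:
        tree = _tree_stage(records, scheme, config.poisson_correction)
        tree_path = emit("tree.nwk", phylo.to_newick(tree) + "\n")

    # --- structures ---------------------------------------------------------
    gate_rows = []
    if config.structures:
        gate_rows = _gate_stage(config)
        emit("gate_access.tsv",
             _param_header(mode=config.distance_mode)
             + structure.gate_table_tsv(gate_rows))

    # --- manifest -----------------------------------------------------------
    manifest = {
        "wee1kit": __version__,
        "numpy": np.__version__,
        "python": sys.version.split()[0],
        "parameters": {
            "ref_id": config.ref_id,
            "catalog": config.catalog,
            "trim_occupancy": config.trim_occupancy,
            "scheme": scheme.name,
            "gap_open": scheme.gap_open,
            "gap_extend": scheme.gap_extend,
            "poisson_correction": config.poisson_correction,
            "distance_mode": config.distance_mode,
            "seed": config.seed,
        },
        "inputs": {
            str(p): _sha256(Path(p))
            for p in list(config.fasta)
            + ([config.alignment] if config.alignment else [])
            + [s[1] for s in config.structures]
        },
    }
    emit("manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "outdir": outdir,
        "artifacts": [str(p) for p in written],
        "alignment": aln,
        "column_map": cmap,
        "conservation": table,
        "flags": flags,
        "gate_measurements": gate_rows,
    }


@_stage("align")
def _align_stage(config: RunConfig, records, scheme):
    if config.alignment:
        rows = seqio.read_alignment(config.alignment)
        return msa_mod.MultipleAlignment(records=tuple(rows))
    return msa_mod.progressive_align(records, scheme)


@_stage("anchor")
def _anchor_stage(aln, ref_id, ref_start):
    return refanchor.build_column_map(aln, ref_id, ref_start=ref_start)


@_stage("annotate")
def _sites_stage(aln, cmap, catalog):
    return call_sites(aln, cmap, catalog)


@_stage("tree")
def _tree_stage(records, scheme, poisson):
    D = msa_mod.distance_matrix(records, scheme)
    if poisson:
        # Poisson-corrected distances -ln(1-p); p capped below 1
        D = -np.log(np.clip(1.0 - D, 1e-4, None))
        np.fill_diagonal(D, 0.0)
    nj = phylo.neighbor_joining(D, [r.id for r in records])
    return phylo.midpoint_root(nj)


@_stage("measure")
def _gate_stage(config: RunConfig):
    structs = [(label, structure.read_pdb(path, name=label))
               for label, path in config.structures]
    gates = config.gates if config.gates else None
    if gates is None:
        raise ValueError("structures given but no gate residue selectors")
    return structure.gate_access_report(structs, gates,
                                        mode=config.distance_mode)
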