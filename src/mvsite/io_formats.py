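"""Readers and writers for the external formats the pipeline touches.

Structures come in as PDB text (parsed with Biopython), base-pairing
annotations as whitespace-separated edge lists, alignments as aligned
FASTA, and predictions go out as TSV.  All indices are converted to the
package-internal convention at this boundary: 0-based, interaction pairs
ordered ``i < j``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio import SeqIO

INTERACTION_KINDS = ("canonical_pair", "noncanonical_pair",
                     "base_ribose", "base_phosphate")

STANDARD_BASES = ("A", "U", "G", "C")


@dataclass
class Residue:
    index: int                      # dense 0-based position in the chain
    auth_seq: int                   # author residue number from the PDB file
    base: str                       # one of A/C/G/U or "other"
    atoms: list[tuple[str, float, float, float]] = field(default_factory=list)

    def coords(self) -> np.ndarray:
        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=float)


@dataclass
class Ligand:
    het_code: str
    atoms: list[tuple[str, float, float, float]] = field(default_factory=list)

    def coords(self) -> np.ndarray:
        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=float)


@dataclass
class StructureRecord:
    """One RNA chain plus every non-water hetero group in the file."""

    chain_id: str
    residues: list[Residue]
    ligands: list[Ligand]

    def __post_init__(self):
        if not self.residues:
            raise ValueError("StructureRecord requires at least one residue")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        for r in self.residues:
            if not np.isfinite(r.coords()).all():
                raise ValueError(f"non-finite coordinates in residue {r.index}")
        for lig in self.ligands:
            if lig.het_code == "HOH":
                raise ValueError("water must not appear as a ligand")

    @property
    def n(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(r.base if r.base in STANDARD_BASES else "N"
                       for r in self.residues)


@dataclass
class SecondaryAnnotation:
    """Base-pair / backbone-contact annotation for a chain of n nucleotides."""

    n: int
    interactions: list[tuple[int, int, str]]
    loop_member: np.ndarray          # (n,) bool

    def __post_init__(self):
        self.loop_member = np.asarray(self.loop_member, dtype=bool)
        if self.loop_member.shape != (self.n,):
            raise ValueError("loop_member length must equal n")
        seen = set()
        for i, j, kind in self.interactions:
            if not (0 <= i < j < self.n):
                raise ValueError(f"interaction ({i},{j}) outside [0,{self.n})")
            if kind not in INTERACTION_KINDS:
                raise ValueError(f"unknown interaction kind {kind!r}")
            if (i, j, kind) in seen:
                raise ValueError(f"duplicate interaction ({i},{j},{kind})")
            seen.add((i, j, kind))


@dataclass
class MsaRecord:
    """Aligned sequences over {A,U,G,C,-}; one row is the study sequence."""

    rows: list[str]
    ids: list[str]
    query_row: int

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("ragged alignment: rows differ in length")
        if not self.rows:
            raise ValueError("empty alignment")
        bad = set(self.rows[self.query_row]) - set("AUGC-")
        if bad:
            raise ValueError(f"query row contains invalid symbols {bad}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def depth(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------

def read_structure(pdb_text: str, chain_id: str) -> StructureRecord:
    """Parse one chain of a PDB file plus all non-water HETATM groups.

    Only the first model of multi-model (NMR) files is used; alternate
    locations resolve to the first conformer; water is dropped.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", io.StringIO(pdb_text))
    model = next(structure.get_models())

    chain_ids = [c.id for c in model]
    if chain_id not in chain_ids:
        raise ValueError(
            f"chain {chain_id!r} not found; available chains: {sorted(chain_ids)}")

    residues: list[Residue] = []
    ligands: list[Ligand] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.id
            atoms = []
            for atom in res.get_unpacked_list():
                if atom.get_altloc() not in (" ", "A", ""):
                    continue        # first conformer only
                x, y, z = atom.coord
                atoms.append((atom.get_name(), float(x), float(y), float(z)))
            if hetflag == "W" or res.get_resname().strip() == "HOH":
                continue
            if hetflag.startswith("H"):
                ligands.append(Ligand(res.get_resname().strip(), atoms))
            elif chain.id == chain_id:
                name = res.get_resname().strip()
                base = name if name in STANDARD_BASES else "other"
                residues.append(Residue(0, resseq, base, atoms))

    if not residues:
        raise ValueError(f"chain {chain_id!r} contains no nucleotide residues")
    # order by author numbering (insertion codes already resolved by parser
    # order), then re-index densely
    residues.sort(key=lambda r: r.auth_seq)
    for i, r in enumerate(residues):
        r.index = i
    return StructureRecord(chain_id, residues, ligands)


def read_secondary_annotation(text: str, n: int) -> SecondaryAnnotation:
    """Parse a whitespace-separated interaction list.

    Lines are either ``i j kind`` (1-based indices, any order) or
    ``loop i`` marking nucleotide i as a loop member.  Blank lines and
    ``#`` comments are ignored.
    """
    interactions: list[tuple[int, int, str]] = []
    loop = np.zeros(n, dtype=bool)
    seen = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "loop":
            i = int(parts[1]) - 1
            if not 0 <= i < n:
                raise ValueError(f"line {lineno}: loop index {parts[1]} outside 1..{n}")
            loop[i] = True
            continue
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 'i j kind', got {raw!r}")
        i, j, kind = int(parts[0]) - 1, int(parts[1]) - 1, parts[2]
        if kind not in INTERACTION_KINDS:
            raise ValueError(f"line {lineno}: unknown interaction kind {kind!r}")
        i, j = min(i, j), max(i, j)
        if not (0 <= i < j < n):
            raise ValueError(f"line {lineno}: indices ({i + 1},{j + 1}) outside 1..{n}")
        if (i, j, kind) not in seen:
            seen.add((i, j, kind))
            interactions.append((i, j, kind))
    return SecondaryAnnotation(n, interactions, loop)


def read_msa(fasta_text: str, query_id: str) -> MsaRecord:
    """Read an aligned FASTA; DNA T is mapped to U, case is folded."""
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if not records:
        raise ValueError("no sequences in alignment")
    rows, ids = [], []
    query_row = None
    for k, rec in enumerate(records):
        seq = str(rec.seq).upper().replace("T", "U")
        rows.append(seq)
        ids.append(rec.id)
        if rec.id == query_id:
            query_row = k
    if len({len(r) for r in rows}) > 1:
        raise ValueError("ragged alignment: rows differ in length")
    if query_row is None:
        raise ValueError(f"query id {query_id!r} not found in alignment")
    return MsaRecord(rows, ids, query_row)


PREDICTION_COLUMNS = ("chain", "residue_index", "base", "probability",
                      "predicted_label", "true_label")


def write_predictions(rows: list[dict]) -> str:
    """Serialize per-nucleotide predictions as TSV (probabilities to 6 dp)."""
    has_truth = any("true_label" in r and r["true_label"] is not None
                    for r in rows)
    cols = PREDICTION_COLUMNS if has_truth else PREDICTION_COLUMNS[:-1]
    lines = ["\t".join(cols)]
    for r in rows:
        vals = [str(r["chain"]), str(r["residue_index"]), str(r["base"]),
                f"{float(r['probability']):.6f}", str(int(r["predicted_label"]))]
        if has_truth:
            vals.append(str(int(r["true_label"])))
        lines.append("\t".join(vals))
    return "\n".join(lines) + "\n"


def read_predictions(text: str) -> list[dict]:
    """Inverse of :func:`write_predictions`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    out = []
    for ln in lines[1:]:
        vals = dict(zip(header, ln.split("\t")))
        out.append({
            "chain": vals["chain"],
            "residue_index": int(vals["residue_index"]),
            "base": vals["base"],
            "probability": float(vals["probability"]),
            "predicted_label": int(vals["predicted_label"]),
            "true_label": int(vals["true_label"]) if "true_label" in vals else None,
        })
    return out


def structure_to_pdb(record: StructureRecord) -> str:
    """Serialize a StructureRecord back to minimal PDB text.

    Used by the synthetic generator to make the full pipeline testable
    from disk; round-trips through :func:`read_structure`.
    """
    lines = []
    serial = 1
    base_names = {"A": "A", "U": "U", "G": "G", "C": "C", "other": "UNK"}
    for res in record.residues:
        resname = base_names.get(res.base, "UNK")
        for name, x, y, z in res.atoms:
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {record.chain_id}"
                f"{res.auth_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00")
            serial += 1
    for li, lig in enumerate(record.ligands, start=1):
        for name, x, y, z in lig.atoms:
            lines.append(
                f"HETATM{serial:5d} {name:<4s}{lig.het_code:>4s} X"
                f"{li:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
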