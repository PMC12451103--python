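"""Synthetic RNA structures with a planted small-molecule pocket.

Residues sit on an idealized A-form-like helix (fixed rise and twist,
Gaussian coordinate noise).  A contiguous-in-3D set of residues is chosen
as the pocket and one ligand atom is placed radially outward of each
pocket residue so that every pocket residue has an atom within 4 A of the
ligand while every non-pocket residue stays beyond a 4.5 A exclusion
margin — the margin keeps the inclusive 4.0 A labeling rule unambiguous.
The generator also emits a hairpin-like secondary annotation and an MSA
with a planted conservation pattern, so the whole pipeline is testable at
desk scale with no downloads.

Realistic thermodynamics is explicitly not the goal; geometric
consistency with the labeling rule is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import (FeatureStats, assemble_features, conservation_scores,
                       one_hot_encode, secondary_feature_vector,
                       standardize, topological_properties)
from .graphs import (MultiViewGraph, assign_labels, build_primary_graph,
                     build_secondary_graph, build_tertiary_graph,
                     representative_coords)
from .io_formats import (Ligand, MsaRecord, Residue, SecondaryAnnotation,
                         StructureRecord)
from .training import split_dataset

BASES = "AUGC"
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# idealized A-form-like geometry
HELIX_RISE = 2.81          # A per residue along the axis
HELIX_TWIST = 32.7         # degrees per residue
HELIX_RADIUS = 9.4         # A, backbone phosphate radius


@dataclass
class SyntheticSpec:
    n_residues: int = 30
    helix_rise: float = HELIX_RISE
    helix_twist: float = HELIX_TWIST
    pocket_size: int = 5
    pocket_signal_strength: float = 2.0    # feature shift, in SD units
    ligand_offset: float = 3.2             # A, radial ligand-atom distance
    noise_sd: float = 0.3                  # A, coordinate noise
    seed: int = 0

    def __post_init__(self):
        if self.pocket_size >= self.n_residues:
            raise ValueError("pocket_size must be smaller than n_residues")
        for v in (self.n_residues, self.helix_rise, self.helix_twist,
                  self.ligand_offset):
            if v <= 0:
                raise ValueError("all scales must be positive")
        if self.noise_sd < 0 or self.pocket_size < 0:
            raise ValueError("noise_sd and pocket_size must be non-negative")


def _helix_atoms(spec: SyntheticSpec, rng: np.random.Generator):
    """Noisy P / C4' / N1 positions for each residue plus clean P anchors."""
    n = spec.n_residues
    theta = np.deg2rad(spec.helix_twist) * np.arange(n)
    z = spec.helix_rise * np.arange(n)
    radial = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
    axis = np.column_stack([np.zeros(n), np.zeros(n), z])
    clean_p = axis + HELIX_RADIUS * radial
    atoms = {}
    for name, radius, dz in (("P", HELIX_RADIUS, 0.0),
                             ("C4'", HELIX_RADIUS - 1.2, 0.6),
                             ("N1", HELIX_RADIUS - 3.5, 0.2)):
        pos = axis + radius * radial
        pos[:, 2] += dz
        atoms[name] = pos + rng.normal(0.0, spec.noise_sd, size=pos.shape)
    return atoms, radial, clean_p


def _hairpin_annotation(n: int, rng: np.random.Generator) -> SecondaryAnnotation:
    """Stem of canonical pairs closing a loop, plus a few extra contacts."""
    stem = max(0, (n - 4) // 2)
    interactions = [(i, n - 1 - i, "canonical_pair") for i in range(stem)]
    loop = np.zeros(n, dtype=bool)
    loop[stem:n - stem] = True
    # sprinkle non-canonical / backbone-contact interactions away from
    # backbone neighbors
    taken = {(i, j) for i, j, _ in interactions}
    kinds = ["noncanonical_pair", "base_ribose", "base_phosphate"]
    for kind in kinds:
        for _ in range(8):
            i = int(rng.integers(0, n))
            j = int(rng.integers(0, n))
            i, j = min(i, j), max(i, j)
            if j - i >= 2 and (i, j) not in taken:
                taken.add((i, j))
                interactions.append((i, j, kind))
                break
    return SecondaryAnnotation(n, interactions, loop)


def _sequence(n: int, rng: np.random.Generator,
              annotation: SecondaryAnnotation) -> str:
    seq = [BASES[int(b)] for b in rng.integers(0, 4, size=n)]
    for i, j, kind in annotation.interactions:
        if kind == "canonical_pair":
            seq[j] = COMPLEMENT[seq[i]]
    return "".join(seq)


def simulate_structure(spec: SyntheticSpec):
    """Build one synthetic chain.

    Returns ``(StructureRecord, SecondaryAnnotation, pocket_indices)``;
    the pocket indices are, by construction, exactly the residues the
    4 A contact rule labels positive.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    annotation = _hairpin_annotation(n, rng)
    seq = _sequence(n, rng, annotation)

    atoms, radial, clean_p = _helix_atoms(spec, rng)
    residues = [
        Residue(i, i + 1, seq[i],
                [(name, *atoms[name][i]) for name in ("P", "C4'", "N1")])
        for i in range(n)]

    if spec.pocket_size == 0:
        record = StructureRecord("A", residues, [])
        warnings.warn("pocket_size is 0; structure has no ligand and all "
                      "labels are 0", stacklevel=2)
        return record, annotation, np.array([], dtype=int)

    rep = atoms["P"]
    seeds = rng.permutation(n)
    for attempt, seed_res in enumerate(seeds):
        dist_to_seed = np.linalg.norm(rep - rep[seed_res], axis=1)
        pocket = np.sort(np.argsort(dist_to_seed, kind="stable")[:spec.pocket_size])
        lig_atoms = [(f"L{k + 1}", *(rep[i] + spec.ligand_offset * radial[i]))
                     for k, i in enumerate(pocket)]
        lig_xyz = np.array([a[1:] for a in lig_atoms])
        ok = True
        for r in residues:
            d = np.linalg.norm(r.coords()[:, None, :] - lig_xyz[None, :, :],
                               axis=-1).min()
            in_pocket = r.index in pocket
            if in_pocket and d > 4.0:
                ok = False
            if not in_pocket and d <= 4.5:
                ok = False
            if not ok:
                break
        if ok:
            ligand = Ligand("LIG", lig_atoms)
            record = StructureRecord("A", residues, [ligand])
            return record, annotation, pocket
        if attempt >= 49:
            break
    raise RuntimeError(
        "could not place a ligand satisfying the 4.0/4.5 A margins after "
        "bounded retries; increase pocket separation (smaller pocket, "
        "larger ligand_offset, or less coordinate noise)")


def simulate_msa(sequence: str, conserved_positions, depth: int,
                 seed: int = 0) -> MsaRecord:
    """Alignment whose conserved columns copy the query base everywhere.

    Non-conserved columns are resampled uniformly from {A,U,G,C} in every
    non-query row, so their expected conservation score is near 0 at depth.
    """
    if depth < 2:
        raise ValueError("MSA depth must be at least 2")
    rng = np.random.default_rng(seed)
    conserved = set(int(i) for i in conserved_positions)
    if any(i < 0 or i >= len(sequence) for i in conserved):
        raise ValueError("conserved positions outside the sequence")
    rows = [sequence]
    for _ in range(depth - 1):
        row = [sequence[c] if c in conserved else BASES[int(rng.integers(0, 4))]
               for c in range(len(sequence))]
        rows.append("".join(row))
    ids = ["query"] + [f"hom{k}" for k in range(1, depth)]
    return MsaRecord(rows, ids, query_row=0)


@dataclass
class DatasetSpec:
    """Study conditions for the synthetic benchmark."""

    n_rnas: int = 40
    length_range: tuple[int, int] = (25, 45)
    pocket_fraction: float = 0.31      # mirrors the ~950:2104 class balance
    pocket_signal_strength: float = 2.0
    noise_sd: float = 0.3
    d_emb: int = 16
    msa_depth: int = 30
    conserved_fraction: float = 0.3
    asa_sd: float = 0.25
    k_primary: int = 13
    k_tertiary: int = 8
    test_fraction: float = 0.2
    val_fraction: float = 0.1
    seed: int = 0


def _simulate_one(dspec: DatasetSpec, index: int, rng: np.random.Generator):
    n = int(rng.integers(dspec.length_range[0], dspec.length_range[1] + 1))
    pocket_size = max(1, round(dspec.pocket_fraction * n))
    spec = SyntheticSpec(n_residues=n, pocket_size=pocket_size,
                         pocket_signal_strength=dspec.pocket_signal_strength,
                         noise_sd=dspec.noise_sd,
                         seed=int(rng.integers(0, 2 ** 31 - 1)))
    record, annotation, pocket = simulate_structure(spec)
    seq = record.sequence()

    n_cons = round(dspec.conserved_fraction * n)
    conserved = rng.choice(n, size=n_cons, replace=False)
    msa = simulate_msa(seq, conserved, dspec.msa_depth,
                       seed=int(rng.integers(0, 2 ** 31 - 1)))
    cons = conservation_scores(msa).scores

    embeddings = rng.normal(0.0, 1.0, size=(n, dspec.d_emb))
    asa = rng.uniform(0.0, 1.0, size=n)

    # plant the learnable signal: shift conservation and ASA of pocket
    # residues upward by `signal` column-SDs
    signal = dspec.pocket_signal_strength
    if signal != 0.0 and len(pocket):
        cons = cons.astype(float).copy()
        cons[pocket] += signal * max(cons.std(), 0.15)
        asa[pocket] += signal * max(asa.std(), dspec.asa_sd)

    coords = representative_coords(record)
    g_p = build_primary_graph(n, k=dspec.k_primary)
    g_s = build_secondary_graph(annotation)
    g_t = build_tertiary_graph(coords, k=dspec.k_tertiary)
    y = assign_labels(record)

    nfm = assemble_features(
        n, conservation=cons, embeddings=embeddings,
        one_hot=one_hot_encode(list(seq)),
        secondary=secondary_feature_vector(annotation),
        topological=topological_properties(g_t.edges, n),
        asa=asa, d_emb=dspec.d_emb)
    return MultiViewGraph(
        chain_id=f"syn{index:03d}", features=nfm,
        graphs={"P": g_p, "S": g_s, "T": g_t}, y=y,
        meta={"coords": coords, "pocket": pocket, "record": record,
              "annotation": annotation, "msa": msa})


def simulate_dataset(n_rnas: int = 40, dspec: DatasetSpec | None = None,
                     seed: int = 0):
    """Generate independent RNAs and return (train, val, test) graph lists.

    Features are standardized with z-score statistics fitted on the
    training chains only.
    """
    if n_rnas < 4:
        raise ValueError("need at least 4 RNAs")
    if dspec is None:
        dspec = DatasetSpec(n_rnas=n_rnas, seed=seed)
    rng = np.random.default_rng(seed)
    graphs = [_simulate_one(dspec, i, rng) for i in range(n_rnas)]

    rest, test = split_dataset(graphs, dspec.test_fraction, seed=seed + 1)
    train, val = split_dataset(rest, dspec.val_fraction, seed=seed + 2)

    stats = FeatureStats.fit([g.features.X for g in train])

    def _std(gs):
        return [MultiViewGraph(g.chain_id, standardize(g.features, stats),
                               g.graphs, g.y, g.meta) for g in gs]

    return _std(train), _std(val), _std(test)


def annotation_to_text(annotation: SecondaryAnnotation) -> str:
    """Serialize to the 1-based edge-list format read_secondary_annotation reads."""
    lines = [f"{i + 1}\t{j + 1}\t{kind}"
             for i, j, kind in annotation.interactions]
    lines += [f"loop\t{i + 1}" for i in np.where(annotation.loop_member)[0]]
    return "\n".join(lines) + "\n"


def msa_to_fasta(msa: MsaRecord) -> str:
    return "".join(f">{i}\n{r}\n" for i, r in zip(msa.ids, msa.rows))
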