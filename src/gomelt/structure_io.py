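"""Structures and native contact maps.

A protein is reduced to its Cα trace: one coordinate per residue, a
contiguous 1-based internal index, and an optional partition of the
sequence into β-strands.  The native contact map derived from such a
trace — all residue pairs within a distance cutoff and at least a
minimum sequence separation apart — defines both the attractive part of
the Gō Hamiltonian and the fraction-of-native-contacts order parameter
Q_N used throughout the analysis.

Point mutations are represented at contact resolution: a destabilising
substitution such as Ile→Ala removes (or down-weights) the native
contacts made by the mutated residue, mimicking the loss of side-chain
packing without rebuilding side chains.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "ProteinStructure",
    "ContactMap",
    "read_structure",
    "write_structure_pdb",
    "generate_barrel_fixture",
    "build_contact_map",
    "apply_mutation",
    "write_contact_map_tsv",
    "read_contact_map_tsv",
]


@dataclass(frozen=True)
class ProteinStructure:
    """Cα-trace representation of a protein.

    Attributes
    ----------
    residue_index : np.ndarray
        Contiguous 1-based integer indices, strictly increasing.
    residue_name : list[str]
        Three-letter residue codes, parallel to ``residue_index``.
    ca_coordinates : np.ndarray, shape (n, 3)
        Cα coordinates in Å.
    strand_ranges : dict[str, tuple[int, int]]
        Strand label (``"b1"`` .. ``"b8"``) → inclusive residue-index
        interval. May be empty for structures without an assigned
        strand partition.
    source_id : str
        Free-text provenance (PDB id, fixture parameters, ...).
    author_numbering : dict[int, str]
        Internal index → original author residue number (with insertion
        code, if any). Empty for synthetic structures.
    """

    residue_index: np.ndarray
    residue_name: list[str]
    ca_coordinates: np.ndarray
    strand_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    source_id: str = ""
    author_numbering: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.residue_index, dtype=int)
        xyz = np.asarray(self.ca_coordinates, dtype=float)
        object.__setattr__(self, "residue_index", idx)
        object.__setattr__(self, "ca_coordinates", xyz)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ValueError("ca_coordinates must have shape (n, 3)")
        if len(idx) != len(xyz) or len(idx) != len(self.residue_name):
            raise ValueError("residue_index, residue_name, ca_coordinates lengths differ")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinate")
        if len(idx) > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("residue indices must be strictly increasing")
        lo, hi = (int(idx[0]), int(idx[-1])) if len(idx) else (0, -1)
        seen: list[tuple[int, int]] = []
        for label, (a, b) in self.strand_ranges.items():
            if not (lo <= a <= b <= hi):
                raise ValueError(f"strand {label} range ({a},{b}) outside residue range")
            for a2, b2 in seen:
                if a <= b2 and a2 <= b:
                    raise ValueError(f"strand {label} overlaps another strand range")
            seen.append((a, b))

    def __len__(self) -> int:
        return len(self.residue_index)


@dataclass(frozen=True)
class ContactMap:
    """Native contact set over a Cα trace.

    ``pairs`` holds unordered residue-index pairs stored as (i, j) with
    i < j; ``r0`` the native Cα–Cα distance of each pair in Å; ``weight``
    a per-pair dimensionless multiplier of the contact well depth ε
    (1 for unperturbed native contacts).
    """

    pairs: np.ndarray          # (m, 2) int, i < j
    r0: np.ndarray             # (m,) float, Å
    weight: np.ndarray         # (m,) float
    min_seq_sep: int
    cutoff: float              # Å
    n_residues: int

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        r0 = np.asarray(self.r0, dtype=float).reshape(-1)
        w = np.asarray(self.weight, dtype=float).reshape(-1)
        if not (len(pairs) == len(r0) == len(w)):
            raise ValueError("pairs, r0, weight lengths differ")
        # canonical order: i < j, sorted lexicographically
        lo = pairs.min(axis=1)
        hi = pairs.max(axis=1)
        order = np.lexsort((hi, lo))
        pairs = np.column_stack([lo, hi])[order]
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "r0", r0[order])
        object.__setattr__(self, "weight", w[order])
        if len(pairs):
            if np.any(hi - lo < self.min_seq_sep):
                raise ValueError("pair violates min_seq_sep")
            if np.any(r0 <= 0):
                raise ValueError("r0 must be positive")
            if np.any(w < 0):
                raise ValueError("weight must be non-negative")

    def __len__(self) -> int:
        return len(self.pairs)

    def pairs_of(self, residue: int) -> np.ndarray:
        """Row indices of all pairs involving ``residue`` (1-based)."""
        return np.flatnonzero((self.pairs[:, 0] == residue) | (self.pairs[:, 1] == residue))


def read_structure(pdb_text: str, chain: str = "A") -> ProteinStructure:
    """Parse the Cα trace of one chain from PDB-format text.

    First model only; HETATM ignored; altloc blank or 'A' retained.
    Residues with no Cα are skipped with a warning; insertion codes are
    flattened into the contiguous internal numbering.
    """
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", io.StringIO(pdb_text)).get_models())
    if chain not in [c.id for c in model]:
        raise ValueError(f"chain {chain!r} not present")
    coords: list[np.ndarray] = []
    names: list[str] = []
    author: dict[int, str] = {}
    for res in model[chain]:
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue  # HETATM / water
        ca_coord = None
        for atom in res:
            if atom.get_name() != "CA":
                continue
            if atom.is_disordered():
                alts = {a.get_altloc(): a for a in atom}
                picked = alts.get("A") or alts.get(" ")
                if picked is None:
                    picked = alts[sorted(alts)[0]]
                atom = picked
            elif atom.get_altloc() not in (" ", "A"):
                continue
            if ca_coord is not None:
                raise ValueError(f"duplicate CA in residue {resseq}{icode.strip()} after altloc filtering")
            ca_coord = np.asarray(atom.get_coord(), dtype=float)
        if ca_coord is None:
            warnings.warn(f"residue {res.get_resname()} {resseq}{icode.strip()} has no CA; skipped")
            continue
        coords.append(ca_coord)
        names.append(res.get_resname())
        author[len(coords)] = f"{resseq}{icode.strip()}"
    if not coords:
        raise ValueError("no CA atoms found in the requested chain")
    n = len(coords)
    return ProteinStructure(
        residue_index=np.arange(1, n + 1),
        residue_name=names,
        ca_coordinates=np.asarray(coords),
        source_id="pdb-text",
        author_numbering=author,
    )


def write_structure_pdb(structure: ProteinStructure, chain: str = "A") -> str:
    """Render the Cα trace as minimal PDB ATOM records (CA-only, ALA-coded
    names preserved, 3-decimal coordinates)."""
    lines = []
    for k, (idx, name, xyz) in enumerate(
        zip(structure.residue_index, structure.residue_name, structure.ca_coordinates), start=1
    ):
        lines.append(
            f"ATOM  {k:5d}  CA  {name:>3s} {chain}{int(idx):4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_barrel_fixture(
    n_strands: int = 8,
    residues_per_strand: int = 8,
    radius: float = 6.5,
    rise: float = 3.8,
    seed: int = 0,
    loop_length: int = 3,
) -> ProteinStructure:
    """Idealised antiparallel β-barrel Cα trace.

    Strands run parallel to the cylinder axis, spaced evenly around a
    cylinder of the given ``radius``; successive strands alternate
    direction (antiparallel) and are joined by short loops of
    ``loop_length`` residues that bulge outward and past the barrel
    ends. Cα spacing along a strand is ``rise`` (3.8 Å default, the
    virtual bond length of an extended chain). Deterministic for fixed
    arguments; ``seed`` perturbs nothing and is accepted for interface
    uniformity (recorded in ``source_id``).
    """
    if n_strands < 3 or residues_per_strand < 3:
        raise ValueError("need n_strands >= 3 and residues_per_strand >= 3")
    # adjacent strands must sit close enough to contact (< ~6.5 Å apart)
    spacing = 2.0 * radius * math.sin(math.pi / n_strands)
    if spacing < 3.5:
        raise ValueError(
            f"radius {radius} Å too small for {n_strands} strands (inter-strand spacing {spacing:.2f} Å)"
        )
    coords: list[list[float]] = []
    strand_ranges: dict[str, tuple[int, int]] = {}
    height = (residues_per_strand - 1) * rise
    for s in range(n_strands):
        theta = 2.0 * math.pi * s / n_strands
        x, y = radius * math.cos(theta), radius * math.sin(theta)
        start = len(coords) + 1
        zs = np.arange(residues_per_strand) * rise
        if s % 2 == 1:
            zs = height - zs  # antiparallel: odd strands run downward
        for z in zs:
            coords.append([x, y, float(z)])
        strand_ranges[f"b{s + 1}"] = (start, len(coords))
        if s < n_strands - 1:
            # outward-bulging loop between this strand's last residue and
            # the next strand's first
            theta_next = 2.0 * math.pi * (s + 1) / n_strands
            z_end = float(zs[-1])
            z_dir = 1.0 if z_end > height / 2 else -1.0  # bulge past the barrel end
            for k in range(1, loop_length + 1):
                frac = k / (loop_length + 1)
                th = theta + (theta_next - theta) * frac
                bulge = radius + 2.5 * math.sin(math.pi * frac)
                z = z_end + z_dir * 2.8 * math.sin(math.pi * frac)
                coords.append([bulge * math.cos(th), bulge * math.sin(th), z])
    n = len(coords)
    return ProteinStructure(
        residue_index=np.arange(1, n + 1),
        residue_name=["ALA"] * n,
        ca_coordinates=np.asarray(coords, dtype=float),
        strand_ranges=strand_ranges,
        source_id=f"barrel-fixture(n_strands={n_strands},rps={residues_per_strand},"
        f"radius={radius},rise={rise},loops={loop_length},seed={seed})",
    )


def build_contact_map(structure: ProteinStructure, cutoff: float = 8.0, min_seq_sep: int = 3) -> ContactMap:
    """Native contact map: all residue pairs with |i−j| ≥ ``min_seq_sep``
    and Cα–Cα distance ≤ ``cutoff`` Å, with r0 set to the native distance."""
    if len(structure) == 0:
        raise ValueError("empty structure")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xyz = structure.ca_coordinates
    idx = structure.residue_index
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    ii, jj = np.triu_indices(len(xyz), k=1)
    sep_ok = np.abs(idx[jj] - idx[ii]) >= min_seq_sep
    near = d[ii, jj] <= cutoff
    keep = sep_ok & near
    pairs = np.column_stack([idx[ii[keep]], idx[jj[keep]]])
    return ContactMap(
        pairs=pairs,
        r0=d[ii[keep], jj[keep]],
        weight=np.ones(keep.sum()),
        min_seq_sep=min_seq_sep,
        cutoff=cutoff,
        n_residues=len(structure),
    )


def apply_mutation(cmap: ContactMap, residue: int, mode: str = "delete", factor: float = 0.0) -> ContactMap:
    """Contact-level surrogate of a destabilising point mutation.

    ``delete`` removes every native contact of ``residue``; ``scale``
    multiplies their weights by ``factor`` (0 ≤ factor ≤ 1). The input
    map is left unmodified.
    """
    if not (1 <= residue <= cmap.n_residues):
        raise ValueError(f"residue {residue} outside structure range 1..{cmap.n_residues}")
    rows = cmap.pairs_of(residue)
    if mode == "delete":
        keep = np.setdiff1d(np.arange(len(cmap)), rows)
        return replace(cmap, pairs=cmap.pairs[keep], r0=cmap.r0[keep], weight=cmap.weight[keep])
    if mode == "scale":
        if not (0.0 <= factor <= 1.0):
            raise ValueError("scale mode requires 0 <= factor <= 1")
        w = cmap.weight.copy()
        w[rows] *= factor
        return replace(cmap, weight=w)
    raise ValueError(f"unknown mutation mode {mode!r}")


def write_contact_map_tsv(cmap: ContactMap) -> str:
    lines = ["i\tj\tr0_angstrom\tweight"]
    for (i, j), r0, w in zip(cmap.pairs, cmap.r0, cmap.weight):
        lines.append(f"{i}\t{j}\t{r0:.6f}\t{w:.6f}")
    return "\n".join(lines) + "\n"


def read_contact_map_tsv(text: str, min_seq_sep: int, cutoff: float, n_residues: int) -> ContactMap:
    rows = [line.split("\t") for line in text.strip().splitlines()[1:]]
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        arr = arr.reshape(0, 4)
    return ContactMap(
        pairs=arr[:, :2].astype(int),
        r0=arr[:, 2],
        weight=arr[:, 3],
        min_seq_sep=min_seq_sep,
        cutoff=cutoff,
        n_residues=n_residues,
    )
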