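"""B-DNA target geometries and point-in-target queries.

Two target models are supported:

* ``high_res`` -- an atomic double helix built by stacking a packaged
  one-base-pair template (idealized A-T pair, both strands) with a rigid
  rotation (twist) and translation (rise) per step.  Each atom carries the
  standard van der Waals-style radius of its element and maps to a
  ``(bp_index, strand, moiety)`` key, where moiety is ``base`` or
  ``sugar_phosphate``.
* ``simple`` -- two interleaved helical stacks of semi-cylindrical
  (half-annulus) backbone segments, one per strand per base pair, following
  the classic thin U-shaped backbone representation.

All coordinates are in nm; the helix axis is +z with base pair 1 centred at
``z = rise/2``.  PDB files can be read for scenario setup; their Angstrom
coordinates are converted to nm at the reader boundary.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: atomic radii used for the target volumes, nm
ATOMIC_RADII_NM = {"H": 0.120, "C": 0.170, "N": 0.150, "O": 0.140, "P": 0.190}

STRANDS = ("labeled", "nonlabeled")
MOIETIES = ("base", "sugar_phosphate")

#: atom names that belong to the sugar-phosphate backbone in PDB residues
_BACKBONE_PDB_NAMES = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}

_DNA_RESNAMES = {"DA", "DT", "DG", "DC", "DU", "DI", "A", "T", "G", "C", "U", "I"}


class MoietyKey(NamedTuple):
    """Unique address of one damage-scoring volume."""

    bp_index: int
    strand: str
    moiety: str


@dataclass(frozen=True)
class Atom:
    """One target atom of the high-resolution model."""

    element: str
    position: np.ndarray          # (3,) nm
    radius: float                 # nm
    bp_index: int
    strand: str
    moiety: str
    base: str = ""                # base identity for base-moiety atoms
    name: str = ""

    @property
    def key(self) -> MoietyKey:
        return MoietyKey(self.bp_index, self.strand, self.moiety)


@dataclass(frozen=True)
class SemiCylinderSegment:
    """Half-annulus backbone segment of the simple model."""

    bp_index: int
    strand: str
    z_center: float               # nm
    thickness: float              # nm, equals the rise
    inner_radius: float           # nm
    outer_radius: float           # nm
    phase_angle: float            # degrees, start of the 180-degree arc

    @property
    def key(self) -> MoietyKey:
        return MoietyKey(self.bp_index, self.strand, "sugar_phosphate")


@dataclass
class BoundingCylinder:
    diameter: float               # nm
    height: float                 # nm
    z0: float = 0.0               # nm, lower face; axis is +z through origin

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        inside = r2 <= (self.diameter / 2.0) ** 2
        inside &= (pts[:, 2] >= self.z0) & (pts[:, 2] <= self.z0 + self.height)
        return inside


@dataclass
class DNAModel:
    """A B-DNA target model (atomic or semi-cylindrical)."""

    kind: str                     # "high_res" | "simple"
    n_bp: int
    rise: float
    twist: float
    bounding_cylinder: BoundingCylinder
    atoms: list[Atom] = field(default_factory=list)
    segments: list[SemiCylinderSegment] = field(default_factory=list)

    # vectorized mirrors of the atom list, filled on demand
    _pos: np.ndarray | None = field(default=None, repr=False)
    _radii: np.ndarray | None = field(default=None, repr=False)
    _tree: cKDTree | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.kind not in ("high_res", "simple"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def n_nucleotides(self) -> int:
        return 2 * self.n_bp

    def atom_arrays(self):
        """(positions, radii, kd-tree) over all atoms, built lazily."""
        if self._pos is None:
            self._pos = np.array([a.position for a in self.atoms], dtype=float)
            self._radii = np.array([a.radius for a in self.atoms], dtype=float)
            self._tree = cKDTree(self._pos)
        return self._pos, self._radii, self._tree

    def source_bp_from_z(self, z: float) -> int:
        """Base-pair slab index nearest to an axial coordinate."""
        bp = int(math.floor(z / self.rise)) + 1
        return min(max(bp, 1), self.n_bp)


def load_bp_template() -> pd.DataFrame:
    """Packaged one-base-pair atom table (element, position, strand, moiety)."""
    with resources.files("nanodna.data").joinpath("bp_template.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def load_bp_template_bonds() -> pd.DataFrame:
    with resources.files("nanodna.data").joinpath("bp_template_bonds.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def _rotz(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_high_res_bdna(
    n_bp: int,
    rise: float = 0.34,
    twist: float = 36.0,
    template: pd.DataFrame | None = None,
    bounding_diameter: float = 2.4,
    bounding_height: float | None = None,
) -> DNAModel:
    """Stack the base-pair template into an atomic double helix.

    Base pair ``i`` (1-based) is the template rotated by ``(i-1)*twist``
    about +z and translated to ``z = (i-0.5)*rise``.  ``bounding_height``
    defaults to the stack height (pass 14.3 with ``n_bp=41`` to reproduce
    the canonical bounding cylinder); the cylinder is expanded if needed so
    that it always contains every atom.
    """
    if n_bp < 1:
        raise ValueError(f"n_bp must be >= 1, got {n_bp}")
    if template is None:
        template = load_bp_template()
    unknown = set(template["element"]) - set(ATOMIC_RADII_NM)
    if unknown:
        raise ValueError(f"unknown element(s) in template: {sorted(unknown)}")

    tpos = template[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    base_col = template["base"].fillna("") if "base" in template else [""] * len(template)
    name_col = template["name"] if "name" in template else [""] * len(template)

    atoms: list[Atom] = []
    for i in range(1, n_bp + 1):
        rot = _rotz((i - 1) * twist)
        shift = np.array([0.0, 0.0, (i - 0.5) * rise])
        pos = tpos @ rot.T + shift
        for j, row in enumerate(template.itertuples(index=False)):
            atoms.append(
                Atom(
                    element=row.element,
                    position=pos[j],
                    radius=ATOMIC_RADII_NM[row.element],
                    bp_index=i,
                    strand=row.strand,
                    moiety=row.moiety,
                    base=str(base_col.iloc[j]) if hasattr(base_col, "iloc") else "",
                    name=str(name_col.iloc[j]) if hasattr(name_col, "iloc") else "",
                )
            )

    allpos = np.array([a.position for a in atoms])
    allrad = np.array([a.radius for a in atoms])
    model = DNAModel(
        kind="high_res", n_bp=n_bp, rise=rise, twist=twist,
        bounding_cylinder=_fit_cylinder(allpos, allrad, n_bp * rise,
                                        bounding_diameter, bounding_height),
        atoms=atoms,
    )
    return model


def _fit_cylinder(positions, radii, stack_height, diameter, height):
    """Bounding cylinder with requested dimensions, grown to contain all
    target volumes."""
    r_needed = float(np.max(np.hypot(positions[:, 0], positions[:, 1]) + radii))
    diameter = max(diameter, 2.0 * r_needed)
    z_lo = min(0.0, float(np.min(positions[:, 2] - radii)))
    z_hi = max(stack_height, float(np.max(positions[:, 2] + radii)))
    if height is None:
        return BoundingCylinder(diameter=diameter, height=z_hi - z_lo, z0=z_lo)
    # centre the requested cylinder on the stack, then grow to fit
    z0 = (stack_height - height) / 2.0
    z0 = min(z0, z_lo)
    z1 = max(z0 + height, z_hi)
    return BoundingCylinder(diameter=diameter, height=z1 - z0, z0=z0)


def build_simple_bdna(
    n_bp: int,
    rise: float = 0.34,
    twist: float = 36.0,
    outer_diameter: float = 2.3,
    inner_diameter: float = 1.0,
    bounding_height: float | None = None,
) -> DNAModel:
    """Two interleaved helical stacks of thin U-shaped backbone segments.

    Each strand contributes one 180-degree half-annulus per base pair; the
    two strands are offset by 180 degrees and each advances by ``twist``
    per step.  Bases are not represented in this model.
    """
    if n_bp < 1:
        raise ValueError(f"n_bp must be >= 1, got {n_bp}")
    if outer_diameter <= 0:
        raise ValueError(f"outer_diameter must be > 0, got {outer_diameter}")
    if not 0 <= inner_diameter < outer_diameter:
        raise ValueError("inner_diameter must satisfy 0 <= inner < outer")

    segments = []
    for i in range(1, n_bp + 1):
        for si, strand in enumerate(STRANDS):
            segments.append(
                SemiCylinderSegment(
                    bp_index=i,
                    strand=strand,
                    z_center=(i - 0.5) * rise,
                    thickness=rise,
                    inner_radius=inner_diameter / 2.0,
                    outer_radius=outer_diameter / 2.0,
                    phase_angle=((i - 1) * twist + 180.0 * si) % 360.0,
                )
            )
    stack_height = n_bp * rise
    if bounding_height is None:
        cyl = BoundingCylinder(diameter=outer_diameter, height=stack_height, z0=0.0)
    else:
        height = max(bounding_height, stack_height)
        cyl = BoundingCylinder(diameter=outer_diameter, height=height,
                               z0=(stack_height - height) / 2.0)
    return DNAModel(kind="simple", n_bp=n_bp, rise=rise, twist=twist,
                    bounding_cylinder=cyl, segments=segments)


# ---------------------------------------------------------------------------
# hit location


@dataclass(frozen=True)
class HitResult:
    """Outcome of a point query against a model.

    region is ``target`` (inside a DNA volume), ``cylinder`` (inside the
    bounding cylinder but outside every target volume; ``key`` then holds
    the nearest moiety), or ``outside``.
    """

    region: str                   # "target" | "cylinder" | "outside"
    key: MoietyKey | None = None


def locate_hit(point: Sequence[float], model: DNAModel) -> HitResult:
    """Locate a single point; see :func:`locate_hits` for the batch form."""
    return locate_hits(np.atleast_2d(np.asarray(point, dtype=float)), model)[0]


def locate_hits(points: np.ndarray, model: DNAModel) -> list[HitResult]:
    """Classify points against the target volumes and bounding cylinder.

    A point inside one or more atoms resolves to the atom with the smallest
    distance to centre; ties go to the lower bp_index, then to the labeled
    strand.  Points inside the bounding cylinder only are reported with the
    nearest moiety attached.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if model.kind == "simple":
        return _locate_hits_simple(points, model)

    pos, radii, tree = model.atom_arrays()
    rmax = float(radii.max())
    in_cyl = model.bounding_cylinder.contains(points)
    neighborhoods = tree.query_ball_point(points, r=rmax)
    results: list[HitResult] = []
    strand_rank = {"labeled": 0, "nonlabeled": 1}
    for p, cyl_ok, idxs in zip(points, in_cyl, neighborhoods):
        best = None
        for j in idxs:
            d = float(np.linalg.norm(p - pos[j]))
            if d <= radii[j]:
                a = model.atoms[j]
                cand = (d, a.bp_index, strand_rank[a.strand], j)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            results.append(HitResult("target", model.atoms[best[3]].key))
        elif cyl_ok:
            _, j = tree.query(p)
            results.append(HitResult("cylinder", model.atoms[int(j)].key))
        else:
            results.append(HitResult("outside"))
    return results


def _locate_hits_simple(points: np.ndarray, model: DNAModel) -> list[HitResult]:
    results = []
    r_in = model.segments[0].inner_radius
    r_out = model.segments[0].outer_radius
    in_cyl = model.bounding_cylinder.contains(points)
    for p, cyl_ok in zip(points, in_cyl):
        bp = int(math.floor(p[2] / model.rise)) + 1
        hit = None
        if 1 <= bp <= model.n_bp:
            r = math.hypot(p[0], p[1])
            if r_in <= r <= r_out:
                az = math.degrees(math.atan2(p[1], p[0])) % 360.0
                for si, strand in enumerate(STRANDS):
                    phase = ((bp - 1) * model.twist + 180.0 * si) % 360.0
                    if (az - phase) % 360.0 < 180.0:
                        hit = MoietyKey(bp, strand, "sugar_phosphate")
                        break
        if hit is not None:
            results.append(HitResult("target", hit))
        elif cyl_ok:
            bp = model.source_bp_from_z(p[2])
            az = math.degrees(math.atan2(p[1], p[0])) % 360.0
            phase = ((bp - 1) * model.twist) % 360.0
            strand = STRANDS[0] if (az - phase) % 360.0 < 180.0 else STRANDS[1]
            results.append(HitResult("cylinder", MoietyKey(bp, strand, "sugar_phosphate")))
        else:
            results.append(HitResult("outside"))
    return results


def moiety_centroid(model: DNAModel, key: MoietyKey) -> np.ndarray:
    """Unweighted centroid of the atoms (or segment arc) of one moiety."""
    if model.kind == "high_res":
        pts = [a.position for a in model.atoms if a.key == key]
        if not pts:
            raise KeyError(f"no atoms for {key}")
        return np.mean(pts, axis=0)
    for seg in model.segments:
        if seg.key == key:
            mid = math.radians(seg.phase_angle + 90.0)
            r = 0.5 * (seg.inner_radius + seg.outer_radius)
            return np.array([r * math.cos(mid), r * math.sin(mid), seg.z_center])
    raise KeyError(f"no segment for {key}")


# ---------------------------------------------------------------------------
# PDB I/O


@dataclass
class PDBAtoms:
    """Atom collection read from a PDB file, in nm.

    DNA-chain atoms carry MoietyKey-compatible fields (bp_index from the
    residue number, strand from the chain order, moiety from the atom-name
    convention: primed names and phosphate names are backbone, ring names
    are base).  Non-DNA residues are kept with moiety ``""``.
    """

    atoms: list[Atom]
    n_skipped: int = 0

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


def read_pdb(path) -> PDBAtoms:
    """Read ATOM/HETATM records of a standard PDB file (coordinates in
    Angstrom, converted to nm)."""
    from Bio.PDB import PDBParser

    with open(path) as fh:
        text = fh.read()
    _validate_pdb_text(text)
    if not text.strip():
        return PDBAtoms(atoms=[])

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("pdb", io.StringIO(text))
    atoms: list[Atom] = []
    n_skipped = 0
    chain_order: dict[str, int] = {}
    for model in structure:
        for chain in model:
            if chain.id not in chain_order:
                chain_order[chain.id] = len(chain_order)
            for residue in chain:
                resname = residue.get_resname().strip()
                is_dna = resname in _DNA_RESNAMES
                for atom in residue:
                    element = (atom.element or "").strip().capitalize()
                    if element not in ATOMIC_RADII_NM:
                        warnings.warn(
                            f"skipping atom {atom.get_name()} with unknown element "
                            f"{element!r}", stacklevel=2)
                        n_skipped += 1
                        continue
                    name = atom.get_name().strip()
                    if is_dna:
                        backbone = ("'" in name) or (name in _BACKBONE_PDB_NAMES)
                        moiety = "sugar_phosphate" if backbone else "base"
                    else:
                        moiety = ""
                    atoms.append(
                        Atom(
                            element=element,
                            position=atom.coord.astype(float) / 10.0,  # A -> nm
                            radius=ATOMIC_RADII_NM[element],
                            bp_index=residue.id[1],
                            strand=STRANDS[chain_order[chain.id] % 2],
                            moiety=moiety,
                            base="",
                            name=name,
                        )
                    )
        break  # first NMR model only
    return PDBAtoms(atoms=atoms, n_skipped=n_skipped)


def _validate_pdb_text(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(
                    f"unparseable coordinate field in PDB record at line {lineno}"
                ) from None


def write_pdb(model: DNAModel, path) -> None:
    """Write a high-resolution model as a PDB file (nm -> Angstrom)."""
    if model.kind != "high_res":
        raise ValueError("only high_res models can be written as PDB")
    chain_ids = {"labeled": "A", "nonlabeled": "B"}
    base_names = {"Thymine": "DT", "Adenine": "DA", "Guanine": "DG",
                  "Cytosine": "DC"}
    resnames: dict[tuple, str] = {}
    for a in model.atoms:
        if a.base in base_names:
            resnames[(a.strand, a.bp_index)] = base_names[a.base]
    with open(path, "w") as fh:
        serial = 1
        for a in model.atoms:
            resname = resnames.get((a.strand, a.bp_index), "DN")
            x, y, z = a.position * 10.0
            name = (a.name.split(".")[-1] if a.name else a.element)[:4]
            fh.write(
                f"ATOM  {serial:5d} {name:<4s}{resname:>4s} "
                f"{chain_ids[a.strand]}{a.bp_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}\n"
            )
            serial += 1
        fh.write("END\n")
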