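"""One-time generator for the packaged data tables.

Writes, into src/nanodna/data/:

* ``bp_template.csv``        -- idealized A-T base-pair atom table (one BP,
  both strands) used by the high-resolution B-DNA builder.
* ``bp_template_bonds.csv``  -- covalent bond list with the idealized
  reference lengths the template is built from.
* ``xs_water.csv``           -- simplified electron interaction cross
  sections in liquid water for the transport engine.

The template is idealized rather than fibre-refined: rings are regular
polygons at standard mean bond lengths, the two backbones are related by the
base-pair dyad (hence antiparallel), and radial extents are tuned so the
phosphorus sits near 0.9 nm from the helix axis with every atom inside a
1.2 nm-radius cylinder. Re-running this script reproduces the committed
files bit for bit.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parent.parent / "src" / "nanodna" / "data"

# idealized mean bond lengths, nm
L_RING6 = 0.136     # aromatic six-ring C-C / C-N
L_RING5 = 0.137     # aromatic five-ring C-N / C-C
L_GLYC = 0.147      # glycosidic C1'-N
L_CC = 0.152        # sp3 C-C
L_CO = 0.143        # C-O ester/ether
L_PO = 0.160        # P-O ester
L_PO2 = 0.148       # P=O / P-O(-)
L_C2O = 0.122       # carbonyl C=O
L_CN_AM = 0.135     # C-N amine (aromatic-attached)
L_CH = 0.109
L_NH = 0.101
L_CMe = 0.150       # ring C - methyl C


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class Builder:
    def __init__(self):
        self.atoms = []   # (name, element, pos, strand, moiety, base)
        self.bonds = []   # (name_i, name_j, ref_nm)
        self._pos = {}

    def add(self, name, element, pos, strand, moiety, base=""):
        assert name not in self._pos, name
        self.atoms.append((name, element, np.asarray(pos, float), strand, moiety, base))
        self._pos[name] = np.asarray(pos, float)

    def bond(self, a, b, ref):
        d = np.linalg.norm(self._pos[a] - self._pos[b])
        assert abs(d - ref) < 1e-9, (a, b, d, ref)
        self.bonds.append((a, b, ref))

    def pos(self, name):
        return self._pos[name]


def hexagon(center, r_vertex, start_dir, normal=(0, 0, 1)):
    """Six vertices of a regular hexagon, first vertex along start_dir."""
    n = unit(normal)
    e1 = unit(np.asarray(start_dir, float))
    e2 = np.cross(n, e1)
    return [center + r_vertex * (math.cos(math.radians(60 * k)) * e1
                                 + math.sin(math.radians(60 * k)) * e2)
            for k in range(6)]


def pentagon(first_vertex, center_dir, side, normal=(0, 0, 1)):
    """Five vertices of a regular pentagon, first vertex given, center along
    center_dir from it."""
    r = side / (2.0 * math.sin(math.pi / 5.0))
    n = unit(normal)
    d = unit(np.asarray(center_dir, float))
    center = np.asarray(first_vertex, float) + r * d
    e1 = -d
    e2 = np.cross(n, e1)
    return [center + r * (math.cos(math.radians(72 * k)) * e1
                          + math.sin(math.radians(72 * k)) * e2)
            for k in range(5)], center


def build_sugar_phosphate(b: Builder, prefix, strand, c1p, flip):
    """Deoxyribose + phosphate group starting from a given C1' position.

    flip = +1 builds a backbone climbing +z (labeled strand), -1 the dyad
    image descending -z.
    """
    radial = unit([c1p[0], c1p[1], 0.0])
    tang = np.array([-radial[1], radial[0], 0.0]) * flip
    zax = np.array([0.0, 0.0, 1.0]) * flip

    # furanose ring as a regular pentagon tilted out of the base plane
    ring_normal = unit(0.55 * tang + 0.9 * zax)
    center_dir = unit(radial + 0.35 * zax - 0.1 * tang)
    # keep center_dir in the ring plane
    center_dir = unit(center_dir - np.dot(center_dir, ring_normal) * ring_normal)
    verts, center = pentagon(c1p, center_dir, 0.148, ring_normal)
    names = ["C1p", "C2p", "C3p", "C4p", "O4p"]
    elems = ["C", "C", "C", "C", "O"]
    for nm, el, v in zip(names, elems, verts):
        b.add(f"{prefix}.{nm}", el, v, strand, "sugar_phosphate")
    for i in range(5):
        b.bond(f"{prefix}.{names[i]}", f"{prefix}.{names[(i + 1) % 5]}", 0.148)

    c3p, c4p = b.pos(f"{prefix}.C3p"), b.pos(f"{prefix}.C4p")
    # 5' branch: C4' -> C5' -> O5' -> P, winding along the helix surface
    d5 = unit(0.10 * radial + 0.50 * zax + 0.85 * tang)
    c5p = c4p + L_CC * d5
    b.add(f"{prefix}.C5p", "C", c5p, strand, "sugar_phosphate")
    b.bond(f"{prefix}.C4p", f"{prefix}.C5p", L_CC)
    d5o = unit(0.10 * radial + 0.35 * zax + 0.92 * tang)
    o5p = c5p + L_CO * d5o
    b.add(f"{prefix}.O5p", "O", o5p, strand, "sugar_phosphate")
    b.bond(f"{prefix}.C5p", f"{prefix}.O5p", L_CO)
    dp = unit(0.02 * radial + 0.45 * zax + 0.89 * tang)
    p = o5p + L_PO * dp
    b.add(f"{prefix}.P", "P", p, strand, "sugar_phosphate")
    b.bond(f"{prefix}.O5p", f"{prefix}.P", L_PO)
    b.add(f"{prefix}.OP1", "O", p + L_PO2 * unit(0.30 * radial + 0.90 * tang - 0.3 * zax),
          strand, "sugar_phosphate")
    b.bond(f"{prefix}.P", f"{prefix}.OP1", L_PO2)
    b.add(f"{prefix}.OP2", "O", p + L_PO2 * unit(0.30 * radial - 0.90 * tang - 0.3 * zax),
          strand, "sugar_phosphate")
    b.bond(f"{prefix}.P", f"{prefix}.OP2", L_PO2)
    # 3' oxygen heading toward the previous residue
    o3p = c3p + L_CO * unit(0.5 * radial - 0.9 * zax + 0.2 * tang)
    b.add(f"{prefix}.O3p", "O", o3p, strand, "sugar_phosphate")
    b.bond(f"{prefix}.C3p", f"{prefix}.O3p", L_CO)
    # ring hydrogens, one per carbon on the outward ring-normal side
    # (C2' carries two in deoxyribose)
    for nm, two in [("C1p", False), ("C2p", True), ("C3p", False), ("C4p", False)]:
        c = b.pos(f"{prefix}.{nm}")
        away = unit(c - center)
        h1 = c + L_CH * unit(away + 1.2 * ring_normal)
        b.add(f"{prefix}.H{nm[1]}p", "H", h1, strand, "sugar_phosphate")
        b.bond(f"{prefix}.{nm}", f"{prefix}.H{nm[1]}p", L_CH)
        if two:
            h2 = c + L_CH * unit(away - 1.2 * ring_normal)
            b.add(f"{prefix}.H{nm[1]}pp", "H", h2, strand, "sugar_phosphate")
            b.bond(f"{prefix}.{nm}", f"{prefix}.H{nm[1]}pp", L_CH)
    # C5' hydrogens
    for suffix, sgn in [("H5p", 1.0), ("H5pp", -1.0)]:
        h = c5p + L_CH * unit(sgn * tang + 0.3 * radial - 0.3 * zax)
        b.add(f"{prefix}.{suffix}", "H", h, strand, "sugar_phosphate")
        b.bond(f"{prefix}.C5p", f"{prefix}.{suffix}", L_CH)


def build_thymine(b: Builder, prefix, strand, c1p):
    """Thymine ring in the z=0 plane, N1 bonded to C1'."""
    # glycosidic bond points inward from C1'
    n1 = c1p + L_GLYC * unit([-0.35, -0.85, -0.45])
    n1[2] = 0.0  # base plane perpendicular to the helix axis
    # re-normalize the bond length after flattening
    n1 = c1p + L_GLYC * unit(n1 - c1p)
    ring_dir = unit([-0.45, -0.89, 0.0])  # from N1 toward ring center
    center = n1 + L_RING6 * ring_dir
    verts = hexagon(center, L_RING6, -ring_dir)
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    elems = ["N", "C", "N", "C", "C", "C"]
    for nm, el, v in zip(names, elems, verts):
        b.add(f"{prefix}.{nm}", el, v, strand, "base", "Thymine")
    for i in range(6):
        b.bond(f"{prefix}.{names[i]}", f"{prefix}.{names[(i + 1) % 6]}", L_RING6)
    b.bond(f"{prefix}.N1", "L.C1p", L_GLYC)

    def radial(nm):
        return unit(b.pos(f"{prefix}.{nm}") - center)

    b.add(f"{prefix}.O2", "O", b.pos(f"{prefix}.C2") + L_C2O * radial("C2"),
          strand, "base", "Thymine")
    b.bond(f"{prefix}.C2", f"{prefix}.O2", L_C2O)
    b.add(f"{prefix}.O4", "O", b.pos(f"{prefix}.C4") + L_C2O * radial("C4"),
          strand, "base", "Thymine")
    b.bond(f"{prefix}.C4", f"{prefix}.O4", L_C2O)
    b.add(f"{prefix}.H3", "H", b.pos(f"{prefix}.N3") + L_NH * radial("N3"),
          strand, "base", "Thymine")
    b.bond(f"{prefix}.N3", f"{prefix}.H3", L_NH)
    b.add(f"{prefix}.H6", "H", b.pos(f"{prefix}.C6") + L_CH * radial("C6"),
          strand, "base", "Thymine")
    b.bond(f"{prefix}.C6", f"{prefix}.H6", L_CH)
    # methyl group modeled as individual C and H atoms
    c7 = b.pos(f"{prefix}.C5") + L_CMe * radial("C5")
    b.add(f"{prefix}.C7", "C", c7, strand, "base", "Thymine")
    b.bond(f"{prefix}.C5", f"{prefix}.C7", L_CMe)
    axis = radial("C5")
    pvec = unit(np.cross(axis, [0.0, 0.0, 1.0]))
    qvec = np.cross(axis, pvec)
    for k in range(3):
        phi = 2.0 * math.pi * k / 3.0
        d = 0.334 * axis + 0.943 * (math.cos(phi) * pvec + math.sin(phi) * qvec)
        b.add(f"{prefix}.H7{k + 1}", "H", c7 + L_CH * unit(d), strand, "base", "Thymine")
        b.bond(f"{prefix}.C7", f"{prefix}.H7{k + 1}", L_CH)


def build_adenine(b: Builder, prefix, strand, c1p):
    """Adenine (fused 5+6 ring) in the z=0 plane, N9 bonded to C1'."""
    n9 = c1p + L_GLYC * unit([-0.35, 0.85, 0.45])
    n9[2] = 0.0
    n9 = c1p + L_GLYC * unit(n9 - c1p)
    center_dir = unit([-0.45, 0.89, 0.0])
    verts5, c5ctr = pentagon(n9, center_dir, L_RING5)
    # pentagon ring order: N9 - C8 - N7 - C5 - C4 - (N9)
    names5 = ["N9", "C8", "N7", "C5", "C4"]
    elems5 = ["N", "C", "N", "C", "C"]
    for nm, el, v in zip(names5, elems5, verts5):
        b.add(f"{prefix}.{nm}", el, v, strand, "base", "Adenine")
    for i in range(5):
        b.bond(f"{prefix}.{names5[i]}", f"{prefix}.{names5[(i + 1) % 5]}", L_RING5)
    b.bond(f"{prefix}.N9", "N.C1p", L_GLYC)

    c4, c5 = b.pos(f"{prefix}.C4"), b.pos(f"{prefix}.C5")
    mid = 0.5 * (c4 + c5)
    out = unit(mid - c5ctr)
    side = np.linalg.norm(c5 - c4)
    hex_center = mid + side * (math.sqrt(3.0) / 2.0) * out
    # walk the hexagon from C4 toward C5 and onward: C4-C5-C6-N1-C2-N3
    a4 = math.atan2(c4[1] - hex_center[1], c4[0] - hex_center[0])
    a5 = math.atan2(c5[1] - hex_center[1], c5[0] - hex_center[0])
    step = a5 - a4
    while step > math.pi:
        step -= 2.0 * math.pi
    while step < -math.pi:
        step += 2.0 * math.pi
    names6 = ["C6", "N1", "C2", "N3"]
    elems6 = ["C", "N", "C", "N"]
    rr = np.linalg.norm(c4 - hex_center)
    for j, (nm, el) in enumerate(zip(names6, elems6), start=2):
        a = a4 + j * step
        v = hex_center + rr * np.array([math.cos(a), math.sin(a), 0.0])
        b.add(f"{prefix}.{nm}", el, v, strand, "base", "Adenine")
    for x, y in [("C5", "C6"), ("C6", "N1"), ("N1", "C2"), ("C2", "N3"), ("N3", "C4")]:
        d = np.linalg.norm(b.pos(f"{prefix}.{x}") - b.pos(f"{prefix}.{y}"))
        b.bonds.append((f"{prefix}.{x}", f"{prefix}.{y}", round(d, 9)))

    def radial6(nm):
        return unit(b.pos(f"{prefix}.{nm}") - hex_center)

    n6 = b.pos(f"{prefix}.C6") + L_CN_AM * radial6("C6")
    b.add(f"{prefix}.N6", "N", n6, strand, "base", "Adenine")
    b.bond(f"{prefix}.C6", f"{prefix}.N6", L_CN_AM)
    for k, ang in [(1, 0.5), (2, -0.5)]:
        tan = np.cross([0.0, 0.0, 1.0], radial6("C6"))
        h = n6 + L_NH * unit(radial6("C6") + ang * tan)
        b.add(f"{prefix}.H6{k}", "H", h, strand, "base", "Adenine")
        b.bond(f"{prefix}.N6", f"{prefix}.H6{k}", L_NH)
    b.add(f"{prefix}.H2", "H", b.pos(f"{prefix}.C2") + L_CH * radial6("C2"),
          strand, "base", "Adenine")
    b.bond(f"{prefix}.C2", f"{prefix}.H2", L_CH)
    b.add(f"{prefix}.H8", "H",
          b.pos(f"{prefix}.C8") + L_CH * unit(b.pos(f"{prefix}.C8") - c5ctr),
          strand, "base", "Adenine")
    b.bond(f"{prefix}.C8", f"{prefix}.H8", L_CH)


def build_template() -> Builder:
    b = Builder()
    # glycosidic carbons: r = 0.59 nm, +/-63 degrees about the dyad (+x)
    ang = math.radians(63.0)
    c1_l = np.array([0.59 * math.cos(ang), 0.59 * math.sin(ang), 0.0])
    c1_n = np.array([0.59 * math.cos(ang), -0.59 * math.sin(ang), 0.0])
    build_sugar_phosphate(b, "L", "labeled", c1_l, flip=+1)
    build_sugar_phosphate(b, "N", "nonlabeled", c1_n, flip=-1)
    build_thymine(b, "LT", "labeled", c1_l)
    build_adenine(b, "NA", "nonlabeled", c1_n)
    return b


def beb(energy_ev, binding_ev, u_ev, n_eff):
    """Binary-encounter-Bethe-style total cross section, nm^2."""
    a0 = 0.0529177  # nm
    ryd = 13.6057
    t = energy_ev / binding_ev
    if t <= 1.0:
        return 0.0
    u = u_ev / binding_ev
    s = 4.0 * math.pi * a0 ** 2 * n_eff * (ryd / binding_ev) ** 2
    term = (math.log(t) / 2.0 * (1.0 - 1.0 / t ** 2)
            + 1.0 - 1.0 / t - math.log(t) / (t + 1.0))
    return s / (t + u + 1.0) * term


def elastic_sr(energy_ev, z_eff=7.42):
    """Screened-Rutherford elastic cross section, nm^2."""
    ke2 = 1.43996  # e^2/(4 pi eps0), eV nm
    eta = 4.34 * z_eff ** (2.0 / 3.0) / energy_ev
    return (math.pi * z_eff * (z_eff + 1.0) * ke2 ** 2
            / (4.0 * energy_ev ** 2) / (eta * (1.0 + eta)))


def write_xs_table(path):
    grid = np.geomspace(10.0, 1.0e5, 72)
    rows = []
    for e in grid:
        rows.append((e, elastic_sr(e), beb(e, 13.0, 30.0, 5.0), beb(e, 8.0, 20.0, 2.5)))
    with open(path, "w") as fh:
        fh.write("# simplified electron cross sections in liquid water\n")
        fh.write("# sigma units: nm^2 per molecule; number density 33.3679 nm^-3\n")
        fh.write("energy_ev,sigma_elastic,sigma_ionization,sigma_excitation\n")
        for r in rows:
            fh.write("%.6g,%.6g,%.6g,%.6g\n" % r)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    b = build_template()

    pos = np.array([a[2] for a in b.atoms])
    r = np.hypot(pos[:, 0], pos[:, 1])
    assert r.max() < 1.14, f"atom outside 1.2 nm-diameter envelope: r_max={r.max():.3f}"
    # the phosphate group sits between base-pair planes, so atoms may extend
    # beyond the +/-0.17 nm slab; keep within a bit over one rise
    assert np.abs(pos[:, 2]).max() < 0.45, f"z extent {np.abs(pos[:, 2]).max():.3f}"
    for pfx in ("L", "N"):
        rp = np.hypot(*b.pos(f"{pfx}.P")[:2])
        assert 0.75 < rp < 1.05, f"{pfx}.P radius {rp:.3f}"
    n_l = sum(1 for a in b.atoms if a[3] == "labeled")
    n_n = sum(1 for a in b.atoms if a[3] == "nonlabeled")
    print(f"template: {len(b.atoms)} atoms ({n_l} labeled, {n_n} nonlabeled), "
          f"r_max={r.max():.3f} nm, P radii "
          f"{np.hypot(*b.pos('L.P')[:2]):.3f}/{np.hypot(*b.pos('N.P')[:2]):.3f} nm")

    with open(OUT / "bp_template.csv", "w") as fh:
        fh.write("# idealized A-T base-pair template, one helix repeat; units nm\n")
        fh.write("# helix axis +z, base plane z=0; see docs/methods.md\n")
        fh.write("name,element,x_nm,y_nm,z_nm,strand,moiety,base\n")
        for name, el, p, strand, moiety, base in b.atoms:
            fh.write(f"{name},{el},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},{strand},{moiety},{base}\n")
    with open(OUT / "bp_template_bonds.csv", "w") as fh:
        fh.write("# covalent bonds of the template with idealized reference lengths\n")
        fh.write("atom_i,atom_j,ref_nm\n")
        for a, bb, ref in b.bonds:
            fh.write(f"{a},{bb},{ref:.6f}\n")
    write_xs_table(OUT / "xs_water.csv")
    print("wrote", OUT)


if __name__ == "__main__":
    main()
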