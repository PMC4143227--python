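"""Crystallographic shell extraction around a heme iron.

Parses PDB structures, collects the non-hydrogen neighbors of the Fe
absorber, groups them into element/distance-window coordination shells,
and flags near-collinear Fe-A-B arrangements whose EXAFS contribution
would carry strong multiple scattering (such paths are excluded from
single-scattering shell fits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .shellmodel import Shell, ShellModel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AtomRecord:
    element: str
    name: str
    resname: str
    resseq: int
    chain: str
    xyz: tuple

    @property
    def coords(self):
        return np.asarray(self.xyz, dtype=float)


@dataclass
class StructureNeighbors:
    """Fe-centered neighbor list, sorted by distance, within rmax."""

    center: AtomRecord
    neighbors: list  # (AtomRecord, distance)
    rmax: float

    def distances(self):
        return np.array([d for _, d in self.neighbors])


def parse_structure(pdb_text):
    """ATOM/HETATM records -> list of AtomRecord (first model only).

    Alternate locations are resolved to the highest-occupancy conformer;
    malformed records are skipped by the underlying parser with a logged
    warning.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    st.remove_alternative_conformations()  # keeps highest occupancy
    atoms = []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                el = atom.element.name
                if not el:
                    log.warning(
                        "skipping atom %s/%s with unknown element",
                        residue.name,
                        atom.name,
                    )
                    continue
                atoms.append(
                    AtomRecord(
                        element=el,
                        name=atom.name,
                        resname=residue.name,
                        resseq=residue.seqid.num,
                        chain=chain.name,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
    return atoms


def _select_fe(atoms, chain=None, resseq=None):
    fes = [
        a
        for a in atoms
        if a.element.upper() == "FE"
        and (chain is None or a.chain == chain)
        and (resseq is None or a.resseq == resseq)
    ]
    if not fes:
        raise ValueError("no Fe atom found (after selectors)")
    if len(fes) > 1:
        raise ValueError(
            f"{len(fes)} Fe atoms found; disambiguate with chain/resseq "
            f"selectors: {[(a.chain, a.resseq) for a in fes]}"
        )
    return fes[0]


def fe_neighbors(atoms, rmax=4.5, chain=None, resseq=None):
    """All non-hydrogen atoms within ``rmax`` (A) of the (unique) Fe."""
    fe = _select_fe(atoms, chain, resseq)
    out = []
    for a in atoms:
        if a is fe or a.element in ("H", "D"):
            continue
        d = float(np.linalg.norm(a.coords - fe.coords))
        if d <= rmax:
            out.append((a, d))
    out.sort(key=lambda t: t[1])
    return StructureNeighbors(center=fe, neighbors=out, rmax=rmax)


#: Default element/distance-window binning (A), chosen to resolve the
#: heme-site shells: porphyrin N, axial O, the two C rings and the outer
#: C ring.  Fully configurable.
DEFAULT_BINS = (
    ("I Fe-N", "N", 1.8, 2.3),
    ("II Fe-O", "O", 2.3, 3.0),
    ("III Fe-C1", "C", 2.9, 3.25),
    ("IV Fe-C2", "C", 3.25, 3.7),
    ("Fe-C4", "C", 4.0, 4.5),
)


def build_shell_model(nbrs, bins=DEFAULT_BINS, sigma2=3.0e-3, s02=0.85):
    """Group neighbors into shells: N = member count, r = mean distance.

    ``bins`` is a sequence of (label, element, r_low, r_high).  Neighbors
    falling in no window are logged and excluded.  Crystallography gives
    no disorder information, so every shell gets the same placeholder
    ``sigma2``.
    """
    if not nbrs.neighbors:
        raise ValueError("empty neighbor list")
    members = {label: [] for label, *_ in bins}
    for atom, d in nbrs.neighbors:
        for label, element, lo, hi in bins:
            if atom.element == element and lo <= d < hi:
                members[label].append(d)
                break
        else:
            log.info(
                "neighbor %s/%s at %.2f A falls in no window; excluded",
                atom.resname,
                atom.name,
                d,
            )
    shells = tuple(
        Shell(label, element, len(ds), float(np.mean(ds)), sigma2)
        for (label, element, _, _), ds in zip(bins, members.values())
        if ds
    )
    return ShellModel(shells=shells, s02=s02, delta_e=0.0)


def collinear_paths(
    atoms,
    angle_threshold=150.0,
    first_shell_rmax=2.5,
    neighbor_cutoff=2.6,
    chain=None,
    resseq=None,
):
    """Near-collinear Fe-A-B triples prone to strong multiple scattering.

    A runs over first-shell atoms (within ``first_shell_rmax`` of Fe), B
    over non-hydrogen atoms within ``neighbor_cutoff`` of A (covering
    bonded and 1-3 contacts; the porphyrin N...C_beta contact is ~2.25 A).
    Triples whose Fe-A-B angle at A reaches ``angle_threshold`` (degrees)
    are returned as ((fe, a, b), angle) sorted by descending angle; any
    hit means the outer atom's shell should be excluded from
    single-scattering fitting.
    """
    fe = _select_fe(atoms, chain, resseq)
    heavy = [a for a in atoms if a.element not in ("H", "D") and a is not fe]
    first = [
        a
        for a in heavy
        if np.linalg.norm(a.coords - fe.coords) <= first_shell_rmax
    ]
    hits = []
    for a in first:
        for b in heavy:
            if b is a:
                continue
            dab = np.linalg.norm(b.coords - a.coords)
            if dab > neighbor_cutoff:
                continue
            v1 = fe.coords - a.coords
            v2 = b.coords - a.coords
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * dab)
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle >= angle_threshold:
                hits.append(((fe, a, b), angle))
    hits.sort(key=lambda t: -t[1])
    return hits


# ---------------------------------------------------------------------------
# synthetic reference geometry


def synthetic_heme_site(axial_o=True, include_his=False):
    """PDB text of an idealized synthetic heme-Fe(III) site.

    A geometric stand-in for a crystallographic heme pocket, built from
    the canonical shell distances of ferric heme-albumin: 4 porphyrin N
    at 2.06 A, one axial tyrosine-phenoxy O at 2.78 A, 8 alpha-C at
    3.07 A, 4 meso-C at 3.43 A and 8 beta-C at 4.28 A placed so the
    Fe-N-C_beta arrangement is near-collinear (~170 deg).  Optionally a
    distal histidine-like N at 2.15 A on the opposite axial side.
    This is synthetic reference geometry, not deposited coordinates.
    """
    records = []

    def hetatm(serial, name, resname, resseq, x, y, z, element):
        records.append(
            f"HETATM{serial:5d} {name:<4s} {resname:>3s} A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{20.00:6.2f}          "
            f"{element:>2s}"
        )

    serial = 1
    hetatm(serial, "FE", "HEM", 1, 0.0, 0.0, 0.0, "FE")
    serial += 1

    # beta-C polar offset solving for a 170 deg Fe-N-C_beta angle
    r_n, r_ca, r_cm, r_cb = 2.06, 3.07, 3.43, 4.28
    theta_ca = np.radians(24.0)
    theta_cb = _collinear_offset(r_n, r_cb, np.radians(170.0))
    idx = 1
    for quadrant in range(4):
        base = quadrant * np.pi / 2
        c, s = np.cos(base), np.sin(base)

        def rot(x, y):
            return c * x - s * y, s * x + c * y

        x, y = rot(r_n, 0.0)
        hetatm(serial, f"N{quadrant+1}", "HEM", 1, x, y, 0.0, "N")
        serial += 1
        for sign in (+1, -1):
            x, y = rot(r_ca * np.cos(theta_ca), sign * r_ca * np.sin(theta_ca))
            hetatm(serial, f"CA{idx}", "HEM", 1, x, y, 0.0, "C")
            serial += 1
            x, y = rot(r_cb * np.cos(theta_cb), sign * r_cb * np.sin(theta_cb))
            hetatm(serial, f"CB{idx}", "HEM", 1, x, y, 0.0, "C")
            serial += 1
            idx += 1
        x, y = rot(r_cm * np.cos(np.pi / 4), r_cm * np.sin(np.pi / 4))
        hetatm(serial, f"CM{quadrant+1}", "HEM", 1, x, y, 0.0, "C")
        serial += 1

    if axial_o:
        hetatm(serial, "OH", "TYR", 161, 0.0, 0.0, 2.78, "O")
        serial += 1
    if include_his:
        hetatm(serial, "NE2", "HIS", 146, 0.0, 0.0, -2.15, "N")
        serial += 1
    records.append("END")
    return "\n".join(records) + "\n"


def _collinear_offset(r_first, r_outer, angle):
    """In-plane polar offset of the outer atom giving the target Fe-A-B
    angle at a first-shell atom on the +x axis."""
    from scipy.optimize import brentq

    def f(theta):
        b = np.array([r_outer * np.cos(theta), r_outer * np.sin(theta)])
        a = np.array([r_first, 0.0])
        v1 = -a
        v2 = b - a
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return np.degrees(np.arccos(np.clip(cosang, -1, 1))) - np.degrees(angle)

    return brentq(f, 1e-4, np.pi / 3)
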