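"""Closed-form beta-barrel pore geometry.

A transmembrane pore is modelled as an ideal cylindrical beta-barrel of
``z`` strands, each strand tilted by an angle ``beta`` from the barrel
axis.  For standard beta-barrels the interstrand (H-bonding) distance is
d = 4.72 A and the backbone rise per residue along the strand is
a = 3.48 A.  The inner backbone radius is

    R = d / (2 sin(pi/z) cos(beta)),

the barrel height is h_b = m a cos(beta) for an m-residue strand, and the
internal volume is V = pi R^2 h_b.

Side chains of consecutive residues in a strand point alternately into and
out of the barrel, giving exactly two packing topologies for a strand.
Comparing the barrel's internal volume with the van der Waals volume of
the inward-pointing side chains decides whether a given barrel can
accommodate a topology, and any excess free volume can be expressed as the
radius of an equivalent cylindrical channel.  Tightly packed barrels may
instead assemble into a ring (e.g. a hexamer of barrels) whose central
hole forms the ion-conducting pore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "VDW_VOLUMES",
    "AB25_35_SEQUENCE",
    "BarrelParams",
    "BarrelGeometry",
    "Topology",
    "PoreRing",
    "RingPoreResult",
    "barrel_radius",
    "barrel_height",
    "barrel_volume",
    "barrel_geometry",
    "assign_topology",
    "inward_volume",
    "total_sidechain_volume",
    "packing_feasibility",
    "equivalent_channel_radius",
    "ring_pore_radius",
    "barrel_report",
]

#: Van der Waals side-chain volumes (A^3) for the residues occurring in
#: the A-beta(25-35) sequence.
VDW_VOLUMES: Mapping[str, float] = {
    "G": 48.0,
    "A": 67.0,
    "S": 73.0,
    "N": 96.0,
    "I": 124.0,
    "L": 124.0,
    "M": 124.0,
    "K": 135.0,
}

#: A-beta residues 25-35 (GSNKGAIIGLM); position 0 is residue 25.
AB25_35_SEQUENCE = "GSNKGAIIGLM"

#: First residue number of the default sequence, used only for labels.
AB25_35_OFFSET = 25


@dataclass(frozen=True)
class BarrelParams:
    """Lattice parameters of an ideal beta-barrel.

    Parameters
    ----------
    z : int
        Number of strands (>= 3).
    beta_deg : float
        Strand tilt from the barrel axis, degrees, in [0, 90).
    m : int
        Residues per strand (default 11, the A-beta 25-35 fragment).
    d : float
        Interstrand distance in Angstrom (default 4.72).
    a : float
        Backbone rise per residue along the strand in Angstrom
        (default 3.48).
    """

    z: int
    beta_deg: float
    m: int = 11
    d: float = 4.72
    a: float = 3.48

    def __post_init__(self) -> None:
        if self.z < 3:
            raise ValueError(f"strand count z must be >= 3, got {self.z}")
        if not 0.0 <= self.beta_deg < 90.0:
            raise ValueError(
                f"strand tilt beta must be in [0, 90) degrees, got {self.beta_deg}"
            )
        if self.m < 0:
            raise ValueError(f"residues per strand m must be >= 0, got {self.m}")
        if self.d <= 0 or self.a <= 0:
            raise ValueError("lattice constants d and a must be positive")

    @property
    def beta_rad(self) -> float:
        return math.radians(self.beta_deg)


@dataclass(frozen=True)
class BarrelGeometry:
    """Derived barrel dimensions: inner backbone radius R (A), height
    h_b (A) and internal volume V (A^3)."""

    R: float
    h_b: float
    V: float


def barrel_radius(params: BarrelParams) -> float:
    """Inner backbone radius R = d / (2 sin(pi/z) cos(beta)), in Angstrom."""
    return params.d / (2.0 * math.sin(math.pi / params.z) * math.cos(params.beta_rad))


def barrel_height(params: BarrelParams) -> float:
    """Barrel height h_b = m a cos(beta), in Angstrom."""
    return params.m * params.a * math.cos(params.beta_rad)


def barrel_volume(params: BarrelParams) -> float:
    """Internal volume V = pi R^2 h_b, in cubic Angstrom."""
    r = barrel_radius(params)
    return math.pi * r * r * barrel_height(params)


def barrel_geometry(params: BarrelParams) -> BarrelGeometry:
    """All three derived dimensions at once."""
    return BarrelGeometry(
        R=barrel_radius(params), h_b=barrel_height(params), V=barrel_volume(params)
    )


@dataclass(frozen=True)
class Topology:
    """One of the two alternating in/out side-chain phases of a strand.

    ``inward`` holds the 0-based positions whose side chains point into
    the barrel.  For the default sequence GSNKGAIIGLM, phase 1 puts
    S26, K28, A30, I32, L34 inside ("topology-1") and phase 0 puts
    G25, N27, G29, I31, G33, M35 inside ("topology-2").
    """

    sequence: str
    inward: tuple[int, ...]
    label: str
    residue_offset: int = AB25_35_OFFSET

    @property
    def inward_residues(self) -> tuple[str, ...]:
        return tuple(f"{self.sequence[i]}{i + self.residue_offset}" for i in self.inward)


def assign_topology(
    sequence: str = AB25_35_SEQUENCE,
    phase: int = 1,
    residue_offset: int = AB25_35_OFFSET,
) -> Topology:
    """Assign alternating inward/outward side chains along a strand.

    ``phase`` selects which alternating set points inward: positions with
    index parity equal to ``phase`` are inward.  For GSNKGAIIGLM,
    ``phase=1`` reproduces topology-1 (Ser26 inward) and ``phase=0``
    topology-2 (Gly25 inward).
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if phase not in (0, 1):
        raise ValueError(f"phase must be 0 or 1, got {phase}")
    bad = sorted({c for c in sequence if not ("A" <= c <= "Z")})
    if bad:
        raise ValueError(f"invalid residue letters in sequence: {bad}")
    inward = tuple(i for i in range(len(sequence)) if i % 2 == phase)
    label = "topology-1" if phase == 1 else "topology-2"
    return Topology(
        sequence=sequence, inward=inward, label=label, residue_offset=residue_offset
    )


def inward_volume(
    topology: Topology, z: int, table: Mapping[str, float] = VDW_VOLUMES
) -> float:
    """Total vdW volume (A^3) required by the inward side chains of ``z``
    strands in the given topology."""
    total = 0.0
    for i in topology.inward:
        residue = topology.sequence[i]
        try:
            total += table[residue]
        except KeyError:
            raise KeyError(
                f"no van der Waals volume for residue {residue!r} "
                f"(position {i + topology.residue_offset})"
            ) from None
    return z * total


def total_sidechain_volume(
    sequence: str = AB25_35_SEQUENCE, table: Mapping[str, float] = VDW_VOLUMES
) -> float:
    """Sum of vdW side-chain volumes over a full strand (A^3)."""
    try:
        return sum(table[c] for c in sequence)
    except KeyError as exc:
        raise KeyError(f"no van der Waals volume for residue {exc.args[0]!r}") from None


def packing_feasibility(volume: float, required: float) -> tuple[bool, float]:
    """Whether an internal volume can accommodate the required side-chain
    volume.  Returns ``(feasible, free_volume)``; the free volume may be
    negative when packing is infeasible."""
    free = volume - required
    return free >= 0.0, free


def equivalent_channel_radius(free_volume: float, h_b: float) -> float:
    """Radius (A) of the cylinder of height ``h_b`` holding ``free_volume``."""
    if free_volume < 0:
        raise ValueError(f"free volume must be non-negative, got {free_volume}")
    if h_b <= 0:
        raise ValueError(f"barrel height must be positive, got {h_b}")
    return math.sqrt(free_volume / (math.pi * h_b))


@dataclass(frozen=True)
class PoreRing:
    """A ring of ``n_barrels`` tangent barrels whose central hole is the
    ion-conducting pore.  ``lining_thickness`` is the side-chain layer
    (A) added to the backbone radius to form the barrel outer radius."""

    n_barrels: int = 6
    lining_thickness: float = 2.0

    def __post_init__(self) -> None:
        if self.n_barrels < 3:
            raise ValueError(f"need at least 3 barrels in a ring, got {self.n_barrels}")
        if self.lining_thickness < 0:
            raise ValueError("lining thickness must be non-negative")


@dataclass(frozen=True)
class RingPoreResult:
    """Ring geometry: barrel outer radius R_out, centre distance rho from
    the pore axis, the raw geometric hole radius rho - R_out, and the
    lined radius with an inner side-chain layer subtracted."""

    n_barrels: int
    barrel_outer_radius: float
    center_distance: float
    raw_radius: float
    lined_radius: float
    convention: str = field(
        default="tangent barrels of radius R_inner + lining; "
        "raw = rho - R_out; lined = raw - lining"
    )


def ring_pore_radius(ring: PoreRing, barrel_inner_radius: float) -> RingPoreResult:
    """Central hole radius of a ring of tangent barrels.

    Barrels of outer radius ``R_out = barrel_inner_radius + lining`` sit
    with centres on a circle of radius ``rho = R_out / sin(pi/n)`` so that
    neighbours touch.  The raw hole radius is ``rho - R_out`` (for a
    hexamer this equals R_out exactly).  Because side chains of the
    pore-facing strands protrude into the hole, a ``lined`` radius with
    the lining subtracted once more is reported as well; the physical
    pore radius lies between the two.
    """
    r_out = barrel_inner_radius + ring.lining_thickness
    rho = r_out / math.sin(math.pi / ring.n_barrels)
    raw = rho - r_out
    return RingPoreResult(
        n_barrels=ring.n_barrels,
        barrel_outer_radius=r_out,
        center_distance=rho,
        raw_radius=raw,
        lined_radius=raw - ring.lining_thickness,
    )


def barrel_report(
    z: int,
    beta_deg: float,
    m: int = 11,
    sequence: str = AB25_35_SEQUENCE,
    d: float = 4.72,
    a: float = 3.48,
    lining_thickness: float = 2.0,
    ring_sizes: tuple[int, ...] = (3, 4, 5, 6, 7, 8),
) -> dict:
    """Full geometric characterisation of one barrel, as a plain dict.

    Covers dimensions, both packing topologies with feasibility and the
    equivalent free-volume channel radius, and the ring-pore table for
    the requested ring sizes.
    """
    params = BarrelParams(z=z, beta_deg=beta_deg, m=m, d=d, a=a)
    geom = barrel_geometry(params)
    report: dict = {
        "params": {"z": z, "beta_deg": beta_deg, "m": m, "d_A": d, "a_A": a},
        "R_A": geom.R,
        "h_b_A": geom.h_b,
        "V_A3": geom.V,
        "topologies": {},
        "ring_pores": {},
    }
    for phase in (1, 0):
        topo = assign_topology(sequence, phase=phase)
        required = inward_volume(topo, z)
        feasible, free = packing_feasibility(geom.V, required)
        entry = {
            "inward_residues": list(topo.inward_residues),
            "required_A3": required,
            "feasible": feasible,
            "free_volume_A3": free,
        }
        if free >= 0:
            entry["channel_radius_A"] = equivalent_channel_radius(free, geom.h_b)
        report["topologies"][topo.label] = entry
    for n in ring_sizes:
        ring = ring_pore_radius(PoreRing(n, lining_thickness), geom.R)
        report["ring_pores"][n] = {
            "center_distance_A": ring.center_distance,
            "raw_radius_A": ring.raw_radius,
            "lined_radius_A": ring.lined_radius,
        }
    return report
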