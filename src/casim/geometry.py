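"""Nuclear geometry, karyotype and chromosome conformations.

The interphase nucleus is a sphere or ellipsoid filled with 46 chromosomes.
Each chromosome is a polymer of 2-kbp monomers on a cubic lattice of 20 nm
pitch (10 nm of fibre per kbp), organised as alternating 60-monomer loops and
60-monomer linkers.  Chromosomes occupy non-overlapping territories
("domains") whose volume is proportional to chromosome length and whose axes
scale with the nuclear semi-axes; a walk may be confined to its domain (no
intermingling) or free to wander through the whole nucleus (intermingling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng, spawn_seeds
from . import _walk

#: lattice pitch of the chromatin random walk, µm (20 nm)
LATTICE_STEP_UM = 0.02
#: DNA content of one monomer, bp
MONOMER_BP = 2000
#: radius of the reference sphere in which domain radii are defined, µm
REFERENCE_RADIUS_UM = 6.0
#: default total domain volume as a fraction of the nuclear volume; kept
#: well below the random-sequential-addition jamming density so 46 disjoint
#: territories always pack
DEFAULT_PACKING_FRACTION = 0.15


class PackingError(RuntimeError):
    """Raised when a chromosome domain cannot be placed without overlap."""


class WalkError(RuntimeError):
    """Raised when the constrained random walk cannot make progress."""


# ---------------------------------------------------------------------------
# nucleus
# ---------------------------------------------------------------------------

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class NucleusGeometry:
    """Spherical or ellipsoidal nucleus, semi-axes in µm, centred at origin."""

    semi_axis_x: float
    semi_axis_y: float
    semi_axis_z: float

    def __post_init__(self):
        if min(self.semi_axis_x, self.semi_axis_y, self.semi_axis_z) <= 0:
            raise ValueError("all semi-axes must be positive")

    @classmethod
    def sphere(cls, radius_um: float) -> "NucleusGeometry":
        return cls(radius_um, radius_um, radius_um)

    @property
    def semi_axes(self) -> np.ndarray:
        return np.array([self.semi_axis_x, self.semi_axis_y, self.semi_axis_z])

    @property
    def shape(self) -> str:
        a, b, c = self.semi_axes
        return "sphere" if a == b == c else "ellipsoid"

    @property
    def volume_um3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    def projected_area_um2(self, axis: str = "z") -> float:
        """Area of the projection perpendicular to ``axis`` (π · ab)."""
        others = [s for k, s in zip("xyz", self.semi_axes) if k != axis]
        if len(others) != 2:
            raise ValueError(f"axis must be one of x|y|z, got {axis!r}")
        return math.pi * others[0] * others[1]

    def contains(self, points_um: np.ndarray) -> np.ndarray:
        """Elementwise test that points (…, 3) lie inside the nucleus."""
        p = np.asarray(points_um, dtype=float)
        q = (p / self.semi_axes) ** 2
        return q.sum(axis=-1) <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# karyotype
# ---------------------------------------------------------------------------

# GRCh38 chromosome lengths (bp) and approximate centromere midpoints (bp).
_HG38 = [
    ("1", 248_956_422, 123_400_000),
    ("2", 242_193_529, 93_900_000),
    ("3", 198_295_559, 90_900_000),
    ("4", 190_214_555, 50_000_000),
    ("5", 181_538_259, 48_800_000),
    ("6", 170_805_979, 59_800_000),
    ("7", 159_345_973, 60_100_000),
    ("8", 145_138_636, 45_200_000),
    ("9", 138_394_717, 43_000_000),
    ("10", 133_797_422, 39_800_000),
    ("11", 135_086_622, 53_400_000),
    ("12", 133_275_309, 35_500_000),
    ("13", 114_364_328, 17_700_000),
    ("14", 107_043_718, 17_200_000),
    ("15", 101_991_189, 19_000_000),
    ("16", 90_338_345, 36_800_000),
    ("17", 83_257_441, 25_100_000),
    ("18", 80_373_285, 18_500_000),
    ("19", 58_617_616, 26_200_000),
    ("20", 64_444_167, 28_100_000),
    ("21", 46_709_983, 12_000_000),
    ("22", 50_818_468, 15_000_000),
    ("X", 156_040_895, 60_600_000),
    ("Y", 57_227_415, 10_400_000),
]


@dataclass(frozen=True)
class Chromosome:
    id: str
    length_bp: int
    centromere_bp: int

    def __post_init__(self):
        if not 0 < self.centromere_bp < self.length_bp:
            raise ValueError(
                f"chromosome {self.id}: centromere must lie strictly inside "
                f"(0, {self.length_bp})")

    @property
    def n_monomers(self) -> int:
        return -(-self.length_bp // MONOMER_BP)  # ceil division


@dataclass(frozen=True)
class Karyotype:
    """Per-chromosome lengths and centromeres plus the lattice constants."""

    chromosomes: tuple[Chromosome, ...]
    monomer_bp: int = MONOMER_BP
    lattice_step_um: float = LATTICE_STEP_UM
    loop_monomers: int = 60
    linker_monomers: int = 60

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    @property
    def n_monomers(self) -> int:
        return sum(c.n_monomers for c in self.chromosomes)

    @classmethod
    def human_male(cls) -> "Karyotype":
        """46,XY: two copies of each autosome plus X and Y."""
        chroms = []
        for name, length, cen in _HG38:
            if name in ("X", "Y"):
                chroms.append(Chromosome(f"chr{name}", length, cen))
            else:
                chroms.append(Chromosome(f"chr{name}_a", length, cen))
                chroms.append(Chromosome(f"chr{name}_b", length, cen))
        return cls(tuple(chroms))

    @classmethod
    def human_female(cls) -> "Karyotype":
        """46,XX — about 1.7% more DNA than the male default."""
        chroms = []
        for name, length, cen in _HG38:
            if name == "Y":
                continue
            if name == "X":
                chroms.append(Chromosome("chrX_a", length, cen))
                chroms.append(Chromosome("chrX_b", length, cen))
            else:
                chroms.append(Chromosome(f"chr{name}_a", length, cen))
                chroms.append(Chromosome(f"chr{name}_b", length, cen))
        return cls(tuple(chroms))

    @classmethod
    def uniform_fixture(cls, n_chromosomes: int = 4,
                        length_bp: int = 10_000_000,
                        centromere_frac: float = 0.4) -> "Karyotype":
        """Reduced equal-length karyotype for fast tests."""
        chroms = tuple(
            Chromosome(f"fix{i + 1}", length_bp, int(length_bp * centromere_frac))
            for i in range(n_chromosomes))
        return cls(chroms)


@dataclass(frozen=True)
class RadiusDistribution:
    """Discrete distribution of spherical nuclear radii in a population."""

    radii_um: tuple[float, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if len(self.radii_um) != len(f):
            raise ValueError("radii and frequencies must have equal length")
        if (f < 0).any():
            raise ValueError("frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")

    @property
    def mean_radius_um(self) -> float:
        return float(np.dot(self.radii_um, self.frequencies))


# ---------------------------------------------------------------------------
# chromosome domains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeDomain:
    """Non-overlapping territory similar in shape to the nucleus.

    ``scale`` is the ratio of the domain semi-axes to the nuclear semi-axes;
    because all domains share the nucleus shape, exact inside/overlap tests
    reduce to sphere tests in the coordinate frame scaled by the nuclear
    semi-axes.
    """

    chromosome: str
    center_um: np.ndarray
    semi_axes_um: np.ndarray
    scale: float

    def contains(self, points_um: np.ndarray) -> np.ndarray:
        p = np.asarray(points_um, dtype=float) - self.center_um
        q = (p / self.semi_axes_um) ** 2
        return q.sum(axis=-1) <= 1.0 + 1e-12


def reference_domain_radii(karyotype: Karyotype,
                           packing_fraction: float = DEFAULT_PACKING_FRACTION,
                           ) -> np.ndarray:
    """Domain radii (µm) in the reference 6-µm sphere.

    Domain volume is proportional to chromosome length (radius ∝ length^(1/3),
    uniform DNA density across territories); the proportionality constant is
    fixed so that the summed domain volume is ``packing_fraction`` of the
    reference nucleus volume.
    """
    lengths = np.array([c.length_bp for c in karyotype.chromosomes], dtype=float)
    v_ref = 4.0 / 3.0 * math.pi * REFERENCE_RADIUS_UM ** 3
    volumes = packing_fraction * v_ref * lengths / lengths.sum()
    return (volumes * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def place_domains(nucleus: NucleusGeometry, karyotype: Karyotype,
                  seed=None, packing_fraction: float = DEFAULT_PACKING_FRACTION,
                  max_retries: int = 10_000) -> list[ChromosomeDomain]:
    """Random sequential insertion of the domains, largest first.

    Centers are sampled uniformly in the shape-scaled frame, rejecting
    placements that protrude from the nucleus or overlap an accepted domain.
    Deterministic given ``seed``.
    """
    rng = as_rng(seed)
    radii_ref = reference_domain_radii(karyotype, packing_fraction)
    scales = radii_ref / REFERENCE_RADIUS_UM
    order = np.argsort(-scales)
    axes = nucleus.semi_axes

    placed_centers: list[np.ndarray] = []   # in the scaled (unit-sphere) frame
    placed_scales: list[float] = []
    out: list[ChromosomeDomain | None] = [None] * len(karyotype)
    for idx in order:
        s = float(scales[idx])
        if s >= 1.0:
            raise PackingError(
                f"domain of chromosome {karyotype.chromosomes[idx].id} does "
                f"not fit inside the nucleus")
        for attempt in range(max_retries):
            v = rng.standard_normal(3)
            v *= (1.0 - s) * rng.random() ** (1.0 / 3.0) / np.linalg.norm(v)
            ok = True
            for c, sc in zip(placed_centers, placed_scales):
                d = v - c
                if d @ d < (s + sc) ** 2:
                    ok = False
                    break
            if ok:
                placed_centers.append(v)
                placed_scales.append(s)
                out[idx] = ChromosomeDomain(
                    chromosome=karyotype.chromosomes[idx].id,
                    center_um=v * axes,
                    semi_axes_um=s * axes,
                    scale=s,
                )
                break
        else:
            raise PackingError(
                f"could not place domain of chromosome "
                f"{karyotype.chromosomes[idx].id} after {max_retries} attempts")
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# random walk
# ---------------------------------------------------------------------------

@dataclass
class ChromosomePath:
    """Ordered monomer positions of one chromosome, integer lattice units."""

    chromosome: str
    positions: np.ndarray          # (n, 3) int32, units of 20 nm
    loop_monomers: int = 60
    linker_monomers: int = 60

    @property
    def n_monomers(self) -> int:
        return self.positions.shape[0]

    def positions_um(self) -> np.ndarray:
        return self.positions.astype(float) * LATTICE_STEP_UM

    def monomer_block(self) -> np.ndarray:
        """'loop' / 'linker' label per monomer from the alternating pattern."""
        period = self.loop_monomers + self.linker_monomers
        phase = np.arange(self.n_monomers) % period
        return np.where(phase < self.loop_monomers, "loop", "linker")


def _sample_start(domain: ChromosomeDomain, nucleus: NucleusGeometry,
                  rng: np.random.Generator, max_retries: int = 10_000
                  ) -> np.ndarray:
    """Uniform lattice point inside the domain (and nucleus)."""
    for _ in range(max_retries):
        u = rng.standard_normal(3)
        u *= rng.random() ** (1.0 / 3.0) / np.linalg.norm(u)
        p = domain.center_um + u * domain.semi_axes_um
        idx = np.rint(p / LATTICE_STEP_UM).astype(np.int32)
        p_snap = idx * LATTICE_STEP_UM
        if domain.contains(p_snap) and nucleus.contains(p_snap):
            return idx
    raise WalkError(
        f"could not place the first monomer inside the domain of "
        f"{domain.chromosome} (degenerate domain?)")


def walk_chromosome(domain: ChromosomeDomain, nucleus: NucleusGeometry,
                    n_monomers: int, constrain: bool, seed=None,
                    loop_monomers: int = 60, linker_monomers: int = 60,
                    loop_budget: int = 1_000_000, step_budget: int = 10_000,
                    ) -> ChromosomePath:
    """Lattice random walk for one chromosome.

    The first monomer is uniform inside the domain; the chain then alternates
    brute-force-closed loops and linkers.  Steps leaving the nucleus (always)
    or the domain (``constrain`` only) are rejected and resampled.
    """
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    rng = as_rng(seed)
    start = _sample_start(domain, nucleus, rng)
    pos = np.zeros((n_monomers, 3), dtype=np.int32)
    pos[0] = start
    if n_monomers > 1:
        step = LATTICE_STEP_UM
        nuc_inv2 = (step / nucleus.semi_axes) ** 2
        dom_c = domain.center_um / step
        dom_inv2 = (step / domain.semi_axes_um) ** 2
        kernel_seed = int(rng.integers(0, 2 ** 31 - 1))
        status, where = _walk.walk_kernel(
            pos, nuc_inv2, dom_c, dom_inv2, constrain,
            loop_monomers, linker_monomers, loop_budget, step_budget,
            kernel_seed)
        if status == _walk.WALK_STUCK:
            raise WalkError(
                f"walk of {domain.chromosome} stuck at monomer {where}: no "
                f"admissible lattice step after {step_budget} resamples")
        if status == _walk.WALK_LOOP_BUDGET:
            raise WalkError(
                f"loop ending at monomer {where} of {domain.chromosome} "
                f"failed to close within {loop_budget} candidates")
    return ChromosomePath(domain.chromosome, pos, loop_monomers, linker_monomers)


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """Nucleus + domains + one conformation per chromosome."""

    nucleus: NucleusGeometry
    karyotype: Karyotype
    domains: list[ChromosomeDomain]
    paths: list[ChromosomePath]
    intermingling: bool
    seed: int | None
    # flat per-monomer views, built in __post_init__
    monomer_chromosome: np.ndarray = field(init=False, repr=False)
    monomer_positions: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.monomer_chromosome = np.concatenate([
            np.full(p.n_monomers, i, dtype=np.int32)
            for i, p in enumerate(self.paths)])
        self.monomer_positions = np.concatenate(
            [p.positions for p in self.paths], axis=0)

    @property
    def n_monomers(self) -> int:
        return self.monomer_positions.shape[0]

    def positions_um(self) -> np.ndarray:
        return self.monomer_positions.astype(float) * LATTICE_STEP_UM

    def intermingling_fraction(self) -> float:
        """Fraction of monomers lying outside their own chromosome domain."""
        outside = 0
        for path, domain in zip(self.paths, self.domains):
            inside = domain.contains(path.positions_um())
            outside += int((~inside).sum())
        return outside / self.n_monomers

    def summary(self) -> dict:
        return {
            "n_chromosomes": len(self.karyotype),
            "n_monomers": self.n_monomers,
            "total_bp": self.karyotype.total_bp,
            "nucleus_volume_um3": self.nucleus.volume_um3,
            "intermingling": self.intermingling,
            "intermingling_fraction": self.intermingling_fraction(),
            "seed": self.seed,
        }


def build_genome(nucleus: NucleusGeometry, karyotype: Karyotype | None = None,
                 intermingle: bool = True, seed: int | None = 0,
                 packing_fraction: float = DEFAULT_PACKING_FRACTION,
                 ) -> GenomeModel:
    """Place domains and walk all chromosomes; bit-reproducible given seed."""
    if karyotype is None:
        karyotype = Karyotype.human_male()
    seeds = spawn_seeds(seed, len(karyotype) + 1)
    domains = place_domains(nucleus, karyotype, seed=seeds[0],
                            packing_fraction=packing_fraction)
    paths = []
    for chrom, domain, s in zip(karyotype.chromosomes, domains, seeds[1:]):
        paths.append(walk_chromosome(
            domain, nucleus, chrom.n_monomers, constrain=not intermingle,
            seed=s, loop_monomers=karyotype.loop_monomers,
            linker_monomers=karyotype.linker_monomers))
    return GenomeModel(nucleus, karyotype, domains, paths,
                       intermingling=intermingle, seed=seed)
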