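"""Synthetic multi-species studies with known spatial genetic structure.

The generator emulates the statistical structure the landscape analysis
assumes, without demographic realism:

* populations are placed uniformly at random in a planar (unit square) or
  lon/lat box domain;
* each species carries two haplotype pools, one per side of a planted
  barrier line; the pools share a fraction (1 - s) of haplotypes, and the
  side backbones differ at ``round(s * backbone_divergence * L)`` fixed
  sites, so cross-barrier pairs are elevated in Phi_ST by an amount
  controlled by the divergence strength s;
* a population's haplotype frequencies are drawn from a symmetric Dirichlet
  over its side's pool with per-haplotype concentration theta(x, y) =
  theta0 + sum of Gaussian bumps: inside a bump frequencies are even (high
  Hd/pi), outside they are drift-skewed (low diversity). For a symmetric
  Dirichlet with concentration a over P haplotypes the expected gene
  diversity is a (P - 1) / (P a + 1), which maps theta to a target Hd;
* individuals are sampled multinomially from the population frequencies.

Microsatellite species follow the same scheme with integer allele pools per
locus. The ground truth (theta field, barrier geometry, expected hotspot
regions) is stored next to the data so recovery tests can score the
pipeline against what was planted.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, box

from .io_formats import (MicrosatDataset, PopulationRecord, RegionPolygonSet,
                         SD_COLUMNS, SequenceDataset, write_fasta_alignment,
                         write_genotype_csv, write_geojson_regions,
                         write_population_csv)

NUCLEOTIDES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: plausible positive output ranges for the species-diversity indices
SD_RANGES = {"ER": (5.0, 120.0), "WE": (0.1, 3.0), "PD": (50.0, 900.0),
             "PE": (0.05, 2.0), "BED": (0.1, 5.0)}


@dataclass(frozen=True)
class Bump:
    """A Gaussian high-diversity anomaly.

    ``radius`` is the bump footprint, defined as twice the Gaussian sigma:
    theta gains ``peak * exp(-d^2 / (2 (radius/2)^2))``, so the anomaly has
    decayed to ~1% of its peak at 1.5 radii from the center.
    """

    center: tuple[float, float]
    radius: float
    peak: float

    @property
    def sigma(self) -> float:
        return self.radius / 2.0


@dataclass(frozen=True)
class Barrier:
    """A line across which haplotype pools diverge; s in [0, 1]."""

    start: tuple[float, float]
    end: tuple[float, float]
    strength: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("barrier strength must lie in [0, 1]")

    def side(self, x: float, y: float) -> int:
        (x1, y1), (x2, y2) = self.start, self.end
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        return 0 if cross >= 0 else 1

    def distance(self, x: float, y: float) -> float:
        return LineString([self.start, self.end]).distance(Point(x, y))


@dataclass
class SimulationConfig:
    """Default configuration of the reference synthetic study.

    5 species x 20 populations x 8 individuals, two within-population
    diversity bumps off the barrier, and one vertical barrier through the
    middle of the unit square with strength 0.8.
    """

    n_species: int = 5
    populations_per_species: int = 20
    individuals_per_population: int = 8
    domain: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)
    crs: str = "planar"
    diversity_bumps: list[Bump] = field(default_factory=lambda: [
        Bump((0.25, 0.75), 0.16, 0.7),
        Bump((0.75, 0.25), 0.16, 0.7),
    ])
    barrier: Barrier = field(default_factory=lambda: Barrier((0.5, 0.0), (0.5, 1.0)))
    theta0: float = 0.015
    sequence_length: int = 300
    n_haplotype_pool: int = 24
    haplotype_mutation_rate: float = 0.02   # per-site, haplotype vs backbone
    backbone_divergence: float = 0.10       # max fraction of fixed cross-barrier sites
    n_microsat_species: int = 0             # simulated instead of sequences
    n_loci: int = 8
    n_allele_pool: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.populations_per_species < 10:
            raise ValueError("need >= 10 populations per species")
        if self.individuals_per_population < 3:
            raise ValueError("need >= 3 individuals per population")
        xmin, ymin, xmax, ymax = self.domain
        for b in self.diversity_bumps:
            if not (xmin <= b.center[0] <= xmax and ymin <= b.center[1] <= ymax):
                import warnings
                warnings.warn(f"bump at {b.center} lies outside the domain",
                              stacklevel=2)

    def theta(self, x: float, y: float) -> float:
        t = self.theta0
        for b in self.diversity_bumps:
            d2 = (x - b.center[0]) ** 2 + (y - b.center[1]) ** 2
            t += b.peak * math.exp(-d2 / (2.0 * b.sigma ** 2))
        return t

    def agd_field(self, x, y) -> np.ndarray:
        """True among-population divergence field: a corridor around the barrier.

        Proximity to the barrier scaled by strength; corridor half-width is
        15% of the domain width.
        """
        xmin, _, xmax, _ = self.domain
        w = 0.15 * (xmax - xmin)
        line = LineString([self.barrier.start, self.barrier.end])
        x, y = np.atleast_1d(x), np.atleast_1d(y)
        d = np.array([line.distance(Point(xi, yi)) for xi, yi in zip(x, y)])
        return self.barrier.strength * np.exp(-d ** 2 / (2 * w ** 2))


@dataclass
class GroundTruth:
    theta_by_population: dict[str, float]
    side_by_population: dict[str, int]
    barrier: Barrier
    bump_centers: list[tuple[float, float]]
    bump_radii: list[float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta_by_population": self.theta_by_population,
            "side_by_population": self.side_by_population,
            "barrier": asdict(self.barrier),
            "bump_centers": self.bump_centers,
            "bump_radii": self.bump_radii,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _mutate(backbone: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Copy of *backbone* with each site substituted with probability *rate*."""
    seq = backbone.copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    for pos in hit:
        choices = NUCLEOTIDES[NUCLEOTIDES != seq[pos]]
        seq[pos] = rng.choice(choices)
    return seq


def _haplotype_pools(cfg: SimulationConfig, rng: np.random.Generator
                     ) -> tuple[list[str], list[str]]:
    """Two side pools sharing (1 - s) of haplotypes, backbones diverged by s."""
    L, P, s = cfg.sequence_length, cfg.n_haplotype_pool, cfg.barrier.strength
    backbone_a = rng.choice(NUCLEOTIDES, size=L)
    n_div = round(s * cfg.backbone_divergence * L)
    backbone_b = backbone_a.copy()
    for pos in rng.choice(L, size=n_div, replace=False):
        choices = NUCLEOTIDES[NUCLEOTIDES != backbone_b[pos]]
        backbone_b[pos] = rng.choice(choices)

    # Shared (cross-barrier) haplotypes derive from an intermediate backbone
    # carrying half of the divergent sites, so they are equidistant from both
    # side pools and do not bias within-side molecular diversity to one side.
    div_pos = np.nonzero(backbone_a != backbone_b)[0]
    backbone_mid = backbone_a.copy()
    backbone_mid[div_pos[: len(div_pos) // 2]] = backbone_b[div_pos[: len(div_pos) // 2]]
    n_shared = round((1.0 - s) * P)
    shared = [_mutate(backbone_mid, cfg.haplotype_mutation_rate, rng)
              for _ in range(n_shared)]
    pool_a = shared + [_mutate(backbone_a, cfg.haplotype_mutation_rate, rng)
                       for _ in range(P - n_shared)]
    pool_b = shared + [_mutate(backbone_b, cfg.haplotype_mutation_rate, rng)
                       for _ in range(P - n_shared)]
    decode = lambda pool: [bytes(seq).decode() for seq in pool]
    return decode(pool_a), decode(pool_b)


def _allele_pools(cfg: SimulationConfig, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Integer allele pools per locus; cross-barrier pools share (1 - s)."""
    K, s = cfg.n_allele_pool, cfg.barrier.strength
    n_shared = round((1.0 - s) * K)
    pools_a, pools_b = [], []
    for locus in range(cfg.n_loci):
        base = locus * 1000  # locus-specific label space
        labels = rng.permutation(np.arange(1, 2 * K + 1)) + base
        shared = labels[:n_shared]
        pools_a.append(np.concatenate([shared, labels[n_shared:K]]))
        pools_b.append(np.concatenate([shared, labels[K:2 * K - n_shared]]))
    return np.asarray(pools_a), np.asarray(pools_b)


def generate_study(config: SimulationConfig
                   ) -> tuple[list, list[PopulationRecord], GroundTruth]:
    """Generate the study: datasets, population table, ground truth.

    Deterministic given the config (the seed is part of the config). The
    first ``n_microsat_species`` species are diploid microsatellite
    datasets, the rest aligned haplotype sequences.
    """
    rng = np.random.default_rng(config.seed)
    xmin, ymin, xmax, ymax = config.domain
    records: list[PopulationRecord] = []
    datasets: list[SequenceDataset | MicrosatDataset] = []
    theta_truth: dict[str, float] = {}
    side_truth: dict[str, int] = {}

    for sp in range(config.n_species):
        species = f"species_{sp + 1:02d}"
        is_microsat = sp < config.n_microsat_species
        xs = rng.uniform(xmin, xmax, config.populations_per_species)
        ys = rng.uniform(ymin, ymax, config.populations_per_species)
        if is_microsat:
            pools_a, pools_b = _allele_pools(config, rng)
        else:
            pool_a, pool_b = _haplotype_pools(config, rng)
        alignment: dict[str, list[str]] = {}
        genotype_frames: dict[str, pd.DataFrame] = {}

        for p in range(config.populations_per_species):
            pop = f"{species}_pop{p + 1:02d}"
            x, y = float(xs[p]), float(ys[p])
            theta = config.theta(x, y)
            side = config.barrier.side(x, y)
            theta_truth[pop] = theta
            side_truth[pop] = side
            n_ind = config.individuals_per_population
            records.append(PopulationRecord(species, pop, x, y, n_ind))

            if is_microsat:
                pools = pools_a if side == 0 else pools_b
                rows = []
                alleles_by_locus = []
                for li in range(config.n_loci):
                    freqs = rng.dirichlet([theta] * config.n_allele_pool)
                    alleles_by_locus.append(
                        rng.choice(pools[li], size=2 * n_ind, p=freqs))
                for ind in range(n_ind):
                    for li in range(config.n_loci):
                        rows.append({
                            "individual_id": f"{pop}_ind{ind + 1}",
                            "locus_id": f"locus_{li + 1:02d}",
                            "allele_a": int(alleles_by_locus[li][2 * ind]),
                            "allele_b": int(alleles_by_locus[li][2 * ind + 1]),
                        })
                genotype_frames[pop] = pd.DataFrame(rows)
            else:
                pool = pool_a if side == 0 else pool_b
                freqs = rng.dirichlet([theta] * len(pool))
                draws = rng.choice(len(pool), size=n_ind, p=freqs)
                alignment[pop] = [pool[i] for i in draws]

        if is_microsat:
            datasets.append(MicrosatDataset(
                species, [f"locus_{li + 1:02d}" for li in range(config.n_loci)],
                genotype_frames))
        else:
            datasets.append(SequenceDataset(species, "cpDNA", alignment))

    truth = GroundTruth(
        theta_by_population=theta_truth, side_by_population=side_truth,
        barrier=config.barrier,
        bump_centers=[b.center for b in config.diversity_bumps],
        bump_radii=[b.radius for b in config.diversity_bumps])
    return datasets, records, truth


def generate_region_grid(config: SimulationConfig, n_regions: int,
                         sd_coupling: float,
                         agd_values: np.ndarray | None = None,
                         noise_scale: float = 1.0,
                         seed: int | None = None
                         ) -> tuple[RegionPolygonSet, pd.DataFrame]:
    """Tessellate the domain into regions and synthesize SD indices.

    Each species-diversity index is an ``sd_coupling``-weighted mixture of a
    standardized divergence signal and independent Gaussian noise, affinely
    rescaled into a plausible positive range. The signal is the supplied
    per-region *agd_values* when given (e.g. the regionally aggregated
    divergence landscape, making r exactly +/-1 at coupling +/-1 with zero
    noise); otherwise the true barrier-proximity divergence field at the
    region centroids.
    """
    if n_regions < 4:
        raise ValueError("need at least 4 regions")
    if not -1.0 <= sd_coupling <= 1.0:
        raise ValueError("sd_coupling must lie in [-1, 1]")
    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    xmin, ymin, xmax, ymax = config.domain
    nx = max(d for d in range(1, int(math.isqrt(n_regions)) + 1)
             if n_regions % d == 0)
    ny = n_regions // nx
    dx, dy = (xmax - xmin) / nx, (ymax - ymin) / ny
    regions, centroids = [], []
    for j in range(ny):
        for i in range(nx):
            poly = box(xmin + i * dx, ymin + j * dy,
                       xmin + (i + 1) * dx, ymin + (j + 1) * dy)
            regions.append((f"region_{j * nx + i + 1:03d}", poly))
            centroids.append((xmin + (i + 0.5) * dx, ymin + (j + 0.5) * dy))
    region_set = RegionPolygonSet(regions, boundary=box(xmin, ymin, xmax, ymax))

    cx, cy = np.array(centroids).T
    base = (np.asarray(agd_values, dtype=float) if agd_values is not None
            else config.agd_field(cx, cy))
    if len(base) != n_regions:
        raise ValueError("agd_values length must equal n_regions")
    spread = base.std()
    z = (base - base.mean()) / spread if spread > 0 else np.zeros_like(base)
    rows = {"region_id": [rid for rid, _ in regions]}
    ortho = math.sqrt(max(0.0, 1.0 - sd_coupling ** 2)) * noise_scale
    for col in SD_COLUMNS:
        noise = rng.standard_normal(n_regions)
        u = sd_coupling * z + ortho * noise
        lo, hi = SD_RANGES[col]
        if u.max() > u.min():
            rows[col] = lo + (hi - lo) * (u - u.min()) / (u.max() - u.min())
        else:
            rows[col] = np.full(n_regions, (lo + hi) / 2.0)
    return region_set, pd.DataFrame(rows)


def save_study(datasets, records, truth: GroundTruth, outdir: str | Path) -> None:
    """Write the generated study in exactly the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_population_csv(records, outdir / "populations.csv")
    manifest = []
    for ds in datasets:
        if ds.marker_type == "sequence":
            fname = f"{ds.species_id}_{ds.marker_id}.fasta"
            write_fasta_alignment(ds, outdir / fname)
        else:
            fname = f"{ds.species_id}_genotypes.csv"
            write_genotype_csv(ds, outdir / fname)
        manifest.append({"species_id": ds.species_id, "marker_id": ds.marker_id,
                         "marker_type": ds.marker_type, "path": fname})
    pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
    truth.to_json(outdir / "ground_truth.json")


def save_regions(region_set: RegionPolygonSet, sd_table: pd.DataFrame,
                 outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_geojson_regions(region_set, outdir / "regions.geojson")
    sd_table.to_csv(outdir / "species_diversity.csv", index=False)
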