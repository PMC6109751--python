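"""Readers, writers and validation for all external formats.

External surface:

* aligned haplotype FASTA per species x marker, headers ``>population|individual``
* genotype CSV (long format: one row per individual x locus, two integer
  allele columns, 0 = missing)
* population CSV (species, population, lon, lat, n_individuals)
* study manifest CSV mapping species x marker to data files
* GeoJSON region/boundary polygons
* ESRI ASCII grid rasters (6-keyword header, nodata -9999)

Everything read is validated into the domain types below before any
statistics are computed; validation failures raise :class:`ValidationError`
naming the offending file/record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .landscape import GeneticLandscape, GridSpec

MISSING_ALLELE = 0  # sentinel allele label in genotype CSVs
SEQUENCE_ALPHABET = set("ACGT-N")
NODATA = -9999.0


class ValidationError(ValueError):
    """Input data violates a format or cross-reference invariant."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PopulationRecord:
    species_id: str
    population_id: str
    lon: float
    lat: float
    n_individuals: int

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(
                f"population {self.population_id}: lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(
                f"population {self.population_id}: lat {self.lat} outside [-90, 90]")
        if self.n_individuals < 1:
            raise ValidationError(
                f"population {self.population_id}: n_individuals must be positive")


@dataclass
class SequenceDataset:
    """One species x marker alignment, grouped by population.

    Sequences are upper-case strings over A/C/G/T/-/N, all of identical
    length; one sequence per sampled individual (organelle or haploid-phased
    nuclear markers).
    """

    species_id: str
    marker_id: str
    alignment: dict[str, list[str]]

    marker_type: str = field(default="sequence", init=False)

    def __post_init__(self) -> None:
        lengths = {len(s) for seqs in self.alignment.values() for s in seqs}
        if len(lengths) > 1:
            raise ValidationError(
                f"{self.species_id}/{self.marker_id}: unequal sequence lengths {sorted(lengths)}")
        for pop, seqs in self.alignment.items():
            for i, s in enumerate(seqs):
                bad = set(s) - SEQUENCE_ALPHABET
                if bad:
                    raise ValidationError(
                        f"{self.species_id}/{self.marker_id}: sequence {i} of "
                        f"population {pop} has invalid symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        for seqs in self.alignment.values():
            if seqs:
                return len(seqs[0])
        return 0

    @property
    def population_ids(self) -> list[str]:
        return list(self.alignment)


@dataclass
class MicrosatDataset:
    """One species' co-dominant diploid microsatellite genotypes.

    ``genotypes`` maps population_id to a DataFrame with columns
    individual_id, locus_id, allele_a, allele_b (integer labels,
    ``MISSING_ALLELE`` = missing).
    """

    species_id: str
    loci: list[str]
    genotypes: dict[str, pd.DataFrame]

    marker_type: str = field(default="microsat", init=False)
    marker_id: str = "nSSR"

    def __post_init__(self) -> None:
        for pop, table in self.genotypes.items():
            dup = table.duplicated(["individual_id", "locus_id"])
            if dup.any():
                row = table[dup].iloc[0]
                raise ValidationError(
                    f"{self.species_id}: individual {row.individual_id} has more "
                    f"than one genotype row at locus {row.locus_id} "
                    f"(population {pop}); diploid data carry exactly two allele slots")

    @property
    def population_ids(self) -> list[str]:
        return list(self.genotypes)


@dataclass
class RegionPolygonSet:
    regions: list[tuple[str, BaseGeometry]]
    boundary: BaseGeometry | None = None

    def __post_init__(self) -> None:
        repaired = []
        for rid, geom in self.regions:
            if not geom.is_valid:
                geom = geom.buffer(0)
            if not geom.is_valid or geom.is_empty:
                raise ValidationError(f"region {rid}: polygon invalid after repair")
            repaired.append((rid, geom))
        self.regions = repaired
        if self.boundary is not None and not self.boundary.is_valid:
            self.boundary = self.boundary.buffer(0)

    @property
    def region_ids(self) -> list[str]:
        return [rid for rid, _ in self.regions]


SD_COLUMNS = ["ER", "WE", "PD", "PE", "BED"]


@dataclass
class FilterReport:
    """Audit trail of the study-inclusion rules."""

    excluded_populations: list[tuple[str, str, str]] = field(default_factory=list)
    excluded_species: list[tuple[str, str]] = field(default_factory=list)
    retained: dict[str, int] = field(default_factory=dict)
    input_counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"species_id": s, "population_id": p, "reason": r}
                for s, p, r in self.excluded_populations]
        rows += [{"species_id": s, "population_id": "", "reason": r}
                 for s, r in self.excluded_species]
        return pd.DataFrame(rows, columns=["species_id", "population_id", "reason"])


# ---------------------------------------------------------------------------
# population table


POPULATION_COLUMNS = ["species_id", "population_id", "lon", "lat", "n_individuals"]


def read_population_csv(path: str | Path) -> list[PopulationRecord]:
    df = pd.read_csv(path)
    missing = set(POPULATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: population CSV missing columns {sorted(missing)}")
    if df.duplicated(["species_id", "population_id"]).any():
        dup = df[df.duplicated(["species_id", "population_id"])].iloc[0]
        raise ValidationError(
            f"{path}: duplicate population ({dup.species_id}, {dup.population_id})")
    return [PopulationRecord(str(r.species_id), str(r.population_id),
                             float(r.lon), float(r.lat), int(r.n_individuals))
            for r in df.itertuples(index=False)]


def write_population_csv(records: list[PopulationRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records], columns=POPULATION_COLUMNS).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# FASTA alignments


def read_fasta_alignment(path: str | Path, species_id: str,
                         marker_id: str) -> SequenceDataset:
    """Read a per-species alignment whose headers are ``population|individual``."""
    alignment: dict[str, list[str]] = {}
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValidationError(
                f"{path}: header {rec.id!r} is not 'population_id|individual_id'")
        pop = rec.id.split("|", 1)[0]
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValidationError(
                f"{path}: sequence {rec.id!r} of species {species_id} has length "
                f"{len(seq)}, expected {length}")
        alignment.setdefault(pop, []).append(seq)
    if not alignment:
        raise ValidationError(f"{path}: empty FASTA")
    return SequenceDataset(species_id, marker_id, alignment)


def write_fasta_alignment(dataset: SequenceDataset, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{pop}|{pop}_{i + 1}", description="")
        for pop, seqs in dataset.alignment.items()
        for i, seq in enumerate(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# genotype CSV (long format)


GENOTYPE_COLUMNS = ["population_id", "individual_id", "locus_id", "allele_a", "allele_b"]


def read_genotype_csv(path: str | Path, species_id: str) -> MicrosatDataset:
    df = pd.read_csv(path)
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: genotype CSV missing columns {sorted(missing)}")
    df = df.astype({"population_id": str, "individual_id": str, "locus_id": str,
                    "allele_a": int, "allele_b": int})
    loci = sorted(df["locus_id"].unique())
    genotypes = {
        str(pop): g[["individual_id", "locus_id", "allele_a", "allele_b"]]
        .reset_index(drop=True)
        for pop, g in df.groupby("population_id", sort=True)
    }
    return MicrosatDataset(species_id, loci, genotypes)


def write_genotype_csv(dataset: MicrosatDataset, path: str | Path) -> None:
    frames = []
    for pop, table in dataset.genotypes.items():
        t = table.copy()
        t.insert(0, "population_id", pop)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeoJSON polygons


def read_geojson_regions(path: str | Path,
                         id_property: str = "region_id") -> RegionPolygonSet:
    with open(path) as fh:
        gj = json.load(fh)
    features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    regions: dict[str, list[BaseGeometry]] = {}
    boundary = None
    for feat in features:
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        rid = props.get(id_property)
        if rid is None or props.get("role") == "boundary":
            boundary = geom if boundary is None else unary_union([boundary, geom])
        else:
            # disjoint polygons sharing an id form one region
            regions.setdefault(str(rid), []).append(geom)
    merged = [(rid, unary_union(geoms)) for rid, geoms in regions.items()]
    return RegionPolygonSet(merged, boundary=boundary)


def write_geojson_regions(region_set: RegionPolygonSet, path: str | Path,
                          id_property: str = "region_id") -> None:
    features = [
        {"type": "Feature", "properties": {id_property: rid},
         "geometry": mapping(geom)}
        for rid, geom in region_set.regions
    ]
    if region_set.boundary is not None:
        features.append({"type": "Feature", "properties": {"role": "boundary"},
                         "geometry": mapping(region_set.boundary)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_species_diversity_csv(path: str | Path,
                               region_set: RegionPolygonSet | None = None) -> pd.DataFrame:
    """Region-level species-diversity indices, consumed as given."""
    df = pd.read_csv(path)
    missing = (set(SD_COLUMNS) | {"region_id"}) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: species-diversity CSV missing {sorted(missing)}")
    df["region_id"] = df["region_id"].astype(str)
    if df["region_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate region_id in species-diversity table")
    if region_set is not None:
        unknown = set(df["region_id"]) - set(region_set.region_ids)
        if unknown:
            raise ValidationError(
                f"{path}: region ids {sorted(unknown)} have no polygon")
    return df


# ---------------------------------------------------------------------------
# study manifest


MANIFEST_COLUMNS = ["species_id", "marker_id", "marker_type", "path"]


def read_study(population_csv_path: str | Path, data_manifest_path: str | Path,
               ) -> tuple[list[SequenceDataset | MicrosatDataset], list[PopulationRecord]]:
    """Read and cross-validate a whole study.

    The manifest CSV maps each species x marker to its data file
    (``marker_type`` in {sequence, microsat}; paths relative to the manifest).
    Every population appearing in a data file must exist in the population
    table with a matching individual count.
    """
    records = read_population_csv(population_csv_path)
    by_species: dict[str, dict[str, PopulationRecord]] = {}
    for r in records:
        by_species.setdefault(r.species_id, {})[r.population_id] = r

    manifest = pd.read_csv(data_manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValidationError(f"{data_manifest_path}: manifest missing {sorted(missing)}")
    base = Path(data_manifest_path).parent

    datasets: list[SequenceDataset | MicrosatDataset] = []
    for row in manifest.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = base / path
        if not path.exists():
            raise ValidationError(f"manifest references missing file {path}")
        species = str(row.species_id)
        if row.marker_type == "sequence":
            ds = read_fasta_alignment(path, species, str(row.marker_id))
        elif row.marker_type == "microsat":
            ds = read_genotype_csv(path, species)
        else:
            raise ValidationError(
                f"{data_manifest_path}: unknown marker_type {row.marker_type!r}")
        pops = by_species.get(species, {})
        for pop in ds.population_ids:
            if pop not in pops:
                raise ValidationError(
                    f"{path}: population {pop!r} of species {species} absent from "
                    f"population table")
            if ds.marker_type == "sequence":
                n = len(ds.alignment[pop])
                expected = pops[pop].n_individuals
                if n != expected:
                    raise ValidationError(
                        f"{path}: population {pop!r} has {n} sequences but the "
                        f"population table records {expected} individuals")
        datasets.append(ds)
    return datasets, records


def apply_inclusion_filters(
    datasets: list[SequenceDataset | MicrosatDataset],
    records: list[PopulationRecord],
    min_populations: int = 10,
    min_individuals: int = 3,
) -> tuple[list, list[PopulationRecord], FilterReport]:
    """Study-inclusion rules applied before any statistics.

    Populations with fewer than *min_individuals* sampled individuals are
    dropped (small samples bias the diversity estimators); species left with
    fewer than *min_populations* populations are dropped entirely.
    """
    report = FilterReport()
    rec_by_key = {(r.species_id, r.population_id): r for r in records}
    kept_datasets = []
    kept_records: dict[tuple[str, str], PopulationRecord] = {}
    for ds in datasets:
        report.input_counts[ds.species_id] = len(ds.population_ids)
        surviving = []
        for pop in ds.population_ids:
            rec = rec_by_key[(ds.species_id, pop)]
            if rec.n_individuals < min_individuals:
                report.excluded_populations.append(
                    (ds.species_id, pop,
                     f"n_individuals={rec.n_individuals} < {min_individuals}"))
            else:
                surviving.append(pop)
        if len(surviving) < min_populations:
            report.excluded_species.append(
                (ds.species_id,
                 f"{len(surviving)} populations after filtering < {min_populations}"))
            continue
        if ds.marker_type == "sequence":
            filtered = SequenceDataset(
                ds.species_id, ds.marker_id,
                {p: ds.alignment[p] for p in surviving})
        else:
            filtered = MicrosatDataset(
                ds.species_id, ds.loci,
                {p: ds.genotypes[p] for p in surviving})
        kept_datasets.append(filtered)
        report.retained[ds.species_id] = len(surviving)
        for p in surviving:
            kept_records[(ds.species_id, p)] = rec_by_key[(ds.species_id, p)]
    if datasets and not kept_datasets:
        raise ValidationError("no data after filtering: every species excluded")
    return kept_datasets, list(kept_records.values()), report


# ---------------------------------------------------------------------------
# ESRI ASCII grid rasters


_HEADER_KEYS = ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value"]


def write_raster(landscape: GeneticLandscape, path: str | Path,
                 fmt: str = "esri_ascii") -> None:
    """Write a landscape as an ESRI ASCII grid (row 0 = northernmost)."""
    if fmt != "esri_ascii":
        raise ValueError(f"unsupported raster format {fmt!r}")
    g = landscape.grid
    body = np.where(landscape.mask, landscape.values, landscape.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n"
                 f"nrows {g.nrows}\n"
                 f"xllcorner {g.origin_x:.10g}\n"
                 f"yllcorner {g.origin_y:.10g}\n"
                 f"cellsize {g.cell_size:.10g}\n"
                 f"NODATA_value {landscape.nodata:.10g}\n")
        np.savetxt(fh, body, fmt="%.6f")


def read_raster(path: str | Path, crs: str = "planar",
                statistic: str = "divergence",
                species_id: str = "multi-species") -> GeneticLandscape:
    header: dict[str, float] = {}
    with open(path) as fh:
        for key in _HEADER_KEYS:
            line = fh.readline().split()
            if len(line) != 2 or line[0].lower() != key.lower():
                raise ValidationError(f"{path}: malformed header, expected {key!r}")
            header[key] = float(line[1])
        body = np.loadtxt(fh, ndmin=2)
    grid = GridSpec(header["xllcorner"], header["yllcorner"], header["cellsize"],
                    int(header["ncols"]), int(header["nrows"]), crs=crs)
    if body.shape != (grid.nrows, grid.ncols):
        raise ValidationError(
            f"{path}: body shape {body.shape} does not match header "
            f"({grid.nrows}, {grid.ncols})")
    nodata = header["NODATA_value"]
    values = np.where(np.isclose(body, nodata), np.nan, body)
    return GeneticLandscape(grid, values, statistic=statistic,
                            species_id=species_id, nodata=nodata)
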