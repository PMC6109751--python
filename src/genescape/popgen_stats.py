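"""Population-genetic statistics.

Within-population diversity:

* gene diversity — Nei's unbiased estimator (n/(n-1)) (1 - sum p_i^2) on
  haplotype counts (Hd, sequence data) or per-locus allele counts averaged
  over loci (HE, microsatellites);
* nucleotide diversity pi — mean per-site pairwise difference under pairwise
  deletion of gapped/ambiguous sites.

Among-population divergence: pairwise Phi_ST/F_ST from a two-population
AMOVA on a gene-copy distance matrix. Distance modes:

* ``molecular_distance`` (Phi_ST) — number of differing sites between
  haplotypes (sequence default);
* ``haplotype_identity`` (conventional F_ST) — 0/1 haplotype identity;
* ``allele_identity_multilocus`` (microsatellite F_ST) — per-locus 0/1 allele
  identity averaged over loci scored in both populations, each individual
  contributing its two allele copies.

Raw statistics are finally rescaled per species x marker by the maximum
observed value so that heterogeneous markers become comparable across
species before interpolation. Negative divergence estimates (sampling noise
around zero differentiation) are clamped to 0 before normalization; the raw
values are kept for audit.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING_ALLELE, MicrosatDataset, SequenceDataset

log = logging.getLogger(__name__)

FST_MODES = ("molecular_distance", "haplotype_identity", "allele_identity_multilocus")


# ---------------------------------------------------------------------------
# result containers


@dataclass
class WithinPopDiversity:
    species_id: str
    marker_id: str
    population_id: str
    gene_diversity: float          # Hd (sequences) or HE (microsats), in [0, 1]
    sequence_diversity: float      # pi per site; NaN for microsatellites


@dataclass
class PairwiseDivergence:
    """Symmetric pairwise divergence matrix for one species x marker."""

    species_id: str
    marker_id: str
    population_ids: list[str]
    matrix_raw: np.ndarray         # may contain negatives and NaN
    mode: str

    matrix: np.ndarray = field(init=False)  # clamped to [0, 1]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix_raw, dtype=float)
        if m.shape != (len(self.population_ids),) * 2:
            raise ValueError("matrix shape does not match population_ids")
        if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T)):
            raise ValueError("pairwise divergence matrix must be symmetric")
        self.matrix_raw = m
        self.matrix = np.clip(m, 0.0, 1.0)
        np.fill_diagonal(self.matrix, 0.0)

    def to_frame(self, normalized: np.ndarray | None = None) -> pd.DataFrame:
        """Long format, one row per unordered pair."""
        rows = []
        pops = self.population_ids
        for i, j in itertools.combinations(range(len(pops)), 2):
            rows.append({
                "species_id": self.species_id, "marker_id": self.marker_id,
                "pop_a": pops[i], "pop_b": pops[j],
                "fst_raw": self.matrix_raw[i, j], "fst": self.matrix[i, j],
                "fst_norm": normalized[i, j] if normalized is not None else np.nan,
                "mode": self.mode,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# within-population diversity


def gene_diversity(allele_counts, unbiased: bool = True) -> float:
    """Nei's gene diversity from haplotype/allele counts.

    Returns (n/(n-1)) (1 - sum p_i^2); the probability that two gene copies
    drawn without replacement differ. NaN if fewer than two copies.
    """
    counts = np.asarray([c for c in allele_counts if c > 0], dtype=float)
    n = counts.sum()
    if n < 2:
        log.warning("gene_diversity undefined for n=%d gene copies", int(n))
        return float("nan")
    h = 1.0 - float(np.square(counts / n).sum())
    return h * n / (n - 1.0) if unbiased else h


def expected_heterozygosity(table: pd.DataFrame, loci: list[str],
                            unbiased: bool = True) -> float:
    """HE for one population: per-locus gene diversity averaged over loci.

    *table* holds individual_id/locus_id/allele_a/allele_b rows. Loci with
    fewer than two scored allele copies are skipped; NaN if no locus
    qualifies.
    """
    per_locus = []
    for locus in loci:
        rows = table[table["locus_id"] == locus]
        alleles = pd.concat([rows["allele_a"], rows["allele_b"]])
        alleles = alleles[alleles != MISSING_ALLELE]
        if len(alleles) < 2:
            continue
        per_locus.append(gene_diversity(alleles.value_counts().to_numpy(),
                                        unbiased=unbiased))
    return float(np.mean(per_locus)) if per_locus else float("nan")


def _pair_site_diff(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """(differences, compared sites) between two encoded sequences.

    Sites where either sequence carries a gap or N are excluded (pairwise
    deletion). Sequences are uint8 arrays of the raw characters.
    """
    valid = ~(np.isin(a, _AMBIGUOUS) | np.isin(b, _AMBIGUOUS))
    return int(np.count_nonzero(a[valid] != b[valid])), int(valid.sum())


_AMBIGUOUS = np.frombuffer(b"-N", dtype=np.uint8)


def encode_sequences(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).upper().encode(), dtype=np.uint8
                         ).reshape(len(seqs), -1) if seqs else np.empty((0, 0), np.uint8)


def nucleotide_diversity(alignment: list[str]) -> float:
    """Per-site nucleotide diversity pi.

    pi = [ sum_{i<j} d_ij / C(n,2) ] / L_eff with d_ij the pairwise-deletion
    difference count and L_eff the mean per-pair compared length. NaN if
    fewer than two sequences; 0 for a monomorphic population.
    """
    n = len(alignment)
    if n < 2:
        log.warning("nucleotide_diversity undefined for %d sequence(s)", n)
        return float("nan")
    enc = encode_sequences(alignment)
    diffs, lengths = [], []
    for i, j in itertools.combinations(range(n), 2):
        d, L = _pair_site_diff(enc[i], enc[j])
        diffs.append(d)
        lengths.append(L)
    l_eff = float(np.mean(lengths))
    if l_eff == 0:
        return float("nan")
    return float(np.mean(diffs)) / l_eff


# ---------------------------------------------------------------------------
# pairwise AMOVA Phi_ST / F_ST


def amova_phi_st(dist: np.ndarray, n_a: int, n_b: int) -> float:
    """Two-population AMOVA fixation index from a gene-copy distance matrix.

    *dist* is the (n_a+n_b) x (n_a+n_b) matrix of squared inter-copy
    distances (for difference counts the count itself plays the role of the
    squared distance, the convention of distance-based AMOVA on haplotype
    data), population A copies first.
    Variance components follow the standard sums-of-squared-deviations
    partition with K=2 groups:

        SSD_total  = sum_{i<j} d_ij / N
        SSD_within = sum over populations of within-pair sums / n_k
        sigma2_w   = SSD_within / (N - 2)
        sigma2_a   = (SSD_among - sigma2_w) / n'
        n'         = (N - (n_a^2 + n_b^2)/N) / (K - 1)

    Returns sigma2_a / (sigma2_a + sigma2_w), unclamped (may be negative).
    Zero total variance (all copies identical) yields 0.
    """
    dist = np.asarray(dist, dtype=float)
    n = n_a + n_b
    if dist.shape != (n, n):
        raise ValueError("distance matrix does not match population sizes")
    if n_a < 2 or n_b < 2:
        raise ValueError("each population needs >= 2 gene copies")
    iu = np.triu_indices(n, k=1)
    ssd_total = dist[iu].sum() / n
    a_block = dist[:n_a, :n_a]
    b_block = dist[n_a:, n_a:]
    ssd_within = (a_block[np.triu_indices(n_a, k=1)].sum() / n_a
                  + b_block[np.triu_indices(n_b, k=1)].sum() / n_b)
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (n - 2)
    n_prime = (n - (n_a ** 2 + n_b ** 2) / n)  # / (K-1) with K=2
    sigma_a = (ssd_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return float(sigma_a / denom)


def sequence_distance_matrix(seqs_a: list[str], seqs_b: list[str],
                             mode: str = "molecular_distance") -> np.ndarray:
    """Inter-copy distance matrix for two populations' haplotypes."""
    seqs = seqs_a + seqs_b
    enc = encode_sequences(seqs)
    n = len(seqs)
    d = np.zeros((n, n))
    if mode == "molecular_distance":
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = _pair_site_diff(enc[i], enc[j])[0]
    elif mode == "haplotype_identity":
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = float(seqs[i] != seqs[j])
    else:
        raise ValueError(f"unknown sequence distance mode {mode!r}")
    return d


def _microsat_copy_table(table: pd.DataFrame, loci: list[str]) -> np.ndarray:
    """(2 * n_individuals, n_loci) allele labels, MISSING_ALLELE for gaps.

    Each individual contributes its two allele slots as two gene copies.
    """
    pivot_a = table.pivot_table(index="individual_id", columns="locus_id",
                                values="allele_a", aggfunc="first")
    pivot_b = table.pivot_table(index="individual_id", columns="locus_id",
                                values="allele_b", aggfunc="first")
    rows = []
    for ind in pivot_a.index:
        for pivot in (pivot_a, pivot_b):
            rows.append([int(pivot.loc[ind, lc]) if lc in pivot.columns
                         and pd.notna(pivot.loc[ind, lc]) else MISSING_ALLELE
                         for lc in loci])
    return np.asarray(rows, dtype=int)


def microsat_distance_matrix(table_a: pd.DataFrame, table_b: pd.DataFrame,
                             loci: list[str]) -> tuple[np.ndarray, int, int, int]:
    """Multilocus allele-identity distances between two populations.

    A locus is used only if both populations have at least one scored copy
    there; within a copy pair, loci missing in either copy are skipped and
    the 0/1 identity sum is rescaled to the shared-locus count, keeping
    distances comparable across copy pairs with different completeness.

    Returns (distance matrix, n_copies_a, n_copies_b, n_shared_loci).
    """
    copies_a = _microsat_copy_table(table_a, loci)
    copies_b = _microsat_copy_table(table_b, loci)
    scored_a = (copies_a != MISSING_ALLELE).any(axis=0)
    scored_b = (copies_b != MISSING_ALLELE).any(axis=0)
    shared = scored_a & scored_b
    n_shared = int(shared.sum())
    if n_shared == 0:
        return np.zeros((0, 0)), len(copies_a), len(copies_b), 0
    copies = np.vstack([copies_a, copies_b])[:, shared]
    present = copies != MISSING_ALLELE
    n = len(copies)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = present[i] & present[j]
        m = int(both.sum())
        if m == 0:
            continue
        diff = int(np.count_nonzero(copies[i, both] != copies[j, both]))
        d[i, j] = d[j, i] = diff * n_shared / m
    return d, len(copies_a), len(copies_b), n_shared


def pairwise_fst(pop_a, pop_b, distance_mode: str = "molecular_distance",
                 loci: list[str] | None = None) -> float:
    """Pairwise Phi_ST/F_ST between two populations (unclamped).

    *pop_a*/*pop_b* are lists of haplotype strings for sequence modes, or
    genotype DataFrames (with *loci*) for ``allele_identity_multilocus``.
    Returns NaN when no informative data remain.
    """
    if distance_mode == "allele_identity_multilocus":
        if loci is None:
            raise ValueError("microsatellite mode requires the locus list")
        d, n_a, n_b, n_shared = microsat_distance_matrix(pop_a, pop_b, loci)
        if n_shared == 0:
            log.warning("no locus scored in both populations; F_ST undefined")
            return float("nan")
    elif distance_mode in ("molecular_distance", "haplotype_identity"):
        d = sequence_distance_matrix(list(pop_a), list(pop_b), distance_mode)
        n_a, n_b = len(pop_a), len(pop_b)
    else:
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    if n_a < 2 or n_b < 2:
        log.warning("pairwise F_ST undefined with <2 gene copies on one side")
        return float("nan")
    return amova_phi_st(d, n_a, n_b)


# ---------------------------------------------------------------------------
# per-species orchestration and normalization


def compute_species_estimates(
    dataset: SequenceDataset | MicrosatDataset,
    fst_mode: str | None = None,
    unbiased_he: bool = True,
) -> tuple[list[WithinPopDiversity], PairwiseDivergence]:
    """All statistics for one species x marker.

    Sequence datasets yield Hd and pi per population; microsatellite
    datasets yield HE only. One full pairwise divergence matrix is computed
    in the marker's default mode unless *fst_mode* overrides it.
    """
    pops = dataset.population_ids
    within: list[WithinPopDiversity] = []
    if dataset.marker_type == "sequence":
        mode = fst_mode or "molecular_distance"
        for pop in pops:
            seqs = dataset.alignment[pop]
            counts = pd.Series(seqs).value_counts().to_numpy()
            within.append(WithinPopDiversity(
                dataset.species_id, dataset.marker_id, pop,
                gene_diversity(counts), nucleotide_diversity(seqs)))
        get = lambda p: dataset.alignment[p]
        loci = None
    else:
        mode = fst_mode or "allele_identity_multilocus"
        for pop in pops:
            within.append(WithinPopDiversity(
                dataset.species_id, dataset.marker_id, pop,
                expected_heterozygosity(dataset.genotypes[pop], dataset.loci,
                                        unbiased=unbiased_he),
                float("nan")))
        get = lambda p: dataset.genotypes[p]
        loci = dataset.loci

    m = np.zeros((len(pops), len(pops)))
    for i, j in itertools.combinations(range(len(pops)), 2):
        m[i, j] = m[j, i] = pairwise_fst(get(pops[i]), get(pops[j]),
                                         distance_mode=mode, loci=loci)
    pairwise = PairwiseDivergence(dataset.species_id, dataset.marker_id,
                                  pops, m, mode)
    return within, pairwise


def _normalize(values: np.ndarray) -> np.ndarray:
    """Divide by the max; a degenerate all-zero (or all-NaN) set maps to 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vmax = np.nanmax(values) if np.isfinite(values).any() else np.nan
    if not np.isfinite(vmax) or vmax == 0.0:
        if np.isfinite(values).any():
            log.warning("all values zero; normalized values set to 0")
        out = np.where(np.isfinite(values), 0.0, np.nan)
        return out
    return values / vmax


def normalize_by_species_max(
    within: list[WithinPopDiversity],
    pairwise: PairwiseDivergence,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Max-rescale one species x marker's statistics into [0, 1].

    Gene diversity, sequence diversity and the clamped divergence matrix are
    each divided by their own within-marker maximum. Returns the
    within-population table (columns ``*_norm`` added) and the normalized
    divergence matrix.
    """
    df = pd.DataFrame([vars(w) for w in within])
    df["gene_diversity_norm"] = _normalize(df["gene_diversity"].to_numpy(float))
    df["sequence_diversity_norm"] = _normalize(df["sequence_diversity"].to_numpy(float))
    fst_norm = _normalize(pairwise.matrix.copy())
    return df, fst_norm
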