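"""Per-individual density, allele-frequency and frameshift statistics.

All per-individual statistics follow the same recipe: compute the
quantity for each individual over that individual's called variants,
then average across individuals. Densities are expressed in variants
per megabase of the analyzed region; allele frequencies are alternate
allele frequencies (AAF) over called chromosomes, with MAF =
min(AAF, 1 - AAF).

The 7 allele-frequency bins are logarithmic with edges
{0.1%, 0.5%, 1%, 5%, 10%, 50%} inside (0, 1], chosen so that the
reporting thresholds used throughout (<1% rare, 1-10%, >=10% common)
are unions of whole bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .core import GT_HET, GT_HOM_ALT, GenotypeMatrix, is_frameshift

__all__ = [
    "AF_BIN_EDGES",
    "AFSpectrum",
    "alt_allele_frequency",
    "minor_allele_frequency",
    "af_bin",
    "variant_density",
    "density_by_af_bin",
    "density_by_length",
    "percent_heterozygous",
    "compare_maf_distributions",
    "deletion_insertion_ratio",
    "frameshift_fraction",
]

#: 8 ascending edges defining 7 left-open right-closed bins on (0, 1].
AF_BIN_EDGES = (0.0, 0.001, 0.005, 0.01, 0.05, 0.10, 0.50, 1.0)


@dataclass
class AFSpectrum:
    """Mean per-individual density (variants/Mb) across the 7 AF bins."""

    bin_edges: tuple[float, ...]
    densities: np.ndarray  # length 7

    @property
    def total_density(self) -> float:
        return float(self.densities.sum())


def alt_allele_frequency(genotypes: np.ndarray) -> float:
    """AAF of one locus from coded genotypes (0, 1, 2; -1 missing).

    Alternate allele count over 2x the number of called samples;
    missing genotypes are excluded from the denominator.
    """
    g = np.asarray(genotypes)
    called = g >= 0
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("all genotypes missing: AAF undefined")
    return float(g[called].sum()) / (2 * n_called)


def minor_allele_frequency(genotypes: np.ndarray) -> float:
    aaf = alt_allele_frequency(genotypes)
    return min(aaf, 1.0 - aaf)


def af_bin(aaf: float, edges=AF_BIN_EDGES) -> int:
    """Bin index 0..6 for an AAF in (0, 1]; left-open, right-closed."""
    if not 0.0 < aaf <= 1.0:
        raise ValueError(f"AAF {aaf} outside (0, 1]")
    inner = np.asarray(edges[1:-1])
    return int(np.searchsorted(inner, aaf, side="left"))


def variant_density(per_individual_counts, region_bp: float) -> float:
    """Mean per-individual variant density in variants per Mb."""
    if region_bp <= 0:
        raise ValueError("region size must be positive")
    counts = np.asarray(per_individual_counts, dtype=float)
    return float(counts.mean() / (region_bp / 1e6))


def _carried(matrix: GenotypeMatrix) -> np.ndarray:
    return matrix.genotypes > 0  # (loci, samples) non-reference calls


def density_by_af_bin(
    matrix: GenotypeMatrix, region_bp: float, edges=AF_BIN_EDGES
) -> AFSpectrum:
    """Per-individual density stratified over the 7 AF bins.

    The per-bin densities sum to the unstratified total density since
    the bins partition (0, 1] and every carried locus has AAF > 0.
    """
    bins = np.array(
        [af_bin(alt_allele_frequency(matrix.genotypes[i]), edges) for i in range(matrix.n_loci)]
    )
    carried = _carried(matrix)
    densities = np.zeros(len(edges) - 1)
    for b in range(len(edges) - 1):
        counts = carried[bins == b].sum(axis=0)
        densities[b] = variant_density(counts, region_bp)
    return AFSpectrum(bin_edges=tuple(edges), densities=densities)


def density_by_length(
    matrix: GenotypeMatrix, region_bp: float
) -> dict[int, float]:
    """Mean per-individual density for each signed INDEL length."""
    lengths = np.array([r.length for r in matrix.loci])
    carried = _carried(matrix)
    out = {}
    for length in np.unique(lengths):
        counts = carried[lengths == length].sum(axis=0)
        out[int(length)] = variant_density(counts, region_bp)
    return out


def percent_heterozygous(matrix: GenotypeMatrix) -> float:
    """Mean over individuals of het / (het + hom-alt) x 100.

    Individuals with zero variant calls are excluded from the average.
    """
    het = (matrix.genotypes == GT_HET).sum(axis=0).astype(float)
    hom = (matrix.genotypes == GT_HOM_ALT).sum(axis=0).astype(float)
    total = het + hom
    ok = total > 0
    if not ok.any():
        raise ValueError("no individual has a variant call")
    return float((het[ok] / total[ok]).mean() * 100.0)


def compare_maf_distributions(setA_mafs, setB_mafs) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two MAF samples.

    Normal approximation with tie correction at usable sample sizes;
    exact method for tiny inputs. Returns (U statistic, p-value).
    """
    a = np.asarray(setA_mafs, dtype=float)
    b = np.asarray(setB_mafs, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both MAF samples must be non-empty")
    # "auto": tie-corrected normal approximation at usable sizes, exact
    # enumeration for tiny tie-free inputs (e.g. n = 1 vs n = 1)
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def deletion_insertion_ratio(matrix: GenotypeMatrix) -> float:
    """Mean over individuals of (#deletions carried) / (#insertions carried).

    Individuals carrying zero insertions are excluded from the average.
    """
    dels = np.array([r.is_deletion for r in matrix.loci])
    carried = _carried(matrix)
    n_del = carried[dels].sum(axis=0).astype(float)
    n_ins = carried[~dels].sum(axis=0).astype(float)
    ok = n_ins > 0
    if not ok.any():
        raise ValueError("no individual carries an insertion")
    return float((n_del[ok] / n_ins[ok]).mean())


def frameshift_fraction(records, per_individual_matrix: GenotypeMatrix | None = None):
    """Fraction of loci whose length is not a multiple of three.

    With a genotype matrix, additionally returns the mean per-individual
    frameshift fraction over each individual's carried loci.
    """
    records = list(records)
    if not records:
        raise ValueError("empty call set")
    flags = np.array([is_frameshift(r.length) for r in records])
    overall = float(flags.mean())
    if per_individual_matrix is None:
        return overall
    carried = _carried(per_individual_matrix)
    per_ind = []
    for s in range(per_individual_matrix.n_samples):
        mask = carried[:, s]
        if mask.sum() == 0:
            continue
        per_ind.append(flags[mask].mean())
    return overall, float(np.mean(per_ind))
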