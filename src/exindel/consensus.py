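"""Consensus scoring of union INDEL alleles with a random forest.

The union call set trades specificity for sensitivity; the consensus
step recovers specificity by scoring every union allele with a random
forest trained on alleles labeled true/false by overlap with an
orthogonal truth call set, keeping alleles whose predicted probability
of being real is at least 0.4 (the default operating point), then
regenotyping kept sites from read counts and pruning sites no longer
called in any individual.

Six covariates drive the classifier: the number of supporting callers,
the mean rank-normalized caller quality, mean site depth over carriers,
the variant-read ratio, the longest homopolymer run in the +/-10 bp
reference context (the dominant INDEL artifact mode), and the absolute
allele length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier

from .core import GT_MISSING, GenotypeMatrix, IndelRecord
from .union import UnionRecord

__all__ = [
    "COVARIATE_NAMES",
    "ConsensusModel",
    "homopolymer_run",
    "build_covariates",
    "label_training",
    "train_consensus_model",
    "apply_consensus",
    "regenotype",
    "DEFAULT_THRESHOLD",
]

COVARIATE_NAMES = (
    "n_callers",
    "norm_qual_mean",
    "site_depth",
    "variant_read_ratio",
    "homopolymer_run",
    "abs_length",
)

#: Alleles with probability below this are excluded from the consensus.
DEFAULT_THRESHOLD = 0.4

_CONTEXT_BP = 10


def homopolymer_run(reference, chrom: str, pos1: int, flank: int = _CONTEXT_BP) -> int:
    """Longest single-base run in the +/-``flank`` bp window around ``pos1``."""
    window = reference.fetch(chrom, pos1 - 1 - flank, pos1 + flank).upper()
    if not window:
        return 0
    best = run = 1
    for prev, cur in zip(window, window[1:]):
        run = run + 1 if cur == prev and cur != "N" else 1
        best = max(best, run)
    return best


def build_covariates(union: list[UnionRecord], reference) -> pd.DataFrame:
    """Assemble the 6-covariate table for a list of union alleles."""
    rows = []
    for rec in union:
        rows.append(
            (
                rec.n_callers,
                rec.norm_qual_mean,
                rec.site_depth,
                rec.variant_read_ratio,
                homopolymer_run(reference, rec.indel.chrom, rec.indel.pos),
                abs(rec.indel.length),
            )
        )
    df = pd.DataFrame(rows, columns=list(COVARIATE_NAMES))
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("non-finite covariate encountered")
    return df


def label_training(
    union: list[UnionRecord],
    truth_keys,
    reference,
) -> pd.DataFrame:
    """Label union alleles against a truth set for classifier training.

    An allele whose indel key appears in ``truth_keys`` is labeled 1
    (true positive), otherwise 0. Returns the covariate table with a
    ``label`` column appended.
    """
    truth_keys = set(truth_keys)
    if not union:
        raise ValueError("empty union call set")
    covariates = build_covariates(union, reference)
    labels = np.fromiter(
        (1 if rec.key() in truth_keys else 0 for rec in union),
        dtype=np.int64,
        count=len(union),
    )
    if labels.sum() == 0:
        raise ValueError(
            "no union allele overlaps the truth set: check normalization, "
            "sample overlap and target regions"
        )
    covariates["label"] = labels
    return covariates


@dataclass
class ConsensusModel:
    """A fitted consensus classifier plus its training metadata."""

    classifier: RandomForestClassifier
    covariate_names: tuple[str, ...]
    seed: int
    n_trees: int
    label_counts: dict[int, int] = field(default_factory=dict)

    def predict_proba(self, covariates: pd.DataFrame) -> np.ndarray:
        """Probability that each allele is a true INDEL, in [0, 1]."""
        X = covariates.loc[:, list(self.covariate_names)].to_numpy(dtype=float)
        return self.classifier.predict_proba(X)[:, 1]


def train_consensus_model(
    labeled: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
) -> ConsensusModel:
    """Fit the random forest on a labeled covariate table.

    The reported probability is the fraction of trees voting "true".
    Deterministic for a fixed seed. Raises if only one class is present.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    y = labeled["label"].to_numpy(dtype=np.int64)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training labels contain a single class ({classes})")
    X = labeled.loc[:, list(COVARIATE_NAMES)].to_numpy(dtype=float)
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    clf.fit(X, y)
    return ConsensusModel(
        classifier=clf,
        covariate_names=COVARIATE_NAMES,
        seed=seed,
        n_trees=n_trees,
        label_counts={int(c): int((y == c).sum()) for c in classes},
    )


def apply_consensus(
    union: list[UnionRecord],
    model: ConsensusModel,
    reference,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[UnionRecord], np.ndarray]:
    """Score union alleles and keep those with probability >= threshold.

    Probability exactly at the threshold is retained (only strictly
    lower probabilities are excluded). Returns the kept records and the
    probabilities of *all* input alleles, in input order.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    if not union:
        return [], np.empty(0)
    probs = model.predict_proba(build_covariates(union, reference))
    kept = [rec for rec, p in zip(union, probs) if p >= threshold]
    return kept, probs


def genotype_likelihoods(
    variant_reads: np.ndarray,
    depth: np.ndarray,
    error_rate: float = 0.02,
    het_ratio: float = 0.5,
) -> np.ndarray:
    """Log-likelihoods of (0/0, 0/1, 1/1) under a binomial read model.

    The alt-read count is binomial(depth, p) with p = ``error_rate`` for
    hom-ref, ``het_ratio`` for het, 1 - ``error_rate`` for hom-alt.
    Shapes broadcast; the genotype axis is appended last.
    """
    v = np.asarray(variant_reads)[..., None]
    d = np.asarray(depth)[..., None]
    p = np.array([error_rate, het_ratio, 1.0 - error_rate])
    return binom.logpmf(v, d, p)


def regenotype(
    sites: list[IndelRecord],
    samples: list[str],
    depth: np.ndarray,
    variant_reads: np.ndarray,
    error_rate: float = 0.02,
    drop_uncalled: bool = True,
) -> GenotypeMatrix:
    """Maximum-likelihood diploid genotypes from per-sample read counts.

    Flat prior over the three genotypes; zero depth yields a missing
    genotype. When ``drop_uncalled`` is set, sites where every sample is
    0/0 or missing are removed from the output (they are no longer
    called in any individual).
    """
    depth = np.asarray(depth, dtype=np.int64)
    variant_reads = np.asarray(variant_reads, dtype=np.int64)
    if depth.shape != (len(sites), len(samples)):
        raise ValueError("depth shape does not match sites × samples")
    with np.errstate(divide="ignore"):
        ll = genotype_likelihoods(variant_reads, depth, error_rate)
    # genotype axis order matches the GT codes: 0/0 -> 0, 0/1 -> 1, 1/1 -> 2
    gts = np.argmax(ll, axis=-1).astype(np.int8)
    gts[depth == 0] = GT_MISSING
    matrix = GenotypeMatrix(sites, samples, gts, depth, variant_reads)
    if drop_uncalled:
        called = np.flatnonzero((matrix.genotypes > 0).any(axis=1))
        matrix = matrix.subset_loci(called)
    return matrix
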