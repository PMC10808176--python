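"""Genotype curation and genomic relationship machinery.

Marker filtering follows the documented rule order for a
genotyping-by-sequencing matrix of a selfing crop: monomorphic markers,
over-missing markers, markers with a rare minor-homozygote class, and
over-heterozygous markers are dropped; remaining missing calls are imputed
to the homozygous state of the more frequent (dominant) allele; finally a
minor-allele-frequency floor is applied.  Relationship matrices are the
VanRaden method-1 additive G and its Hadamard square H (additive-by-
additive epistasis).  Population structure is inspected via Rogers'
distances and principal coordinate analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = [
    "GenotypeMatrix",
    "FilterReport",
    "KinshipMatrix",
    "PCoAResult",
    "filter_markers",
    "compute_grm",
    "compute_epistatic",
    "rogers_distance",
    "pcoa",
]


@dataclass
class GenotypeMatrix:
    """Accessions × markers matrix of alternative-allele counts.

    ``codes`` is float with entries in {0, 1, 2} and ``nan`` for missing
    calls.  ``allele_freqs`` (alternative-allele frequency per marker) is
    filled after imputation.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray
    allele_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        n, m = self.codes.shape
        if n != len(self.accession_ids) or m != len(self.marker_ids):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.accession_ids)} accessions × {len(self.marker_ids)} markers"
            )
        valid = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def is_imputed(self) -> bool:
        return not np.isnan(self.codes).any()

    def subset_accessions(self, labels: list[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in labels if a not in pos]
        if missing:
            raise KeyError(f"unknown accessions: {missing[:5]}")
        idx = [pos[a] for a in labels]
        return GenotypeMatrix(
            accession_ids=list(labels),
            marker_ids=list(self.marker_ids),
            codes=self.codes[idx],
            allele_freqs=None if self.allele_freqs is None else self.allele_freqs.copy(),
        )


@dataclass
class FilterReport:
    rules: list[tuple[str, int]] = field(default_factory=list)
    n_markers_in: int = 0
    n_markers_out: int = 0

    def as_dict(self) -> dict:
        return {
            "n_markers_in": self.n_markers_in,
            "n_markers_out": self.n_markers_out,
            "rules": [{"rule": r, "markers_removed": k} for r, k in self.rules],
        }


@dataclass
class KinshipMatrix:
    """Labeled symmetric PSD relationship matrix (additive or epistatic)."""

    labels: list[str]
    values: np.ndarray
    kind: str = "additive"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape inconsistent with labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("kinship matrix must be symmetric")

    def block(self, rows: list[str], cols: list[str]) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.labels)}
        ri = [pos[a] for a in rows]
        ci = [pos[a] for a in cols]
        return self.values[np.ix_(ri, ci)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def filter_markers(
    matrix: GenotypeMatrix,
    missing_max: float = 0.10,
    hom_count_min: float = 0.10,
    het_max: float = 0.01,
    maf_min: float = 0.01,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the marker quality rules in their documented order and impute.

    1. drop monomorphic markers (all non-missing calls one homozygote);
    2. drop markers with missing fraction > ``missing_max``;
    3. drop markers whose rarer homozygote class is < ``hom_count_min`` of
       non-missing calls;
    4. drop markers with heterozygote fraction > ``het_max``;
    5. impute missing calls to the homozygous code of the more frequent
       (dominant) allele;
    6. drop markers with post-imputation MAF < ``maf_min``.
    """
    codes = matrix.codes.copy()
    keep = np.arange(matrix.n_markers)
    report = FilterReport(n_markers_in=matrix.n_markers)

    def apply(rule: str, drop_mask: np.ndarray) -> None:
        nonlocal codes, keep
        report.rules.append((rule, int(drop_mask.sum())))
        codes = codes[:, ~drop_mask]
        keep = keep[~drop_mask]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-nan columns
        obs = ~np.isnan(codes)
        n_obs = obs.sum(axis=0)
        n_hom0 = np.nansum(codes == 0.0, axis=0)
        n_hom2 = np.nansum(codes == 2.0, axis=0)
        mono = (n_obs == 0) | (n_hom0 == n_obs) | (n_hom2 == n_obs)
    apply("monomorphic", mono)

    miss_frac = np.isnan(codes).mean(axis=0)
    apply("missing_fraction", miss_frac > missing_max)

    obs = ~np.isnan(codes)
    n_obs = obs.sum(axis=0)
    n_hom0 = (codes == 0.0).sum(axis=0)
    n_hom2 = (codes == 2.0).sum(axis=0)
    rarer_hom = np.minimum(n_hom0, n_hom2) / np.maximum(n_obs, 1)
    apply("minor_homozygote_count", rarer_hom < hom_count_min)

    het_frac = (codes == 1.0).sum(axis=0) / np.maximum((~np.isnan(codes)).sum(axis=0), 1)
    apply("heterozygosity", het_frac > het_max)

    # dominant-allele imputation: missing -> homozygote of the majority allele
    with np.errstate(invalid="ignore"):
        alt_freq = np.nanmean(codes, axis=0) / 2.0
    fill = np.where(alt_freq >= 0.5, 2.0, 0.0)
    nan_mask = np.isnan(codes)
    codes[nan_mask] = np.broadcast_to(fill, codes.shape)[nan_mask]

    p = codes.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    apply("minor_allele_frequency", maf < maf_min)

    if codes.shape[1] == 0:
        raise ValueError("all markers removed by filtering")

    report.n_markers_out = codes.shape[1]
    out = GenotypeMatrix(
        accession_ids=list(matrix.accession_ids),
        marker_ids=[matrix.marker_ids[j] for j in keep],
        codes=codes,
        allele_freqs=codes.mean(axis=0) / 2.0,
    )
    return out, report


def compute_grm(matrix: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden method-1 additive genomic relationship matrix.

    G = Z Z' / (2 Σ_k p_k (1 - p_k)) with Z the column-centered codes
    (codes − 2 p_k) and p_k the alternative-allele frequency.
    """
    if not matrix.is_imputed:
        raise ValueError("genotype matrix must be imputed before computing G")
    if matrix.n_markers < 2:
        raise ValueError("need at least 2 markers")
    p = matrix.allele_freqs
    if p is None:
        p = matrix.codes.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("no polymorphism: sum p(1-p) is zero")
    z = matrix.codes - 2.0 * p
    g = (z @ z.T) / denom
    g = (g + g.T) / 2.0
    return KinshipMatrix(labels=list(matrix.accession_ids), values=g, kind="additive")


def compute_epistatic(G: KinshipMatrix) -> KinshipMatrix:
    """Additive-by-additive epistatic kinship H = G ∘ G (Hadamard square)."""
    if G.kind != "additive":
        raise ValueError("epistatic kinship is derived from an additive G")
    return KinshipMatrix(labels=list(G.labels), values=G.values**2, kind="epistatic")


def rogers_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Rogers' distances between genomic profiles.

    Per locus d_l(i, j) = sqrt(½ Σ_alleles (p_a^i − p_a^j)²) with
    individual allele frequencies in {0, ½, 1}; the distance is the mean
    over loci.  For biallelic codes this reduces to mean |c_i − c_j| / 2,
    bounded in [0, 1].
    """
    if not matrix.is_imputed:
        raise ValueError("genotype matrix must be imputed before computing distances")
    freqs = matrix.codes / 2.0
    d = pdist(freqs, metric="cityblock") / matrix.n_markers
    return DistanceMatrix(squareform(d), ids=matrix.accession_ids)


def pcoa(distances: DistanceMatrix | np.ndarray, n_axes: int = 2) -> PCoAResult:
    """Classical metric scaling of a distance matrix.

    Negative eigenvalues (non-Euclidean residue) are dropped; proportions
    of explained variation are computed over the positive eigenvalues
    only.  If fewer positive axes exist than requested, the result is
    truncated with a warning.
    """
    if not isinstance(distances, DistanceMatrix):
        distances = DistanceMatrix(np.asarray(distances, dtype=float))
    res = _skbio_pcoa(distances, method="eigh")
    eig = res.eigvals.to_numpy()
    pos = eig > 1e-12 * max(eig.max(), 1.0)
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    eig_pos = eig[pos][:n_axes]
    coords = res.samples.to_numpy()[:, :n_axes]
    prop = eig[pos][:n_axes] / eig[pos].sum()
    coords = pd.DataFrame(
        coords,
        index=list(distances.ids),
        columns=[f"PCo{i + 1}" for i in range(n_axes)],
    )
    return PCoAResult(coordinates=coords, eigenvalues=eig_pos, proportion_explained=prop)
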