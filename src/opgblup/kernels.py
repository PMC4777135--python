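"""Pedigree and genomic relationship kernels.

Builds the covariance structures used by the mixed-model machinery:

* ``A`` — the average numerator relationship matrix from a pedigree
  (tabular method), giving *expected* additive relationships
  (half-sibs 0.25, parent-offspring 0.5).
* ``G_add`` — the realized additive genomic relationship matrix
  (VanRaden), ``ZZ' / 2 Σ p_i(1-p_i)`` with ``Z`` the allele-frequency
  centered dosage matrix.
* ``G_dom`` — the dominance relationship matrix, either the classical
  (Vitezica) parameterization or the genotypic (Su) alternative.
* Hadamard products of the above for first-order epistatic terms
  (additive×additive, dominance×dominance, additive×dominance).

All kernels are returned as :class:`RelationshipKernel` objects carrying
sample identifiers, so downstream code can align them with phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencyVector",
    "PedigreeTable",
    "RelationshipKernel",
    "compute_allele_frequencies",
    "build_numerator_relationship",
    "build_additive_kernel",
    "build_dominance_kernel",
    "hadamard",
    "stabilize",
    "relationship_summaries",
]

_SYMMETRY_TOL = 1e-10


class ConfigurationError(ValueError):
    """Raised for invalid user-supplied configuration or parameters."""


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, bad ordering)."""


@dataclass
class GenotypeMatrix:
    """Individuals × biallelic loci dosage matrix.

    Dosages count copies of the alternative allele (0, 1 or 2); missing
    calls are stored as NaN.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosages: np.ndarray  # float array, NaN = missing

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.locus_ids):
            raise ValueError(
                f"dosage matrix is {self.dosages.shape} but there are "
                f"{len(self.sample_ids)} samples and {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != m:
            raise ValueError("duplicate locus ids")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosages must be 0/1/2 or missing; found {bad[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.dosages)

    def subset_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sample_ids,
            [self.locus_ids[i] for i in np.atleast_1d(index)],
            self.dosages[:, index],
        )


@dataclass
class AlleleFrequencyVector:
    """Per-locus frequency ``p`` of the counted (alternative) allele."""

    locus_ids: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1 or len(self.p) != len(self.locus_ids):
            raise ValueError("p must be 1-D and match locus_ids")
        if ((self.p <= 0) | (self.p >= 1)).any():
            raise ValueError("retained frequencies must be strictly in (0, 1)")

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p


@dataclass
class PedigreeTable:
    """Ordered pedigree rows ``(individual, dam, sire)``.

    Parents must be listed before their offspring; an unknown parent is
    ``None``.  Validation walks the rows once, so errors name the first
    offending row.
    """

    rows: list[tuple[str, str | None, str | None]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        norm = []
        for i, (ind, dam, sire) in enumerate(self.rows):
            ind = str(ind)
            dam = None if dam in (None, "", "0") or (isinstance(dam, float) and np.isnan(dam)) else str(dam)
            sire = None if sire in (None, "", "0") or (isinstance(sire, float) and np.isnan(sire)) else str(sire)
            if ind in seen:
                raise PedigreeError(f"row {i}: duplicate individual {ind!r}")
            for parent in (dam, sire):
                if parent is not None and parent not in seen:
                    raise PedigreeError(
                        f"row {i}: parent {parent!r} of {ind!r} not listed earlier "
                        "(pedigree must be ordered, parents before offspring)"
                    )
            if ind in (dam, sire):
                raise PedigreeError(f"row {i}: {ind!r} is its own parent")
            seen.add(ind)
            norm.append((ind, dam, sire))
        self.rows = norm

    @property
    def individuals(self) -> list[str]:
        return [r[0] for r in self.rows]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PedigreeTable":
        cols = {c.lower(): c for c in frame.columns}
        for needed in ("id", "dam", "sire"):
            if needed not in cols:
                raise PedigreeError(f"pedigree table lacks column {needed!r}")
        rows = [
            (r[cols["id"]], r[cols["dam"]], r[cols["sire"]])
            for _, r in frame.iterrows()
        ]
        return cls(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["id", "dam", "sire"])


@dataclass
class RelationshipKernel:
    """Labeled symmetric relationship matrix over named samples."""

    label: str
    sample_ids: list[str]
    matrix: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"kernel matrix {self.matrix.shape} does not match {n} sample ids"
            )
        asym = np.abs(self.matrix - self.matrix.T).max() if n else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:.2e})")
        # enforce exact symmetry so downstream eigen/cholesky is stable
        self.matrix = (self.matrix + self.matrix.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def align(self, ids: Sequence[str]) -> np.ndarray:
        """Submatrix over ``ids`` (in that order)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"kernel {self.label!r} lacks samples {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return self.matrix[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# allele frequencies

def compute_allele_frequencies(
    g: GenotypeMatrix,
    external: Mapping[str, float] | AlleleFrequencyVector | None = None,
) -> tuple[AlleleFrequencyVector, np.ndarray]:
    """Observed alternative-allele frequencies with monomorphic loci dropped.

    Parameters
    ----------
    g
        Genotype matrix; missing dosages are excluded from both numerator
        and denominator.
    external
        Optional externally supplied frequencies (e.g. founder
        frequencies) keyed by locus id, used instead of the observed
        sample frequencies.  Loci with an external frequency outside
        (0, 1) are dropped like monomorphic ones.

    Returns
    -------
    (freqs, retained)
        The frequency vector over retained loci and the integer index of
        those loci into ``g.locus_ids``.
    """
    if g.n_samples == 0 or g.n_loci == 0:
        raise ConfigurationError("empty genotype matrix")
    if external is not None:
        if isinstance(external, AlleleFrequencyVector):
            ext = dict(zip(external.locus_ids, external.p))
        else:
            ext = dict(external)
        missing = [l for l in g.locus_ids if l not in ext]
        if missing:
            raise ConfigurationError(
                f"external frequencies missing for loci {missing[:5]}"
            )
        p = np.array([ext[l] for l in g.locus_ids], dtype=float)
    else:
        with np.errstate(invalid="ignore"):
            counts = np.sum(np.isfinite(g.dosages), axis=0)
            sums = np.nansum(g.dosages, axis=0)
        all_missing = counts == 0
        if all_missing.any():
            warnings.warn(
                f"{int(all_missing.sum())} loci have no called genotypes; dropped"
            )
        p = np.full(g.n_loci, np.nan)
        ok = counts > 0
        p[ok] = sums[ok] / (2.0 * counts[ok])
    polymorphic = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    retained = np.flatnonzero(polymorphic)
    if retained.size == 0:
        raise ConfigurationError("all loci monomorphic or missing; nothing retained")
    n_dropped = g.n_loci - retained.size
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} monomorphic/unusable loci")
    freqs = AlleleFrequencyVector(
        [g.locus_ids[i] for i in retained], p[retained]
    )
    return freqs, retained


# ---------------------------------------------------------------------------
# pedigree A-matrix

def build_numerator_relationship(ped: PedigreeTable) -> RelationshipKernel:
    """Average numerator relationship matrix by the tabular method.

    ``a_jj = 1 + a(dam_j, sire_j)/2`` (0 when either parent is unknown)
    and ``a_jk = (a(k, dam_j) + a(k, sire_j))/2`` for ``k < j``, unknown
    parents contributing 0.  Equals twice the coancestry (kinship)
    matrix of the pedigree.
    """
    ids = ped.individuals
    pos = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    parents = [
        (pos[d] if d is not None else -1, pos[s] if s is not None else -1)
        for (_, d, s) in ped.rows
    ]
    for j in range(n):
        dj, sj = parents[j]
        if j:
            contrib = np.zeros(j)
            if dj >= 0:
                contrib += A[dj, :j]
            if sj >= 0:
                contrib += A[sj, :j]
            A[j, :j] = A[:j, j] = contrib / 2.0
        inbreeding = A[dj, sj] / 2.0 if dj >= 0 and sj >= 0 else 0.0
        A[j, j] = 1.0 + inbreeding
    return RelationshipKernel("A", ids, A)


# ---------------------------------------------------------------------------
# genomic kernels

def _aligned_dosages(g: GenotypeMatrix, f: AlleleFrequencyVector) -> np.ndarray:
    pos = {l: i for i, l in enumerate(g.locus_ids)}
    missing = [l for l in f.locus_ids if l not in pos]
    if missing:
        raise ConfigurationError(
            f"genotype matrix lacks loci {missing[:5]} named in frequency vector"
        )
    idx = np.array([pos[l] for l in f.locus_ids])
    return g.dosages[:, idx]


def build_additive_kernel(
    g: GenotypeMatrix, f: AlleleFrequencyVector
) -> RelationshipKernel:
    """VanRaden additive genomic relationship matrix.

    ``G_add = ZZ' / (2 Σ_i p_i q_i)`` where ``Z = M - 2p`` columnwise.
    Missing dosages are mean-imputed with ``2 p_i`` (a centered value of
    zero), which preserves the zero-centering of ``Z``.
    """
    M = _aligned_dosages(g, f)
    Z = M - 2.0 * f.p
    Z[~np.isfinite(Z)] = 0.0  # mean imputation
    denom = 2.0 * np.sum(f.p * f.q)
    if denom <= 0:
        raise ConfigurationError("no polymorphic loci: additive denominator is zero")
    G = (Z @ Z.T) / denom
    return RelationshipKernel("G_add", g.sample_ids, G, {"denominator": denom})


def build_dominance_kernel(
    g: GenotypeMatrix,
    f: AlleleFrequencyVector,
    parameterization: str = "classical",
) -> RelationshipKernel:
    """Dominance genomic relationship matrix.

    ``classical`` (Vitezica): the dominance design ``W`` codes the
    reference homozygote as ``-2p²``, the heterozygote as ``2pq`` and
    the alternative homozygote as ``-2q²``, and
    ``G_dom = WW' / Σ_i (2 p_i q_i)²``.

    ``genotypic`` (Su): heterozygosity indicator centered by its HWE
    expectation ``2pq``; denominator ``Σ_i 2 p_i q_i (1 - 2 p_i q_i)``.

    Missing genotypes take the zero (expected-value) code.
    """
    M = _aligned_dosages(g, f)
    p, q = f.p, f.q
    if parameterization == "classical":
        W = np.where(
            M == 0.0, -2.0 * p**2, np.where(M == 1.0, 2.0 * p * q, -2.0 * q**2)
        )
        W = np.where(np.isfinite(M), W, 0.0)
        denom = float(np.sum((2.0 * p * q) ** 2))
        label = "G_dom"
    elif parameterization == "genotypic":
        H = np.where(M == 1.0, 1.0, 0.0) - 2.0 * p * q
        W = np.where(np.isfinite(M), H, 0.0)
        denom = float(np.sum(2.0 * p * q * (1.0 - 2.0 * p * q)))
        label = "G_dom_geno"
    else:
        raise ConfigurationError(
            f"unknown dominance parameterization {parameterization!r}"
        )
    if denom <= 0:
        raise ConfigurationError("dominance denominator is zero")
    G = (W @ W.T) / denom
    return RelationshipKernel(
        label, g.sample_ids, G, {"denominator": denom, "parameterization": parameterization}
    )


_HADAMARD_LABELS = {
    ("G_add", "G_add"): "AxA",
    ("G_dom", "G_dom"): "DxD",
    ("G_add", "G_dom"): "AxD",
    ("G_dom", "G_add"): "AxD",
    ("A", "A"): "AxA",
}


def hadamard(k1: RelationshipKernel, k2: RelationshipKernel) -> RelationshipKernel:
    """Entrywise (Hadamard) product of two kernels over the same samples.

    Used to build first-order epistatic covariances: ``AxA = G_add#G_add``,
    ``DxD = G_dom#G_dom``, ``AxD = G_add#G_dom``.  The Schur product
    theorem guarantees the result is PSD when both factors are.
    """
    if k1.sample_ids != k2.sample_ids:
        raise ValueError(
            f"cannot multiply kernels over different samples "
            f"({k1.label!r} vs {k2.label!r})"
        )
    label = _HADAMARD_LABELS.get((k1.label, k2.label), f"{k1.label}x{k2.label}")
    return RelationshipKernel(label, k1.sample_ids, k1.matrix * k2.matrix)


def stabilize(k: RelationshipKernel, epsilon: float = 0.01) -> RelationshipKernel:
    """Shrink a kernel toward the identity: ``K* = (1-ε)K + εI``.

    Guarantees positive definiteness for PSD ``K`` and any ε > 0; used
    when a genomic kernel is numerically singular (e.g. fewer effective
    markers than individuals).
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ConfigurationError("epsilon must be in [0, 1]")
    out = (1.0 - epsilon) * k.matrix + epsilon * np.eye(k.n)
    meta = dict(k.meta, stabilize_epsilon=epsilon)
    result = RelationshipKernel(k.label, k.sample_ids, out, meta)
    if epsilon > 0.0:
        lam_min = float(np.linalg.eigvalsh(result.matrix)[0])
        if lam_min <= 0.0:
            raise ValueError(
                f"kernel {k.label!r} still not positive definite at "
                f"epsilon={epsilon} (min eigenvalue {lam_min:.3e}); "
                "increase epsilon"
            )
    return result


# ---------------------------------------------------------------------------
# summaries

@dataclass
class RelationshipSummary:
    within: pd.DataFrame  # value collection stats per scope
    histogram: pd.DataFrame
    within_values: np.ndarray
    among_values: np.ndarray
    flags: list[str]


def relationship_summaries(
    k: RelationshipKernel,
    family: Mapping[str, str],
    bin_width: float = 0.05,
) -> RelationshipSummary:
    """Within- vs among-family off-diagonal relationship distributions.

    For uncontaminated maternal half-sib families the within-family
    values cluster around 0.25 and among-family values around 0.0.
    """
    missing = [s for s in k.sample_ids if s not in family]
    if missing:
        raise KeyError(f"family map lacks samples {missing[:5]}")
    fam = np.array([str(family[s]) for s in k.sample_ids])
    iu, ju = np.triu_indices(k.n, k=1)
    vals = k.matrix[iu, ju]
    same = fam[iu] == fam[ju]
    within, among = vals[same], vals[~same]
    flags = []
    if within.size == 0:
        flags.append("no within-family pairs (singleton families only)")
    stats = pd.DataFrame(
        {
            "scope": ["within", "among"],
            "n_pairs": [within.size, among.size],
            "mean": [
                float(np.mean(within)) if within.size else np.nan,
                float(np.mean(among)) if among.size else np.nan,
            ],
            "sd": [
                float(np.std(within, ddof=1)) if within.size > 1 else np.nan,
                float(np.std(among, ddof=1)) if among.size > 1 else np.nan,
            ],
        }
    )
    if vals.size:
        lo = np.floor(vals.min() / bin_width) * bin_width
        hi = np.ceil(vals.max() / bin_width) * bin_width + bin_width / 2
        edges = np.arange(lo, hi + bin_width, bin_width)
    else:
        edges = np.array([0.0, bin_width])
    w_counts, _ = np.histogram(within, bins=edges)
    a_counts, _ = np.histogram(among, bins=edges)
    hist = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "within_count": w_counts,
            "among_count": a_counts,
        }
    )
    return RelationshipSummary(stats, hist, within, among, flags)
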