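"""Additive relationship matrices: A, A⁻¹, G, A_gg, blended Gₐ and H⁻¹.

The single-step evaluation combines the pedigree-expected relationships
(numerator relationship matrix ``A``) with marker-realized relationships
(genomic matrix ``G = WW'/q``) through

    H⁻¹ = A⁻¹ + [0 0; 0 Gₐ⁻¹ − A_gg⁻¹],

where ``A_gg`` is the genotyped-animal submatrix of ``A`` and
``Gₐ = βG + α`` is the genomic matrix rescaled so that its mean diagonal and
overall mean match those of ``A_gg``.  All matrices are kept dense: the
pipeline targets populations of a few thousand animals, where dense linear
algebra is both simplest and fastest.
"""
from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DataError, NumericalError, PedigreeError, PipelineOrderError, SingularSystemError
from .genotype_qc import GenotypeMatrix
from .pedigree import PedigreeTable
from .utils import symmetrize

logger = logging.getLogger(__name__)

KINDS = ("A", "A_inv", "G", "A_gg", "G_a", "H_inv", "H")

#: eigenvalue floor below which Gₐ is considered near-singular and jittered
GA_JITTER = 1e-8


@dataclass
class RelationshipMatrix:
    """A symmetric, id-indexed relationship matrix tagged by kind."""

    kind: str
    ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise DataError(f"unknown relationship-matrix kind {self.kind!r}")
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DataError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if n and np.max(np.abs(self.values - self.values.T)) > 1e-8:
            raise DataError(f"{self.kind} matrix is not symmetric")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def positions(self) -> dict[int, int]:
        return {int(a): i for i, a in enumerate(self.ids)}

    def submatrix(self, ids) -> np.ndarray:
        """Principal submatrix in the order of ``ids``."""
        pos = self.positions
        try:
            idx = np.array([pos[int(a)] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise DataError(f"id {exc.args[0]} absent from {self.kind} matrix") from exc
        return self.values[np.ix_(idx, idx)]


# ---------------------------------------------------------------------- #
# pedigree-based matrices
# ---------------------------------------------------------------------- #
def tabular_a(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    With animals in parents-first order, a_ij for j < i is the average of
    the relationships of i's parents with j, and the diagonal is
    ``1 + F_i`` with inbreeding ``F_i`` equal to half the parents'
    relationship.
    """
    n = len(pedigree)
    sire, dam = pedigree.parent_indices()
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * a[s, :i]
        if d >= 0:
            row += 0.5 * a[d, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(kind="A", ids=pedigree.ids, values=a)


def inbreeding(pedigree: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen–Luo ancestor-tracing method.

    For each animal the algorithm accumulates ``a_ii = Σ L_j² d_j`` over its
    ancestors, where L_j are the path coefficients and d_j the
    within-family (Mendelian-sampling) variances; ``F_i = a_ii − 1``.  Runs
    in O(ancestors) per animal and never forms A.
    """
    n = len(pedigree)
    sire, dam = pedigree.parent_indices()
    f = np.zeros(n)
    dvec = np.zeros(n)
    lvals = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        dvec[i] = (
            1.0
            - (0.25 * (1.0 + f[s]) if s >= 0 else 0.0)
            - (0.25 * (1.0 + f[d]) if d >= 0 else 0.0)
        )
        if s < 0 and d < 0:
            f[i] = 0.0
            continue
        # trace ancestors in decreasing (descendants-first) order
        heap = [-i]
        in_heap = {i}
        lvals[i] = 1.0
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = lvals[j]
            lvals[j] = 0.0
            aii += lj * lj * dvec[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    lvals[p] += 0.5 * lj
                    if p not in in_heap:
                        in_heap.add(p)
                        heapq.heappush(heap, -p)
            in_heap.discard(j)
        f[i] = aii - 1.0
    return f


def a_inverse(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Sparse-structured A⁻¹ from Henderson's rules with inbreeding.

    Uses Meuwissen–Luo inbreeding coefficients to form each animal's
    Mendelian-sampling variance d_i, then adds the classic
    ``[1, −½, −½]`` contribution scaled by 1/d_i for the (animal, sire,
    dam) triple.  Never forms A.
    """
    n = len(pedigree)
    sire, dam = pedigree.parent_indices()
    f = inbreeding(pedigree)
    fs = np.where(sire >= 0, f[np.maximum(sire, 0)], -1.0)
    fd = np.where(dam >= 0, f[np.maximum(dam, 0)], -1.0)
    dvec = 1.0 - 0.25 * (1.0 + fs) - 0.25 * (1.0 + fd)
    ainv = np.zeros((n, n))
    for i in range(n):
        alpha = 1.0 / dvec[i]
        parents = [p for p in (sire[i], dam[i]) if p >= 0]
        ainv[i, i] += alpha
        for p in parents:
            ainv[i, p] -= alpha / 2.0
            ainv[p, i] -= alpha / 2.0
        for p in parents:
            for q in parents:
                ainv[p, q] += alpha / 4.0
    return RelationshipMatrix(kind="A_inv", ids=pedigree.ids, values=ainv)


# ---------------------------------------------------------------------- #
# genomic matrices
# ---------------------------------------------------------------------- #
def genomic_relationship(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden-style genomic relationship matrix G = WW'/q.

    Each marker column is centered on its observed mean and standardized by
    its sample standard deviation (divisor n−1), so that
    ``trace(G) = n − 1`` exactly and the average diagonal is about one —
    the same scale as A.  Requires a fully imputed, polymorphic matrix.
    """
    m = np.asarray(genotypes.data, dtype=np.float64)
    if np.isnan(m).any():
        raise PipelineOrderError(
            "genotype matrix still has missing entries; run imputation first"
        )
    n, q = m.shape
    if q == 0:
        raise DataError("genotype matrix has no markers")
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.nonzero(sd == 0)[0][0])
        raise PipelineOrderError(
            f"marker {genotypes.markers[j]!r} has zero variance; "
            "run the MAF/monomorphism filter first"
        )
    w = (m - mean) / sd
    g = symmetrize(w @ w.T / q)
    return RelationshipMatrix(kind="G", ids=np.asarray(genotypes.ids), values=g)


def extract_agg(a: RelationshipMatrix, genotyped_ids) -> RelationshipMatrix:
    """Submatrix of A for the genotyped animals, in the given order."""
    if a.kind != "A":
        raise DataError(f"extract_agg expects kind A, got {a.kind}")
    values = a.submatrix(genotyped_ids)
    return RelationshipMatrix(kind="A_gg", ids=np.asarray(genotyped_ids), values=values)


# ---------------------------------------------------------------------- #
# blending and H⁻¹
# ---------------------------------------------------------------------- #
@dataclass
class BlendCoefficients:
    """Affine blend Gₐ = βG + α matching G's moments to A_gg's."""

    alpha: float
    beta: float


def solve_blend(g: RelationshipMatrix, agg: RelationshipMatrix) -> BlendCoefficients:
    """Solve the two moment-matching equations for (α, β).

        Avg(diag(G))·β + α = Avg(diag(A_gg))
        Avg(G)·β + α = Avg(A_gg)

    Avg(·) averages all n² entries; Avg(diag(·)) the n diagonal entries.
    """
    if len(g) != len(agg):
        raise DataError(f"dimension mismatch: G is {len(g)}, A_gg is {len(agg)}")
    if len(g) < 2:
        raise DataError("blending needs at least 2 animals")
    dg = float(np.mean(np.diag(g.values)))
    mg = float(np.mean(g.values))
    da = float(np.mean(np.diag(agg.values)))
    ma = float(np.mean(agg.values))
    denom = dg - mg
    scale = max(abs(dg), abs(mg), 1.0)
    if abs(denom) < 1e-12 * scale:
        raise SingularSystemError(
            f"Avg(diag(G)) = Avg(G) = {dg:.6g}: blending system is singular"
        )
    beta = (da - ma) / denom
    alpha = da - beta * dg
    return BlendCoefficients(alpha=alpha, beta=beta)


def blend_ga(g: RelationshipMatrix, coeffs: BlendCoefficients) -> RelationshipMatrix:
    """Apply Gₐ = βG + α to every entry (diagonal and off-diagonal)."""
    values = coeffs.beta * g.values + coeffs.alpha
    return RelationshipMatrix(kind="G_a", ids=g.ids, values=values)


def assemble_h_inverse(
    a_inv: RelationshipMatrix,
    agg: RelationshipMatrix,
    g_a: RelationshipMatrix,
    genotyped_ids,
) -> RelationshipMatrix:
    """H⁻¹ = A⁻¹ + block-embedded (Gₐ⁻¹ − A_gg⁻¹) on the genotyped block.

    The correction block is added in place on the genotyped animals'
    positions within the pedigree ordering; no physical reordering of A⁻¹
    is performed.  A near-singular Gₐ gets a one-shot diagonal jitter
    (logged); if it stays singular a NumericalError reports the smallest
    eigenvalue.
    """
    genotyped_ids = np.asarray(genotyped_ids)
    pos = a_inv.positions
    try:
        idx = np.array([pos[int(a)] for a in genotyped_ids], dtype=np.int64)
    except KeyError as exc:
        raise DataError(f"genotyped id {exc.args[0]} absent from A⁻¹") from exc
    if len(genotyped_ids) == 0:
        return RelationshipMatrix(kind="H_inv", ids=a_inv.ids, values=a_inv.values.copy())
    if not (
        len(agg) == len(g_a) == len(genotyped_ids)
        and np.array_equal(np.asarray(agg.ids), genotyped_ids)
        and np.array_equal(np.asarray(g_a.ids), genotyped_ids)
    ):
        raise DataError("A_gg, Gₐ and genotyped_ids must agree in ids and order")
    ga_values = g_a.values
    ga_inv = _robust_inverse(ga_values, "Gₐ")
    agg_inv = _robust_inverse(agg.values, "A_gg")
    h = a_inv.values.copy()
    h[np.ix_(idx, idx)] += ga_inv - agg_inv
    return RelationshipMatrix(kind="H_inv", ids=a_inv.ids, values=symmetrize(h))


def _robust_inverse(m: np.ndarray, label: str) -> np.ndarray:
    """Symmetric inverse with the documented jitter policy."""
    eigmin = float(scipy.linalg.eigvalsh(m, subset_by_index=[0, 0])[0])
    if eigmin < GA_JITTER:
        logger.warning(
            "%s smallest eigenvalue %.3g < %.1g: adding diagonal jitter", label, eigmin, GA_JITTER
        )
        m = m + GA_JITTER * np.eye(len(m))
        eigmin = float(scipy.linalg.eigvalsh(m, subset_by_index=[0, 0])[0])
        if eigmin <= 0:
            raise NumericalError(
                f"{label} singular even after jitter (min eigenvalue {eigmin:.3g})"
            )
    try:
        cho = scipy.linalg.cho_factor(m)
        inv = scipy.linalg.cho_solve(cho, np.eye(len(m)))
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"{label} Cholesky failed: {exc}") from exc
    return symmetrize(inv)


def h_from_h_inverse(h_inv: RelationshipMatrix) -> RelationshipMatrix:
    """Dense inverse of H⁻¹, for use as the ssGBLUP covariance Δ = H.

    The evaluation equations only ever need H⁻¹, but the Gibbs sampler in
    this package parameterises the genetic effects through their covariance,
    so H itself is materialised once per analysis (desk-scale populations
    keep this cheap).
    """
    if h_inv.kind != "H_inv":
        raise DataError(f"expected kind H_inv, got {h_inv.kind}")
    values = _robust_inverse(h_inv.values, "H⁻¹")
    return RelationshipMatrix(kind="H", ids=h_inv.ids, values=values)


# ---------------------------------------------------------------------- #
# diagnostics
# ---------------------------------------------------------------------- #
def matrix_summary(m: RelationshipMatrix) -> dict[str, float]:
    """Min/max/mean of the diagonal and off-diagonal entries.

    These are the diagnostics used to check that A, G and H sit on a common
    scale (average diagonal about one) before they are used as covariance
    structures.
    """
    if len(m) == 0:
        raise DataError("empty relationship matrix")
    diag = np.diag(m.values)
    out = {
        "diag_min": float(diag.min()),
        "diag_max": float(diag.max()),
        "diag_mean": float(diag.mean()),
    }
    if len(m) > 1:
        off = m.values[~np.eye(len(m), dtype=bool)]
        out.update(
            offdiag_min=float(off.min()),
            offdiag_max=float(off.max()),
            offdiag_mean=float(off.mean()),
        )
    else:
        out.update(offdiag_min=np.nan, offdiag_max=np.nan, offdiag_mean=np.nan)
    return out
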