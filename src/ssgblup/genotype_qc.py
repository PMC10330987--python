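"""SNP genotype quality control.

Implements the marker-editing pipeline used before building the genomic
relationship matrix: intersection of the two chip panels, call-rate
statistics and filtering, allele-frequency estimation from pre-imputation
calls, mean imputation of missing genotypes with 2θ̂ⱼ, and removal of
monomorphic / low-MAF markers.  The canonical order is

    intersect → call-rate filter → frequency estimation → imputation → MAF filter

and every operation returns a new :class:`GenotypeMatrix`, leaving its input
untouched.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, EmptyResultError, PipelineOrderError

#: numerical guard for threshold comparisons on ratios of small integers
_EPS = 1e-12


@dataclass
class GenotypeMatrix:
    """Animals × markers additive genotype codes {0, 1, 2, missing}.

    ``data`` is a float array with NaN for missing calls (entries become
    real-valued after mean imputation).  ``panel`` tags each marker with its
    chip membership ("A", "B" or "AB" for shared markers) and ``freqs``
    holds the per-marker estimated frequency θ̂ⱼ of the allele coded as one,
    once :func:`estimate_allele_frequencies` has run.
    """

    ids: np.ndarray
    markers: np.ndarray
    data: np.ndarray
    panel: np.ndarray | None = None
    freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.markers = np.asarray(self.markers)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (len(self.ids), len(self.markers)):
            raise DataError(
                f"genotype data shape {self.data.shape} does not match "
                f"{len(self.ids)} animals × {len(self.markers)} markers"
            )
        if len(np.unique(self.ids)) != len(self.ids):
            raise DataError("duplicate animal ids in genotype matrix")
        if len(np.unique(self.markers)) != len(self.markers):
            raise DataError("duplicate marker ids in genotype matrix")
        observed = self.data[~np.isnan(self.data)]
        if observed.size and (np.min(observed) < 0 or np.max(observed) > 2):
            raise DataError("genotype codes outside [0, 2]")
        if self.panel is not None:
            self.panel = np.asarray(self.panel)
            if len(self.panel) != len(self.markers):
                raise DataError("panel tags do not match marker count")
        if self.freqs is not None:
            self.freqs = np.asarray(self.freqs, dtype=np.float64)
            ok = np.isnan(self.freqs) | ((self.freqs >= 0) & (self.freqs <= 1))
            if len(self.freqs) != len(self.markers) or not ok.all():
                raise DataError("allele frequencies must be in [0, 1]")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.data)

    def take_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to a boolean or index marker selection."""
        return GenotypeMatrix(
            ids=self.ids,
            markers=self.markers[keep],
            data=self.data[:, keep],
            panel=None if self.panel is None else self.panel[keep],
            freqs=None if self.freqs is None else self.freqs[keep],
        )


@dataclass
class GenotypeQcReport:
    """Marker/animal accounting for each genotype-editing rule, in order."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def add(self, rule: str, n_removed: int) -> None:
        self.steps.append((rule, int(n_removed)))

    def removed(self, rule: str) -> int:
        return dict(self.steps).get(rule, 0)


# ---------------------------------------------------------------------- #
# operations
# ---------------------------------------------------------------------- #
def intersect_panels(panel_a: GenotypeMatrix, panel_b: GenotypeMatrix) -> GenotypeMatrix:
    """Keep the markers shared by two chip panels; pool the animals.

    Each animal's calls come from its own panel.  An animal present on both
    chips must agree on every shared, non-missing call; conflicting calls
    raise a DataError (consistent duplicates are merged, preferring
    non-missing calls).
    """
    shared = [m for m in panel_a.markers.tolist() if m in set(panel_b.markers.tolist())]
    if not shared:
        raise EmptyResultError("chip panels share no markers; nothing to analyze")
    shared = np.asarray(shared)
    col_a = {m: j for j, m in enumerate(panel_a.markers.tolist())}
    col_b = {m: j for j, m in enumerate(panel_b.markers.tolist())}
    a_idx = np.array([col_a[m] for m in shared.tolist()])
    b_idx = np.array([col_b[m] for m in shared.tolist()])
    data_a = panel_a.data[:, a_idx]
    data_b = panel_b.data[:, b_idx]

    ids_a = panel_a.ids.tolist()
    set_a = {int(i) for i in ids_a}
    ids_b_new = [i for i in panel_b.ids.tolist() if int(i) not in set_a]
    ids = np.asarray(ids_a + ids_b_new)
    rows = np.full((len(ids), len(shared)), np.nan)
    rows[: len(ids_a)] = data_a
    pos = {int(a): i for i, a in enumerate(ids)}
    for rb, animal in enumerate(panel_b.ids.tolist()):
        r = pos[int(animal)]
        if r < len(ids_a):  # duplicate animal: merge, check conflicts
            existing = rows[r]
            incoming = data_b[rb]
            both = ~np.isnan(existing) & ~np.isnan(incoming)
            if np.any(existing[both] != incoming[both]):
                j = int(np.nonzero(both)[0][np.nonzero(existing[both] != incoming[both])[0][0]])
                raise DataError(
                    f"animal {animal} has conflicting calls at marker "
                    f"{shared[j]!r} across panels"
                )
            fill = np.isnan(existing) & ~np.isnan(incoming)
            rows[r, fill] = incoming[fill]
        else:
            rows[r] = data_b[rb]
    return GenotypeMatrix(
        ids=ids, markers=shared, data=rows, panel=np.full(len(shared), "AB")
    )


@dataclass
class CallRateStats:
    """Per-marker call rates and per-individual missing proportions."""

    marker_call_rate: np.ndarray
    individual_missing: np.ndarray

    @property
    def marker_call_rate_mean(self) -> float:
        return float(self.marker_call_rate.mean())

    @property
    def marker_call_rate_sd(self) -> float:
        return float(self.marker_call_rate.std(ddof=1)) if len(self.marker_call_rate) > 1 else 0.0

    @property
    def individual_missing_mean(self) -> float:
        return float(self.individual_missing.mean())

    @property
    def individual_missing_sd(self) -> float:
        return float(self.individual_missing.std(ddof=1)) if len(self.individual_missing) > 1 else 0.0


def call_rate_stats(g: GenotypeMatrix) -> CallRateStats:
    """Marker call rates (non-missing/animals) and individual missingness."""
    if g.n_animals == 0 or g.n_markers == 0:
        raise DataError("empty genotype matrix")
    miss = g.missing_mask()
    return CallRateStats(
        marker_call_rate=1.0 - miss.mean(axis=0),
        individual_missing=miss.mean(axis=1),
    )


def filter_markers_by_call_rate(
    g: GenotypeMatrix, threshold: float = 0.95
) -> tuple[GenotypeMatrix, GenotypeQcReport]:
    """Remove markers whose call rate is strictly below the threshold."""
    stats = call_rate_stats(g)
    keep = stats.marker_call_rate >= threshold - _EPS
    if not keep.any():
        raise EmptyResultError(f"all markers below call-rate threshold {threshold}")
    report = GenotypeQcReport()
    report.add("call_rate", int((~keep).sum()))
    return g.take_markers(keep), report


def estimate_allele_frequencies(g: GenotypeMatrix) -> GenotypeMatrix:
    """θ̂ⱼ = (sum of non-missing codes) / (2 × non-missing count), per marker.

    Computed from pre-imputation calls only; a marker with no calls at all
    gets θ̂ = NaN and is swept out later by the monomorphism filter.
    """
    miss = g.missing_mask()
    counts = (~miss).sum(axis=0)
    sums = np.where(miss, 0.0, g.data).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    return GenotypeMatrix(
        ids=g.ids, markers=g.markers, data=g.data.copy(), panel=g.panel, freqs=freqs
    )


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call at marker j with 2θ̂ⱼ (mean imputation)."""
    if g.freqs is None:
        raise PipelineOrderError(
            "allele frequencies not estimated; run estimate_allele_frequencies first"
        )
    data = g.data.copy()
    miss = np.isnan(data)
    fill = np.broadcast_to(2.0 * g.freqs, data.shape)
    data[miss] = fill[miss]
    return GenotypeMatrix(
        ids=g.ids, markers=g.markers, data=data, panel=g.panel, freqs=g.freqs
    )


def filter_maf_and_monomorphic(
    g: GenotypeMatrix, maf_threshold: float = 0.04
) -> tuple[GenotypeMatrix, GenotypeQcReport]:
    """Remove monomorphic markers and those with MAF strictly below threshold."""
    if g.freqs is None:
        raise PipelineOrderError(
            "allele frequencies not estimated; run estimate_allele_frequencies first"
        )
    theta = g.freqs
    with np.errstate(invalid="ignore"):
        maf = np.minimum(theta, 1.0 - theta)
        polymorphic = (theta > 0.0) & (theta < 1.0)
        keep = polymorphic & (maf >= maf_threshold - _EPS)
    keep = np.where(np.isnan(theta), False, keep)
    if not keep.any():
        raise EmptyResultError("no polymorphic markers left after MAF filter")
    report = GenotypeQcReport()
    report.add("monomorphic", int((~polymorphic | np.isnan(theta)).sum()))
    report.add("maf", int((polymorphic & ~np.isnan(theta) & ~keep).sum()))
    return g.take_markers(keep), report


def run_genotype_qc(
    panel_a: GenotypeMatrix,
    panel_b: GenotypeMatrix | None = None,
    call_rate_threshold: float = 0.95,
    maf_threshold: float = 0.04,
    individual_missing_threshold: float | None = None,
) -> tuple[GenotypeMatrix, GenotypeQcReport, CallRateStats]:
    """Full marker-editing pass in the canonical order.

    Individual-level removal is off by default: the pipeline reports
    per-individual missingness but, like the study design it mirrors,
    removes no animals unless an explicit threshold is supplied.
    """
    g = intersect_panels(panel_a, panel_b) if panel_b is not None else panel_a
    report = GenotypeQcReport()
    report.add("shared_markers", g.n_markers)
    stats = call_rate_stats(g)
    if individual_missing_threshold is not None:
        keep_rows = stats.individual_missing <= individual_missing_threshold + _EPS
        report.add("individual_missingness", int((~keep_rows).sum()))
        g = GenotypeMatrix(
            ids=g.ids[keep_rows],
            markers=g.markers,
            data=g.data[keep_rows],
            panel=g.panel,
            freqs=g.freqs,
        )
    g, r1 = filter_markers_by_call_rate(g, call_rate_threshold)
    report.steps.extend(r1.steps)
    g = estimate_allele_frequencies(g)
    g = impute_missing(g)
    g, r2 = filter_maf_and_monomorphic(g, maf_threshold)
    report.steps.extend(r2.steps)
    report.add("markers_retained", g.n_markers)
    return g, report, stats
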