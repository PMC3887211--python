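"""Peptide-mass-fingerprint matching and delta-mass modification discovery.

Matches an observed MS1 peak list against a theoretical digest fingerprint
(greedy nearest-mass within tolerance, singly protonated assumed for MALDI),
and scans for peaks explained only as ``base + k x delta`` shifted forms —
the step that flags an unexpected +14 Da methyl form of a predicted peptide.
Intensity is carried through the report but never used for matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .digestion import FingerprintRow
from .errors import InputError
from .peaks import PeakList

#: Default MS1 match tolerance (Da): externally calibrated reflectron MALDI.
DEFAULT_MS1_TOL = 0.3


@dataclass(frozen=True)
class PeakMatch:
    peak_mz: float
    peak_intensity: float
    row: FingerprintRow
    error: float  # observed - theoretical, Da


@dataclass
class MatchReport:
    """Outcome of matching one fingerprint spectrum against a theoretical table."""

    matched: list[PeakMatch] = field(default_factory=list)
    unmatched_peaks: list[tuple[float, float]] = field(default_factory=list)
    unobserved_theoreticals: list[FingerprintRow] = field(default_factory=list)

    @property
    def modified_hits(self) -> list[PeakMatch]:
        """Matches whose theoretical row carries at least one modification."""
        return [m for m in self.matched if m.row.n_mods > 0]


def match(
    peaklist: PeakList, fingerprint: list[FingerprintRow], tol: float = DEFAULT_MS1_TOL
) -> MatchReport:
    """Assign each observed peak to its nearest theoretical m/z within ``tol``.

    Each peak receives at most one explanation; one theoretical row may
    explain several peaks. Ties in mass error are broken by fewer
    modifications, then fewer missed cleavages, then lower m/z.
    """
    if tol <= 0:
        raise InputError("tolerance must be > 0")
    if not fingerprint:
        raise InputError("empty theoretical fingerprint")
    if peaklist.ms_level != 1:
        raise InputError("fingerprint matching expects an MS1 peak list")

    report = MatchReport()
    explained = set()
    for peak_mz, peak_int in zip(peaklist.mz, peaklist.intensity):
        best = None
        for row in fingerprint:
            err = peak_mz - row.mz
            if abs(err) > tol:
                continue
            key = (abs(err), row.n_mods, row.record.missed_cleavages, row.mz)
            if best is None or key < best[0]:
                best = (key, row, err)
        if best is None:
            report.unmatched_peaks.append((float(peak_mz), float(peak_int)))
        else:
            _, row, err = best
            report.matched.append(PeakMatch(float(peak_mz), float(peak_int), row, float(err)))
            explained.add(id(row))
    report.unobserved_theoreticals = [r for r in fingerprint if id(r) not in explained]
    return report


@dataclass(frozen=True)
class DeltaHit:
    """A peak explained as an unmodified theoretical mass plus k copies of a delta."""

    peak_mz: float
    peak_intensity: float
    base: FingerprintRow
    k: int
    error: float


def delta_scan(
    peaklist: PeakList,
    fingerprint_unmodified: list[FingerprintRow],
    delta: float,
    tol: float = DEFAULT_MS1_TOL,
    max_k: int = 2,
) -> list[DeltaHit]:
    """Find peaks lying within ``tol`` of ``base + k * delta`` for k = 1..max_k.

    Runs against the *unmodified* theoretical rows only, so it discovers
    shifted forms regardless of whether a modification-aware fingerprint was
    built; k = 0 (the unshifted mass itself) is never reported.
    """
    if delta == 0:
        raise InputError("delta must be non-zero")
    if tol <= 0:
        raise InputError("tolerance must be > 0")
    hits = []
    for peak_mz, peak_int in zip(peaklist.mz, peaklist.intensity):
        for row in fingerprint_unmodified:
            if row.n_mods:
                continue
            for k in range(1, max_k + 1):
                shifted = row.mz + k * delta / row.charge
                err = peak_mz - shifted
                if abs(err) <= tol:
                    hits.append(
                        DeltaHit(float(peak_mz), float(peak_int), row, k, float(err))
                    )
    return hits
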