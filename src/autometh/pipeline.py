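"""The site-mapping workflow: digest -> theoretical fingerprint -> peak
matching -> delta-mass scan -> MS/MS localization, chained into one report.

Given a construct sequence, an MS1 fingerprint spectrum, and zero or more
CID spectra, the pipeline names every peptide observed only in a mass-
shifted (modified) form and, where a matching MS/MS spectrum exists,
localizes the modified residue in full-protein numbering. Without MS/MS
input the run degrades to delta-scan discovery and says so explicitly.
"""

from __future__ import annotations

from dataclasses import asdict

from .chem import BUILTIN_MODIFICATIONS, Modification, ModifiedPeptide, mz, peptide_neutral_mass
from .digestion import TRYPSIN, ProteaseRule, digest, theoretical_fingerprint
from .errors import InputError
from .io import RunConfig
from .msms import localize
from .peaks import PeakList
from .pmf import delta_scan, match

_PROTEASES = {"trypsin": TRYPSIN}


def _resolve_mods(names: tuple[str, ...], registry: dict[str, Modification] | None):
    registry = registry or BUILTIN_MODIFICATIONS
    mods = []
    for name in names:
        if name not in registry:
            raise InputError(f"unknown modification {name!r}")
        mods.append(registry[name])
    return mods


def _assign_precursor(spectrum: PeakList, delta_hits, mods, tol: float):
    """Pick the (base peptide, modification, count) whose modified precursor
    mass best explains an MS2 spectrum's precursor m/z."""
    if spectrum.precursor_mz is None:
        return None
    z = spectrum.precursor_charge or 1
    best = None
    for hit in delta_hits:
        for mod in mods:
            expected = mz(
                peptide_neutral_mass(ModifiedPeptide(hit.base.record.sequence))
                + hit.k * mod.delta_mass,
                z,
            )
            err = abs(spectrum.precursor_mz - expected)
            if err <= tol and (best is None or err < best[0]):
                best = (err, hit, mod)
    return None if best is None else (best[1], best[2])


def run_site_mapping(
    parent: str,
    ms1: PeakList,
    ms2_spectra: list[PeakList] | None = None,
    config: RunConfig | None = None,
    mod_registry: dict[str, Modification] | None = None,
) -> dict:
    """Run the full site-mapping workflow and return a JSON-serializable report."""
    config = config or RunConfig()
    if config.protease not in _PROTEASES:
        raise InputError(f"unknown protease {config.protease!r}")
    rule: ProteaseRule = _PROTEASES[config.protease]
    mods = _resolve_mods(config.variable_mods, mod_registry)
    ms2_spectra = ms2_spectra or []

    peptides = digest(
        parent, rule, config.max_missed, parent_offset=config.parent_offset
    )
    fingerprint = theoretical_fingerprint(peptides, mods, charge=1)
    unmodified_rows = [r for r in fingerprint if r.n_mods == 0]

    report_match = match(ms1, fingerprint, config.ms1_tol)
    all_hits = []
    for mod in mods:
        for hit in delta_scan(
            ms1, unmodified_rows, mod.delta_mass, config.ms1_tol, mod.max_per_peptide
        ):
            all_hits.append((mod, hit))

    modified_peptides = [
        {
            "peptide": hit.base.record.sequence,
            "start": hit.base.record.start,
            "end": hit.base.record.end,
            "modification": mod.name,
            "count": hit.k,
            "observed_mz": hit.peak_mz,
            "theoretical_unmodified_mz": hit.base.mz,
        }
        for mod, hit in all_hits
    ]

    localizations = []
    for spec in ms2_spectra:
        assigned = _assign_precursor(
            spec, [h for _, h in all_hits], mods, config.precursor_tol
        )
        if assigned is None:
            localizations.append(
                {
                    "title": spec.title,
                    "status": "precursor not explained by any delta-scan hit",
                }
            )
            continue
        hit, mod = assigned
        result = localize(
            spec,
            hit.base.record.sequence,
            mod,
            tol=config.ms2_tol,
            any_site=config.any_site,
            parent_offset=config.parent_offset,
            peptide_start=hit.base.record.start,
            precursor_tol=config.precursor_tol,
        )
        localizations.append(
            {
                "title": spec.title,
                "peptide": result.peptide,
                "modification": result.modification,
                "best_site": result.best_site,
                "residue_label": result.residue_label,
                "site_determining_matched": result.site_determining_matched,
                "candidate_scores": {
                    c.position: c.score for c in result.candidate_sites
                },
                "warnings": result.warnings,
            }
        )

    return {
        "config": asdict(config),
        "n_peptides": len(peptides),
        "n_theoretical_rows": len(fingerprint),
        "n_peaks": len(ms1),
        "n_matched": len(report_match.matched),
        "n_unmatched_peaks": len(report_match.unmatched_peaks),
        "matched_peptides": sorted(
            {m.row.record.sequence for m in report_match.matched}
        ),
        "modified_peptides": modified_peptides
        if modified_peptides
        else "no methylated form detected",
        "localization": localizations if ms2_spectra else "not performed",
    }
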