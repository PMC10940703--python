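"""Study orchestration: run demux -> composition -> kinetics -> serology ->
viability over a sample manifest and emit figure-like report tables.

A study manifest names every sample (with its analyte — DNA for vector
uptake, cDNA for expression, perfusate for clearance, input for the
pre-injection mix), the dose context, and optional serology and viability
inputs. Analytes are always explicit rather than inferred from file names:
the DNA-vs-cDNA distinction carries the uptake-vs-expression interpretation
and must never be guessed. Re-running an identical manifest yields
byte-identical report tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .composition import (CompositionProfile, cluster_profiles, fractions,
                          normalize_to_input)
from .demux import (BarcodeCountTable, BarcodeLibrary, DemuxParams,
                    count_barcodes, read_paired_fastq)
from .kinetics import (DoseContext, PerfusateSeries, classify_persistence,
                       demux_concentration, dose_report)
from .serology import end_titer, load_elisa_table, reactivity_score
from .viability import ViabilityPanel, assess_viability

__all__ = ["SampleSpec", "StudyManifest", "ReportBundle", "ManifestError",
           "run_study"]


class ManifestError(ValueError):
    pass


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    analyte: str  # DNA | cDNA | perfusate | input
    r1: str
    r2: str
    graft: str = "whole"  # LLSG | ERG | whole
    timepoint_hours: float | None = None

    def __post_init__(self) -> None:
        if self.analyte not in ("DNA", "cDNA", "perfusate", "input"):
            raise ManifestError(
                f"sample {self.sample_id}: unknown analyte {self.analyte!r}"
            )
        if self.graft not in ("LLSG", "ERG", "whole"):
            raise ManifestError(
                f"sample {self.sample_id}: unknown graft {self.graft!r}"
            )


@dataclass
class StudyManifest:
    library_tsv: str
    library_config: Mapping[str, Any]
    samples: Sequence[SampleSpec]
    input_mix_sample: str
    dose: Mapping[str, Any] | None = None
    elisa_table: str | None = None
    viability_panel: Mapping[str, Any] | None = None
    perfusate: Mapping[str, Any] | None = None  # {"csv": ..., "samples": [...]}
    demux: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
        return cls(samples=samples, **raw)

    def validate(self) -> None:
        if not self.samples:
            raise ManifestError(
                "manifest has no samples: the input-mix sample "
                f"{self.input_mix_sample!r} is missing"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ManifestError("sample_ids are not unique")
        if self.input_mix_sample not in ids:
            raise ManifestError(
                f"input-mix sample {self.input_mix_sample!r} not in manifest"
            )
        mixes = [s for s in self.samples if s.analyte == "input"]
        if len(mixes) != 1 or mixes[0].sample_id != self.input_mix_sample:
            raise ManifestError(
                "exactly one sample must carry analyte 'input' and match "
                "input_mix_sample"
            )
        for s in self.samples:
            for path in (s.r1, s.r2):
                if not Path(path).exists():
                    raise ManifestError(f"sample {s.sample_id}: missing {path}")
        if not Path(self.library_tsv).exists():
            raise ManifestError(f"missing barcode library {self.library_tsv}")


@dataclass
class ReportBundle:
    outdir: Path
    counts: dict[str, BarcodeCountTable]
    profiles: dict[str, CompositionProfile]
    dose: Mapping[str, float] | None
    titers: pd.DataFrame | None
    viability: Mapping[str, Any] | None
    clearance: pd.DataFrame | None
    errors: list[dict[str, str]]
    run_log: Mapping[str, Any]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def run_study(manifest: StudyManifest, outdir: str | Path) -> ReportBundle:
    """Execute the full pipeline for a manifest; one TSV per figure-like
    output plus a JSON run log. Stage contract errors are collected per
    sample, not raised."""
    manifest.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    lib = BarcodeLibrary.from_tsv(manifest.library_tsv, manifest.library_config)
    params = DemuxParams(**dict(manifest.demux))
    errors: list[dict[str, str]] = []

    counts: dict[str, BarcodeCountTable] = {}
    for spec in manifest.samples:
        try:
            table = count_barcodes(read_paired_fastq(spec.r1, spec.r2), lib,
                                   params, sample_id=spec.sample_id)
            table.to_tsv(outdir / f"{spec.sample_id}.counts.tsv")
            counts[spec.sample_id] = table
        except Exception as exc:  # collected, reported with offending sample
            errors.append({"sample_id": spec.sample_id, "stage": "demux",
                           "error": str(exc)})

    profiles: dict[str, CompositionProfile] = {}
    input_profile = None
    if manifest.input_mix_sample in counts:
        input_profile = fractions(counts[manifest.input_mix_sample],
                                  analyte="input")
        profiles[manifest.input_mix_sample] = input_profile
    by_spec = {s.sample_id: s for s in manifest.samples}
    for sid, table in counts.items():
        if sid == manifest.input_mix_sample or input_profile is None:
            continue
        try:
            prof = fractions(table, analyte=by_spec[sid].analyte)
            profiles[sid] = normalize_to_input(prof, input_profile)
        except Exception as exc:
            errors.append({"sample_id": sid, "stage": "composition",
                           "error": str(exc)})

    comp_rows = {}
    for sid, prof in profiles.items():
        comp_rows[sid] = prof.normalized_pct or prof.fractions
    comp_df = pd.DataFrame(comp_rows).sort_index()
    comp_df.index.name = "variant"
    _write_tsv(comp_df, outdir / "composition.tsv")

    # cluster variants on their DNA / cDNA percentage profiles per analyte
    for analyte in ("DNA", "cDNA"):
        cols = [sid for sid in comp_df.columns
                if by_spec[sid].analyte == analyte]
        if len(cols) >= 1 and len(comp_df) >= 2:
            tree = cluster_profiles(comp_df[cols])
            (outdir / f"clusters_{analyte}.nwk").write_text(tree.to_newick() + "\n")

    clearance_df = None
    if manifest.perfusate is not None and input_profile is not None:
        try:
            pf = pd.read_csv(manifest.perfusate["csv"])
            sample_order = list(manifest.perfusate["samples"])
            series = PerfusateSeries(
                timepoints=tuple(float(t) for t in pf["timepoint_hours"]),
                total_conc=tuple(float(c) for c in pf["total_vg_per_ml"]),
                variant_fraction=tuple(
                    fractions(counts[sid], analyte="perfusate")
                    for sid in sample_order
                ),
                initial_total=float(manifest.perfusate.get(
                    "initial_total", pf["total_vg_per_ml"].iloc[0])),
                input_mix=input_profile,
            )
            _conc, pct = demux_concentration(series)
            clearance_df = pd.DataFrame(
                pct, index=[f"{t:g}h" for t in series.timepoints]).T.sort_index()
            clearance_df.index.name = "variant"
            clearance_df["class_final"] = [
                classify_persistence(clearance_df.iloc[i, -1])
                for i in range(len(clearance_df))
            ]
            _write_tsv(clearance_df, outdir / "clearance.tsv")
        except Exception as exc:
            errors.append({"sample_id": "<perfusate>", "stage": "kinetics",
                           "error": str(exc)})

    dose = None
    if manifest.dose is not None:
        dose = dose_report(DoseContext(**dict(manifest.dose)))
        with open(outdir / "dose_report.json", "w") as fh:
            json.dump(dose, fh, indent=2, sort_keys=True)

    titers_df = None
    if manifest.elisa_table is not None:
        assays = load_elisa_table(manifest.elisa_table)
        rows = []
        for capsid, assay in assays.items():
            result = end_titer(assay)
            rows.append({"capsid": capsid, "end_titer": result.label,
                         "reactivity_score": reactivity_score(
                             result, assay.dilutions)})
        titers_df = pd.DataFrame(rows).set_index("capsid").sort_index()
        _write_tsv(titers_df, outdir / "titers.tsv")

    viability = None
    if manifest.viability_panel is not None:
        verdict = assess_viability(ViabilityPanel(**dict(manifest.viability_panel)))
        viability = {"viable": verdict.viable,
                     "lactate_ok": verdict.lactate_ok,
                     "satisfied_secondary": list(verdict.satisfied_secondary)}
        with open(outdir / "viability.json", "w") as fh:
            json.dump(viability, fh, indent=2)

    run_log = {
        "aavbench_version": __version__,
        "seed": manifest.seed,
        "demux_params": {"min_overlap": params.min_overlap,
                         "max_mismatch_frac": params.max_mismatch_frac,
                         "max_hamming": params.max_hamming},
        "library": {"n_variants": len(lib.entries),
                    "barcode_length": lib.barcode_length,
                    "expected_merged_length": lib.expected_merged_length,
                    "length_tolerance": lib.length_tolerance},
        "samples": [s.sample_id for s in manifest.samples],
        "errors": errors,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)

    return ReportBundle(outdir=outdir, counts=counts, profiles=profiles,
                        dose=dose, titers=titers_df, viability=viability,
                        clearance=clearance_df, errors=errors, run_log=run_log)
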