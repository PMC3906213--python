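"""End-to-end driver: simulate (or load) -> preprocess -> analyse -> report.

Everything is deterministic for a fixed seed and input set; every output
file is listed in a JSON manifest with its SHA-256 content hash, and a run
log records the probe-count ledger at each stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import arrayio
from .config import RunConfig, TRAITS
from .dmr import (
    BetweenGroupDMA,
    WithinPairDMA,
    cross_design_overlap,
    family_screen,
    pair_deltas,
    skew_test,
)
from .exceptions import TwinMethError
from .preprocess import preprocess
from .simulate import simulate_cohort
from .trait import TraitCorrelation, flag_extreme_pairs

logger = logging.getLogger("twinmeth")


@dataclass
class RunResult:
    outdir: Path
    outputs: dict[str, str] = field(default_factory=dict)  # relative path -> sha256
    log_lines: list[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(paths: dict[str, str]):
    required = ("signals", "manifest", "sample_sheet", "traits")
    missing = [k for k in required if k not in paths]
    if missing:
        raise TwinMethError(f"input paths missing: {missing}")
    return (
        arrayio.read_signals(paths["signals"]),
        arrayio.read_manifest(paths["manifest"]),
        arrayio.read_sample_sheet(paths["sample_sheet"]),
        arrayio.read_trait_table(paths["traits"]),
    )


def run_pipeline(config: RunConfig) -> RunResult:
    problems = config.validate()
    if problems:
        raise TwinMethError("invalid run configuration: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = RunResult(outdir=outdir)
    log = result.log_lines

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        result.outputs[name] = _sha256(path)

    # ---- stage: inputs ---------------------------------------------------
    try:
        if config.simulation is not None:
            cohort = simulate_cohort(config.simulation)
            signals, manifest = cohort.signals, cohort.manifest
            sheet, traits = cohort.sample_sheet, cohort.traits
            emit("manifest.tsv", lambda p: arrayio.write_manifest(manifest, p))
            emit("sample_sheet.csv", lambda p: arrayio.write_sample_sheet(sheet, p))
            emit("trait_scores.csv", lambda p: arrayio.write_trait_table(traits, p))
            emit("truth_table.tsv", lambda p: arrayio.write_truth_table(cohort.truth, p))
            log.append(f"simulated cohort: {signals.shape[0]} probes, "
                       f"{signals.shape[1]} samples, seed {config.simulation.seed}")
        else:
            signals, manifest, sheet, traits = _load_inputs(config.input_paths)
            log.append(f"loaded cohort: {signals.shape[0]} probes, "
                       f"{signals.shape[1]} samples")
    except TwinMethError as exc:
        raise TwinMethError(f"stage 'inputs' failed: {exc}") from exc

    # ---- stage: preprocess ----------------------------------------------
    try:
        pp = preprocess(signals, manifest, config.detection_threshold)
    except TwinMethError as exc:
        raise TwinMethError(f"stage 'preprocess' failed: {exc}") from exc
    log.extend(pp.report.log_lines())
    emit("filter_report.tsv", lambda p: pp.report.to_tsv(p))
    emit("beta.tsv", lambda p: arrayio.write_matrix(pp.beta, p))
    emit("transformed.tsv", lambda p: arrayio.write_matrix(pp.transformed, p))
    emit(
        "vst_reference.tsv",
        lambda p: pp.vst.reference_frame().to_csv(p, sep="\t", index=False),
    )

    # ---- stage: within-pair designs --------------------------------------
    results = {}
    groups_present = set(sheet["group"])
    design_group = {
        "asd": "discordant_asd",
        "social": "discordant_social",
        "rrbi": "discordant_rrbi",
        "communication": "discordant_communication",
    }
    try:
        for design in config.designs:
            if design != "combined" and design_group.get(design) not in groups_present:
                log.append(f"design '{design}': no pairs present, skipped")
                continue
            model = WithinPairDMA(pp.beta, pp.transformed, sheet, design, manifest)
            res = model.fit()
            results[design] = res
            log.append(
                f"design '{design}': {res.n_units} pairs, "
                f"{res.n_probes_tested} probes tested, Bonferroni cutoff "
                f"{res.bonferroni_cutoff:.3g}"
            )
            emit(f"dmr_{design}.tsv", lambda p, r=res: r.to_tsv(p))
            emit(
                f"dmr_{design}_top{config.top_k}.bed",
                lambda p, r=res: arrayio.write_bed(r.top(config.top_k), manifest, p),
            )
    except TwinMethError as exc:
        raise TwinMethError(f"stage 'within-pair' failed: {exc}") from exc

    # ---- stage: family screen + skew -------------------------------------
    try:
        if "asd" in results:
            delta_asd = pair_deltas(pp.beta, pp.transformed, sheet, "asd")
            hits = family_screen(delta_asd, config.family_threshold)
            emit(
                "family_hits.tsv",
                lambda p: hits.to_csv(p, sep="\t", index=False, float_format="%.6g"),
            )
            per_pair = (
                hits.groupby("pair_id").size().reindex(delta_asd.pairs, fill_value=0)
            )
            log.append(
                f"family screen (|delta-beta| >= {config.family_threshold}): "
                f"{len(hits)} hits, mean {per_pair.mean():.1f} per pair"
            )
            if "concordant_unaffected" in groups_present:
                delta_un = pair_deltas(pp.beta, pp.transformed, sheet, "unaffected")
                skew = skew_test(
                    delta_asd, delta_un, ranked=results["asd"].records,
                    top_k=config.top_k,
                )
                emit(
                    "skew_test.json",
                    lambda p: Path(p).write_text(
                        json.dumps(
                            {
                                "ks_statistic": skew.ks_statistic,
                                "p_value": skew.p_value,
                                "top_k": skew.top_k,
                                "top_mean_abs_discordant": skew.top_mean_abs_discordant,
                                "top_mean_abs_comparison": skew.top_mean_abs_comparison,
                            },
                            indent=1,
                        )
                        + "\n"
                    ),
                )
                log.append(
                    f"skew test: KS={skew.ks_statistic:.4f} p={skew.p_value:.3g}"
                )
    except TwinMethError as exc:
        raise TwinMethError(f"stage 'family-screen' failed: {exc}") from exc

    # ---- stage: between-group --------------------------------------------
    try:
        cases = sheet.loc[sheet["asd_affected"], "sample_id"].tolist()
        controls = sheet.loc[
            sheet["group"] == "concordant_unaffected", "sample_id"
        ].tolist()
        if len(cases) >= 2 and len(controls) >= 2:
            res = BetweenGroupDMA(
                pp.beta, pp.transformed, cases, controls, manifest,
                design="case_control",
            ).fit()
            results["case_control"] = res
            log.append(
                f"case-control: {len(cases)} cases vs {len(controls)} controls, "
                f"{res.n_probes_tested} autosomal probes tested "
                f"(sex-chromosome probes removed: "
                f"{len(pp.beta) - res.n_probes_tested - len(res.degenerate_probes)})"
            )
            emit("dmr_case_control.tsv", lambda p, r=res: r.to_tsv(p))
        sporadic = sheet.loc[sheet["familial_class"] == "sporadic", "sample_id"].tolist()
        familial = sheet.loc[sheet["familial_class"] == "familial", "sample_id"].tolist()
        if len(sporadic) >= 2 and len(familial) >= 2:
            res = BetweenGroupDMA(
                pp.beta, pp.transformed, sporadic, familial, manifest,
                design="sporadic_vs_familial",
            ).fit()
            results["sporadic_vs_familial"] = res
            log.append(
                f"sporadic vs familial: {len(sporadic)} vs {len(familial)} samples"
            )
            emit("dmr_sporadic_vs_familial.tsv", lambda p, r=res: r.to_tsv(p))
    except TwinMethError as exc:
        raise TwinMethError(f"stage 'between-group' failed: {exc}") from exc

    # ---- stage: overlap ---------------------------------------------------
    if len(results) >= 2:
        overlap, corr = cross_design_overlap(results, k=config.top_k)
        emit(
            "overlap.tsv",
            lambda p: overlap.to_csv(p, sep="\t", index=False, float_format="%.6g"),
        )
        emit(
            "overlap_rank_correlation.tsv",
            lambda p: corr.to_csv(p, sep="\t", float_format="%.6g"),
        )
        log.append(f"cross-design overlap over {len(results)} ranked lists")

    # ---- stage: trait correlation ----------------------------------------
    try:
        if traits is not None and len(traits):
            flagged = []
            if "asd" in results:
                flagged = flag_extreme_pairs(
                    pp.beta, traits, sheet,
                    results["asd"].top(config.top_k)["probe_id"].tolist(),
                )
            for trait_name in TRAITS:
                model = TraitCorrelation(pp.beta, traits, sheet, trait_name)
                res = model.fit(exclude_pairs=flagged or None)
                emit(f"trait_corr_{trait_name}.tsv", lambda p, r=res: r.to_tsv(p))
            log.append(
                "trait correlations computed for "
                + ", ".join(TRAITS)
                + (f"; extreme pair(s) flagged: {flagged}" if flagged
                   else "; no extreme pairs flagged")
            )
    except TwinMethError as exc:
        raise TwinMethError(f"stage 'trait-correlation' failed: {exc}") from exc

    # ---- run log + manifest ----------------------------------------------
    emit("run_log.txt", lambda p: Path(p).write_text("\n".join(log) + "\n"))
    manifest_json = json.dumps(dict(sorted(result.outputs.items())), indent=1) + "\n"
    (outdir / "output_manifest.json").write_text(manifest_json)
    result.outputs["output_manifest.json"] = _sha256(outdir / "output_manifest.json")
    return result
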