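"""End-to-end orchestration: simulate/load -> calibrate -> correct ->
classify -> statistics -> report.

The pipeline consumes control arrays (NTC, wild-type plasmid, mutant
plasmid) to draw thresholds and fit the bleed-through correction,
optional heterozygous-plasmid arrays to estimate allele dropout, and
sample (cell) arrays for QC statistics, occupancy comparison, genotyping,
VAF and the test of the observed zygosity distribution against the bulk
all-heterozygous model.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import apply_bleedthrough_correction, calibrate_all, calibration_to_dict
from .classify import (
    amp_negative_fraction,
    array_map_text,
    classify_array,
    genotype_counts,
    occupancy_counts,
    qc_counts,
)
from .io import RunManifest, save_calibration, write_well_table
from .stats import (
    compare_occupancy,
    compute_vaf,
    estimate_ado,
    expected_zygosity_under_het,
    fpr_fnr,
    het_array_calls_from_table,
    occupancy_from_negative_fraction,
    zygosity_distribution_test,
)
from .synthetic import SimulationConfig, control_config, simulate_array
from .types import ArrayData, Channel, TemplateKind, ValidationError


@dataclass
class PipelineRunConfig:
    """Synthetic-bundle pipeline settings.

    Array counts mirror a typical chip campaign: a few control arrays per
    template for calibration, six heterozygous-plasmid replicates for
    allele dropout, and a set of cell arrays for genotyping.
    """

    seed: int = 0
    n_ntc: int = 2
    n_wt_plasmid: int = 3
    n_mut_plasmid: int = 2
    n_het_plasmid: int = 6
    n_cell_arrays: int = 4
    zygosity_mix: tuple = (0.20, 0.50, 0.30)
    overrides: dict = field(default_factory=dict)  # applied to every SimulationConfig


def simulate_bundle(cfg: PipelineRunConfig) -> dict[str, list]:
    """Simulate the full array bundle a pipeline run consumes.

    Seeds are derived deterministically from ``cfg.seed`` (one increment
    per array), so a bundle is reproducible from the run seed alone.
    Returns a dict with keys ``controls``, ``het``, ``samples`` and
    parallel ``*_truth`` lists.
    """
    out: dict[str, list] = {
        "controls": [],
        "controls_truth": [],
        "het": [],
        "het_truth": [],
        "samples": [],
        "samples_truth": [],
    }
    seed = cfg.seed
    plan = [
        (TemplateKind.NTC, cfg.n_ntc, "controls"),
        (TemplateKind.WT_PLASMID, cfg.n_wt_plasmid, "controls"),
        (TemplateKind.MUT_PLASMID, cfg.n_mut_plasmid, "controls"),
        (TemplateKind.HET_PLASMID, cfg.n_het_plasmid, "het"),
        (TemplateKind.CELLS, cfg.n_cell_arrays, "samples"),
    ]
    for kind, count, role in plan:
        for i in range(count):
            if kind == TemplateKind.CELLS:
                sim = SimulationConfig(
                    template_kind=kind,
                    zygosity_mix=cfg.zygosity_mix,
                    seed=seed,
                    array_id=f"cells-{i}",
                    **cfg.overrides,
                )
            else:
                sim = control_config(kind, seed=seed, array_id=f"{kind.value.lower()}-{i}", **cfg.overrides)
            arr, truth = simulate_array(sim)
            out[role].append(arr)
            out[f"{role}_truth"].append(truth)
            seed += 1
    return out


def run_pipeline(
    controls: list[ArrayData],
    samples: list[ArrayData],
    het_arrays: list[ArrayData] | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
    manifest_config: dict | None = None,
) -> dict:
    """Execute calibration, classification and statistics; return the report.

    Raises before any sample processing if the control set cannot
    calibrate all three probe channels. If ``out_dir`` is given, writes
    ``report.json``, ``calibration.json``, per-array call tables and text
    array maps, and ``manifest.json``.
    """
    het_arrays = het_arrays or []
    collected_warnings: list[str] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        calibrations, bleed = calibrate_all(controls)
        collected_warnings += [str(w.message) for w in wlist]

    report: dict = {
        "calibration": calibration_to_dict(calibrations, bleed),
        "arrays": {},
        "ado": None,
        "genotyping": None,
        "seed": seed,
    }

    call_tables: dict[str, "object"] = {}
    for arr in [*controls, *het_arrays, *samples]:
        corrected = apply_bleedthrough_correction(arr, bleed)
        table = classify_array(corrected, calibrations)
        call_tables[arr.array_id] = (arr, table)
        entry: dict = {
            "template_kind": arr.template_kind.value,
            "n_wells": int(len(table)),
            "n_filled": int(table["filled"].sum()),
            "genotype_counts": genotype_counts(table),
        }
        if arr.template_kind == TemplateKind.CELLS:
            qc = qc_counts(table)
            fpr, fnr = fpr_fnr(qc)
            occ = occupancy_counts(table)
            total = occ["n_zero"] + occ["n_single"] + occ["n_multi"]
            est = occupancy_from_negative_fraction(total, max(occ["n_zero"] / total, 1e-12))
            comp = compare_occupancy((occ["n_zero"], occ["n_single"], occ["n_multi"]), est)
            entry["qc_counts"] = qc
            entry["fpr"] = _nan_to_none(fpr)
            entry["fnr"] = _nan_to_none(fnr)
            entry["occupancy"] = {
                "observed": occ,
                "lambda_hat": est.lambda_hat,
                "expected_single": est.expected_single,
                "expected_multi": est.expected_multi,
                "ratio_single": comp.ratio_single,
                "ratio_multi": comp.ratio_multi,
                "p_doublet_excess": comp.p_doublet_excess,
            }
            g = entry["genotype_counts"]
            if g["n_wt"] + g["n_het"] + g["n_mut"] > 0:
                entry["vaf_percent"] = compute_vaf(g["n_mut"], g["n_het"], g["n_wt"])
        report["arrays"][arr.array_id] = entry

    if het_arrays:
        records = [het_array_calls_from_table(call_tables[a.array_id][1], a.array_id) for a in het_arrays]
        ado = estimate_ado(records)
        report["ado"] = {
            "ado_wt": ado.ado_wt,
            "ado_mut": ado.ado_mut,
            "sd_wt": ado.sd_wt,
            "sd_mut": ado.sd_mut,
            "per_array_wt": ado.per_array_wt,
            "per_array_mut": ado.per_array_mut,
            "n_calls_total": ado.n_calls_total,
        }

    if samples:
        pooled = {"n_wt": 0, "n_het": 0, "n_mut": 0}
        vafs = []
        for arr in samples:
            g = report["arrays"][arr.array_id]["genotype_counts"]
            for key in pooled:
                pooled[key] += g[key]
            if "vaf_percent" in report["arrays"][arr.array_id]:
                vafs.append(report["arrays"][arr.array_id]["vaf_percent"])
        geno: dict = {"pooled_counts": pooled}
        if pooled["n_wt"] + pooled["n_het"] + pooled["n_mut"] > 0:
            geno["vaf_percent"] = compute_vaf(pooled["n_mut"], pooled["n_het"], pooled["n_wt"])
            geno["vaf_per_array"] = vafs
            geno["vaf_mean"] = float(np.mean(vafs)) if vafs else None
            geno["vaf_sd"] = float(np.std(vafs, ddof=1)) if len(vafs) > 1 else None
            if report["ado"] is not None:
                probs = expected_zygosity_under_het(report["ado"]["ado_wt"], report["ado"]["ado_mut"])
                geno["expected_under_het"] = {"p_wt": probs[0], "p_het": probs[1], "p_mut": probs[2]}
                geno["p_vs_all_het_model"] = zygosity_distribution_test(
                    (pooled["n_wt"], pooled["n_het"], pooled["n_mut"]), probs, seed=seed
                )
        report["genotyping"] = geno

    report["warnings"] = collected_warnings

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        save_calibration(report["calibration"], out_dir / "calibration.json")
        for array_id, (arr, table) in call_tables.items():
            table.to_csv(out_dir / f"calls_{array_id}.tsv", sep="\t", index=False)
            (out_dir / f"map_{array_id}.txt").write_text(array_map_text(table) + "\n")
        manifest = RunManifest(
            run_id=f"run-{seed}",
            seed=seed,
            config=manifest_config or {},
            package_version=__version__,
        )
        manifest.save(out_dir / "manifest.json")
    return report


def run_synthetic_pipeline(cfg: PipelineRunConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate a bundle from the run config and push it through the pipeline."""
    bundle = simulate_bundle(cfg)
    manifest_config = dataclasses.asdict(cfg)
    manifest_config["zygosity_mix"] = list(cfg.zygosity_mix)
    return run_pipeline(
        bundle["controls"],
        bundle["samples"],
        het_arrays=bundle["het"],
        out_dir=out_dir,
        seed=cfg.seed,
        manifest_config=manifest_config,
    )


def rerun_from_manifest(manifest_path: str | Path, out_dir: str | Path | None = None) -> dict:
    """Re-execute a synthetic run exactly as recorded in its manifest."""
    manifest = RunManifest.load(manifest_path)
    cfg_dict = dict(manifest.config)
    if not cfg_dict:
        raise ValidationError("manifest carries no pipeline config; cannot rerun")
    cfg_dict["zygosity_mix"] = tuple(cfg_dict.get("zygosity_mix", (0.20, 0.50, 0.30)))
    cfg = PipelineRunConfig(**cfg_dict)
    return run_synthetic_pipeline(cfg, out_dir=out_dir)


def _nan_to_none(x: float):
    return None if x != x else float(x)
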