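"""End-to-end stage orchestration with reproducibility metadata.

Each ``run_*`` function chains the library stages for one analysis, writes
its outputs under ``out_dir`` and returns a manifest recording the config
hash, seeds and a checksum per written file, so an identical invocation is
verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, antigen, design, elispot, epitopes, repertoire

log = logging.getLogger(__name__)

#: The trial enrolled tumours expressing at least this many neoantigens;
#: enforced here as a warning gate, not a hard failure.
MIN_TARGETS_WARN = 5


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _write_manifest(out_dir: Path, stage: str, config: dict, outputs: dict[str, Path]) -> Path:
    manifest = {
        "stage": stage,
        "tool_version": __version__,
        "config": config,
        "config_hash": _config_hash(config),
        "output_checksums": {name: _sha256(Path(p)) for name, p in outputs.items()},
    }
    path = out_dir / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path


def run_design(config: dict) -> dict:
    """antigen construction -> epitope scoring -> prioritization/assembly.

    Config keys: transcripts_fasta, transcripts_tsv, variants_tsv,
    hla_tsv (or ``hla_alleles`` list), patient_id, out_dir, predictor_seed,
    optional germline_tsv / linker_aa / selection_cap.
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    patient_id = config.get("patient_id", "patient")

    transcripts = antigen.read_transcripts(config["transcripts_fasta"], config["transcripts_tsv"])
    variants = antigen.read_variants(config["variants_tsv"])
    germline = (
        antigen.read_germline_calls(config["germline_tsv"])
        if config.get("germline_tsv")
        else []
    )
    if "hla_alleles" in config:
        hla = [epitopes.normalize_allele(a) for a in config["hla_alleles"]]
    else:
        hla = epitopes.read_hla_typing(config["hla_tsv"])[patient_id]

    mps_list = antigen.build_patient_mps(transcripts, variants, germline)
    predictor = epitopes.MockPredictor(seed=int(config.get("predictor_seed", 0)))
    score_table, scores = epitopes.score_all(mps_list, hla, predictor)

    vaccine = design.build_design(
        patient_id,
        mps_list,
        scores,
        transcripts,
        variants,
        linker_aa=config.get("linker_aa", design.DEFAULT_LINKER),
        selection_cap=int(config.get("selection_cap", design.SELECTION_CAP)),
    )
    if len(vaccine.selected) < int(config.get("min_targets", MIN_TARGETS_WARN)):
        log.warning(
            "patient %s: only %d vaccine targets selected (eligibility gate is %d)",
            patient_id, len(vaccine.selected), MIN_TARGETS_WARN,
        )
    design.validate_design(vaccine)

    outputs = design.emit_design_report(vaccine, out_dir, scores, transcripts, variants)
    antigen.write_mps_table(mps_list, out_dir / f"{patient_id}_mps.tsv")
    outputs["mps_tsv"] = out_dir / f"{patient_id}_mps.tsv"
    score_table.to_csv(out_dir / f"{patient_id}_scores.tsv", sep="\t", index=False)
    outputs["scores_tsv"] = out_dir / f"{patient_id}_scores.tsv"
    manifest = _write_manifest(out_dir, "design", config, outputs)
    return {"design": vaccine, "outputs": outputs, "manifest": manifest}


def run_immunomonitoring(config: dict) -> dict:
    """ELISpot calls for every (antigen, timepoint), classification of the
    earliest-vs-latest timepoint pair, and kinetics over immunogenic antigens.

    Config keys: elispot_tsv, out_dir, optional alpha/B/seed/policy/tntc_cap.
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    df = elispot.read_elispot_tsv(config["elispot_tsv"])
    measurements = elispot.measurements_from_frame(df)
    kwargs = dict(
        alpha=float(config.get("alpha", elispot.ALPHA)),
        B=int(config.get("B", elispot.DEFAULT_B)),
        seed=int(config.get("seed", 0)),
        policy=config.get("policy", "require_2x"),
        tntc_cap=float(config.get("tntc_cap", elispot.TNTC_DEFAULT_CAP)),
    )

    controls = {
        (m.patient_id, m.timepoint, m.assay_arm): m
        for m in measurements
        if m.antigen_id == "medium"
    }
    calls = []
    calls_by_time: dict[str, list[elispot.ResponseCall]] = {}
    day_of: dict[str, int] = {}
    for m in measurements:
        if m.antigen_id == "medium":
            continue
        key = (m.patient_id, m.timepoint, m.assay_arm)
        if key not in controls:
            raise ValueError(f"no medium-only control for {key}")
        call = elispot.call_response(m, controls[key], **kwargs)
        calls.append(call)
        calls_by_time.setdefault(m.timepoint, []).append(call)
        day_of[m.timepoint] = m.day

    timepoints = sorted(day_of, key=day_of.get)
    classifications = []
    if len(timepoints) >= 2:
        pre_tp, post_tp = timepoints[0], timepoints[-1]
        pre_by_ag = {c.antigen_id: c for c in calls_by_time[pre_tp]}
        for post_call in calls_by_time[post_tp]:
            pre_call = pre_by_ag.get(post_call.antigen_id)
            if pre_call is not None:
                classifications.append(elispot.classify_response(pre_call, post_call))

    immunogenic = {
        c.antigen_id
        for c in classifications
        if c.response_class in (elispot.ResponseClass.DE_NOVO, elispot.ResponseClass.AMPLIFIED)
    }
    kinetics = elispot.multiantigen_kinetics(calls_by_time, immunogenic)

    calls_tsv = out_dir / "elispot_calls.tsv"
    pd.DataFrame(
        {
            "antigen_id": [c.antigen_id for c in calls],
            "timepoint": [c.timepoint for c in calls],
            "p_value": [c.p_value for c in calls],
            "p_eq": [c.p_eq for c in calls],
            "p_2x": [c.p_2x for c in calls],
            "mean_count": [c.mean_count for c in calls],
            "spots_per_million": [c.spots_per_million for c in calls],
            "positive": [c.positive for c in calls],
        }
    ).to_csv(calls_tsv, sep="\t", index=False)
    class_tsv = out_dir / "elispot_classification.tsv"
    pd.DataFrame(
        {
            "antigen_id": [c.antigen_id for c in classifications],
            "response_class": [c.response_class.value for c in classifications],
            "fold_change": [c.fold_change_post_vs_pre for c in classifications],
        }
    ).to_csv(class_tsv, sep="\t", index=False)
    kinetics_tsv = out_dir / "elispot_kinetics.tsv"
    kinetics.rename_axis("timepoint").to_frame().to_csv(kinetics_tsv, sep="\t")
    outputs = {"calls_tsv": calls_tsv, "classification_tsv": class_tsv, "kinetics_tsv": kinetics_tsv}
    manifest = _write_manifest(out_dir, "elispot", config, outputs)
    return {
        "calls": calls,
        "classifications": classifications,
        "kinetics": kinetics,
        "immunogenic": immunogenic,
        "outputs": outputs,
        "manifest": manifest,
    }


def run_revimmo(config: dict) -> dict:
    """Full reverse-immunomonitoring chain over bulk + single-cell TCR data.

    Config keys: pre_tsv, post_tsv, sc_tsv, out_dir; optional tumour_tsv,
    luminescence_tsv, per_class_max, total_max.
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    if not config.get("pre_tsv"):
        raise ValueError("missing pre-treatment repertoire")
    pre = repertoire.read_bulk_repertoire(config["pre_tsv"], "pre")
    post = repertoire.read_bulk_repertoire(config["post_tsv"], "post")
    paired = repertoire.gate_paired(repertoire.read_single_cell_clonotypes(config["sc_tsv"]))

    enrichments = repertoire.compute_enrichment(pre, post)
    candidates = repertoire.rank_and_select(
        enrichments,
        paired,
        per_class_max=int(config.get("per_class_max", repertoire.PER_CLASS_MAX)),
        total_max=int(config.get("total_max", repertoire.TOTAL_MAX)),
    )

    reactivity = []
    tracked_clones = [c.trb_cdr3_aa for c in candidates]
    if config.get("luminescence_tsv"):
        lum = pd.read_csv(config["luminescence_tsv"], sep="\t")
        reactivity = repertoire.call_reactivity(lum)
        specific = repertoire.specific_tcrs(reactivity)
        if "trb_cdr3_aa" in lum.columns:
            by_tcr = dict(zip(lum["tcr_id"], lum["trb_cdr3_aa"]))
            tracked_clones = sorted({by_tcr[t] for t in specific if t in by_tcr})

    repertoires = {"pre": pre, "post": post}
    if config.get("tumour_tsv"):
        repertoires["tumour"] = repertoire.read_bulk_repertoire(config["tumour_tsv"], "tumour")
    tracking = repertoire.track_clones(tracked_clones, repertoires)

    outputs = {}
    enr_tsv = out_dir / "enrichment.tsv"
    repertoire.enrichment_table(enrichments).to_csv(enr_tsv, sep="\t", index=False)
    outputs["enrichment_tsv"] = enr_tsv
    cand_tsv = out_dir / "candidates.tsv"
    repertoire.enrichment_table(candidates).to_csv(cand_tsv, sep="\t", index=False)
    outputs["candidates_tsv"] = cand_tsv
    if reactivity:
        react_tsv = out_dir / "reactivity.tsv"
        pd.DataFrame(
            {
                "tcr_id": [r.tcr_id for r in reactivity],
                "antigen_id": [r.antigen_id for r in reactivity],
                "hla_allele": [r.hla_allele for r in reactivity],
                "fold_over_control": [r.fold_over_control for r in reactivity],
                "specific": [r.specific for r in reactivity],
            }
        ).to_csv(react_tsv, sep="\t", index=False)
        outputs["reactivity_tsv"] = react_tsv
    track_tsv = out_dir / "tracking.tsv"
    tracking.rename_axis("trb_cdr3_aa").to_csv(track_tsv, sep="\t")
    outputs["tracking_tsv"] = track_tsv
    manifest = _write_manifest(out_dir, "revimmo", config, outputs)
    return {
        "enrichments": enrichments,
        "candidates": candidates,
        "reactivity": reactivity,
        "tracking": tracking,
        "outputs": outputs,
        "manifest": manifest,
    }
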